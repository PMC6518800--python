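"""Benchmark evaluation: top-K precision/recall/fscore, PR curves and AUC,
bipartite density, subcellular weight statistics, frequency-stratified hit
counts, and subsample robustness.

Predictions are the ranked (mutated) genes; the benchmark is the curated
per-cancer driver list.  At a cutoff K: TP = |top-K ∩ benchmark|,
FP = K - TP, FN = |benchmark| - TP, and

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    fscore    = 2 * precision * recall / (precision + recall)

with fscore defined as 0 when precision + recall = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import CohortError, SubdyquencyError
from .io import LocalizationMap
from .matrices import ExpressionMatrix, MutationMatrix
from .outliers import OutlierConfig
from .ranking import RankingResult
from .subcellular import CompartmentCatalog
from .walk import WalkConfig, run_subdyquency

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationMetrics:
    K: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    fscore: float


@dataclass
class PRCurve:
    """Precision/recall at every K = 1..K_max plus the trapezoidal AUC.

    The AUC integrates precision over the recall values traced out by the
    K-sweep (sorted by recall, which is non-decreasing in K); zero-width
    recall segments contribute nothing, so a curve spanning a single recall
    value has AUC 0.
    """

    points: pd.DataFrame  # columns K, precision, recall
    auc: float


@dataclass(frozen=True)
class SubcellularStats:
    """Average localization edge weight for driver vs non-driver mutated genes.

    Undefined quantities (an edge class that is empty) are ``None``, never 0.
    """

    compartment_coverage: float
    avg_driver_outlying_weight: float | None
    avg_nondriver_outlying_weight: float | None
    ratio: float | None


@dataclass
class StratifiedCounts:
    """Benchmark hits in the top K split by mutation count <= cutoff vs >."""

    cutoff: int
    counts: dict[int, tuple[int, int]]  # K -> (low_count, high_count)


def precision_recall_fscore(
    ranking: RankingResult, benchmark: Iterable[str], K: int
) -> EvaluationMetrics:
    """Top-K agreement between the ranking and a benchmark driver set."""
    benchmark = frozenset(benchmark)
    if not benchmark:
        raise SubdyquencyError("benchmark gene set is empty")
    top = ranking.top(K)  # raises for K outside 1..len
    tp = len(set(top) & benchmark)
    fp = K - tp
    fn = len(benchmark) - tp
    precision = tp / K
    recall = tp / len(benchmark)
    denom = precision + recall
    fscore = 2 * precision * recall / denom if denom > 0 else 0.0
    return EvaluationMetrics(K, tp, fp, fn, precision, recall, fscore)


def pr_auc(
    ranking: RankingResult, benchmark: Iterable[str], k_max: int = 200
) -> PRCurve:
    """Precision-recall curve over K = 1..k_max and its trapezoidal AUC."""
    benchmark = frozenset(benchmark)
    if not benchmark:
        raise SubdyquencyError("benchmark gene set is empty")
    if not 1 <= k_max <= len(ranking):
        raise ValueError(f"k_max={k_max} outside 1..{len(ranking)}")
    hits = np.array([g in benchmark for g in ranking.top(k_max)], dtype=float)
    tp = np.cumsum(hits)
    ks = np.arange(1, k_max + 1)
    precision = tp / ks
    recall = tp / len(benchmark)
    order = np.argsort(recall, kind="stable")
    auc = float(np.trapezoid(precision[order], recall[order]))
    points = pd.DataFrame({"K": ks, "precision": precision, "recall": recall})
    return PRCurve(points=points, auc=auc)


def density_degree(n_mutated: int, n_outlying: int, n_edges: int) -> float:
    """Realized bipartite edges divided by all possible mutated x outlying pairs."""
    if n_mutated < 1 or n_outlying < 1:
        raise ValueError("both sides of the bipartite graph must be non-empty")
    possible = n_mutated * n_outlying
    if not 0 <= n_edges <= possible:
        raise ValueError(f"edge count {n_edges} outside 0..{possible}")
    return n_edges / possible


def subcellular_weight_stats(
    edges: Iterable[tuple[str, str, float]],
    drivers: Iterable[str],
    loc: LocalizationMap,
    mutated: Iterable[str],
) -> SubcellularStats:
    """Average edge weight of driver-outlying vs non-driver-outlying pairs.

    ``edges`` are (mutated gene, outlying gene, weight) triples carrying the
    localization weights; ``compartment_coverage`` is the fraction of
    ``mutated`` genes with at least one compartment annotation.
    """
    mutated = set(mutated)
    drivers = set(drivers)
    if not drivers <= mutated:
        raise SubdyquencyError("drivers must be a subset of the mutated gene set")
    driver_w: list[float] = []
    other_w: list[float] = []
    for m, _o, w in edges:
        (driver_w if m in drivers else other_w).append(w)
    avg_driver = float(np.mean(driver_w)) if driver_w else None
    avg_other = float(np.mean(other_w)) if other_w else None
    ratio = (
        avg_driver / avg_other
        if avg_driver is not None and avg_other is not None and avg_other > 0
        else None
    )
    coverage = (
        sum(1 for g in mutated if loc.get(g)) / len(mutated) if mutated else 0.0
    )
    return SubcellularStats(
        compartment_coverage=coverage,
        avg_driver_outlying_weight=avg_driver,
        avg_nondriver_outlying_weight=avg_other,
        ratio=ratio,
    )


def frequency_stratified_counts(
    ranking: RankingResult,
    benchmark: Iterable[str],
    mut: MutationMatrix,
    K_list: Sequence[int],
    cutoff: int = 3,
) -> StratifiedCounts:
    """Benchmark hits among the top K, split into low variation frequency
    (mutated in <= cutoff patients) vs high (> cutoff), for each K."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    benchmark = frozenset(benchmark)
    mut_counts = mut.mutation_counts()
    counts: dict[int, tuple[int, int]] = {}
    for K in K_list:
        top = ranking.top(K)
        low = high = 0
        for g in top:
            if g not in benchmark:
                continue
            if int(mut_counts.get(g, 0)) <= cutoff:
                low += 1
            else:
                high += 1
        counts[K] = (low, high)
    return StratifiedCounts(cutoff=cutoff, counts=counts)


def alpha_sweep(
    mut: MutationMatrix,
    expr: ExpressionMatrix,
    graph: nx.Graph,
    loc: LocalizationMap,
    benchmark: Iterable[str],
    alphas: Sequence[float],
    k_max: int = 200,
    outlier_config: OutlierConfig = OutlierConfig(),
    catalog: CompartmentCatalog | None = None,
) -> pd.DataFrame:
    """PR-AUC of the full pipeline at each damping factor alpha."""
    benchmark = frozenset(benchmark)
    rows = []
    for alpha in alphas:
        ranking = run_subdyquency(
            mut, expr, graph, loc,
            walk_config=WalkConfig(alpha=alpha),
            outlier_config=outlier_config,
            benchmark=benchmark,
            catalog=catalog,
        )
        curve = pr_auc(ranking, benchmark, k_max=min(k_max, len(ranking)))
        rows.append({"alpha": alpha, "auc": curve.auc})
    return pd.DataFrame(rows)


def robustness_subsample(
    mut: MutationMatrix,
    expr: ExpressionMatrix,
    graph: nx.Graph,
    loc: LocalizationMap,
    benchmark: Iterable[str],
    fractions: Sequence[float],
    repeats: int = 10,
    K: int = 200,
    seed: int = 0,
    walk_config: WalkConfig = WalkConfig(),
    outlier_config: OutlierConfig = OutlierConfig(),
    catalog: CompartmentCatalog | None = None,
) -> pd.DataFrame:
    """Mean top-K precision over random patient subsamples of each fraction.

    For each fraction f, ceil(f * N) patients are drawn without replacement
    ``repeats`` times; the full pipeline reruns per subsample (variation
    frequencies recomputed on the subsample) and precisions are averaged.
    Deterministic given ``seed``.  Subsamples where every patient yields an
    empty bipartite graph are skipped with a warning.
    """
    benchmark = frozenset(benchmark)
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fraction {f} outside (0, 1]")
    rng = np.random.default_rng(seed)
    patients = list(mut.patients)
    rows = []
    for f in fractions:
        size = math.ceil(f * len(patients))
        precisions = []
        for _ in range(repeats):
            chosen = list(rng.choice(patients, size=size, replace=False))
            try:
                ranking = run_subdyquency(
                    mut.subset_patients(chosen),
                    expr.subset_patients(chosen),
                    graph, loc,
                    walk_config=walk_config,
                    outlier_config=outlier_config,
                    benchmark=benchmark,
                    catalog=catalog,
                )
            except CohortError:
                logger.warning("subsample at fraction %.2f unusable; skipped", f)
                continue
            k = min(K, len(ranking))
            precisions.append(precision_recall_fscore(ranking, benchmark, k).precision)
        rows.append(
            {
                "fraction": f,
                "mean_precision": float(np.mean(precisions)) if precisions else float("nan"),
                "n_repeats_used": len(precisions),
            }
        )
    return pd.DataFrame(rows)
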