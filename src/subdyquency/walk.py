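"""Per-patient bipartite graphs, the three-pass random walk, and ranking.

For each patient a bipartite graph is built with the patient's mutated genes
on one side and its expression-outlying genes on the other; an edge exists
exactly when the influence network links the pair, and carries the
localization-reliability weight.  Nodes with no edges are dropped from their
side.  With W the n x m weight matrix, M and O the cohort variation
frequencies of the retained mutated / outlying genes and alpha the damping
factor, the walk performs exactly three passes:

    R1_m = alpha * M + (1 - alpha) * W  @ O
    R_o  = alpha * O + (1 - alpha) * W' @ R1_m
    R_m  = alpha * M + (1 - alpha) * W  @ R_o

W is used raw — no row or column normalization — so mutated genes touching
many reliable outlying neighbors accumulate mass, which is the intended
driver signal.  Final scores sum R_m over all patients in which the gene was
retained; genes never entering any bipartite graph are absent from the
ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import CohortError, SubdyquencyError
from .frequency import FrequencyVectors, compute_frequencies
from .io import LocalizationMap
from .matrices import (
    ExpressionMatrix,
    MutationMatrix,
    OutlierMatrix,
    intersect_cohort,
)
from .outliers import OutlierConfig, call_outliers_from_expression
from .ranking import RankingResult
from .subcellular import CompartmentCatalog, build_catalog, edge_weight

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WalkConfig:
    """Walk parameters; alpha in [0, 1] trades own frequency vs network mass."""

    alpha: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class PatientBipartite:
    """One patient's mutated x outlying bipartite graph.

    ``W[i, j] > 0`` iff the influence graph links ``mutated_nodes[i]`` to
    ``outlying_nodes[j]``.  After construction W holds 0/1 adjacency; after
    :func:`weight_bipartite` the positive entries hold localization weights.
    """

    patient: str
    mutated_nodes: list[str]
    outlying_nodes: list[str]
    W: np.ndarray = field(repr=False)

    @property
    def is_empty(self) -> bool:
        return not self.mutated_nodes or not self.outlying_nodes

    @property
    def n_edges(self) -> int:
        return int((self.W > 0).sum())


@dataclass
class WalkScores:
    """Final per-patient scores: R_m over mutated genes, R_o over outlying."""

    patient: str
    rm: dict[str, float]
    ro: dict[str, float]


def build_patient_bipartite(
    patient: str,
    mut: MutationMatrix,
    out: OutlierMatrix,
    graph: nx.Graph,
) -> PatientBipartite:
    """Unweighted bipartite graph for one patient.

    Sides are the patient's mutated / outlying genes present in the influence
    graph; an edge exists iff the influence graph has it; zero-degree nodes
    are dropped from their side.  A gene both mutated and outlying in the
    patient appears on both sides (the influence graph has no self-loops, so
    it never pairs with itself).
    """
    if patient not in set(mut.patients) or patient not in set(out.patients):
        raise CohortError(f"patient {patient!r} missing from the cohort matrices")
    mutated = [g for g in mut.mutated_in(patient) if g in graph]
    outlying_set = {g for g in out.outlying_in(patient) if g in graph}
    if not mutated or not outlying_set:
        logger.debug("patient %s yields an empty bipartite graph", patient)
        return PatientBipartite(patient, [], [], np.zeros((0, 0)))

    neighbor_sets = {g: set(graph[g]) & outlying_set for g in mutated}
    mutated = [g for g in mutated if neighbor_sets[g]]
    connected_outlying = set().union(*(neighbor_sets[g] for g in mutated)) if mutated else set()
    outlying = sorted(connected_outlying)
    if not mutated:
        logger.debug("patient %s yields an empty bipartite graph", patient)
        return PatientBipartite(patient, [], [], np.zeros((0, 0)))

    col = {g: j for j, g in enumerate(outlying)}
    W = np.zeros((len(mutated), len(outlying)))
    for i, g in enumerate(mutated):
        for o in neighbor_sets[g]:
            W[i, col[o]] = 1.0
    return PatientBipartite(patient, mutated, outlying, W)


def weight_bipartite(
    b: PatientBipartite,
    catalog: CompartmentCatalog,
    loc: LocalizationMap,
) -> PatientBipartite:
    """Replace adjacency 1s with localization-reliability edge weights."""
    if b.is_empty:
        return b
    W = b.W.copy()
    for i, gi in enumerate(b.mutated_nodes):
        row = W[i]
        for j in np.nonzero(row)[0]:
            row[j] = edge_weight(catalog, loc, gi, b.outlying_nodes[j])
    return PatientBipartite(b.patient, b.mutated_nodes, b.outlying_nodes, W)


def walk_patient(
    b: PatientBipartite,
    freq: FrequencyVectors,
    cfg: WalkConfig = WalkConfig(),
) -> WalkScores:
    """Run the three walk passes on one weighted patient bipartite graph."""
    if b.is_empty:
        return WalkScores(b.patient, {}, {})
    try:
        M = np.array([freq.mutated[g] for g in b.mutated_nodes])
        O = np.array([freq.outlying[g] for g in b.outlying_nodes])
    except KeyError as exc:
        raise SubdyquencyError(
            f"gene {exc.args[0]!r} has no variation frequency"
        ) from None
    a = cfg.alpha
    r1 = a * M + (1 - a) * (b.W @ O)
    ro = a * O + (1 - a) * (b.W.T @ r1)
    rm = a * M + (1 - a) * (b.W @ ro)
    return WalkScores(
        b.patient,
        rm=dict(zip(b.mutated_nodes, rm.tolist())),
        ro=dict(zip(b.outlying_nodes, ro.tolist())),
    )


def aggregate_and_rank(
    per_patient: list[WalkScores],
    freq: FrequencyVectors,
    benchmark: frozenset[str] | set[str] | None = None,
) -> RankingResult:
    """Sum per-patient R_m scores into the final descending ranking.

    Ties break by higher mutation frequency, then lexicographic gene symbol,
    so the ordering is fully deterministic.
    """
    if not per_patient:
        raise CohortError("no per-patient walk scores to aggregate")
    totals: dict[str, float] = {}
    for scores in per_patient:
        for g, v in scores.rm.items():
            totals[g] = totals.get(g, 0.0) + v
    benchmark = frozenset(benchmark or ())
    records = sorted(
        (
            (-score, -freq.mutated[g], g)
            for g, score in totals.items()
        ),
    )
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(records) + 1),
            "gene": [g for _, _, g in records],
            "score": [-s for s, _, _ in records],
            "mutation_frequency": [-f for _, f, _ in records],
            "is_benchmark": [g in benchmark for _, _, g in records],
        }
    )
    return RankingResult(table)


def run_subdyquency(
    mut: MutationMatrix,
    expr: ExpressionMatrix,
    graph: nx.Graph,
    loc: LocalizationMap,
    walk_config: WalkConfig = WalkConfig(),
    outlier_config: OutlierConfig = OutlierConfig(),
    benchmark: frozenset[str] | set[str] | None = None,
    catalog: CompartmentCatalog | None = None,
) -> RankingResult:
    """End-to-end pipeline: outliers -> frequencies -> per-patient walks -> ranking.

    ``catalog`` defaults to one built from ``loc`` (global compartment
    counts); pass an explicit catalog to use database-wide sizes.
    Deterministic for fixed inputs and configuration.
    """
    mut, expr = intersect_cohort(mut, expr)
    out = call_outliers_from_expression(expr, outlier_config)
    freq = compute_frequencies(mut, out)
    if catalog is None:
        catalog = build_catalog(loc)
    per_patient = []
    n_empty = 0
    for patient in mut.patients:
        b = build_patient_bipartite(patient, mut, out, graph)
        if b.is_empty:
            n_empty += 1
            continue
        b = weight_bipartite(b, catalog, loc)
        per_patient.append(walk_patient(b, freq, walk_config))
    if n_empty:
        logger.warning("%d patient(s) produced empty bipartite graphs", n_empty)
    if not per_patient:
        raise CohortError("every patient produced an empty bipartite graph")
    return aggregate_and_rank(per_patient, freq, benchmark)
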