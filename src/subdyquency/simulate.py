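"""Synthetic tumor cohorts with planted driver genes.

The generator emulates the joint structure the ranking method exploits:
planted drivers mutate more often than passengers, their network neighbors
are pushed to expression-outlier status in the patients where the driver is
mutated, and driver-neighbor pairs are preferentially co-localized in the
largest subcellular compartments.  It emits the same five inputs a real
analysis needs — mutation matrix, expression matrix, influence network,
localization map and benchmark (the planted drivers) — so the full pipeline
is testable without any external download.

Expression is generated as log-normal counts and the planted outliers are
verified against the package's own log2 / z-score / threshold pipeline: the
pushed values are re-checked after cohort standardization and pushed further
until they strictly exceed the default |z| > 2 rule (construction, check and
retry), so "planted" always means "called".

All randomness flows from the single config seed through spawned
sub-streams, one per generation stage (structure, localization, mutations,
expression), so each stage is independently reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .errors import SubdyquencyError
from .io import LocalizationMap
from .matrices import ExpressionMatrix, MutationMatrix
from .subcellular import HUMAN_COMPARTMENT_SIZES

logger = logging.getLogger(__name__)

#: log2-space standard deviation of baseline expression noise
_LOG_SD = 0.25
#: initial planted-outlier offset, in baseline standard deviations
_INITIAL_PUSH = 6.0
#: z threshold the planted outliers are verified against (pipeline default)
_Z_TARGET = 2.0
#: cap on the planted fraction of a gene column.  A standardized column can
#: hold at most ~1/(1+z^2) of its mass beyond z sd (one-sided pushes top out
#: at z = sqrt((1-f)/f)), so f < 0.2 is a hard feasibility bound for z > 2;
#: 0.15 leaves headroom for baseline noise.
_MAX_PLANTED_FRACTION = 0.15


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Rates are per-patient Bernoulli probabilities.  The defaults describe a
    cohort with a strong planted signal: drivers mutate in ~15% of patients
    against a 1% passenger background, carry extra network edges, and drive
    ~40% of their neighbors to outlier status in the patients where they are
    mutated, mostly within shared large compartments.
    """

    n_patients: int = 200
    n_genes: int = 500
    n_drivers: int = 20
    compartments: dict[str, float] = field(
        default_factory=lambda: dict(HUMAN_COMPARTMENT_SIZES)
    )
    driver_mutation_rate: float = 0.15
    passenger_mutation_rate: float = 0.01
    network_degree: float = 6.0
    driver_extra_degree: int = 10
    outlier_base_rate: float = 0.02
    outlier_driven_rate: float = 0.4
    colocalization_bias: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "driver_mutation_rate", "passenger_mutation_rate",
            "outlier_base_rate", "outlier_driven_rate", "colocalization_bias",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0 < self.n_drivers < self.n_genes:
            raise ValueError("need 0 < n_drivers < n_genes")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if any(s <= 0 for s in self.compartments.values()):
            raise ValueError("compartment size weights must be positive")


@dataclass
class SyntheticCohort:
    """The five pipeline inputs plus the planted ground truth.

    ``planted_outliers`` records which (patient, gene) entries the generator
    pushed to outlier status — a diagnostic, not a pipeline input.
    """

    mutation: MutationMatrix
    expression: ExpressionMatrix
    graph: nx.Graph
    localization: LocalizationMap
    true_drivers: frozenset[str]
    planted_outliers: pd.DataFrame = field(repr=False)


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _build_graph(
    genes: list[str], drivers: list[str], cfg: CohortConfig, rng: np.random.Generator
) -> nx.Graph:
    n = len(genes)
    p = min(cfg.network_degree / (n - 1), 1.0)
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < p
    for a, b in zip(iu[mask], ju[mask]):
        graph.add_edge(genes[a], genes[b])
    # extra outlier-neighbor edges per driver
    for d in drivers:
        candidates = [g for g in genes if g != d and not graph.has_edge(d, g)]
        if len(candidates) < cfg.driver_extra_degree:
            raise SubdyquencyError(
                f"driver {d} cannot receive {cfg.driver_extra_degree} extra edges; "
                f"only {len(candidates)} non-adjacent genes remain"
            )
        extra = rng.choice(len(candidates), size=cfg.driver_extra_degree, replace=False)
        for idx in extra:
            graph.add_edge(d, candidates[idx])
    return graph


def _build_localization(
    genes: list[str],
    drivers: list[str],
    graph: nx.Graph,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> LocalizationMap:
    names = list(cfg.compartments)
    weights = np.array([cfg.compartments[c] for c in names], dtype=float)
    probs = weights / weights.sum()
    assignments: dict[str, set[str]] = {}
    for g in genes:
        k = min(int(rng.integers(1, 4)), len(names))
        chosen = rng.choice(len(names), size=k, replace=False, p=probs)
        assignments[g] = {names[i] for i in chosen}
    top2 = [names[i] for i in np.argsort(weights)[::-1][:2]]
    for d in drivers:
        for nb in graph[d]:
            if rng.random() < cfg.colocalization_bias:
                c = top2[int(rng.integers(0, len(top2)))]
                assignments[d].add(c)
                assignments[nb].add(c)
    return {g: frozenset(s) for g, s in assignments.items()}


def _build_mutations(
    patients: list[str],
    genes: list[str],
    drivers: set[str],
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> MutationMatrix:
    rates = np.array(
        [cfg.driver_mutation_rate if g in drivers else cfg.passenger_mutation_rate
         for g in genes]
    )
    m = (rng.random((cfg.n_patients, len(genes))) < rates).astype(np.int8)
    # every planted driver must be mutated somewhere; redraw whole columns so
    # the driver count distribution stays the >=1-truncated Bernoulli sum,
    # the same truncation ranking implicitly applies to passengers
    for j, g in enumerate(genes):
        if g in drivers:
            while m[:, j].sum() == 0:
                m[:, j] = rng.random(cfg.n_patients) < rates[j]
    df = pd.DataFrame(m, index=patients, columns=genes)
    return MutationMatrix(df)


def _build_expression(
    patients: list[str],
    genes: list[str],
    drivers: list[str],
    graph: nx.Graph,
    mutation: MutationMatrix,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    n_p, n_g = len(patients), len(genes)
    gene_index = {g: j for j, g in enumerate(genes)}
    mu = rng.uniform(3.0, 10.0, size=n_g)
    log_expr = rng.normal(mu, _LOG_SD, size=(n_p, n_g))

    # an entry's outlier probability is outlier_driven_rate when the gene
    # neighbors a driver mutated in that patient, outlier_base_rate otherwise
    # (one draw per entry, so driven == base is an exact null)
    adj = np.zeros((len(drivers), n_g), dtype=bool)
    for k, d in enumerate(drivers):
        for nb in graph[d]:
            adj[k, gene_index[nb]] = True
    mut_genes = mutation.genes
    driver_mut = np.column_stack(
        [mutation.data[d].to_numpy() if d in mut_genes else np.zeros(n_p, dtype=np.int8)
         for d in drivers]
    )
    driven_mask = (driver_mut @ adj) > 0
    prob = np.where(driven_mask, cfg.outlier_driven_rate, cfg.outlier_base_rate)
    planted = rng.random((n_p, n_g)) < prob

    # push planted entries upward, then verify against the pipeline's own
    # z-scoring; grow the offset until every planted call strictly clears
    # the threshold (planting inflates the column sd, so one pass can
    # undershoot when many patients share a planted gene)
    max_planted = max(1, int(_MAX_PLANTED_FRACTION * n_p))
    for j in range(n_g):
        rows = np.nonzero(planted[:, j])[0]
        if len(rows) > max_planted:
            # cohort z-scoring cannot call this many same-gene outliers;
            # keep a random feasible subset
            keep = rng.choice(len(rows), size=max_planted, replace=False)
            drop = np.setdiff1d(np.arange(len(rows)), keep)
            planted[rows[drop], j] = False
            rows = rows[np.sort(keep)]
        if len(rows) == 0:
            continue
        push = _INITIAL_PUSH
        for _ in range(60):
            log_expr[rows, j] = mu[j] + push * _LOG_SD
            col = log_expr[:, j]
            z = (col - col.mean()) / col.std(ddof=1)
            if (z[rows] > _Z_TARGET).all():
                break
            push *= 1.5
        else:  # pragma: no cover - offset growth always terminates in practice
            raise SubdyquencyError(f"could not plant outliers for gene {genes[j]}")

    values = np.maximum(np.exp2(log_expr) - 1.0, 0.0)
    expr = ExpressionMatrix(pd.DataFrame(values, index=patients, columns=genes))
    planted_df = pd.DataFrame(planted.astype(np.int8), index=patients, columns=genes)
    return expr, planted_df


def generate_cohort(cfg: CohortConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort; deterministic given ``cfg.seed``."""
    stage_seeds = np.random.SeedSequence(cfg.seed).spawn(5)
    rng_struct, rng_loc, rng_mut, rng_expr, rng_pick = (
        np.random.default_rng(s) for s in stage_seeds
    )
    genes = _gene_ids(cfg.n_genes)
    drivers = sorted(
        genes[i] for i in rng_pick.choice(cfg.n_genes, size=cfg.n_drivers, replace=False)
    )
    graph = _build_graph(genes, drivers, cfg, rng_struct)
    localization = _build_localization(genes, drivers, graph, cfg, rng_loc)
    patients = [f"P{i:04d}" for i in range(1, cfg.n_patients + 1)]
    mutation = _build_mutations(patients, genes, set(drivers), cfg, rng_mut)
    expression, planted = _build_expression(
        patients, genes, drivers, graph, mutation, cfg, rng_expr
    )
    return SyntheticCohort(
        mutation=mutation,
        expression=expression,
        graph=graph,
        localization=localization,
        true_drivers=frozenset(drivers),
        planted_outliers=planted,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the five standard input files; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": out_dir / "mutations.tsv",
        "expression": out_dir / "expression.tsv",
        "network": out_dir / "network.tsv",
        "localization": out_dir / "localization.tsv",
        "benchmark": out_dir / "drivers.txt",
    }
    cohort.mutation.data.to_csv(paths["mutations"], sep="\t")
    cohort.expression.data.to_csv(paths["expression"], sep="\t")
    with open(paths["network"], "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in cohort.graph.edges):
            fh.write(f"{a}\t{b}\n")
    with open(paths["localization"], "w") as fh:
        for g in sorted(cohort.localization):
            for c in sorted(cohort.localization[g]):
                fh.write(f"{g}\t{c}\n")
    with open(paths["benchmark"], "w") as fh:
        for g in sorted(cohort.true_drivers):
            fh.write(g + "\n")
    return paths


def load_config(path: str | Path) -> CohortConfig:
    """Load a :class:`CohortConfig` from a YAML mapping (missing keys default)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SubdyquencyError(f"{path}: cohort config must be a YAML mapping")
    known = set(CohortConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise SubdyquencyError(f"{path}: unknown config keys {sorted(unknown)}")
    return CohortConfig(**raw)


def dump_config(cfg: CohortConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
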