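import numpy as np
import pandas as pd
import pytest

from subdyquency import (
    HUMAN_COMPARTMENT_SIZES,
    CohortConfig,
    RankingResult,
    build_catalog,
    generate_cohort,
)


@pytest.fixture(scope="session")
def human_catalog():
    """Catalog built from the 11-compartment human size table."""
    return build_catalog(HUMAN_COMPARTMENT_SIZES)


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-driver cohort shared by integration-style tests."""
    cfg = CohortConfig(
        n_patients=40, n_genes=60, n_drivers=5, driver_extra_degree=5, seed=11
    )
    return generate_cohort(cfg)


def make_ranking(genes, benchmark=(), scores=None, frequencies=None):
    """Build a RankingResult with the given gene order (scores descending)."""
    n = len(genes)
    if scores is None:
        scores = np.linspace(1.0, 0.1, n) if n else []
    if frequencies is None:
        frequencies = [0.5] * n
    benchmark = set(benchmark)
    return RankingResult(
        pd.DataFrame(
            {
                "rank": np.arange(1, n + 1),
                "gene": list(genes),
                "score": list(scores),
                "mutation_frequency": list(frequencies),
                "is_benchmark": [g in benchmark for g in genes],
            }
        )
    )
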