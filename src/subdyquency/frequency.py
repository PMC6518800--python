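"""Cohort variation frequencies used to initialize the random walk.

A mutated gene's variation frequency M(g) is the fraction of cohort patients
in which it carries a mutation.  An outlying gene's frequency O(g) follows a
two-condition rule: if the gene is also mutated in at least one patient its
frequency equals its mutation frequency; a never-mutated outlying gene gets
the floor value 1/N, one event out of the total sample count.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import CohortError
from .matrices import MutationMatrix, OutlierMatrix


@dataclass(frozen=True)
class FrequencyVectors:
    """Cohort size N plus the mutated (M) and outlying (O) frequency maps."""

    n: int
    mutated: dict[str, float]
    outlying: dict[str, float]


def mutation_frequency(mut: MutationMatrix) -> dict[str, float]:
    """M(g) = (#patients with a mutation in g) / N for every mutated gene."""
    n = mut.n_patients
    if n < 1:
        raise CohortError("mutation matrix has an empty cohort")
    counts = mut.mutation_counts()
    return {g: c / n for g, c in counts.items() if c >= 1}


def outlying_frequency(mut: MutationMatrix, out: OutlierMatrix) -> dict[str, float]:
    """O(g) for every gene outlying in >= 1 patient.

    Equals the mutation frequency when the gene is mutated somewhere in the
    cohort, otherwise 1/N.
    """
    if set(mut.patients) != set(out.patients):
        raise CohortError("mutation and outlier matrices cover different cohorts")
    n = mut.n_patients
    if n < 1:
        raise CohortError("empty cohort")
    mut_counts = mut.mutation_counts()
    freqs: dict[str, float] = {}
    for g, c in out.outlier_counts().items():
        if c < 1:
            continue
        m = int(mut_counts.get(g, 0))
        freqs[g] = m / n if m >= 1 else 1.0 / n
    return freqs


def compute_frequencies(mut: MutationMatrix, out: OutlierMatrix) -> FrequencyVectors:
    """Both frequency maps for a cohort, bundled with N."""
    return FrequencyVectors(
        n=mut.n_patients,
        mutated=mutation_frequency(mut),
        outlying=outlying_frequency(mut, out),
    )
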