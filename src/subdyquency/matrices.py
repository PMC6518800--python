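"""Patient x gene matrices used throughout the pipeline.

All three matrix types wrap a :class:`pandas.DataFrame` whose index holds
patient identifiers and whose columns hold gene symbols.  Validation happens
at construction so downstream code can rely on the invariants (binary values,
unique identifiers, finite non-negative expression).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CohortError, FormatError

logger = logging.getLogger(__name__)


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} identifiers: {dups[:5]}")


def _check_binary(df: pd.DataFrame, what: str) -> None:
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{what} matrix entry for patient {df.index[r]!r}, gene "
            f"{df.columns[c]!r} is {values[r, c]!r}; expected 0 or 1"
        )


@dataclass
class MutationMatrix:
    """Binary patient x gene incidence of non-silent somatic mutations.

    A gene is *mutated* when it carries a mutation in at least one patient;
    all-zero gene columns are dropped at construction (with a warning) so
    every column of ``data`` corresponds to a mutated gene.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "patient")
        _check_unique(self.data.columns, "gene")
        _check_binary(self.data, "mutation")
        self.data = self.data.astype(np.int8)
        empty = self.data.columns[self.data.sum(axis=0) == 0]
        if len(empty):
            logger.warning(
                "dropping %d gene column(s) with no mutation events", len(empty)
            )
            self.data = self.data.drop(columns=empty)

    @property
    def patients(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_patients(self) -> int:
        return len(self.data.index)

    def mutated_in(self, patient: str) -> list[str]:
        """Genes mutated in one patient."""
        row = self.data.loc[patient]
        return list(row.index[row.to_numpy() == 1])

    def mutation_counts(self) -> pd.Series:
        """Per-gene number of patients carrying a mutation."""
        return self.data.sum(axis=0)

    def subset_patients(self, patients: list[str]) -> "MutationMatrix":
        return MutationMatrix(self.data.loc[list(patients)].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MutationMatrix):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class OutlierMatrix:
    """Binary patient x gene matrix; 1 marks a gene expression-outlying in a patient."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "patient")
        _check_unique(self.data.columns, "gene")
        _check_binary(self.data, "outlier")
        self.data = self.data.astype(np.int8)

    @property
    def patients(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def outlying_in(self, patient: str) -> list[str]:
        row = self.data.loc[patient]
        return list(row.index[row.to_numpy() == 1])

    def outlier_counts(self) -> pd.Series:
        return self.data.sum(axis=0)

    def subset_patients(self, patients: list[str]) -> "OutlierMatrix":
        return OutlierMatrix(self.data.loc[list(patients)].copy())


@dataclass
class ExpressionMatrix:
    """Patient x gene expression values: raw read counts or pre-normalized."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "patient")
        _check_unique(self.data.columns, "gene")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise FormatError("expression matrix contains non-finite values")
        if (values < 0).any():
            raise FormatError("expression matrix contains negative values")
        self.data = self.data.astype(float)

    @property
    def patients(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def subset_patients(self, patients: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(patients)].copy())


def intersect_cohort(
    mut: MutationMatrix, expr: ExpressionMatrix
) -> tuple[MutationMatrix, ExpressionMatrix]:
    """Restrict both matrices to patients present in each.

    Patients missing from either input are dropped with a warning; the
    analysis cohort is always the intersection.
    """
    shared = [p for p in mut.patients if p in set(expr.patients)]
    dropped = (len(mut.patients) - len(shared)) + (len(expr.patients) - len(shared))
    if dropped:
        logger.warning(
            "dropping %d patient(s) absent from one of mutation/expression inputs",
            dropped,
        )
    if not shared:
        raise CohortError("no patients shared between mutation and expression data")
    return mut.subset_patients(shared), expr.subset_patients(shared)
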