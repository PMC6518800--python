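"""Per-patient expression-outlier calling via cohort z-scores.

A gene is called outlying in a patient when its (optionally log2-transformed)
expression z-score across the tumor cohort is strictly beyond +/- threshold
(default 2.0).  Standardization is per gene, across patients, with the sample
(n-1) standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CohortError, FormatError
from .matrices import ExpressionMatrix, OutlierMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutlierConfig:
    """Outlier-calling parameters.

    z_threshold
        absolute z-score beyond which a gene is outlying (strict inequality).
    log_transform
        apply log2(x + 1) before standardizing; disable for matrices that are
        already variance-stabilized / normalized.
    """

    z_threshold: float = 2.0
    log_transform: bool = True

    def __post_init__(self) -> None:
        if not self.z_threshold > 0:
            raise ValueError("z_threshold must be positive")


def zscore_transform(expr: ExpressionMatrix, log_transform: bool = True) -> pd.DataFrame:
    """Per-gene z-scores across the cohort, after optional log2(x+1).

    Genes with zero variance across patients get an all-zero z column (they
    can never be outlying) and a logged warning.
    """
    if len(expr.patients) < 2:
        raise CohortError("z-scoring requires at least 2 patients (sample sd undefined)")
    values = expr.data.to_numpy(dtype=float)
    if log_transform:
        values = np.log2(values + 1.0)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning(
            "%d gene(s) have zero expression variance; their z-scores are 0",
            int(zero_var.sum()),
        )
    safe_sd = np.where(zero_var, 1.0, sd)
    z = (values - mean) / safe_sd
    z[:, zero_var] = 0.0
    return pd.DataFrame(z, index=expr.data.index, columns=expr.data.columns)


def call_outliers(z: pd.DataFrame, config: OutlierConfig = OutlierConfig()) -> OutlierMatrix:
    """Threshold a z-score matrix into binary outlier calls.

    An entry is 1 iff z > threshold or z < -threshold (strict inequalities).
    """
    values = z.to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"non-finite z-score for patient {z.index[r]!r}, gene {z.columns[c]!r}"
        )
    calls = (values > config.z_threshold) | (values < -config.z_threshold)
    return OutlierMatrix(
        pd.DataFrame(calls.astype(np.int8), index=z.index, columns=z.columns)
    )


def call_outliers_from_expression(
    expr: ExpressionMatrix, config: OutlierConfig = OutlierConfig()
) -> OutlierMatrix:
    """Convenience composition of :func:`zscore_transform` and :func:`call_outliers`."""
    return call_outliers(zscore_transform(expr, config.log_transform), config)
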