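"""Ranked gene lists produced by the walk and consumed by the evaluators."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError

#: column order of the tabular representation
RANKING_COLUMNS = ("rank", "gene", "score", "mutation_frequency", "is_benchmark")


@dataclass
class RankingResult:
    """Genes ordered by descending final walk score.

    ``table`` has columns ``rank`` (1-based, contiguous), ``gene``, ``score``
    (non-negative, non-increasing), ``mutation_frequency`` (cohort variation
    frequency in (0, 1]) and ``is_benchmark`` (True when the gene appears in
    the supplied benchmark list; all False when no benchmark was given).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(RANKING_COLUMNS) - set(self.table.columns)
        if missing:
            raise FormatError(f"ranking table missing columns: {sorted(missing)}")
        self.table = self.table.loc[:, list(RANKING_COLUMNS)].reset_index(drop=True)
        ranks = self.table["rank"].to_numpy()
        if len(ranks) and not np.array_equal(ranks, np.arange(1, len(ranks) + 1)):
            raise FormatError("ranks must be contiguous 1..N in order")
        scores = self.table["score"].to_numpy(dtype=float)
        if len(scores) and (np.diff(scores) > 1e-12).any():
            raise FormatError("scores must be non-increasing with rank")
        if len(scores) and (scores < 0).any():
            raise FormatError("scores must be non-negative")
        self.table["is_benchmark"] = self.table["is_benchmark"].astype(bool)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def top(self, k: int) -> list[str]:
        """The top-``k`` ranked gene symbols."""
        if not 1 <= k <= len(self):
            raise ValueError(f"K={k} outside 1..{len(self)}")
        return list(self.table["gene"].iloc[:k])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RankingResult):
            return NotImplemented
        return self.table.equals(other.table)
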