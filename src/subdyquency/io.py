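"""Readers and writers for the tabular input/output formats.

Supported inputs are plain delimited text (tab by default): wide or long
mutation matrices, a wide expression matrix, a two-column gene-gene edge
list, a two-column gene -> compartment assignment file and a one-symbol-per-
line benchmark driver list.  Readers are strict: malformed rows raise a
:class:`~subdyquency.errors.FormatError` instead of being skipped.

Gene symbols are matched exactly (case-sensitive, no alias resolution);
:func:`warn_case_collisions` reports symbols that differ only by case across
input files, which usually signals an upstream identifier problem.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError
from .matrices import ExpressionMatrix, MutationMatrix
from .ranking import RANKING_COLUMNS, RankingResult

logger = logging.getLogger(__name__)

LocalizationMap = dict[str, frozenset[str]]


def read_mutation_matrix(
    path: str | Path, form: str = "wide", delimiter: str = "\t"
) -> MutationMatrix:
    """Read a binary patient x gene mutation matrix.

    ``form="wide"``: header row of gene symbols, first column patient ids,
    cells 0/1.  ``form="long"``: two columns (patient, gene), one row per
    mutation event; duplicate events collapse to a single 1.
    """
    if form == "wide":
        df = pd.read_csv(path, sep=delimiter, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return MutationMatrix(df)
    if form == "long":
        pairs = _read_two_column(path, delimiter, what="mutation event")
        patients = list(dict.fromkeys(p for p, _ in pairs))
        genes = sorted({g for _, g in pairs})
        df = pd.DataFrame(0, index=patients, columns=genes, dtype=np.int8)
        for p, g in pairs:
            df.loc[p, g] = 1
        return MutationMatrix(df)
    raise ValueError(f"unknown mutation matrix form {form!r}")


def read_expression_matrix(path: str | Path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a wide patient x gene expression matrix (counts or normalized)."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df)


def _read_two_column(
    path: str | Path, delimiter: str, what: str
) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(delimiter)
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 fields for {what}, "
                    f"got {len(fields)}"
                )
            pairs.append((fields[0], fields[1]))
    return pairs


def read_influence_graph(path: str | Path, delimiter: str = "\t") -> nx.Graph:
    """Read an undirected gene-gene edge list.

    Self-loops are dropped with a logged warning; reversed duplicate edges
    collapse to a single undirected edge.
    """
    graph = nx.Graph()
    n_self = 0
    for a, b in _read_two_column(path, delimiter, what="edge"):
        if a == b:
            n_self += 1
            continue
        graph.add_edge(a, b)
    if n_self:
        logger.warning("dropped %d self-loop edge(s)", n_self)
    return graph


def read_localization(path: str | Path, delimiter: str = "\t") -> LocalizationMap:
    """Read gene -> compartment assignments, one (gene, compartment) row each."""
    assignments: dict[str, set[str]] = {}
    for gene, compartment in _read_two_column(path, delimiter, what="assignment"):
        if not compartment:
            raise FormatError(f"{path}: empty compartment name for gene {gene!r}")
        assignments.setdefault(gene, set()).add(compartment)
    return {g: frozenset(c) for g, c in assignments.items()}


def read_benchmark(path: str | Path) -> frozenset[str]:
    """Read a one-gene-symbol-per-line benchmark driver list."""
    with open(path) as fh:
        genes = {line.strip() for line in fh if line.strip()}
    return frozenset(genes)


def write_ranking(ranking: RankingResult, path: str | Path, delimiter: str = "\t") -> None:
    """Write a ranking as a delimited table; re-reading reproduces it exactly."""
    ranking.table.to_csv(path, sep=delimiter, index=False, columns=list(RANKING_COLUMNS))


def read_ranking(path: str | Path, delimiter: str = "\t") -> RankingResult:
    df = pd.read_csv(path, sep=delimiter)
    if list(df.columns) != list(RANKING_COLUMNS):
        raise FormatError(
            f"{path}: expected ranking columns {list(RANKING_COLUMNS)}, got {list(df.columns)}"
        )
    if len(df):
        df["gene"] = df["gene"].astype(str)
    else:
        df = df.astype(
            {"rank": int, "gene": str, "score": float,
             "mutation_frequency": float, "is_benchmark": bool}
        )
    return RankingResult(df)


def warn_case_collisions(*symbol_sets: Iterable[str]) -> set[frozenset[str]]:
    """Report gene symbols that differ only by letter case across inputs.

    Returns the set of colliding symbol groups (also logged as warnings);
    symbols are never folded or merged.
    """
    by_fold: dict[str, set[str]] = {}
    for symbols in symbol_sets:
        for s in symbols:
            by_fold.setdefault(s.casefold(), set()).add(s)
    collisions = {frozenset(group) for group in by_fold.values() if len(group) > 1}
    for group in collisions:
        logger.warning("gene symbols differ only by case: %s", sorted(group))
    return collisions
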