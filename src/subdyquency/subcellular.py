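"""Compartment significance scores and localization-based edge weights.

Each subcellular compartment I gets a significance score

    SC(I) = C_X(I) / C_M

where C_X(I) is the number of proteins annotated to I and C_M is the size of
the largest compartment, so SC lies in (0, 1] and the largest compartment
scores exactly 1.  An interaction between genes i and j is weighted by the
maximum SC over their shared compartments; pairs with no shared compartment
(including genes with no annotation at all) fall back to the minimum
significance SC(C_N) = C_N / C_M, the score of the smallest compartment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .errors import SubdyquencyError
from .io import LocalizationMap

#: Protein counts of the 11 canonical human compartments in the subcellular
#: localization database release used for weighting.  Shipped as a documented
#: default; any compartment->size table may be supplied instead.
HUMAN_COMPARTMENT_SIZES: dict[str, int] = {
    "Nucleus": 13938,
    "Cytosol": 13726,
    "Cytoskeleton": 3236,
    "Peroxisome": 4605,
    "Lysosome": 1906,
    "Endoplasmic reticulum": 4160,
    "Golgi apparatus": 3275,
    "Plasma membrane": 8719,
    "Endosome": 825,
    "Extracellular space": 8589,
    "Mitochondrion": 7130,
}


@dataclass(frozen=True)
class CompartmentCatalog:
    """Compartment sizes plus the derived significance scores.

    sizes
        compartment name -> positive protein/gene count C_X.
    c_max, c_min
        largest and smallest compartment sizes (C_M, C_N).
    sc
        compartment name -> significance C_X / C_M in (0, 1].
    """

    sizes: dict[str, float]
    c_max: float
    c_min: float
    sc: dict[str, float]

    @property
    def min_weight(self) -> float:
        """SC of the smallest compartment — the no-shared-compartment fallback."""
        return self.c_min / self.c_max

    def significance_score(self, compartment: str) -> float:
        try:
            return self.sc[compartment]
        except KeyError:
            raise KeyError(f"unknown compartment {compartment!r}") from None


def build_catalog(
    source: LocalizationMap | Mapping[str, float],
) -> CompartmentCatalog:
    """Build a catalog from a localization map or an explicit size table.

    From a gene -> compartment-set map, a compartment's size is its number of
    distinct annotated genes.  A mapping of compartment -> positive number is
    taken verbatim as the size table.
    """
    if not source:
        raise SubdyquencyError("cannot build a compartment catalog from an empty source")
    first = next(iter(source.values()))
    if isinstance(first, (int, float)):
        sizes = {str(k): float(v) for k, v in source.items()}
        for name, size in sizes.items():
            if not size > 0:
                raise SubdyquencyError(f"compartment {name!r} has non-positive size {size}")
    else:
        counts: dict[str, int] = {}
        for compartments in source.values():
            for c in compartments:
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            raise SubdyquencyError("localization map assigns no compartments")
        sizes = {k: float(v) for k, v in counts.items()}
    c_max = max(sizes.values())
    c_min = min(sizes.values())
    sc = {name: size / c_max for name, size in sizes.items()}
    return CompartmentCatalog(sizes=sizes, c_max=c_max, c_min=c_min, sc=sc)


def significance_score(catalog: CompartmentCatalog, compartment: str) -> float:
    """SC(I) = C_X(I) / C_M for a compartment of the catalog."""
    return catalog.significance_score(compartment)


def edge_weight(
    catalog: CompartmentCatalog, loc: LocalizationMap, i: str, j: str
) -> float:
    """Localization-reliability weight of the interaction between genes i and j.

    The maximum significance score over shared compartments, or the minimum
    compartment significance SC(C_N) when the genes share none (genes absent
    from ``loc`` have an empty compartment set).
    """
    shared = frozenset(loc.get(i, ())) & frozenset(loc.get(j, ()))
    if shared:
        return max(catalog.sc[c] for c in shared)
    return catalog.min_weight
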