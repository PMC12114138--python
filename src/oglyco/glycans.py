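"""Built-in glycan compositions and the 2-AB released-glycan library.

The library covers the mucin core 1 family observed on CTP-fusion proteins:
the four major glycoforms (core 1 and its mono-/di-sialylated extensions,
including the branched monosialyl isomer), the alkaline peeling byproducts
(NeuAcGal, NeuAc) and the mono-deacetylated species.  Isomers share a
composition and are told apart only by retention-time windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from .masses import GlycanComposition, GlycanLabel, GlycanSpecies, GlycanState

__all__ = [
    "CORE1",
    "CORE1_NEUAC1",
    "CORE1_NEUAC2",
    "DEFAULT_ALLOWED_GLYCANS",
    "LibraryEntry",
    "DEFAULT_LIBRARY",
    "MAJOR_GLYCAN_NAMES",
    "species_category",
]

CORE1 = GlycanComposition(HexNAc=1, Hex=1)
CORE1_NEUAC1 = GlycanComposition(HexNAc=1, Hex=1, NeuAc=1)
CORE1_NEUAC2 = GlycanComposition(HexNAc=1, Hex=1, NeuAc=2)

#: Glycan set used for glycopeptide searches (pre-sialidase).
DEFAULT_ALLOWED_GLYCANS: Tuple[GlycanComposition, ...] = (
    CORE1,
    CORE1_NEUAC1,
    CORE1_NEUAC2,
)


@dataclass(frozen=True)
class LibraryEntry:
    species: GlycanSpecies
    category: str  # major_glycan | peeling_byproduct | deacetylation_byproduct
    rt_window: Optional[Tuple[float, float]] = None  # minutes
    parent: Optional[str] = None  # short_name of parent species for byproducts


def _ab(name: str, comp: GlycanComposition, state: GlycanState = GlycanState.INTACT) -> GlycanSpecies:
    return GlycanSpecies(name, comp, GlycanLabel.TWO_AB, state)


MAJOR_GLYCAN_NAMES: Tuple[str, ...] = (
    "GalGalNAc",
    "NeuAcGalGalNAc",
    "Gal(NeuAcGalNAc)",
    "NeuAcGal(NeuAcGalNAc)",
)

DEFAULT_LIBRARY: Tuple[LibraryEntry, ...] = (
    LibraryEntry(_ab("GalGalNAc", CORE1), "major_glycan", (7.0, 9.0)),
    LibraryEntry(_ab("NeuAcGalGalNAc", CORE1_NEUAC1), "major_glycan", (12.4, 13.4)),
    LibraryEntry(_ab("Gal(NeuAcGalNAc)", CORE1_NEUAC1), "major_glycan", (13.4, 14.4)),
    LibraryEntry(_ab("NeuAcGal(NeuAcGalNAc)", CORE1_NEUAC2), "major_glycan", (15.5, 16.5)),
    LibraryEntry(
        _ab("NeuAcGal", GlycanComposition(Hex=1, NeuAc=1)),
        "peeling_byproduct",
        (10.6, 11.3),
    ),
    LibraryEntry(
        _ab("NeuAc", GlycanComposition(NeuAc=1)),
        "peeling_byproduct",
        (11.3, 11.8),
    ),
    LibraryEntry(
        _ab("NeuAcGalGalNAc-deAc", CORE1_NEUAC1, GlycanState.MONO_DEACETYLATED),
        "deacetylation_byproduct",
        (14.6, 15.5),
        parent="NeuAcGalGalNAc",
    ),
    LibraryEntry(
        _ab("NeuAcGal(NeuAcGalNAc)-deAc", CORE1_NEUAC2, GlycanState.MONO_DEACETYLATED),
        "deacetylation_byproduct",
        (16.8, 17.8),
        parent="NeuAcGal(NeuAcGalNAc)",
    ),
)


def species_category(species: GlycanSpecies) -> str:
    """Infer the profiling category of a glycan species from its structure.

    Mono-deacetylated species are deacetylation byproducts; species lacking
    the core HexNAc are peeling byproducts; everything else is a major glycan.
    """
    if species.state is GlycanState.MONO_DEACETYLATED:
        return "deacetylation_byproduct"
    if species.composition.get("HexNAc") == 0:
        return "peeling_byproduct"
    return "major_glycan"
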