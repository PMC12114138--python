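"""Monoisotopic mass arithmetic for peptides, glycans and glycopeptide ions.

Every other module in the package computes masses exclusively through the
functions defined here.  All masses are monoisotopic and expressed in daltons;
``m/z`` values use the proton mass (not the hydrogen-atom mass) for charging.

Conventions
-----------
* Peptide "neutral mass" is the sum of residue masses plus one water.
* Glycan compositions are counted in *residue* (dehydrated) form; the free
  reducing glycan adds one water.
* 2-AB labeling (reductive amination with 2-aminobenzamide) adds a net
  +120.068748 Da to the free reducing glycan (+C7H8N2O - H2O + H2).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence, Tuple

__all__ = [
    "RESIDUE_MASSES",
    "MONOSACCHARIDE_MASSES",
    "VARIABLE_MODS",
    "WATER",
    "PROTON",
    "TWO_AB_NET",
    "ACETYL",
    "HEXNAC_REMNANT",
    "NH3",
    "HYDROGEN",
    "GlycanComposition",
    "GlycanLabel",
    "GlycanState",
    "GlycanSpecies",
    "peptide_neutral_mass",
    "glycan_neutral_mass",
    "labeled_glycan_mz",
    "glycopeptide_precursor_mz",
    "mz_from_neutral",
    "neutral_from_mz",
    "ppm_error",
]

# Monoisotopic residue (dehydrated) masses of the 20 standard amino acids.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

# Monosaccharide residue masses; these four names are the only composition
# keys accepted anywhere downstream.
MONOSACCHARIDE_MASSES: dict[str, float] = {
    "HexNAc": 203.079373,
    "Hex": 162.052824,
    "NeuAc": 291.095417,
    "Fuc": 146.057909,
}

WATER = 18.010565
PROTON = 1.0072765
HYDROGEN = 1.007825
NH3 = 17.026549
TWO_AB_NET = 120.068748  # net mass added by 2-AB reductive amination
ACETYL = 42.010565
HEXNAC_REMNANT = 203.079373

# Variable modifications (delta masses as configured for the search).
VARIABLE_MODS: dict[str, float] = {
    "oxidation": 15.995,
    "deamidation": 0.9804,
}


class GlycanLabel(str, Enum):
    NONE = "none"
    TWO_AB = "two_AB"


class GlycanState(str, Enum):
    INTACT = "intact"
    MONO_DEACETYLATED = "mono_deacetylated"


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide counts naming a glycoform, e.g. HexNAc(1)Hex(1)."""

    counts: Tuple[Tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int] | Iterable[Tuple[str, int]] = (), **kw: int):
        items = dict(counts)
        items.update(kw)
        for key, n in items.items():
            if key not in MONOSACCHARIDE_MASSES:
                raise ValueError(f"unknown monosaccharide {key!r}")
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {key} must be a non-negative integer, got {n!r}")
        canonical = tuple(
            (key, items[key]) for key in MONOSACCHARIDE_MASSES if items.get(key, 0) > 0
        )
        object.__setattr__(self, "counts", canonical)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def get(self, key: str) -> int:
        return dict(self.counts).get(key, 0)

    @property
    def is_empty(self) -> bool:
        return not self.counts

    @property
    def total(self) -> int:
        return sum(n for _, n in self.counts)

    def __str__(self) -> str:  # HexNAc(1)Hex(1) style
        return "".join(f"{k}({n})" for k, n in self.counts) or "empty"


@dataclass(frozen=True)
class GlycanSpecies:
    """A named glycan entity: composition plus label and acetylation state.

    ``short_name`` is unique within a library; isomeric species (identical
    composition, distinct chromatographic behavior) carry distinct names.
    """

    short_name: str
    composition: GlycanComposition
    label: GlycanLabel = GlycanLabel.NONE
    state: GlycanState = GlycanState.INTACT

    def __post_init__(self) -> None:
        if self.composition.is_empty:
            raise ValueError(f"{self.short_name}: empty composition")
        if self.state is GlycanState.MONO_DEACETYLATED and self.composition.get("NeuAc") < 1:
            raise ValueError(
                f"{self.short_name}: mono-deacetylation requires at least one NeuAc"
            )


def peptide_neutral_mass(
    sequence: str, mods: Sequence[Tuple[int, str]] = ()
) -> float:
    """Neutral monoisotopic mass of a peptide: residues + water + mod deltas.

    ``mods`` is a list of ``(position, mod_name)`` with 1-based positions.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    total = WATER
    for i, letter in enumerate(sequence, start=1):
        try:
            total += RESIDUE_MASSES[letter]
        except KeyError:
            raise ValueError(f"unknown residue {letter!r} at position {i}") from None
    for pos, name in mods:
        if not 1 <= pos <= len(sequence):
            raise ValueError(f"modification position {pos} outside 1..{len(sequence)}")
        try:
            total += VARIABLE_MODS[name]
        except KeyError:
            raise ValueError(f"unknown modification {name!r}") from None
    return total


def glycan_neutral_mass(comp: GlycanComposition, form: str = "residue") -> float:
    """Neutral mass of a glycan composition.

    ``form='residue'`` sums dehydrated residue masses; ``'free_reducing'``
    adds one water for the released glycan.
    """
    if comp.is_empty:
        raise ValueError("empty glycan composition")
    mass = sum(MONOSACCHARIDE_MASSES[k] * n for k, n in comp.counts)
    if form == "free_reducing":
        mass += WATER
    elif form != "residue":
        raise ValueError(f"unknown form {form!r}")
    return mass


def mz_from_neutral(neutral: float, charge: int) -> float:
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral + charge * PROTON) / charge


def neutral_from_mz(mz: float, charge: int) -> float:
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * PROTON


def labeled_glycan_mz(species: GlycanSpecies, charge: int = 1) -> float:
    """m/z of a 2-AB labeled glycan species (optionally mono-deacetylated)."""
    if species.label is not GlycanLabel.TWO_AB:
        raise ValueError("labeled_glycan_mz requires a 2-AB labeled species")
    neutral = glycan_neutral_mass(species.composition, "free_reducing") + TWO_AB_NET
    if species.state is GlycanState.MONO_DEACETYLATED:
        neutral -= ACETYL
    return mz_from_neutral(neutral, charge)


def glycopeptide_precursor_mz(
    sequence: str,
    site_glycans: Mapping[int, GlycanComposition],
    charge: int,
    mods: Sequence[Tuple[int, str]] = (),
) -> float:
    """Precursor m/z of a glycopeptide; glycan positions are 1-based within
    ``sequence`` and must fall on S or T."""
    neutral = peptide_neutral_mass(sequence, mods)
    for pos, comp in site_glycans.items():
        if not 1 <= pos <= len(sequence):
            raise ValueError(f"glycan position {pos} outside 1..{len(sequence)}")
        if sequence[pos - 1] not in ("S", "T"):
            raise ValueError(
                f"glycan at position {pos} ({sequence[pos - 1]}) is not on S/T"
            )
        neutral += glycan_neutral_mass(comp, "residue")
    return mz_from_neutral(neutral, charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed parts-per-million error of ``observed`` against ``theoretical``."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical
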