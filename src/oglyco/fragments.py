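"""Theoretical backbone fragment ions for glycopeptides and peak matching.

Generates HCD (b/y) and EThcD (c/z) series with three glycan retention
states per fragment:

* ``full``     - the fragment keeps the complete glycans of every occupied
                 site inside its residue range (ETD-type behavior);
* ``hexnac_remnant`` - the fragment keeps a single +203.0794 Da core HexNAc
                 per occupied site in range (the diagnostic "b + N" ions of
                 collisional spectra);
* ``none``     - naked backbone fragment (complete gas-phase glycan loss).

z-ion conventions are explicit because ETD-type spectra are conventionally
annotated with the radical z+1 ("z-dot") species:
``z = y - 17.02655``, ``z_dot = y - 16.01872``, ``z_plus1 = y - 15.01090``
(all deltas at charge 1).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .digest import Glycopeptide
from .masses import (
    HEXNAC_REMNANT,
    MONOSACCHARIDE_MASSES,
    NH3,
    PROTON,
    RESIDUE_MASSES,
    WATER,
    glycan_neutral_mass,
    ppm_error,
)

__all__ = [
    "Series",
    "GlycanRetention",
    "TheoreticalIon",
    "Spectrum",
    "PeakMatch",
    "OXONIUM_IONS",
    "backbone_ion_mz",
    "theoretical_ion_set",
    "oxonium_ions",
    "match_peaks",
]


class Series(str, Enum):
    B = "b"
    Y = "y"
    C = "c"
    Z = "z"
    Z_DOT = "z_dot"
    Z_PLUS1 = "z_plus1"
    OXONIUM = "oxonium"


#: m/z offset (at charge 1) of each series relative to the summed residue
#: masses of its range.
_SERIES_OFFSET = {
    Series.B: PROTON,
    Series.C: PROTON + NH3,
    Series.Y: WATER + PROTON,
    Series.Z: WATER + PROTON - 17.026549,
    Series.Z_DOT: WATER + PROTON - 16.018724,
    Series.Z_PLUS1: WATER + PROTON - 15.010899,
}

_N_TERMINAL = (Series.B, Series.C)
_C_TERMINAL = (Series.Y, Series.Z, Series.Z_DOT, Series.Z_PLUS1)


class GlycanRetention(str, Enum):
    FULL = "full"
    HEXNAC_REMNANT = "hexnac_remnant"
    NONE = "none"


@dataclass(frozen=True)
class TheoreticalIon:
    series: Series
    index: int
    charge: int
    glycan_state: GlycanRetention
    mz: float
    name: str = ""

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        state = {"full": "+G", "hexnac_remnant": "+N", "none": ""}[self.glycan_state.value]
        charge = f"({self.charge}+)" if self.charge > 1 else ""
        series = {"z_dot": "z•", "z_plus1": "z+1"}.get(self.series.value, self.series.value)
        return f"{series}{self.index}{state}{charge}"


@dataclass
class Spectrum:
    """A centroided MS/MS peak list with its precursor."""

    precursor_mz: float
    precursor_charge: int
    peaks: List[Tuple[float, float]]
    id: str = ""

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        if any(intensity < 0 for _, intensity in self.peaks):
            raise ValueError("negative peak intensity")
        self.peaks = sorted(self.peaks)


@dataclass(frozen=True)
class PeakMatch:
    ion: TheoreticalIon
    peak_mz: float
    peak_intensity: float
    error_ppm: float


def _fragment_range(series: Series, index: int, length: int) -> Tuple[int, int]:
    if not 1 <= index <= length - 1:
        raise ValueError(f"fragment index {index} outside 1..{length - 1}")
    if series in _N_TERMINAL:
        return 1, index
    return length - index + 1, length


def backbone_ion_mz(
    glycopeptide: Glycopeptide,
    series: Series,
    index: int,
    charge: int = 1,
    glycan_state: GlycanRetention = GlycanRetention.NONE,
) -> float:
    """m/z of one backbone fragment of a glycopeptide."""
    series = Series(series)
    glycan_state = GlycanRetention(glycan_state)
    if series is Series.OXONIUM:
        raise ValueError("oxonium ions are not backbone fragments")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    sequence = glycopeptide.sequence
    lo, hi = _fragment_range(series, index, len(sequence))
    mz1 = sum(RESIDUE_MASSES[r] for r in sequence[lo - 1 : hi]) + _SERIES_OFFSET[series]
    sites_in_range = [
        (pos, comp)
        for pos, comp in glycopeptide.local_site_glycans().items()
        if lo <= pos <= hi
    ]
    if glycan_state is GlycanRetention.FULL:
        if not sites_in_range:
            raise ValueError(f"{series.value}{index}: no glycosite in fragment range")
        mz1 += sum(glycan_neutral_mass(comp, "residue") for _, comp in sites_in_range)
    elif glycan_state is GlycanRetention.HEXNAC_REMNANT:
        if not sites_in_range:
            raise ValueError(f"{series.value}{index}: no glycosite in fragment range")
        mz1 += HEXNAC_REMNANT * len(sites_in_range)
    return (mz1 + (charge - 1) * PROTON) / charge


def oxonium_ions(include_water_loss: bool = True) -> List[TheoreticalIon]:
    """Diagnostic glycan oxonium ions (HexNAc 204.0867 etc.)."""
    # oxonium m/z = residue mass + proton (HexNAc 204.0867, HexNAcHex
    # 366.1395, NeuAc 292.1027), optionally with a water loss
    fragments = {
        "HexNAc": MONOSACCHARIDE_MASSES["HexNAc"],
        "HexNAcHex": MONOSACCHARIDE_MASSES["HexNAc"] + MONOSACCHARIDE_MASSES["Hex"],
        "NeuAc": MONOSACCHARIDE_MASSES["NeuAc"],
    }
    ions = []
    for name, residue_mass in fragments.items():
        mz = residue_mass + PROTON
        ions.append(
            TheoreticalIon(Series.OXONIUM, 0, 1, GlycanRetention.NONE, mz, f"ox-{name}")
        )
        if include_water_loss:
            ions.append(
                TheoreticalIon(
                    Series.OXONIUM, 0, 1, GlycanRetention.NONE, mz - WATER, f"ox-{name}-H2O"
                )
            )
    return ions


OXONIUM_IONS: Tuple[TheoreticalIon, ...] = tuple(oxonium_ions())


def theoretical_ion_set(
    glycopeptide: Glycopeptide,
    mode: str = "EThcD",
    charges: Sequence[int] = (1,),
    series: Optional[Sequence[Series]] = None,
    states: Optional[Sequence[GlycanRetention]] = None,
    z_convention: Series = Series.Z_DOT,
    include_oxonium: bool = False,
) -> List[TheoreticalIon]:
    """Complete theoretical ion list for a glycopeptide.

    HCD defaults to b/y with naked, remnant and glycan-retaining states
    (collisional activation strips glycans readily); EThcD defaults to
    c/z-dot where each fragment simply keeps the glycans in its range.
    """
    if mode not in ("HCD", "EThcD"):
        raise ValueError(f"unknown mode {mode!r}")
    if series is None:
        series = (
            (Series.B, Series.Y)
            if mode == "HCD"
            else (Series.C, Series(z_convention))
        )
    if states is None:
        states = (
            (GlycanRetention.NONE, GlycanRetention.HEXNAC_REMNANT, GlycanRetention.FULL)
            if mode == "HCD"
            else (GlycanRetention.FULL,)
        )
    length = len(glycopeptide.sequence)
    local_sites = glycopeptide.local_site_glycans()
    ions: Dict[Tuple, TheoreticalIon] = {}
    for ser in series:
        ser = Series(ser)
        for index in range(1, length):
            lo, hi = _fragment_range(ser, index, length)
            has_site = any(lo <= pos <= hi for pos in local_sites)
            for charge in charges:
                # naked form is the only state defined for site-free ranges;
                # emit it even when only glycan-bearing states were requested
                applicable = set(states) if has_site else {GlycanRetention.NONE}
                for state in applicable:
                    mz = backbone_ion_mz(glycopeptide, ser, index, charge, state)
                    key = (ser, index, charge, state)
                    ions[key] = TheoreticalIon(ser, index, charge, state, mz)
    out = list(ions.values())
    if include_oxonium:
        out.extend(OXONIUM_IONS)
    return out


def match_peaks(
    spectrum: Spectrum,
    ions: Iterable[TheoreticalIon],
    tolerance_ppm: Optional[float] = 20.0,
    tolerance_da: Optional[float] = None,
) -> List[PeakMatch]:
    """Match theoretical ions to the nearest spectrum peak within tolerance.

    Ties on |error| go to the higher-intensity peak; one peak may satisfy
    several ions.  Exactly one of the tolerances must be given.
    """
    if (tolerance_ppm is None) == (tolerance_da is None):
        raise ValueError("specify exactly one of tolerance_ppm / tolerance_da")
    peaks = spectrum.peaks
    if not peaks:
        return []
    mzs = [p[0] for p in peaks]
    matches: List[PeakMatch] = []
    for ion in ions:
        tol = (
            tolerance_da
            if tolerance_da is not None
            else ion.mz * tolerance_ppm * 1e-6
        )
        lo = bisect.bisect_left(mzs, ion.mz - tol)
        hi = bisect.bisect_right(mzs, ion.mz + tol)
        if lo == hi:
            continue
        best = min(
            peaks[lo:hi], key=lambda p: (round(abs(p[0] - ion.mz), 9), -p[1])
        )
        matches.append(
            PeakMatch(ion, best[0], best[1], ppm_error(best[0], ion.mz))
        )
    return matches
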