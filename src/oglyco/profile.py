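"""Released 2-AB glycan chromatogram assignment and quantitation metrics.

Consumes already-integrated peak tables (retention time, fluorescence area,
optional observed m/z), assigns peaks to a glycan library by mass (isomers by
retention-time window), and computes normalized peak-area percentages,
replicate RSD, dilution-series linearity and recovery rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .glycans import DEFAULT_LIBRARY, LibraryEntry
from .masses import labeled_glycan_mz, ppm_error

__all__ = [
    "ChromPeak",
    "ProfileAssignment",
    "assign_peaks",
    "normalize_areas",
    "replicate_rsd",
    "linearity",
    "recovery_rate",
]


@dataclass(frozen=True)
class ChromPeak:
    retention_time: float  # minutes
    area: float  # fluorescence area units
    observed_mz: Optional[float] = None
    sample_id: str = ""
    protein_amount: Optional[float] = None  # micrograms

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("peak area must be >= 0")
        if self.retention_time <= 0:
            raise ValueError("retention time must be > 0")


@dataclass(frozen=True)
class ProfileAssignment:
    peak: ChromPeak
    species_name: Optional[str]
    category: str  # major_glycan | peeling_byproduct | deacetylation_byproduct | unassigned
    ppm: Optional[float] = None
    isomer_group: Tuple[str, ...] = ()


def assign_peaks(
    peaks: Iterable[ChromPeak],
    library: Sequence[LibraryEntry] = DEFAULT_LIBRARY,
    tolerance_da: Optional[float] = 0.02,
    tolerance_ppm: Optional[float] = None,
    charge: int = 1,
) -> List[ProfileAssignment]:
    """Assign chromatogram peaks to library species by observed m/z.

    The nearest library species within tolerance wins; species with
    indistinguishable m/z (isomers) are resolved by their configured
    retention-time windows, otherwise the peak is labeled as an isomer
    group.  Peaks without an m/z, or without a match, are ``unassigned``.
    """
    library = list(library)
    if not library:
        raise ValueError("empty glycan library")
    if (tolerance_da is None) == (tolerance_ppm is None):
        raise ValueError("specify exactly one of tolerance_da / tolerance_ppm")
    theo = [(entry, labeled_glycan_mz(entry.species, charge)) for entry in library]
    out: List[ProfileAssignment] = []
    for peak in peaks:
        if peak.observed_mz is None:
            out.append(ProfileAssignment(peak, None, "unassigned"))
            continue
        hits: List[Tuple[float, LibraryEntry, float]] = []
        for entry, mz in theo:
            delta = abs(peak.observed_mz - mz)
            tol = tolerance_da if tolerance_da is not None else mz * tolerance_ppm * 1e-6
            if delta <= tol:
                hits.append((delta, entry, mz))
        if not hits:
            out.append(ProfileAssignment(peak, None, "unassigned"))
            continue
        best_delta = min(h[0] for h in hits)
        # isomers: equal mass within float noise of the closest hit
        close = [h for h in hits if h[0] - best_delta < 1e-6]
        if len(close) > 1:
            in_window = [
                h
                for h in close
                if h[1].rt_window
                and h[1].rt_window[0] <= peak.retention_time <= h[1].rt_window[1]
            ]
            if len(in_window) == 1:
                close = in_window
        if len(close) == 1:
            _, entry, mz = close[0]
            out.append(
                ProfileAssignment(
                    peak, entry.species.short_name, entry.category,
                    ppm_error(peak.observed_mz, mz),
                )
            )
        else:
            names = tuple(sorted(h[1].species.short_name for h in close))
            out.append(
                ProfileAssignment(
                    peak, None, close[0][1].category,
                    ppm_error(peak.observed_mz, close[0][2]),
                    isomer_group=names,
                )
            )
    return out


def normalize_areas(
    assignments: Iterable[ProfileAssignment], scope: str = "major_only"
) -> Dict[str, float]:
    """Peak-area percentage per species over the chosen scope.

    ``major_only`` normalizes over the four major glycans (the default
    reporting convention); ``all_assigned`` includes byproducts.
    """
    if scope not in ("major_only", "all_assigned"):
        raise ValueError(f"unknown scope {scope!r}")
    areas: Dict[str, float] = {}
    for a in assignments:
        if a.species_name is None:
            continue
        if scope == "major_only" and a.category != "major_glycan":
            continue
        areas[a.species_name] = areas.get(a.species_name, 0.0) + a.peak.area
    total = sum(areas.values())
    if not areas:
        raise ValueError("no assigned peaks in scope")
    if total <= 0:
        raise ValueError("zero total assigned area")
    return {name: 100.0 * area / total for name, area in sorted(areas.items())}


def replicate_rsd(percentage_tables: Sequence[Dict[str, float]]) -> Dict[str, float]:
    """Relative standard deviation (100 x sd/mean, n-1 sd) across replicates.

    A species missing from a replicate contributes 0% there, with a warning.
    """
    if len(percentage_tables) < 2:
        raise ValueError("need at least two replicates")
    species = sorted({name for table in percentage_tables for name in table})
    out: Dict[str, float] = {}
    for name in species:
        values = []
        for i, table in enumerate(percentage_tables):
            if name not in table:
                warnings.warn(
                    f"species {name!r} missing from replicate {i}; treated as 0%",
                    stacklevel=2,
                )
            values.append(table.get(name, 0.0))
        arr = np.asarray(values, dtype=float)
        mean = arr.mean()
        if mean == 0:
            raise ValueError(f"species {name!r} has zero mean across replicates")
        out[name] = 100.0 * arr.std(ddof=1) / mean
    return out


def linearity(series: Sequence[Tuple[float, float]]) -> Tuple[float, float, float]:
    """Ordinary least squares of area against protein amount.

    Returns ``(slope, intercept, r_squared)``.  A constant response is a
    perfect fit of a flat line and reports R^2 = 0 by convention.
    """
    if len({x for x, _ in series}) < 3:
        raise ValueError("need at least three distinct protein amounts")
    x = np.asarray([p[0] for p in series], dtype=float)
    y = np.asarray([p[1] for p in series], dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return float(slope), float(intercept), 0.0
    residuals = y - (slope * x + intercept)
    r_squared = 1.0 - float((residuals**2).sum()) / ss_tot
    return float(slope), float(intercept), float(r_squared)


def recovery_rate(
    measured_area: float,
    protein_amount: float,
    reference_area: float,
    reference_amount: float = 40.0,
) -> float:
    """Recovery % against proportional scaling of the reference amount.

    ``100 x measured / (reference_area x protein_amount / reference_amount)``.
    """
    if protein_amount <= 0 or reference_amount <= 0:
        raise ValueError("protein amounts must be positive")
    if reference_area <= 0:
        raise ValueError("reference area must be positive")
    if measured_area < 0:
        raise ValueError("measured area must be >= 0")
    theoretical = reference_area * protein_amount / reference_amount
    return 100.0 * measured_area / theoretical
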