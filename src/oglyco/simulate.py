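"""Ground-truthed synthetic data for every pipeline stage.

Two generators, both driven by a single integer seed:

* glycopeptide MS/MS spectra with configurable ion coverage, Gaussian
  ppm-scale mass error and uniform decoy peaks, plus a truth table of every
  planted glycopeptide and site;
* chromatographic fluorescence-area tables for replicate, stability and
  dilution-series experiments with multiplicative (lognormal) noise and
  configurable byproduct fractions.

The bundled FSH-CTP preset reproduces the experimentally observed inventory
of sixteen core-1 glycopeptides from the 28-residue CTP region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .digest import FSH_CTP, Glycopeptide, PeptideSpan, Protein
from .fragments import Spectrum, theoretical_ion_set
from .glycans import CORE1, DEFAULT_LIBRARY
from .masses import GlycanComposition, labeled_glycan_mz

__all__ = [
    "CTP_GLYCOSITES",
    "fsh_ctp_inventory",
    "SpectraParams",
    "ProfileParams",
    "GroundTruth",
    "fsh_ctp_truth",
    "simulate_spectra",
    "simulate_profile_tables",
]

#: Candidate glycosite set of the CTP region: the six previously reported
#: sites plus the additionally observed S124.
CTP_GLYCOSITES: Tuple[int, ...] = (114, 115, 121, 124, 126, 132, 134)

# Observed core-1 glycopeptide inventory: (start, end, occupied sites,
# precursor charge).  Locations recomputed from the sequence where the
# published coordinates were internally inconsistent.
_CTP_INVENTORY: Tuple[Tuple[int, int, Tuple[int, ...], int], ...] = (
    (115, 123, (115,), 2),            # SKAPPPSLP
    (121, 125, (121,), 2),            # SLPSP
    (126, 139, (126,), 2),            # SRLPGPSDTPILPQ
    (132, 139, (132,), 2),            # SDTPILPQ
    (134, 139, (134,), 2),            # TPILPQ
    (121, 131, (121,), 2),            # SLPSPSRLPGP
    (114, 120, (114, 115), 2),        # SSKAPPP
    (114, 123, (114, 115), 2),        # SSKAPPPSLP
    (114, 123, (114, 121), 2),        # SSKAPPPSLP
    (115, 125, (115, 121), 2),        # SKAPPPSLPSP
    (126, 139, (126, 132), 2),        # SRLPGPSDTPILPQ
    (121, 139, (121, 132), 3),        # SLPSPSRLPGPSDTPILPQ
    (114, 125, (114, 124), 2),        # SSKAPPPSLPSP
    (114, 125, (114, 115, 121), 3),   # SSKAPPPSLPSP
    (126, 139, (126, 132, 134), 3),   # SRLPGPSDTPILPQ
    (124, 139, (124, 126, 132), 3),   # SPSRLPGPSDTPILPQ
)


def fsh_ctp_inventory(
    glycan: GlycanComposition = CORE1,
) -> List[Tuple[Glycopeptide, int]]:
    """The sixteen observed (glycopeptide, charge) pairs of the CTP preset."""
    out = []
    for start, end, sites, charge in _CTP_INVENTORY:
        span = PeptideSpan(
            FSH_CTP.subsequence(start, end),
            start,
            end,
            missed_cleavages=sum(1 for s in sites if s != start),
        )
        out.append((Glycopeptide(span, {s: glycan for s in sites}), charge))
    return out


@dataclass(frozen=True)
class SpectraParams:
    mode: str = "EThcD"
    coverage: float = 1.0  # fraction of theoretical ions emitted
    ppm_error_sd: float = 0.0  # Gaussian m/z error, ppm
    decoy_peaks: int = 0  # uniform random peaks per spectrum
    fragment_charges: Tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")
        if self.ppm_error_sd < 0 or self.decoy_peaks < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class ProfileParams:
    #: species -> percentage of total major-glycan response; sums to 100
    proportions: Tuple[Tuple[str, float], ...] = (
        ("GalGalNAc", 8.0),
        ("NeuAcGalGalNAc", 42.0),
        ("Gal(NeuAcGalNAc)", 15.0),
        ("NeuAcGal(NeuAcGalNAc)", 35.0),
    )
    #: byproduct species -> fraction of its parent's area
    byproduct_fractions: Tuple[Tuple[str, float], ...] = (
        ("NeuAcGal", 0.03),
        ("NeuAc", 0.02),
        ("NeuAcGalGalNAc-deAc", 0.01),
        ("NeuAcGal(NeuAcGalNAc)-deAc", 0.01),
    )
    replicate_cv: float = 0.0  # multiplicative noise CV
    n_replicates: int = 6
    replicate_amount: float = 60.0  # micrograms
    amounts: Tuple[float, ...] = (10.0, 20.0, 40.0, 60.0, 100.0)
    stability_hours: Tuple[float, ...] = (0.0, 12.0, 24.0, 48.0)
    response_per_ug: float = 1000.0  # area units per microgram of protein

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.proportions)
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"proportions must sum to 100, got {total}")
        if self.replicate_cv < 0:
            raise ValueError("replicate_cv must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    protein: Protein
    glycoforms: Tuple[Tuple[Glycopeptide, int], ...]
    spectra_params: SpectraParams = SpectraParams()
    profile_params: ProfileParams = ProfileParams()
    seed: int = 0


def fsh_ctp_truth(
    seed: int = 0,
    spectra_params: SpectraParams = SpectraParams(),
    profile_params: ProfileParams = ProfileParams(),
) -> GroundTruth:
    return GroundTruth(
        protein=FSH_CTP,
        glycoforms=tuple(fsh_ctp_inventory()),
        spectra_params=spectra_params,
        profile_params=profile_params,
        seed=seed,
    )


# intensity ranks: C-terminal series strongest, then N-terminal, then
# glycan-stripped remnants (arbitrary but documented ordering)
_BASE_INTENSITY = {"y": 100.0, "z": 100.0, "z_dot": 100.0, "z_plus1": 100.0,
                   "b": 70.0, "c": 70.0, "oxonium": 30.0}


def simulate_spectra(
    truth: GroundTruth,
) -> Tuple[List[Spectrum], pd.DataFrame]:
    """Generate one spectrum per planted glycoform, plus a truth table.

    A seeded random subset (``coverage``) of the theoretical ion set is
    emitted with Gaussian ppm error; decoy peaks are drawn uniformly over
    the spectrum m/z range with intensities resampled from the emitted-ion
    intensity distribution.  Identical truth (including seed) yields
    identical output.
    """
    params = truth.spectra_params
    rng = np.random.default_rng(truth.seed)
    spectra: List[Spectrum] = []
    rows = []
    for i, (glycopeptide, charge) in enumerate(truth.glycoforms):
        ions = theoretical_ion_set(
            glycopeptide, mode=params.mode, charges=params.fragment_charges
        )
        keep_mask = rng.random(len(ions)) < params.coverage
        kept = [ion for ion, keep in zip(ions, keep_mask) if keep]
        peaks: List[Tuple[float, float]] = []
        for ion in kept:
            mz = ion.mz
            if params.ppm_error_sd > 0:
                mz *= 1.0 + rng.normal(0.0, params.ppm_error_sd) * 1e-6
            base = _BASE_INTENSITY.get(ion.series.value, 50.0)
            if ion.glycan_state.value == "hexnac_remnant":
                base *= 0.5
            peaks.append((mz, base * float(rng.uniform(0.5, 1.5))))
        if params.decoy_peaks:
            if peaks:
                lo = min(p[0] for p in peaks) * 0.9
                hi = max(p[0] for p in peaks) * 1.1
                intensities = np.array([p[1] for p in peaks])
            else:
                lo, hi = 200.0, 2000.0
                intensities = np.array([10.0, 100.0])
            for _ in range(params.decoy_peaks):
                peaks.append(
                    (float(rng.uniform(lo, hi)), float(rng.choice(intensities)))
                )
        precursor = glycopeptide.precursor_mz(charge)
        if params.ppm_error_sd > 0:
            precursor *= 1.0 + rng.normal(0.0, params.ppm_error_sd) * 1e-6
        spectrum_id = f"synthetic.{i:04d}.{glycopeptide}"
        if not peaks and params.coverage == 0 and params.decoy_peaks == 0:
            spectrum_id += ".EMPTY"
        spectra.append(Spectrum(precursor, charge, peaks, id=spectrum_id))
        rows.append(
            {
                "spectrum_id": spectrum_id,
                "sequence": glycopeptide.sequence,
                "start": glycopeptide.span.start,
                "end": glycopeptide.span.end,
                "charge": charge,
                "precursor_mz": precursor,
                "sites": ";".join(
                    f"{pos}:{comp}" for pos, comp in glycopeptide.site_glycans
                ),
                "n_planted_ions": len(kept),
                "n_decoy_peaks": params.decoy_peaks,
            }
        )
    return spectra, pd.DataFrame(rows)


def _species_mz(name: str) -> float:
    for entry in DEFAULT_LIBRARY:
        if entry.species.short_name == name:
            return labeled_glycan_mz(entry.species, 1)
    raise KeyError(name)


def _species_rt(name: str) -> float:
    for entry in DEFAULT_LIBRARY:
        if entry.species.short_name == name and entry.rt_window:
            return 0.5 * (entry.rt_window[0] + entry.rt_window[1])
    raise KeyError(name)


def _noise(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return float(rng.lognormal(-0.5 * sigma**2, sigma))


def _sample_rows(
    rng: np.random.Generator,
    params: ProfileParams,
    sample_id: str,
    amount: float,
) -> List[dict]:
    proportions = dict(params.proportions)
    byproducts = dict(params.byproduct_fractions)
    parent_of = {
        entry.species.short_name: entry.parent
        for entry in DEFAULT_LIBRARY
        if entry.parent
    }
    # peeling byproducts scale with the total sialylated pool
    sialyl_total = sum(
        p for name, p in proportions.items() if "NeuAc" in name
    )
    rows = []
    areas: Dict[str, float] = {}
    for name, pct in proportions.items():
        areas[name] = (
            params.response_per_ug * amount * (pct / 100.0) * _noise(rng, params.replicate_cv)
        )
    for name, fraction in byproducts.items():
        parent = parent_of.get(name)
        if parent:
            base = areas.get(parent, 0.0)
        else:
            base = params.response_per_ug * amount * (sialyl_total / 100.0)
        areas[name] = base * fraction * _noise(rng, params.replicate_cv)
    for name, area in areas.items():
        rows.append(
            {
                "sample_id": sample_id,
                "rt_min": _species_rt(name),
                "area": area,
                "mz": _species_mz(name),
                "protein_amount_ug": amount,
                "species_truth": name,
            }
        )
    return rows


def simulate_profile_tables(truth: GroundTruth) -> Dict[str, pd.DataFrame]:
    """Replicate, stability and dilution-series peak tables (seeded).

    Species areas follow ``response x amount x proportion`` with lognormal
    multiplicative noise; byproducts are added as configured fractions of
    their parents.  Returns CSV-ready frames keyed ``replicates``,
    ``stability`` and ``dilution``.
    """
    params = truth.profile_params
    rng = np.random.default_rng(truth.seed + 1)  # decoupled from spectra
    replicate_rows: List[dict] = []
    for i in range(params.n_replicates):
        replicate_rows.extend(
            _sample_rows(rng, params, f"rep{i + 1}", params.replicate_amount)
        )
    stability_rows: List[dict] = []
    for hours in params.stability_hours:
        rows = _sample_rows(rng, params, f"t{hours:g}h", params.replicate_amount)
        for row in rows:
            row["storage_hours"] = hours
        stability_rows.extend(rows)
    dilution_rows: List[dict] = []
    for amount in params.amounts:
        dilution_rows.extend(_sample_rows(rng, params, f"amt{amount:g}ug", amount))
    return {
        "replicates": pd.DataFrame(replicate_rows),
        "stability": pd.DataFrame(stability_rows),
        "dilution": pd.DataFrame(dilution_rows),
    }
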