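"""Closed-search identification of glycopeptide spectra.

Each spectrum is compared against an enumerated candidate list (digestion
products x glycoform assignments): candidates passing the precursor
tolerance are scored by the number of matched theoretical backbone ions, and
the top scorer wins.  Ties between indistinguishable candidates are kept and
reported, and site localization then only trusts what all tied candidates
agree on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .digest import Glycopeptide
from .fragments import (
    PeakMatch,
    Spectrum,
    match_peaks,
    theoretical_ion_set,
)
from .localize import EvidenceTier, SiteAssignment, localize_spectrum
from .masses import ppm_error

__all__ = ["Identification", "identify_spectrum", "identify", "localize_identifications"]


@dataclass
class Identification:
    spectrum: Spectrum
    glycopeptide: Glycopeptide
    score: int
    precursor_ppm: float
    matches: List[PeakMatch]
    tied_with: Tuple[Glycopeptide, ...] = ()

    @property
    def is_ambiguous(self) -> bool:
        return bool(self.tied_with)


def identify_spectrum(
    spectrum: Spectrum,
    candidates: Sequence[Glycopeptide],
    mode: str = "EThcD",
    precursor_ppm: float = 10.0,
    fragment_ppm: float = 20.0,
    min_score: int = 1,
    fragment_charges: Sequence[int] = (1,),
) -> Optional[Identification]:
    """Best-matching candidate for one spectrum, or None.

    Precursor filtering is by signed ppm at the spectrum's charge; scoring
    counts matched theoretical backbone ions.  Ties on score are broken by
    smaller |precursor ppm|; exact ties are retained in ``tied_with``.
    """
    scored: List[Tuple[int, float, Glycopeptide, List[PeakMatch]]] = []
    for candidate in candidates:
        theo_mz = candidate.precursor_mz(spectrum.precursor_charge)
        prec_err = ppm_error(spectrum.precursor_mz, theo_mz)
        if abs(prec_err) > precursor_ppm:
            continue
        ions = theoretical_ion_set(candidate, mode=mode, charges=fragment_charges)
        matches = match_peaks(spectrum, ions, tolerance_ppm=fragment_ppm)
        scored.append((len(matches), prec_err, candidate, matches))
    if not scored:
        return None
    scored.sort(key=lambda t: (-t[0], abs(t[1]), t[2].key()))
    best_score, best_err, best, best_matches = scored[0]
    if best_score < min_score:
        return None
    tied = tuple(
        cand
        for score, err, cand, _ in scored[1:]
        if score == best_score and abs(abs(err) - abs(best_err)) < 1e-9
    )
    return Identification(spectrum, best, best_score, best_err, best_matches, tied)


def identify(
    spectra: Sequence[Spectrum],
    candidates: Sequence[Glycopeptide],
    mode: str = "EThcD",
    precursor_ppm: float = 10.0,
    fragment_ppm: float = 20.0,
    min_score: int = 1,
) -> List[Identification]:
    """Identify a batch of spectra against one candidate list."""
    out = []
    for spectrum in spectra:
        ident = identify_spectrum(
            spectrum,
            candidates,
            mode=mode,
            precursor_ppm=precursor_ppm,
            fragment_ppm=fragment_ppm,
            min_score=min_score,
        )
        if ident is not None:
            out.append(ident)
    return out


def localize_identifications(
    identifications: Sequence[Identification],
    mode: str = "EThcD",
    enzyme_rule: bool = True,
) -> List[SiteAssignment]:
    """Site assignments for identified spectra, demoting tied evidence.

    When a spectrum's identification is tied between candidates, only sites
    occupied in *every* tied candidate are reported, and their evidence is
    capped at ``enzyme_inferred`` (N-terminal site) or ``ambiguous``; the
    fragments demonstrably failed to discriminate the alternatives.
    """
    assignments: List[SiteAssignment] = []
    for ident in identifications:
        spectrum_assignments = localize_spectrum(
            ident.glycopeptide,
            ident.matches,
            mode=mode,
            enzyme_rule=enzyme_rule,
            spectrum_id=ident.spectrum.id,
        )
        if ident.is_ambiguous:
            consensus = set(ident.glycopeptide.sites)
            for other in ident.tied_with:
                consensus &= set(other.sites)
            demoted = []
            for a in spectrum_assignments:
                if a.protein_position not in consensus:
                    continue
                cap = (
                    EvidenceTier.ENZYME_INFERRED
                    if enzyme_rule and a.protein_position == ident.glycopeptide.span.start
                    else EvidenceTier.AMBIGUOUS
                )
                demoted.append(
                    SiteAssignment(
                        a.protein_position,
                        a.residue,
                        a.composition,
                        min(a.evidence, cap),
                        (),
                        a.spectrum_id,
                        a.glycopeptide_key,
                    )
                )
            spectrum_assignments = demoted
        assignments.extend(spectrum_assignments)
    return assignments
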