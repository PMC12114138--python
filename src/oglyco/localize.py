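"""Site-level glycosylation assignments with explicit evidence tiers.

The evidence model mirrors how O-glycosite claims are actually argued from
OpeRATOR-product spectra, ordered from strongest to weakest:

``direct_bracketing``   matched c/z ions confine the glycan mass shift to a
                        single residue (ETD-type evidence);
``single_candidate``    the peptide holds exactly one S/T and backbone
                        fragments identify it;
``remnant_localized``   a matched fragment retaining a core HexNAc (or the
                        full glycan) covers exactly one candidate S/T;
``enzyme_inferred``     no ion evidence, but the site is the peptide's
                        N-terminal residue, which OpeRATOR specificity
                        requires to be glycosylated;
``ambiguous``           nothing above applies.

Evidence is reported, never silently upgraded: enzyme-inferred sites stay
distinct from ion-proven ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .digest import Glycopeptide
from .fragments import GlycanRetention, PeakMatch, Series
from .masses import GlycanComposition

__all__ = [
    "EvidenceTier",
    "SiteAssignment",
    "localize_spectrum",
    "aggregate_sites",
    "DEFAULT_PRIOR_SITES",
]

#: Previously reported O-glycosylation sites of the FSH-CTP region.
DEFAULT_PRIOR_SITES: Tuple[int, ...] = (114, 115, 121, 126, 132, 134)

_N_TERMINAL_SERIES = {Series.B, Series.C}
_C_TERMINAL_SERIES = {Series.Y, Series.Z, Series.Z_DOT, Series.Z_PLUS1}


class EvidenceTier(IntEnum):
    """Totally ordered localization evidence levels (higher is stronger)."""

    AMBIGUOUS = 0
    ENZYME_INFERRED = 1
    REMNANT_LOCALIZED = 2
    SINGLE_CANDIDATE = 3
    DIRECT_BRACKETING = 4

    def __str__(self) -> str:
        return self.name.lower()


@dataclass(frozen=True)
class SiteAssignment:
    protein_position: int
    residue: str
    composition: GlycanComposition
    evidence: EvidenceTier
    supporting_ions: Tuple[PeakMatch, ...]
    spectrum_id: str = ""
    glycopeptide_key: Tuple = ()

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T"):
            raise ValueError(f"site residue must be S/T, got {self.residue!r}")


def _candidate_positions(sequence: str) -> List[int]:
    return [i + 1 for i, r in enumerate(sequence) if r in ("S", "T")]


def _prefix_knowledge(
    glycopeptide: Glycopeptide, matches: Sequence[PeakMatch]
) -> Tuple[Dict[int, int], Dict[int, List[PeakMatch]]]:
    """Known prefix glycan counts implied by matched c/z ions.

    In ETD-type spectra each backbone fragment keeps the glycans of its
    range, so a matched ion's m/z encodes how many occupied sites the range
    holds.  ``prefix[i]`` is the number of occupied sites among residues
    1..i.  Index 0 and the full length are always known (zero glycans before
    the peptide; the precursor fixes the total).
    """
    n = len(glycopeptide.sequence)
    occupied = sorted(glycopeptide.local_site_glycans())

    def occupied_upto(i: int) -> int:
        return sum(1 for p in occupied if p <= i)

    prefix: Dict[int, int] = {0: 0, n: len(occupied)}
    witnesses: Dict[int, List[PeakMatch]] = {0: [], n: []}
    for match in matches:
        ion = match.ion
        if ion.series in _N_TERMINAL_SERIES:
            idx = ion.index
        elif ion.series in _C_TERMINAL_SERIES:
            idx = n - ion.index
        else:
            continue
        prefix[idx] = occupied_upto(idx)
        witnesses.setdefault(idx, []).append(match)
    return prefix, witnesses


def _bracketed_sites(
    glycopeptide: Glycopeptide, matches: Sequence[PeakMatch]
) -> Dict[int, List[PeakMatch]]:
    """Occupied local positions pinned to a single residue by matched ions.

    Between two consecutive known prefix indices i < j the occupancy count
    rises by d; when the interval (i, j] contains exactly d candidate S/T
    residues, each of them is unambiguously glycosylated.
    """
    sequence = glycopeptide.sequence
    candidates = _candidate_positions(sequence)
    occupied = set(glycopeptide.local_site_glycans())
    prefix, witnesses = _prefix_knowledge(glycopeptide, matches)
    known = sorted(prefix)
    pinned: Dict[int, List[PeakMatch]] = {}
    for i, j in zip(known, known[1:]):
        d = prefix[j] - prefix[i]
        interval_candidates = [p for p in candidates if i < p <= j]
        support = witnesses.get(i, []) + witnesses.get(j, [])
        # require ion evidence: the precursor alone (interval 0..n) never
        # counts as bracketing even when it fixes the total glycan count
        if d >= 1 and len(interval_candidates) == d and support:
            for p in interval_candidates:
                if p in occupied:
                    pinned[p] = support
    return pinned


def localize_spectrum(
    glycopeptide: Glycopeptide,
    matches: Sequence[PeakMatch],
    mode: str = "EThcD",
    enzyme_rule: bool = True,
    spectrum_id: str = "",
) -> List[SiteAssignment]:
    """Assign the strongest achievable evidence tier to each glycosite.

    ``matches`` must come from matching this glycopeptide's theoretical ions
    (fragment indices are validated against the sequence length).
    """
    if mode not in ("HCD", "EThcD"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(glycopeptide.sequence)
    for match in matches:
        if match.ion.series is not Series.OXONIUM and not 1 <= match.ion.index <= n - 1:
            raise ValueError(
                f"match {match.ion.label} inconsistent with peptide of length {n}"
            )
    sequence = glycopeptide.sequence
    candidates = _candidate_positions(sequence)
    local_sites = glycopeptide.local_site_glycans()
    backbone_matches = [m for m in matches if m.ion.series is not Series.OXONIUM]

    bracketed: Dict[int, List[PeakMatch]] = {}
    if mode == "EThcD":
        bracketed = _bracketed_sites(glycopeptide, backbone_matches)

    assignments: List[SiteAssignment] = []
    for local_pos in sorted(local_sites):
        comp = local_sites[local_pos]
        tier = EvidenceTier.AMBIGUOUS
        support: Tuple[PeakMatch, ...] = ()
        if local_pos in bracketed:
            tier = EvidenceTier.DIRECT_BRACKETING
            support = tuple(bracketed[local_pos])
        elif len(candidates) == 1 and backbone_matches:
            tier = EvidenceTier.SINGLE_CANDIDATE
            support = tuple(backbone_matches)
        else:
            isolating = [
                m
                for m in backbone_matches
                if m.ion.glycan_state
                in (GlycanRetention.FULL, GlycanRetention.HEXNAC_REMNANT)
                and _covers_exactly(m.ion, n, candidates, local_pos)
            ]
            if mode == "HCD" and isolating:
                tier = EvidenceTier.REMNANT_LOCALIZED
                support = tuple(isolating)
        if tier is EvidenceTier.AMBIGUOUS and enzyme_rule and local_pos == 1:
            tier = EvidenceTier.ENZYME_INFERRED
        assignments.append(
            SiteAssignment(
                protein_position=glycopeptide.span.start + local_pos - 1,
                residue=sequence[local_pos - 1],
                composition=comp,
                evidence=tier,
                supporting_ions=support,
                spectrum_id=spectrum_id,
                glycopeptide_key=glycopeptide.key(),
            )
        )
    return assignments


def _covers_exactly(ion, length: int, candidates: List[int], local_pos: int) -> bool:
    """True when the ion's residue range contains exactly one candidate S/T
    and it is ``local_pos``."""
    if ion.series in _N_TERMINAL_SERIES:
        lo, hi = 1, ion.index
    else:
        lo, hi = length - ion.index + 1, length
    in_range = [p for p in candidates if lo <= p <= hi]
    return in_range == [local_pos]


def aggregate_sites(
    assignments: Iterable[SiteAssignment],
    prior_sites: Iterable[int] = DEFAULT_PRIOR_SITES,
) -> pd.DataFrame:
    """Aggregate per-spectrum assignments into a protein site table.

    One row per distinct position with the best evidence tier observed, the
    number of distinct supporting glycopeptides, and a ``novel`` flag for
    positions absent from the prior-knowledge list.  Aggregation is
    idempotent and order-independent.
    """
    prior = set(prior_sites)
    by_position: Dict[int, List[SiteAssignment]] = {}
    for assignment in assignments:
        by_position.setdefault(assignment.protein_position, []).append(assignment)
    rows = []
    for position in sorted(by_position):
        group = by_position[position]
        residues = {a.residue for a in group}
        if len(residues) > 1:
            raise ValueError(
                f"conflicting residue letters at position {position}: {sorted(residues)}"
            )
        best = max(a.evidence for a in group)
        glycopeptides = {a.glycopeptide_key for a in group}
        rows.append(
            {
                "position": position,
                "residue": residues.pop(),
                "evidence": str(best),
                "n_glycopeptides": len(glycopeptides),
                "n_spectra": len({a.spectrum_id for a in group}),
                "novel": position not in prior,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["position", "residue", "evidence", "n_glycopeptides", "n_spectra", "novel"],
    )
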