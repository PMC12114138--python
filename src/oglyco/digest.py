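"""In-silico OpeRATOR + sialidase digestion of an O-glycoprotein.

OpeRATOR cleaves the peptide backbone immediately N-terminal to an
O-glycosylated Ser/Thr, so every true product starts with a glycosylated
residue.  Digestion operates on a *candidate glycosite set* supplied by the
caller (the enzyme only cuts where a glycan is actually present, which is
sample dependent); a convenience mode treats every S/T as a candidate.

Coordinates are 1-based and inclusive throughout, using a configurable
numbering offset so that fusion-protein numbering (e.g. a C-terminal peptide
spanning residues 112-139) can be used directly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .masses import (
    GlycanComposition,
    glycan_neutral_mass,
    glycopeptide_precursor_mz,
    peptide_neutral_mass,
)

__all__ = [
    "Protein",
    "PeptideSpan",
    "Glycopeptide",
    "FSH_CTP",
    "apply_sialidase",
    "all_st_positions",
    "digest",
    "enumerate_glycoforms",
    "enumerate_glycopeptides",
]


@dataclass(frozen=True)
class Protein:
    """A protein (or protein region) with its numbering offset."""

    sequence: str
    first_residue: int = 1
    id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty protein sequence")

    @property
    def last_residue(self) -> int:
        return self.first_residue + len(self.sequence) - 1

    def residue(self, position: int) -> str:
        if not self.first_residue <= position <= self.last_residue:
            raise ValueError(
                f"position {position} outside {self.first_residue}..{self.last_residue}"
            )
        return self.sequence[position - self.first_residue]

    def subsequence(self, start: int, end: int) -> str:
        if start > end:
            raise ValueError(f"start {start} > end {end}")
        self.residue(start)
        self.residue(end)
        return self.sequence[start - self.first_residue : end - self.first_residue + 1]


#: The 28-residue O-glycosylated C-terminal peptide region, numbered 112-139.
FSH_CTP = Protein("SSSSKAPPPSLPSPSRLPGPSDTPILPQ", first_residue=112, id="FSH-CTP")


@dataclass(frozen=True)
class PeptideSpan:
    """A digestion product located on the protein (1-based, inclusive)."""

    sequence: str
    start: int
    end: int
    missed_cleavages: int = 0
    is_glycopeptide: bool = True  # False for the N-terminal leftover piece

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"span {self.start}-{self.end} inconsistent with sequence "
                f"length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def local_position(self, protein_position: int) -> int:
        """Convert a protein coordinate to a 1-based peptide coordinate."""
        if not self.contains(protein_position):
            raise ValueError(f"position {protein_position} outside span")
        return protein_position - self.start + 1


@dataclass(frozen=True)
class Glycopeptide:
    """A peptide span plus a site -> glycan map (protein coordinates)."""

    span: PeptideSpan
    site_glycans: Tuple[Tuple[int, GlycanComposition], ...]

    def __init__(
        self,
        span: PeptideSpan,
        site_glycans: Mapping[int, GlycanComposition] | Iterable[Tuple[int, GlycanComposition]],
    ):
        items = dict(site_glycans)
        for pos, comp in items.items():
            if not span.contains(pos):
                raise ValueError(f"glycan position {pos} outside span {span.start}-{span.end}")
            residue = span.sequence[pos - span.start]
            if residue not in ("S", "T"):
                raise ValueError(f"glycan at {pos} ({residue}) is not on S/T")
            if comp.is_empty:
                raise ValueError(f"empty glycan composition at {pos}")
        object.__setattr__(self, "span", span)
        object.__setattr__(
            self, "site_glycans", tuple(sorted(items.items(), key=lambda kv: kv[0]))
        )

    @property
    def sequence(self) -> str:
        return self.span.sequence

    @property
    def sites(self) -> Tuple[int, ...]:
        return tuple(pos for pos, _ in self.site_glycans)

    def local_site_glycans(self) -> Dict[int, GlycanComposition]:
        """Site map keyed by 1-based peptide coordinates."""
        return {self.span.local_position(pos): comp for pos, comp in self.site_glycans}

    def neutral_mass(self) -> float:
        mass = peptide_neutral_mass(self.sequence)
        for _, comp in self.site_glycans:
            mass += glycan_neutral_mass(comp, "residue")
        return mass

    def precursor_mz(self, charge: int) -> float:
        return glycopeptide_precursor_mz(self.sequence, self.local_site_glycans(), charge)

    def occupied_missed_cleavages(self) -> int:
        """Internal (non-N-terminal) glycan-occupied sites in the span."""
        return sum(1 for pos in self.sites if pos != self.span.start)

    def key(self) -> Tuple[str, int, int, Tuple[Tuple[int, str], ...]]:
        return (
            self.sequence,
            self.span.start,
            self.span.end,
            tuple((p, str(c)) for p, c in self.site_glycans),
        )

    def __str__(self) -> str:
        sites = ",".join(f"{self.span.sequence[p - self.span.start]}{p}" for p in self.sites)
        return f"{self.sequence}({self.span.start}-{self.span.end})[{sites}]"


def apply_sialidase(comp: GlycanComposition) -> GlycanComposition:
    """Remove all sialic acids (NeuAc) from a composition.

    May return an empty composition (e.g. for free NeuAc), which downstream
    validation rejects as a glycan.
    """
    remaining = {k: n for k, n in comp.counts if k != "NeuAc"}
    return GlycanComposition(remaining)


def all_st_positions(protein: Protein) -> Tuple[int, ...]:
    """All candidate glycosites: every S/T position in protein coordinates."""
    return tuple(
        protein.first_residue + i
        for i, letter in enumerate(protein.sequence)
        if letter in ("S", "T")
    )


def _validate_sites(protein: Protein, glycosites: Iterable[int]) -> List[int]:
    sites = sorted(set(glycosites))
    for pos in sites:
        residue = protein.residue(pos)
        if residue not in ("S", "T"):
            raise ValueError(f"glycosite {pos} is {residue}, not S/T")
    return sites


def digest(
    protein: Protein,
    glycosites: Iterable[int],
    max_missed: int = 3,
    mode: str = "specific",
    emit_leftover: bool = True,
) -> List[PeptideSpan]:
    """Enumerate OpeRATOR products for a candidate glycosite set.

    In ``specific`` mode every span starts at a glycosite and ends one
    residue before another glycosite (or at the protein C-terminus), skipping
    at most ``max_missed`` internal glycosites.  ``semi_specific`` mode
    additionally allows ragged C-termini: any end position before the next
    enforced boundary.  The N-terminal leftover preceding the first glycosite
    is emitted flagged ``is_glycopeptide=False`` (toggleable).

    Output is duplicate-free and sorted by (start, end).
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if mode not in ("specific", "semi_specific"):
        raise ValueError(f"unknown digestion mode {mode!r}")
    sites = _validate_sites(protein, glycosites)
    spans: List[PeptideSpan] = []
    if not sites:
        return spans
    last = protein.last_residue
    for i, start in enumerate(sites):
        later = sites[i + 1 :]
        # enforced boundaries: each later glycosite, then the C-terminus
        boundaries = [(g, k) for k, g in enumerate(later)] + [(last + 1, len(later))]
        for boundary, missed in boundaries:
            if missed > max_missed:
                break
            end = boundary - 1
            spans.append(
                PeptideSpan(protein.subsequence(start, end), start, end, missed)
            )
            if mode == "semi_specific":
                prev_boundary = start if missed == 0 else boundaries[missed - 1][0]
                for ragged_end in range(prev_boundary, end):
                    spans.append(
                        PeptideSpan(
                            protein.subsequence(start, ragged_end),
                            start,
                            ragged_end,
                            missed,
                        )
                    )
    if emit_leftover and sites[0] > protein.first_residue:
        start, end = protein.first_residue, sites[0] - 1
        spans.append(
            PeptideSpan(protein.subsequence(start, end), start, end, 0, is_glycopeptide=False)
        )
    unique = {(s.start, s.end): s for s in sorted(spans, key=lambda s: s.missed_cleavages)}
    return sorted(unique.values(), key=lambda s: (s.start, s.end))


def enumerate_glycoforms(
    span: PeptideSpan,
    glycosites: Iterable[int],
    allowed: Sequence[GlycanComposition],
    occupancy: str = "full",
    max_missed: Optional[int] = None,
) -> List[Glycopeptide]:
    """Enumerate glycoform assignments for one digestion product.

    ``occupancy='full'`` assigns an allowed composition to *every* glycosite
    in the span (|allowed|^n_sites glycoforms).  ``occupancy='partial'``
    additionally allows internal sites to be unoccupied (the enzyme cannot
    have cut at an unoccupied site, so only occupied internal sites count as
    missed cleavages; filtered at ``max_missed`` when given).  The N-terminal
    site is always glycosylated.
    """
    if not allowed:
        raise ValueError("allowed glycan list is empty")
    for comp in allowed:
        if comp.is_empty:
            raise ValueError("allowed glycans must be non-empty compositions")
    sites_in_span = sorted(p for p in set(glycosites) if span.contains(p))
    if not sites_in_span:
        raise ValueError(f"span {span.start}-{span.end} contains no glycosite")
    if span.start not in sites_in_span:
        raise ValueError(
            f"span {span.start}-{span.end} does not start at a glycosite; "
            "OpeRATOR products carry an N-terminal glycan"
        )
    internal = [p for p in sites_in_span if p != span.start]
    if occupancy == "full":
        occupied_sets: List[Tuple[int, ...]] = [tuple(sites_in_span)]
    elif occupancy == "partial":
        occupied_sets = []
        for r in range(len(internal) + 1):
            if max_missed is not None and r > max_missed:
                break
            for combo in itertools.combinations(internal, r):
                occupied_sets.append((span.start, *combo))
    else:
        raise ValueError(f"unknown occupancy mode {occupancy!r}")
    glycoforms: List[Glycopeptide] = []
    for occupied in occupied_sets:
        for assignment in itertools.product(allowed, repeat=len(occupied)):
            glycoforms.append(Glycopeptide(span, dict(zip(occupied, assignment))))
    return glycoforms


def enumerate_glycopeptides(
    protein: Protein,
    glycosites: Iterable[int],
    allowed: Sequence[GlycanComposition],
    max_missed: int = 3,
    mode: str = "specific",
    occupancy: str = "full",
) -> List[Glycopeptide]:
    """Digest and enumerate glycoforms in one step (the closed search space).

    With ``occupancy='partial'`` the missed-cleavage budget applies to
    glycan-occupied internal sites (unoccupied candidate sites are not
    cleavage opportunities), so span generation itself is unbounded.
    """
    sites = _validate_sites(protein, glycosites)
    span_missed = len(sites) if occupancy == "partial" else max_missed
    spans = digest(protein, sites, span_missed, mode, emit_leftover=False)
    out: List[Glycopeptide] = []
    for span in spans:
        if not any(span.start == p for p in sites):
            continue
        out.extend(
            enumerate_glycoforms(
                span,
                sites,
                allowed,
                occupancy=occupancy,
                max_missed=max_missed if occupancy == "partial" else None,
            )
        )
    return out
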