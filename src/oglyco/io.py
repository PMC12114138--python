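"""File formats: FASTA proteins, MGF peak lists, CSV peak tables.

MGF is the required text spectrum format (BEGIN IONS / TITLE / PEPMASS /
CHARGE / peak rows); read-after-write is the identity on the supported
fields with peak values at six decimals.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, List, Optional, Union

import pandas as pd

from .digest import Protein
from .fragments import Spectrum
from .masses import RESIDUE_MASSES
from .profile import ChromPeak

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_mgf",
    "write_mgf",
    "read_peak_table",
    "write_peak_table",
]

logger = logging.getLogger("oglyco")

PathLike = Union[str, Path]


def read_fasta(path: PathLike, first_residue: int = 1) -> List[Protein]:
    """Parse a FASTA file into protein records (uppercased, validated).

    Residue letters outside the 20 standard amino acids are rejected with
    the offending line number.  ``first_residue`` sets the numbering offset
    applied to every record.
    """
    records: List[Protein] = []
    header: Optional[str] = None
    chunks: List[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        sequence = "".join(chunks)
        if not sequence:
            raise ValueError(f"{path}: record {header!r} (line {header_line}) is empty")
        records.append(Protein(sequence, first_residue, id=header.split()[0]))

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}:{lineno}: sequence before header")
                seq = line.upper().replace(" ", "")
                for letter in seq:
                    if letter not in RESIDUE_MASSES:
                        raise ValueError(
                            f"{path}:{lineno}: illegal residue {letter!r}"
                        )
                chunks.append(seq)
    flush()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[Protein], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as handle:
        for record in records:
            handle.write(f">{record.id or 'protein'}\n")
            for i in range(0, len(record.sequence), width):
                handle.write(record.sequence[i : i + width] + "\n")


def write_mgf(spectra: Iterable[Spectrum], path: PathLike) -> None:
    """Write spectra as MGF with six-decimal peak values."""
    with open(path, "w") as handle:
        for spectrum in spectra:
            handle.write("BEGIN IONS\n")
            handle.write(f"TITLE={spectrum.id}\n")
            handle.write(f"PEPMASS={spectrum.precursor_mz:.6f}\n")
            handle.write(f"CHARGE={spectrum.precursor_charge}+\n")
            for mz, intensity in spectrum.peaks:
                handle.write(f"{mz:.6f} {intensity:.6f}\n")
            handle.write("END IONS\n")


def read_mgf(path: PathLike) -> List[Spectrum]:
    """Read an MGF file; blocks lacking PEPMASS are skipped with a warning."""
    spectra: List[Spectrum] = []
    in_block = False
    title = ""
    pepmass: Optional[float] = None
    charge = 1
    peaks: List[tuple] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line == "BEGIN IONS":
                in_block = True
                title, pepmass, charge, peaks = "", None, 1, []
            elif line == "END IONS":
                if pepmass is None:
                    logger.warning("%s:%d: spectrum without PEPMASS skipped", path, lineno)
                elif not peaks:
                    logger.warning("%s:%d: empty spectrum block skipped", path, lineno)
                else:
                    spectra.append(Spectrum(pepmass, charge, peaks, id=title))
                in_block = False
            elif in_block:
                if line.startswith("TITLE="):
                    title = line[6:]
                elif line.startswith("PEPMASS="):
                    pepmass = float(line[8:].split()[0])
                elif line.startswith("CHARGE="):
                    charge = int(line[7:].rstrip("+"))
                elif line[0].isdigit():
                    parts = line.split()
                    peaks.append((float(parts[0]), float(parts[1])))
    return spectra


_PEAK_COLUMNS = ["sample_id", "rt_min", "area", "mz", "protein_amount_ug"]


def read_peak_table(path: PathLike) -> List[ChromPeak]:
    """Read a chromatographic peak table CSV into ChromPeak objects.

    Required columns: sample_id, rt_min, area; optional: mz,
    protein_amount_ug (blank cells allowed).
    """
    frame = pd.read_csv(path, comment="#")
    missing = {"sample_id", "rt_min", "area"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    peaks = []
    for _, row in frame.iterrows():
        mz = row.get("mz")
        amount = row.get("protein_amount_ug")
        peaks.append(
            ChromPeak(
                retention_time=float(row["rt_min"]),
                area=float(row["area"]),
                observed_mz=None if pd.isna(mz) else float(mz),
                sample_id=str(row["sample_id"]),
                protein_amount=None if pd.isna(amount) else float(amount),
            )
        )
    return peaks


def write_peak_table(peaks: Iterable[ChromPeak], path: PathLike, header: str = "") -> None:
    frame = pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "rt_min": p.retention_time,
                "area": p.area,
                "mz": p.observed_mz,
                "protein_amount_ug": p.protein_amount,
            }
            for p in peaks
        ],
        columns=_PEAK_COLUMNS,
    )
    with open(path, "w") as handle:
        if header:
            handle.write(f"# {header}\n")
        frame.to_csv(handle, index=False)
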