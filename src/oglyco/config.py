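"""Pipeline configuration with search-engine-style defaults.

Defaults mirror the validated search settings: 10 ppm precursor and 20 ppm
fragment tolerance, up to three missed cleavages, semi-specific N-terminal
S/T cleavage, and the three core-1 family glycans before desialylation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import yaml

from .glycans import DEFAULT_ALLOWED_GLYCANS
from .localize import DEFAULT_PRIOR_SITES
from .masses import GlycanComposition

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    precursor_ppm: float = 10.0
    fragment_ppm: float = 20.0
    profile_tolerance_da: float = 0.02
    z_convention: str = "z_dot"  # z | z_dot | z_plus1
    max_missed_cleavages: int = 3
    digestion_mode: str = "semi_specific"  # specific | semi_specific
    allowed_glycans: Tuple[GlycanComposition, ...] = DEFAULT_ALLOWED_GLYCANS
    prior_sites: Tuple[int, ...] = DEFAULT_PRIOR_SITES
    numbering_offset: int = 1
    apply_sialidase: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("precursor_ppm", "fragment_ppm", "profile_tolerance_da"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if self.digestion_mode not in ("specific", "semi_specific"):
            raise ValueError(f"unknown digestion mode {self.digestion_mode!r}")
        if self.z_convention not in ("z", "z_dot", "z_plus1"):
            raise ValueError(f"unknown z convention {self.z_convention!r}")

    def provenance(self) -> str:
        """One-line settings summary embedded in every report header."""
        glycans = ",".join(str(c) for c in self.allowed_glycans)
        return (
            f"oglyco config: precursor_ppm={self.precursor_ppm} "
            f"fragment_ppm={self.fragment_ppm} profile_da={self.profile_tolerance_da} "
            f"z={self.z_convention} max_missed={self.max_missed_cleavages} "
            f"mode={self.digestion_mode} glycans=[{glycans}] "
            f"prior_sites={list(self.prior_sites)} offset={self.numbering_offset} "
            f"sialidase={self.apply_sialidase} seed={self.seed}"
        )


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from YAML; unknown keys are rejected."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "allowed_glycans" in raw:
        raw["allowed_glycans"] = tuple(
            GlycanComposition(counts) for counts in raw["allowed_glycans"]
        )
    if "prior_sites" in raw:
        raw["prior_sites"] = tuple(int(p) for p in raw["prior_sites"])
    return PipelineConfig(**raw)
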