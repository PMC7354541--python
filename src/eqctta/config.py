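"""Run configuration: every analysis convention as a named, serialisable key.

Each place where the filtration-histogram technique admits a choice —
SSF list, entropy bin count, mask erosion, moment convention,
significance level — surfaces here so sensitivity to the convention can
be probed from a YAML file or the command line without touching code.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .errors import InputError
from .filtration import DEFAULT_SSF_MM


@dataclass
class RunConfig:
    """Settings for the simulate -> extract -> correlate -> report workflow."""

    # texture conventions
    ssf_list: tuple[float, ...] = DEFAULT_SSF_MM
    entropy_bins: int = 256
    erosion: bool = True
    excess_kurtosis: bool = True
    min_pixels: int = 50

    # association analysis
    alpha: float = 0.05
    markers: tuple[str, ...] = ("cpa_percent", "ecv", "elf", "ishak")
    benjamini_hochberg: bool = False

    # simulation (used by the simulate/all subcommands)
    n_patients: int = 29
    eq_missing_fraction: float = 8.0 / 29.0
    seed: int = 7
    hepatocyte_loss: bool = False

    # paths
    manifest: Optional[str] = None
    clinical: Optional[str] = None
    out_dir: str = "eqctta_out"

    def __post_init__(self) -> None:
        self.ssf_list = tuple(float(s) for s in self.ssf_list)
        if any(s < 0 for s in self.ssf_list):
            raise InputError("ssf values must be >= 0")
        if len(set(self.ssf_list)) != len(self.ssf_list):
            raise InputError("ssf_list contains duplicates")
        if not (0.0 < self.alpha < 1.0):
            raise InputError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.entropy_bins < 2:
            raise InputError("entropy_bins must be >= 2")
        self.markers = tuple(self.markers)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    def digest(self) -> str:
        """Stable hash of the configuration, for run provenance."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
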