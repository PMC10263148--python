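"""Pipeline configuration: YAML-backed, flag-overridable."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .constants import (
    DEFAULT_CONTACT_THRESHOLD,
    DEFAULT_CUTOFF_HZ,
    DEFAULT_MIN_CONTACT_SAMPLES,
    DEFAULT_NEUTRAL_TOL,
    DEFAULT_RATE_HZ,
)


@dataclass
class PipelineConfig:
    out_dir: str = "limbkin_out"
    seed: int = 0
    preset: str = "bradypus"
    n_forelimb: Optional[int] = None  # None -> preset default (57)
    n_hindlimb: Optional[int] = None  # None -> preset default (90)
    rate_hz: float = DEFAULT_RATE_HZ
    cutoff_hz: float = DEFAULT_CUTOFF_HZ
    contact_threshold: float = DEFAULT_CONTACT_THRESHOLD
    min_contact_samples: int = DEFAULT_MIN_CONTACT_SAMPLES
    neutral_tol: float = DEFAULT_NEUTRAL_TOL
    zero_xy_crosstalk: bool = True
    stride_denominator: str = "per_direction"  # or 'total_vertical'
    rank_transform: bool = False
    n_strides: int = 20

    def validate(self) -> None:
        if not 0 < self.cutoff_hz < self.rate_hz / 2:
            raise ValueError("cutoff must lie in (0, rate/2)")
        if not 0 < self.contact_threshold < 1:
            raise ValueError("contact threshold must lie in (0, 1)")
        if self.stride_denominator not in ("per_direction", "total_vertical"):
            raise ValueError(
                "stride_denominator must be 'per_direction' or 'total_vertical'"
            )
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**payload)
        config.validate()
        return config

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path
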