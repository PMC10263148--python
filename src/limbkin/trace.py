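"""Three-channel force-trace container with trial metadata and state tracking.

A :class:`ForceTrace` holds the fore-aft (x), mediolateral (y) and vertical
(z) channels of one trial, in newtons, at a fixed sampling rate.  The
``state`` flag records the processing stage and may only move forward through
``raw -> corrected -> filtered -> canonical`` (stages may be skipped, never
revisited).

Traces round-trip through plain text: a CSV with columns
``t_s,fx_N,fy_N,fz_N`` plus a JSON sidecar (``<name>.meta.json``) carrying the
sampling rate, state, trial metadata and — for synthetic traces — the
analytic ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

STATE_ORDER = {"raw": 0, "corrected": 1, "filtered": 2, "canonical": 3}

TRACE_COLUMNS = ("t_s", "fx_N", "fy_N", "fz_N")

LIMBS = ("forelimb", "hindlimb")
SIDES = ("left", "right")


@dataclass
class TrialMeta:
    """Per-trial metadata needed to correct and canonicalize a trace."""

    trial_id: str
    animal_id: str
    limb: str
    side: Optional[str] = None
    direction: Optional[int] = None  # +1: travel along +x; -1: along -x
    foot_position_cm: Optional[float] = None
    body_mass_kg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.limb not in LIMBS:
            raise ValueError(f"limb must be one of {LIMBS}, got {self.limb!r}")
        if self.side is not None and self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.direction is not None and self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


@dataclass
class ForceTrace:
    rate_hz: float
    forces: np.ndarray  # (n, 3): columns fx, fy, fz in N
    state: str = "raw"
    meta: Optional[TrialMeta] = None
    truth: Optional[object] = None  # analytic LimbKinetics for synthetic traces

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.ndim != 2 or self.forces.shape[1] != 3:
            raise ValueError("forces must be an (n, 3) array of fx, fy, fz in N")
        if not np.all(np.isfinite(self.forces)):
            raise ValueError("forces contain non-finite values")
        if not self.rate_hz > 0:
            raise ValueError("sampling rate must be positive")
        if self.state not in STATE_ORDER:
            raise ValueError(f"unknown state {self.state!r}")

    # -- basic views -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.forces.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz

    @property
    def fx(self) -> np.ndarray:
        return self.forces[:, 0]

    @property
    def fy(self) -> np.ndarray:
        return self.forces[:, 1]

    @property
    def fz(self) -> np.ndarray:
        return self.forces[:, 2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    # -- state machine -----------------------------------------------------
    def with_forces(self, forces: np.ndarray, state: Optional[str] = None) -> "ForceTrace":
        """Copy of this trace with new channel data and (optionally) a new state.

        States only advance: moving backwards raises ``ValueError``.
        """
        new_state = self.state if state is None else state
        if STATE_ORDER[new_state] < STATE_ORDER[self.state]:
            raise ValueError(
                f"state may not move backwards ({self.state!r} -> {new_state!r})"
            )
        return ForceTrace(self.rate_hz, np.asarray(forces, float), new_state,
                          meta=self.meta, truth=self.truth)

    # -- I/O ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t, "fx_N": self.fx, "fy_N": self.fy, "fz_N": self.fz}
        )

    def write(self, path: str | Path) -> Path:
        """Write ``<path>`` as CSV and ``<path stem>.meta.json`` as sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "rate_hz": self.rate_hz,
            "state": self.state,
            "meta": dataclasses.asdict(self.meta) if self.meta is not None else None,
            "truth": (
                dataclasses.asdict(self.truth)
                if dataclasses.is_dataclass(self.truth)
                else self.truth
            ),
        }
        sidecar_path = path.with_suffix(".meta.json")
        sidecar_path.write_text(json.dumps(sidecar, indent=1))
        return path

    @classmethod
    def read(cls, path: str | Path) -> "ForceTrace":
        path = Path(path)
        try:
            frame = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ValueError(f"could not parse trace CSV {path}: {exc}") from exc
        missing = [c for c in TRACE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"trace CSV {path} lacks columns {missing}")
        sidecar_path = path.with_suffix(".meta.json")
        if not sidecar_path.exists():
            raise ValueError(f"trace {path} has no sidecar {sidecar_path.name}")
        sidecar = json.loads(sidecar_path.read_text())
        meta = TrialMeta(**sidecar["meta"]) if sidecar.get("meta") else None
        return cls(
            rate_hz=float(sidecar["rate_hz"]),
            forces=frame[["fx_N", "fy_N", "fz_N"]].to_numpy(float),
            state=sidecar.get("state", "raw"),
            meta=meta,
            truth=sidecar.get("truth"),
        )
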