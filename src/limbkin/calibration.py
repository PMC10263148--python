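"""Force-platform compliance and cross-talk calibration and correction.

The instrumented grip attachment bends under load, so the force registered by
the load cell is an attenuated, cross-coupled version of the applied force,
and the distortion depends on where along the attachment the foot lands.
Calibration loads of known weight applied at known positions along each axis
yield per-(axis, position) linear regressions of channel reading on applied
force.  The slopes assemble, column-wise, into a position-indexed gain matrix
G(p); inverting the interpolated G at the documented foot position recovers
the true applied force:

    F_true = G(p)^-1 · (reading − offset)

Offsets are normally removed with a per-trial pre-contact baseline (unloaded
drift is trial-specific); the regression intercepts serve as fallback offsets
when no unloaded window exists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .trace import ForceTrace

AXES = ("x", "y", "z")
AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

OBS_COLUMNS = ("loaded_axis", "position_cm", "applied_N", "rx_N", "ry_N", "rz_N")


@dataclass(frozen=True)
class CalibrationObservation:
    """One loading of the platform: known force on one axis at one position."""

    loaded_axis: str
    position_cm: float
    applied_n: float
    readings: tuple  # (rx, ry, rz) in N

    def __post_init__(self) -> None:
        if self.loaded_axis not in AXES:
            raise ValueError(f"loaded_axis must be one of {AXES}")
        if not self.applied_n > 0:
            raise ValueError("applied force must be positive")
        if len(self.readings) != 3:
            raise ValueError("readings must hold the three channel values")


def observations_to_frame(obs: Iterable[CalibrationObservation]) -> pd.DataFrame:
    rows = [
        (o.loaded_axis, o.position_cm, o.applied_n, *o.readings) for o in obs
    ]
    return pd.DataFrame(rows, columns=list(OBS_COLUMNS))


def frame_to_observations(frame: pd.DataFrame) -> List[CalibrationObservation]:
    missing = [c for c in OBS_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"calibration table lacks columns {missing}")
    return [
        CalibrationObservation(
            loaded_axis=row.loaded_axis,
            position_cm=float(row.position_cm),
            applied_n=float(row.applied_N),
            readings=(float(row.rx_N), float(row.ry_N), float(row.rz_N)),
        )
        for row in frame.itertuples()
    ]


@dataclass
class AxisPositionFit:
    """Per-channel OLS fit of reading on applied force for one (axis, position)."""

    loaded_axis: str
    position_cm: float
    slopes: np.ndarray  # (3,) dimensionless, one per reading channel
    intercepts: np.ndarray  # (3,) N
    r_squared: np.ndarray  # (3,)
    n_loads: int


def fit_calibration(
    obs: Union[pd.DataFrame, Iterable[CalibrationObservation]],
) -> List[AxisPositionFit]:
    """Fit reading-on-force regressions for every (loaded axis, position) cell.

    Each cell needs at least three distinct load levels.  R² is reported per
    channel; for a channel with zero variance (e.g. an uncoupled channel in
    noiseless data) R² is 1 when the residuals vanish and 0 otherwise.
    """
    frame = obs if isinstance(obs, pd.DataFrame) else observations_to_frame(obs)
    if isinstance(obs, pd.DataFrame):
        frame_to_observations(frame.head(1))  # column check
    fits: List[AxisPositionFit] = []
    for (axis, pos), cell in frame.groupby(["loaded_axis", "position_cm"], sort=True):
        w = cell["applied_N"].to_numpy(float)
        if np.unique(w).size < 3:
            raise ValueError(
                f"calibration cell (axis={axis}, position={pos} cm) has fewer "
                "than 3 distinct load levels"
            )
        design = np.column_stack([np.ones_like(w), w])
        readings = cell[["rx_N", "ry_N", "rz_N"]].to_numpy(float)
        coef, *_ = np.linalg.lstsq(design, readings, rcond=None)
        resid = readings - design @ coef
        ss_res = np.sum(resid**2, axis=0)
        ss_tot = np.sum((readings - readings.mean(axis=0)) ** 2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(
                ss_tot > 0, 1.0 - ss_res / ss_tot, (ss_res < 1e-20).astype(float)
            )
        fits.append(
            AxisPositionFit(
                loaded_axis=str(axis),
                position_cm=float(pos),
                slopes=coef[1],
                intercepts=coef[0],
                r_squared=r2,
                n_loads=int(np.unique(w).size),
            )
        )
    return fits


@dataclass
class CorrectionModel:
    """Position-indexed gain matrices and offsets inverting the distortion.

    ``gains[k]`` is the 3×3 matrix G at ``positions[k]`` whose column ``a`` is
    the response of the three channels to a unit load on axis ``a``.  Entries
    are interpolated linearly in position between grid points; no
    extrapolation beyond the calibrated range.
    """

    positions: np.ndarray  # (m,) cm, sorted
    gains: np.ndarray  # (m, 3, 3)
    offsets: np.ndarray  # (m, 3) N
    r_squared: np.ndarray  # (m, 3, 3)
    zeroed_xy_crosstalk: bool = False
    max_condition: float = field(default=1e6, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        order = np.argsort(self.positions)
        self.positions = self.positions[order]
        self.gains = np.asarray(self.gains, float)[order]
        self.offsets = np.asarray(self.offsets, float)[order]
        self.r_squared = np.asarray(self.r_squared, float)[order]
        if self.positions.size < 2:
            raise ValueError("correction model needs at least 2 positions")
        self._check_invertible()

    def _check_invertible(self) -> None:
        probes = np.union1d(
            self.positions, (self.positions[:-1] + self.positions[1:]) / 2
        )
        for p in probes:
            g = self.gain_at(p)
            if np.linalg.cond(g) > self.max_condition:
                raise ValueError(
                    f"gain matrix ill-conditioned at position {p} cm"
                )

    def _interp(self, table: np.ndarray, position_cm: float) -> np.ndarray:
        lo, hi = self.positions[0], self.positions[-1]
        if not lo <= position_cm <= hi:
            raise ValueError(
                f"position {position_cm} cm outside calibrated range "
                f"[{lo}, {hi}] cm (no extrapolation)"
            )
        flat = table.reshape(len(self.positions), -1)
        out = np.array(
            [np.interp(position_cm, self.positions, flat[:, j]) for j in range(flat.shape[1])]
        )
        return out.reshape(table.shape[1:])

    def gain_at(self, position_cm: float) -> np.ndarray:
        return self._interp(self.gains, position_cm)

    def offset_at(self, position_cm: float) -> np.ndarray:
        return self._interp(self.offsets, position_cm)

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "positions_cm": self.positions.tolist(),
                "gains": self.gains.tolist(),
                "offsets_N": self.offsets.tolist(),
                "r_squared": self.r_squared.tolist(),
                "zeroed_xy_crosstalk": self.zeroed_xy_crosstalk,
            },
            indent=1,
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "CorrectionModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            positions=np.array(payload["positions_cm"]),
            gains=np.array(payload["gains"]),
            offsets=np.array(payload["offsets_N"]),
            r_squared=np.array(payload["r_squared"]),
            zeroed_xy_crosstalk=bool(payload["zeroed_xy_crosstalk"]),
        )


def build_correction_model(
    fits: Sequence[AxisPositionFit],
    zero_xy_crosstalk: bool = True,
    max_condition: float = 1e6,
) -> CorrectionModel:
    """Assemble a :class:`CorrectionModel` from per-cell calibration fits.

    Column ``a`` of G(p) holds the three channel slopes under axis-``a``
    loading at position ``p``.  With ``zero_xy_crosstalk`` (the default) the
    x↔y entries are forced to zero — the situation in which coupling between
    the two horizontal channels cannot be estimated; the full-matrix path is
    available for complete calibrations.  Channel offsets are the mean of the
    three per-axis regression intercepts.
    """
    positions = sorted({f.position_cm for f in fits})
    if len(positions) < 2:
        raise ValueError("need fits at >= 2 positions")
    by_cell = {(f.loaded_axis, f.position_cm): f for f in fits}
    gains = np.zeros((len(positions), 3, 3))
    offsets = np.zeros((len(positions), 3))
    r2 = np.zeros((len(positions), 3, 3))
    for k, p in enumerate(positions):
        for axis in AXES:
            fit = by_cell.get((axis, p))
            if fit is None:
                raise ValueError(f"no calibration fit for axis {axis} at {p} cm")
            a = AXIS_INDEX[axis]
            gains[k, :, a] = fit.slopes
            r2[k, :, a] = fit.r_squared
            offsets[k] += fit.intercepts / len(AXES)
    if zero_xy_crosstalk:
        gains[:, 0, 1] = 0.0
        gains[:, 1, 0] = 0.0
    return CorrectionModel(
        positions=np.array(positions),
        gains=gains,
        offsets=offsets,
        r_squared=r2,
        zeroed_xy_crosstalk=zero_xy_crosstalk,
        max_condition=max_condition,
    )


def correct_trace(
    raw: ForceTrace,
    model: CorrectionModel,
    foot_position_cm: Optional[float] = None,
    baseline_s: float = 0.5,
    use_model_offsets: bool = False,
) -> ForceTrace:
    """Invert platform compliance and cross-talk for one trial.

    Per sample: ``F = G(p)^-1 · (reading − offset)`` with G and the offsets
    interpolated at the documented foot position ``p``.  By default the
    offset is the per-trial baseline, the channel mean over the first
    ``baseline_s`` seconds of the (unloaded) trace; with
    ``use_model_offsets`` the calibration intercepts are subtracted instead.
    """
    if foot_position_cm is None:
        if raw.meta is None or raw.meta.foot_position_cm is None:
            raise ValueError("foot position required (argument or trial metadata)")
        foot_position_cm = raw.meta.foot_position_cm
    gain = model.gain_at(foot_position_cm)
    if use_model_offsets:
        offset = model.offset_at(foot_position_cm)
    elif baseline_s > 0:
        n_base = min(int(round(baseline_s * raw.rate_hz)), raw.n_samples)
        offset = raw.forces[:n_base].mean(axis=0)
    else:
        offset = np.zeros(3)
    corrected = np.linalg.solve(gain, (raw.forces - offset).T).T
    return raw.with_forces(corrected, "corrected")
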