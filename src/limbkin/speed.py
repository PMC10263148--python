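"""Within-stride speed from tracked 2D landmarks.

Video frames provide a center-of-mass (CoM) point plus two reference
landmarks a known distance apart on the beam; the landmark separation
calibrates pixel space, and the CoM net displacement over a stride window
gives speed.  Pose estimation itself is upstream — the input here is a
tracked-coordinates table (``frame,com_x,com_y,ref1_x,ref1_y,ref2_x,ref2_y``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

#: nominal video frame rate, Hz
DEFAULT_FRAME_RATE_HZ = 60.0

#: nominal separation of the two beam reference landmarks, cm
DEFAULT_LANDMARK_SEPARATION_CM = 106.0

TRACK_COLUMNS = ("frame", "com_x", "com_y", "ref1_x", "ref1_y", "ref2_x", "ref2_y")


@dataclass
class TrackedSeries:
    frame_rate_hz: float
    com_px: np.ndarray  # (n, 2)
    ref1_px: np.ndarray  # (n, 2)
    ref2_px: np.ndarray  # (n, 2)
    known_separation_cm: float = DEFAULT_LANDMARK_SEPARATION_CM

    def __post_init__(self) -> None:
        self.com_px = np.atleast_2d(np.asarray(self.com_px, float))
        self.ref1_px = np.atleast_2d(np.asarray(self.ref1_px, float))
        self.ref2_px = np.atleast_2d(np.asarray(self.ref2_px, float))
        if not self.frame_rate_hz > 0:
            raise ValueError("frame rate must be positive")
        if not self.known_separation_cm > 0:
            raise ValueError("known landmark separation must be positive")
        if not (len(self.com_px) == len(self.ref1_px) == len(self.ref2_px)):
            raise ValueError("landmark series must have equal lengths")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
        known_separation_cm: float = DEFAULT_LANDMARK_SEPARATION_CM,
    ) -> "TrackedSeries":
        frame = pd.read_csv(path)
        missing = [c for c in TRACK_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"tracking CSV {path} lacks columns {missing}")
        frame = frame.sort_values("frame")
        return cls(
            frame_rate_hz=frame_rate_hz,
            com_px=frame[["com_x", "com_y"]].to_numpy(float),
            ref1_px=frame[["ref1_x", "ref1_y"]].to_numpy(float),
            ref2_px=frame[["ref2_x", "ref2_y"]].to_numpy(float),
            known_separation_cm=known_separation_cm,
        )


@dataclass(frozen=True)
class SpeedEstimate:
    scale_cm_per_px: float
    speed_ms: float
    frames_used: int


def spatial_scale(series: TrackedSeries) -> float:
    """cm-per-pixel conversion: known separation over the median pixel distance.

    The median over frames makes the scale robust to per-frame tracking
    jitter.  Coincident reference landmarks raise ``ValueError``.
    """
    dist = np.linalg.norm(series.ref1_px - series.ref2_px, axis=1)
    med = float(np.median(dist))
    if med <= np.finfo(float).eps:
        raise ValueError("reference landmarks are coincident; cannot calibrate")
    return series.known_separation_cm / med


def stride_speed(
    series: TrackedSeries,
    scale_cm_per_px: Optional[float] = None,
    window: Optional[Tuple[int, int]] = None,
    frame_to_frame: bool = False,
) -> SpeedEstimate:
    """Speed over a stride window, m/s.

    Default: net CoM displacement over elapsed time (steady trials show no
    visible acceleration, so endpoints suffice and per-frame noise cancels).
    ``frame_to_frame`` averages instantaneous frame-to-frame speeds instead,
    for sensitivity checks.
    """
    if scale_cm_per_px is None:
        scale_cm_per_px = spatial_scale(series)
    n = len(series.com_px)
    i0, i1 = window if window is not None else (0, n - 1)
    if not 0 <= i0 < i1 < n:
        raise ValueError(f"stride window ({i0}, {i1}) invalid for {n} frames")
    elapsed = (i1 - i0) / series.frame_rate_hz
    com = series.com_px[i0 : i1 + 1]
    if frame_to_frame:
        step = np.linalg.norm(np.diff(com, axis=0), axis=1).sum()
        speed = step * scale_cm_per_px / 100.0 / elapsed
    else:
        disp_px = float(np.linalg.norm(com[-1] - com[0]))
        speed = disp_px * scale_cm_per_px / 100.0 / elapsed
    return SpeedEstimate(
        scale_cm_per_px=scale_cm_per_px,
        speed_ms=float(speed),
        frames_used=i1 - i0 + 1,
    )
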