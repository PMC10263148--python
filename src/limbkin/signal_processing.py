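"""Filtering, contact detection and sign-convention canonicalization.

The processing order mirrors the analysis chain of the instrumented-beam
experiment: corrected traces are low-pass filtered with a zero-phase Fourier
(brickwall) filter, limb contacts are detected from the vertical channel, and
the axes are remapped into the canonical gait frame in which propulsion,
lateral force and substrate pull are all positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .constants import (
    DEFAULT_CONTACT_THRESHOLD,
    DEFAULT_CUTOFF_HZ,
    DEFAULT_MIN_CONTACT_SAMPLES,
)
from .trace import ForceTrace, TrialMeta

#: sign of the canonical vertical axis relative to the laboratory +z (up).
#: The animal hangs below the substrate and pulls it downward, so the lab
#: vertical reading is negative during contact; canonical vertical is the
#: positive pull magnitude.
LAB_VERTICAL_SIGN = -1


@dataclass(frozen=True)
class ContactEvent:
    """Half-open sample interval [onset, offset) of one limb contact."""

    onset: int
    offset: int
    rate_hz: float

    def __post_init__(self) -> None:
        if not self.onset < self.offset:
            raise ValueError("contact onset must precede offset")

    @property
    def duration_s(self) -> float:
        return (self.offset - self.onset) / self.rate_hz


def fourier_lowpass(trace: ForceTrace, cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> ForceTrace:
    """Zero-phase brickwall low-pass: zero every DFT bin above ``cutoff_hz``.

    The filter is a projection (idempotent), preserves DC exactly, and
    introduces no phase shift, so peak timing is untouched.
    """
    if not cutoff_hz < trace.rate_hz / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist ({trace.rate_hz / 2} Hz)"
        )
    n = trace.n_samples
    spectrum = np.fft.rfft(trace.forces, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / trace.rate_hz)
    spectrum[freqs > cutoff_hz, :] = 0.0
    out = np.fft.irfft(spectrum, n=n, axis=0)
    return trace.with_forces(out, "filtered")


def detect_contact(
    trace: ForceTrace,
    body_weight_n: float,
    threshold_frac: float = DEFAULT_CONTACT_THRESHOLD,
    min_samples: int = DEFAULT_MIN_CONTACT_SAMPLES,
) -> List[ContactEvent]:
    """Detect limb contacts from the vertical channel.

    A contact starts where ``|fz|`` exceeds ``threshold_frac * body_weight``
    and persists for at least ``min_samples``; it ends when the signal stays
    below threshold for at least ``min_samples``.  Shorter dropouts are
    bridged.  Returns an empty list when nothing crosses threshold.
    """
    if not body_weight_n > 0:
        raise ValueError("body weight must be positive")
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold fraction must lie in (0, 1)")
    above = np.abs(trace.fz) > threshold_frac * body_weight_n
    edges = np.flatnonzero(np.diff(np.r_[0, above.astype(np.int8), 0]))
    starts, ends = edges[::2], edges[1::2]

    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < min_samples:
            merged[-1][1] = e  # bridge a sub-persistence dropout
        else:
            merged.append([s, e])
    return [
        ContactEvent(onset=s, offset=e, rate_hz=trace.rate_hz)
        for s, e in merged
        if e - s >= min_samples
    ]


def _canonical_signs(meta: TrialMeta) -> np.ndarray:
    if meta is None or meta.side is None or meta.direction is None:
        raise ValueError(
            "canonicalization requires trial metadata with limb side and "
            "direction of travel"
        )
    sx = float(meta.direction)  # propulsion positive along travel direction
    # +y points to the animal's left when traveling +x (camera convention);
    # lateral (away from the midline) must come out positive.
    sy = float(meta.direction) * (1.0 if meta.side == "left" else -1.0)
    sz = float(LAB_VERTICAL_SIGN)  # report substrate pull as positive
    return np.array([sx, sy, sz])


def canonicalize(trace: ForceTrace) -> ForceTrace:
    """Remap axes into the canonical gait frame by per-axis sign flips.

    Canonical frame: +x = propulsive, -x = braking; +y = lateral (away from
    the midline), -y = medial; +z = pull on the substrate.  The flip pattern
    depends on direction of travel and limb side, so the same canonical trace
    results from a contact and its mirrored (opposite side, opposite travel)
    counterpart.
    """
    signs = _canonical_signs(trace.meta)
    return trace.with_forces(trace.forces * signs, "canonical")


def decanonicalize(trace: ForceTrace, meta: TrialMeta) -> ForceTrace:
    """Inverse of :func:`canonicalize`: canonical-frame -> laboratory frame.

    Used by the synthetic generator, which constructs profiles in the
    canonical frame and then expresses them as the platform would record them
    for the given limb side and travel direction.  Output state is ``raw``.
    """
    signs = _canonical_signs(meta)  # sign flips are involutions
    return ForceTrace(
        trace.rate_hz, trace.forces * signs, "raw", meta=meta, truth=trace.truth
    )
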