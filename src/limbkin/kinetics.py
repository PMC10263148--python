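"""Stance-phase peak forces, impulses, limb role and stride weight support.

Five directional quantities are extracted per contact — vertical (V),
propulsive (P), braking (B), medial (M) and lateral (L) peak force and
impulse — plus the net fore-aft impulse, whose sign classifies the limb as
net propulsive (+) or net braking (−) within a tolerance band.  Peak forces
are expressed as a percentage of body weight (%BW) and impulses as a
percentage of body weight · seconds (%BWS).

Sign conventions follow the canonical gait frame (see
:mod:`limbkin.signal_processing`): braking and medial quantities are stored
signed-negative; magnitudes are available via :meth:`LimbKinetics.magnitudes`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Dict, Optional

import numpy as np

from .constants import DEFAULT_NEUTRAL_TOL, GRAVITY
from .signal_processing import ContactEvent
from .trace import ForceTrace


@dataclass(frozen=True)
class AnimalRecord:
    animal_id: str
    body_mass_kg: float

    def __post_init__(self) -> None:
        if not self.body_mass_kg > 0:
            raise ValueError("body mass must be positive")

    @property
    def body_weight_n(self) -> float:
        return self.body_mass_kg * GRAVITY


#: the ten directional quantities, in export order
PEAK_FIELDS = ("vpk", "ppk", "bpk", "mpk", "lpk")
IMPULSE_FIELDS = ("jv", "jp", "jb", "jm", "jl")


@dataclass
class LimbKinetics:
    """Peak/impulse set for one limb contact (forces %BW, impulses %BWS)."""

    limb: str
    vpk: float
    ppk: float
    bpk: float  # <= 0
    mpk: float  # <= 0
    lpk: float
    jv: float
    jp: float
    jb: float  # <= 0
    jm: float  # <= 0
    jl: float
    net_fore_aft: float
    role: str
    duration_s: float
    speed_ms: Optional[float] = None

    def magnitudes(self) -> Dict[str, float]:
        """Absolute values of the ten directional quantities."""
        return {
            name: abs(getattr(self, name)) for name in PEAK_FIELDS + IMPULSE_FIELDS
        }

    @classmethod
    def from_dict(cls, payload: Dict) -> "LimbKinetics":
        names = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in payload.items() if k in names})


def extract_peaks(
    trace: ForceTrace, event: ContactEvent, animal: AnimalRecord
) -> Dict[str, float]:
    """Directional peak forces over the contact window, in %BW.

    Requires a canonical-frame trace.  V_pk is the maximum vertical pull;
    P_pk/L_pk the largest positive fore-aft/mediolateral forces; B_pk/M_pk
    the most negative (zero when the channel never crosses zero in that
    direction).
    """
    fx, fy, fz = _window(trace, event)
    scale = 100.0 / animal.body_weight_n
    return {
        "vpk": float(fz.max() * scale),
        "ppk": float(max(fx.max(), 0.0) * scale),
        "bpk": float(min(fx.min(), 0.0) * scale),
        "mpk": float(min(fy.min(), 0.0) * scale),
        "lpk": float(max(fy.max(), 0.0) * scale),
    }


def compute_impulses(
    trace: ForceTrace, event: ContactEvent, animal: AnimalRecord
) -> Dict[str, float]:
    """Directional impulses and net fore-aft impulse over the contact, %BWS.

    Trapezoidal integration at the native sampling rate.  The propulsive and
    braking impulses integrate the positive and negative parts of the
    fore-aft channel, so ``jp + jb`` equals the net fore-aft impulse exactly.
    """
    fx, fy, fz = _window(trace, event)
    dt = 1.0 / trace.rate_hz
    scale = 100.0 / animal.body_weight_n

    def integral(y: np.ndarray) -> float:
        return float(np.trapezoid(y, dx=dt) * scale)

    return {
        "jv": integral(fz),
        "jp": integral(np.clip(fx, 0.0, None)),
        "jb": integral(np.clip(fx, None, 0.0)),
        "jm": integral(np.clip(fy, None, 0.0)),
        "jl": integral(np.clip(fy, 0.0, None)),
        "net_fore_aft": integral(fx),
    }


def classify_role(net_fore_aft: float, tol: float = DEFAULT_NEUTRAL_TOL) -> str:
    """Limb functional role from the signed net fore-aft impulse (%BWS)."""
    if not np.isfinite(net_fore_aft):
        raise ValueError("net fore-aft impulse must be finite")
    if net_fore_aft > tol:
        return "net propulsive"
    if net_fore_aft < -tol:
        return "net braking"
    return "neutral"


def contact_kinetics(
    trace: ForceTrace,
    event: ContactEvent,
    animal: AnimalRecord,
    neutral_tol: float = DEFAULT_NEUTRAL_TOL,
    speed_ms: Optional[float] = None,
) -> LimbKinetics:
    """Full per-contact kinetics record (peaks, impulses, role, duration)."""
    peaks = extract_peaks(trace, event, animal)
    impulses = compute_impulses(trace, event, animal)
    net = impulses.pop("net_fore_aft")
    limb = trace.meta.limb if trace.meta is not None else "forelimb"
    return LimbKinetics(
        limb=limb,
        **peaks,
        **impulses,
        net_fore_aft=net,
        role=classify_role(net, neutral_tol),
        duration_s=event.duration_s,
        speed_ms=speed_ms,
    )


@dataclass(frozen=True)
class StrideSupport:
    """Forelimb/hindlimb shares of stride impulse, in percent.

    ``denominator='per_direction'`` divides each limb's impulse by the
    two-limb total of the same direction (vertical, propulsive, braking
    handled separately).  ``denominator='total_vertical'`` divides every
    directional impulse by the two-limb total *vertical* impulse instead.
    In both variants the two vertical percentages sum to 100.
    """

    stride_id: str
    fore_jv: float
    hind_jv: float
    fore_jp: float
    hind_jp: float
    fore_jb: float
    hind_jb: float
    fore_pct_vertical: float
    hind_pct_vertical: float
    fore_pct_propulsive: float
    hind_pct_propulsive: float
    fore_pct_braking: float
    hind_pct_braking: float
    denominator: str


def stride_support(
    fore: LimbKinetics,
    hind: LimbKinetics,
    stride_id: str = "stride",
    denominator: str = "per_direction",
) -> StrideSupport:
    """Partition one stride's weight support between fore- and hindlimb.

    Requires one forelimb and one hindlimb contact from the same stride.
    """
    if fore.limb != "forelimb" or hind.limb != "hindlimb":
        raise ValueError("stride_support expects (forelimb, hindlimb) kinetics")
    if denominator not in ("per_direction", "total_vertical"):
        raise ValueError("denominator must be 'per_direction' or 'total_vertical'")
    total_jv = fore.jv + hind.jv
    if total_jv <= 0:
        raise ValueError("total vertical impulse must be positive")

    def share(a: float, b: float) -> tuple[float, float]:
        if denominator == "total_vertical":
            return 100.0 * a / total_jv, 100.0 * b / total_jv
        total = a + b
        if total == 0:
            return float("nan"), float("nan")
        return 100.0 * a / total, 100.0 * b / total

    pv = share(fore.jv, hind.jv)
    pp = share(fore.jp, hind.jp)
    pb = share(abs(fore.jb), abs(hind.jb))
    return StrideSupport(
        stride_id=stride_id,
        fore_jv=fore.jv, hind_jv=hind.jv,
        fore_jp=fore.jp, hind_jp=hind.jp,
        fore_jb=fore.jb, hind_jb=hind.jb,
        fore_pct_vertical=pv[0], hind_pct_vertical=pv[1],
        fore_pct_propulsive=pp[0], hind_pct_propulsive=pp[1],
        fore_pct_braking=pb[0], hind_pct_braking=pb[1],
        denominator=denominator,
    )


def _window(trace: ForceTrace, event: ContactEvent) -> tuple[np.ndarray, ...]:
    if trace.state != "canonical":
        raise ValueError("kinetics require a canonical-frame trace")
    if event.offset > trace.n_samples:
        raise ValueError("contact event extends past the end of the trace")
    sl = slice(event.onset, event.offset)
    fx, fy, fz = trace.fx[sl], trace.fy[sl], trace.fz[sl]
    if fx.size == 0:
        raise ValueError("empty contact window")
    return fx, fy, fz
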