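"""Synthetic single-contact force profiles, cohorts and platform distortion.

No raw force recordings from the suspensory-walking experiments are publicly
deposited, so every downstream stage of the pipeline is exercised against
synthetic traces with known analytic ground truth:

* :func:`generate_contact_profile` builds one contact from half-sine lobes
  (vertical half-sine; fore-aft propulsive/braking lobe pair split at a
  configurable time; mediolateral lateral/medial lobe pair).  Half-sine lobes
  have the closed-form impulse ``2 * amplitude * duration / pi``, which is
  attached to the trace as ground truth.
* :func:`generate_cohort` draws per-contact targets (vertical peak, net
  fore-aft impulse, lateral/medial peaks, contact duration) from per-limb
  distributions, solves the lobe amplitudes that realize the targets, and
  emits laboratory-frame traces with full ground truth.  The packaged
  ``bradypus`` preset encodes the pooled statistics reported for three-toed
  sloths (hindlimb-biased vertical peaks, net-propulsive forelimbs,
  net-braking hindlimbs, appreciable lateral peaks in both limb pairs).
* :class:`PlatformModel` and :func:`apply_platform_distortion` simulate the
  compliance of the instrumented grip attachment — position-dependent gain
  attenuation, channel cross-talk, offsets and sensor noise — and
  :func:`generate_calibration_dataset` reproduces the 10-load x 5-position x
  3-axis static calibration protocol used to invert it.

Magnitude targets are drawn from zero-truncated normal distributions whose
*realized* (post-truncation) mean equals the requested mean; see
``docs/methods.md`` for the moment-matching details and its limits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterator, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .constants import DEFAULT_NOISE_SD_N, DEFAULT_RATE_HZ, GRAVITY
from .kinetics import AnimalRecord, LimbKinetics, classify_role
from .signal_processing import decanonicalize
from .trace import ForceTrace, TrialMeta

#: default calibration protocol: 10 masses spanning 0.1-3.40 kg ...
DEFAULT_CAL_MASSES_KG = (0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 3.40)
#: ... at five positions along the attachment (cm from the load cell)
DEFAULT_CAL_POSITIONS_CM = (-5.0, -2.5, 0.0, 2.5, 5.0)


def half_sine_lobe_impulse(amplitude: float, duration_s: float) -> float:
    """Closed-form impulse of a half-sine lobe: ``2 * A * duration / pi``."""
    return 2.0 * amplitude * duration_s / math.pi


# ---------------------------------------------------------------------------
# truncated-normal samplers
# ---------------------------------------------------------------------------

def truncated_normal(
    mean: float,
    sd: float,
    rng: np.random.Generator,
    size: Optional[int] = None,
    lower: float = 0.0,
) -> np.ndarray:
    """Sample N(mean, sd) truncated below at ``lower`` (parent parameters)."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return np.full(size if size is not None else 1, float(mean))
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                               size=size, random_state=rng)


def _std_trunc_moments(a: float) -> tuple[float, float]:
    """(mean, sd) of a standard normal truncated below at ``a``."""
    lam = stats.norm.pdf(a) / stats.norm.sf(a)
    var = 1.0 + a * lam - lam**2
    return lam, math.sqrt(max(var, 0.0))


#: largest usable standardized truncation point; the coefficient of variation
#: of a zero-truncated normal saturates near 0.97 as a -> +inf
_A_MAX = 5.0


def zero_truncated_normal_params(mean: float, sd: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a zero-truncated normal with realized mean ``mean``.

    The realized sd matches ``sd`` whenever the target coefficient of
    variation is attainable by the family; above the family's supremum the
    truncation point is capped and the realized sd falls short of the target
    (the mean stays exact).
    """
    if mean <= 0:
        raise ValueError("zero-truncated magnitude needs a positive mean")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return float(mean), 0.0
    target_cv = sd / mean

    def cv_of(a: float) -> float:
        lam, s = _std_trunc_moments(a)
        return s / (lam - a)

    a_lo = min(-12.0, -3.0 / target_cv)
    if target_cv >= cv_of(_A_MAX):
        a = _A_MAX
    elif target_cv <= cv_of(a_lo):
        a = a_lo
    else:
        a = optimize.brentq(lambda x: cv_of(x) - target_cv, a_lo, _A_MAX)
    lam, _ = _std_trunc_moments(a)
    sigma = mean / (lam - a)
    return -a * sigma, sigma


def calibrated_zero_truncated(
    mean: float, sd: float, rng: np.random.Generator, size: Optional[int] = None
) -> np.ndarray:
    """Zero-truncated normal samples whose expectation equals ``mean``."""
    mu, sigma = zero_truncated_normal_params(mean, sd)
    if sigma == 0:
        return np.full(size if size is not None else 1, mu)
    a = (0.0 - mu) / sigma
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma,
                               size=size, random_state=rng)


# ---------------------------------------------------------------------------
# single-contact profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileParams:
    """Shape parameters of one synthetic contact (canonical frame, %BW)."""

    duration_s: float  # T: contact duration
    vertical_peak: float  # %BW
    fore_aft_split_s: float  # time separating the two fore-aft lobes, 0 < tau < T
    propulsive_peak: float  # %BW, amplitude of the propulsive lobe
    braking_peak: float  # %BW, magnitude of the braking lobe
    medial_peak: float  # %BW, magnitude
    lateral_peak: float  # %BW
    ml_split_s: float  # time separating lateral and medial lobes
    noise_sd: float = 0.0  # %BW, additive white Gaussian
    propulsion_first: bool = True
    lateral_first: bool = True

    def validate(self, rate_hz: float) -> None:
        values = (
            self.duration_s, self.vertical_peak, self.fore_aft_split_s,
            self.propulsive_peak, self.braking_peak, self.medial_peak,
            self.lateral_peak, self.ml_split_s, self.noise_sd,
        )
        if not all(np.isfinite(values)):
            raise ValueError("profile parameters must be finite")
        if not self.duration_s > 0:
            raise ValueError("contact duration must be positive")
        if not 0 < self.fore_aft_split_s < self.duration_s:
            raise ValueError("fore-aft split must lie strictly inside the contact")
        if not 0 < self.ml_split_s < self.duration_s:
            raise ValueError("mediolateral split must lie strictly inside the contact")
        for name in ("vertical_peak", "propulsive_peak", "braking_peak",
                     "medial_peak", "lateral_peak", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if rate_hz < 2.0 / self.duration_s:
            raise ValueError("sampling rate too low for the contact duration")


def _lobe_pair(
    t: np.ndarray,
    split_s: float,
    duration_s: float,
    first_amp: float,
    second_amp: float,
) -> np.ndarray:
    """Two opposed half-sine lobes on [0, split) and [split, T)."""
    out = np.zeros_like(t)
    first = t < split_s
    out[first] = first_amp * np.sin(np.pi * t[first] / split_s)
    second = ~first
    out[second] = second_amp * np.sin(
        np.pi * (t[second] - split_s) / (duration_s - split_s)
    )
    return out


def profile_truth(
    params: ProfileParams, limb: str = "forelimb", speed_ms: Optional[float] = None
) -> LimbKinetics:
    """Analytic peak/impulse ground truth of a noiseless profile."""
    T, tau = params.duration_s, params.fore_aft_split_s
    dp, db = (tau, T - tau) if params.propulsion_first else (T - tau, tau)
    dl, dm = (
        (params.ml_split_s, T - params.ml_split_s)
        if params.lateral_first
        else (T - params.ml_split_s, params.ml_split_s)
    )
    jp = half_sine_lobe_impulse(params.propulsive_peak, dp)
    jb = -half_sine_lobe_impulse(params.braking_peak, db)
    net = jp + jb
    return LimbKinetics(
        limb=limb,
        vpk=params.vertical_peak,
        ppk=params.propulsive_peak,
        bpk=-params.braking_peak,
        mpk=-params.medial_peak,
        lpk=params.lateral_peak,
        jv=half_sine_lobe_impulse(params.vertical_peak, T),
        jp=jp,
        jb=jb,
        jm=-half_sine_lobe_impulse(params.medial_peak, dm),
        jl=half_sine_lobe_impulse(params.lateral_peak, dl),
        net_fore_aft=net,
        role=classify_role(net),
        duration_s=T,
        speed_ms=speed_ms,
    )


def generate_contact_profile(
    params: ProfileParams,
    body_weight_n: float,
    rate_hz: float = DEFAULT_RATE_HZ,
    seed: Optional[int | np.random.Generator] = None,
    lead_s: float = 1.0,
    trail_s: float = 1.0,
    meta: Optional[TrialMeta] = None,
) -> ForceTrace:
    """One synthetic contact in the canonical frame, in newtons.

    The contact occupies ``ceil(T * rate)`` samples between unloaded lead-in
    and lead-out segments; the analytic ground truth (peaks and closed-form
    lobe impulses, %BW / %BWS) is attached as ``trace.truth``.
    """
    params.validate(rate_hz)
    if not body_weight_n > 0:
        raise ValueError("body weight must be positive")
    n_contact = math.ceil(params.duration_s * rate_hz)
    n_lead = int(round(lead_s * rate_hz))
    n_trail = int(round(trail_s * rate_hz))
    t = np.arange(n_contact) / rate_hz

    T = params.duration_s
    fz = params.vertical_peak * np.sin(np.pi * np.minimum(t, T) / T)
    if params.propulsion_first:
        fx = _lobe_pair(t, params.fore_aft_split_s, T,
                        params.propulsive_peak, -params.braking_peak)
    else:
        fx = _lobe_pair(t, params.fore_aft_split_s, T,
                        -params.braking_peak, params.propulsive_peak)
    if params.lateral_first:
        fy = _lobe_pair(t, params.ml_split_s, T,
                        params.lateral_peak, -params.medial_peak)
    else:
        fy = _lobe_pair(t, params.ml_split_s, T,
                        -params.medial_peak, params.lateral_peak)

    contact = np.column_stack([fx, fy, fz])
    forces = np.vstack(
        [np.zeros((n_lead, 3)), contact, np.zeros((n_trail, 3))]
    ) * (body_weight_n / 100.0)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        forces = forces + rng.normal(
            0.0, params.noise_sd * body_weight_n / 100.0, forces.shape
        )
    limb = meta.limb if meta is not None else "forelimb"
    return ForceTrace(
        rate_hz=rate_hz,
        forces=forces,
        state="canonical",
        meta=meta,
        truth=profile_truth(params, limb=limb),
    )


# ---------------------------------------------------------------------------
# platform distortion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlatformModel:
    """Ground-truth distortion of the instrumented grip attachment.

    The recorded force is ``G(p) · F_true + o(p) + noise`` where ``p`` is the
    contact position in cm from the load cell.  Diagonal gains fall off away
    from the center (bending compliance); vertical load bleeds into the
    horizontal channels (cross-talk), anti-symmetrically into x (the
    attachment tilts with the bending direction) and symmetrically into y.
    Every entry is piecewise-linear in ``p`` with its only kink at the
    center, so a grid calibration at the five standard positions captures
    the distortion exactly.

    ``xy_gain`` couples the two horizontal channels and defaults to zero,
    the situation in which that coupling cannot be estimated from the
    calibration protocol.
    """

    diag_center: tuple = (0.94, 0.93, 0.90)  # gains at p=0 for x, y, z
    diag_edge_drop: tuple = (0.03, 0.03, 0.05)  # additional attenuation at |p|=span
    zx_bend_gain: float = 0.04  # z load -> x reading at the span edge, odd in p
    zy_gain_center: float = 0.02  # z load -> y reading at the center
    zy_gain_edge: float = 0.02  # additional z->y at the edge, even in p
    xz_gain: float = 0.03  # x load -> z reading, position-independent
    yz_gain_edge: float = 0.02  # y load -> z reading at the edge
    xy_gain: float = 0.0  # x <-> y coupling (unobservable by default protocol)
    offsets_center_n: tuple = (0.05, -0.04, 0.10)
    oz_edge_n: float = 0.04  # extra vertical offset at the edge
    half_span_cm: float = 5.0
    noise_sd_n: float = DEFAULT_NOISE_SD_N
    attachment_mass_kg: float = 0.140  # documented; inertial effects not modeled

    def __post_init__(self) -> None:
        for g in self.diag_center:
            if not 0 < g <= 1.2:
                raise ValueError("diagonal gains must lie in (0, 1.2]")

    def _check_position(self, position_cm: float) -> None:
        if abs(position_cm) > self.half_span_cm:
            raise ValueError(
                f"position {position_cm} cm outside the calibrated "
                f"+/-{self.half_span_cm} cm range"
            )

    def gain_matrix(self, position_cm: float) -> np.ndarray:
        self._check_position(position_cm)
        u = abs(position_cm) / self.half_span_cm
        s = position_cm / self.half_span_cm
        gx, gy, gz = (
            c - d * u for c, d in zip(self.diag_center, self.diag_edge_drop)
        )
        return np.array(
            [
                [gx, self.xy_gain, self.zx_bend_gain * s],
                [self.xy_gain, gy, self.zy_gain_center + self.zy_gain_edge * u],
                [self.xz_gain, self.yz_gain_edge * u, gz],
            ]
        )

    def offset(self, position_cm: float) -> np.ndarray:
        self._check_position(position_cm)
        u = abs(position_cm) / self.half_span_cm
        ox, oy, oz = self.offsets_center_n
        return np.array([ox, oy, oz + self.oz_edge_n * u])


def apply_platform_distortion(
    trace: ForceTrace,
    platform: PlatformModel,
    position_cm: Optional[float] = None,
    seed: Optional[int | np.random.Generator] = None,
) -> ForceTrace:
    """Record a true trace through the distorting platform (output is raw)."""
    if position_cm is None:
        if trace.meta is None or trace.meta.foot_position_cm is None:
            raise ValueError("contact position required (argument or metadata)")
        position_cm = trace.meta.foot_position_cm
    gain = platform.gain_matrix(position_cm)
    recorded = trace.forces @ gain.T + platform.offset(position_cm)
    if platform.noise_sd_n > 0:
        rng = np.random.default_rng(seed)
        recorded = recorded + rng.normal(0.0, platform.noise_sd_n, recorded.shape)
    meta = trace.meta
    if meta is not None and meta.foot_position_cm is None:
        meta = replace(meta, foot_position_cm=position_cm)
    return ForceTrace(trace.rate_hz, recorded, "raw", meta=meta, truth=trace.truth)


def generate_calibration_dataset(
    platform: PlatformModel,
    masses_kg: Sequence[float] = DEFAULT_CAL_MASSES_KG,
    positions_cm: Sequence[float] = DEFAULT_CAL_POSITIONS_CM,
    seed: Optional[int | np.random.Generator] = None,
) -> pd.DataFrame:
    """Static calibration observations: axes x masses x positions.

    For every axis, position and mass the applied force ``m * g`` is loaded
    along that axis and the three distorted channel readings are recorded.
    Columns: ``loaded_axis, position_cm, applied_N, rx_N, ry_N, rz_N``.
    """
    if len(masses_kg) == 0 or len(positions_cm) == 0:
        raise ValueError("masses and positions must be non-empty")
    if any(m <= 0 for m in masses_kg):
        raise ValueError("calibration masses must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for axis_idx, axis in enumerate(("x", "y", "z")):
        for p in positions_cm:
            gain = platform.gain_matrix(p)
            off = platform.offset(p)
            for m in masses_kg:
                w = m * GRAVITY
                applied = np.zeros(3)
                applied[axis_idx] = w
                reading = gain @ applied + off
                if platform.noise_sd_n > 0:
                    reading = reading + rng.normal(0.0, platform.noise_sd_n, 3)
                rows.append((axis, p, w, *reading))
    return pd.DataFrame(
        rows, columns=["loaded_axis", "position_cm", "applied_N",
                       "rx_N", "ry_N", "rz_N"]
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dist:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Per-limb distributional targets for a synthetic cohort of contacts."""

    limb: str
    n_contacts: int
    vertical_peak: Dist  # %BW
    net_impulse: Dist  # %BWS, signed
    lateral_peak: Dist  # %BW
    medial_peak: Dist  # %BW magnitude
    minor_fore_aft_peak: Dist  # %BW: braking lobe for a net-propulsive limb, etc.
    duration_s: Dist = Dist(3.0, 0.5)
    speed_ms: Dist = Dist(0.12, 0.04)
    body_mass_kg: Dist = Dist(3.84, 0.3)
    n_animals: int = 5
    rate_hz: float = DEFAULT_RATE_HZ
    fore_aft_split_frac: float = 0.75
    ml_split_frac: float = 0.4
    propulsion_first: bool = True
    lateral_first: bool = True
    min_duration_s: float = 1.0

    def __post_init__(self) -> None:
        if self.n_contacts < 1:
            raise ValueError("n_contacts must be >= 1")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if not self.rate_hz > 0:
            raise ValueError("sampling rate must be positive")
        if not 0 < self.fore_aft_split_frac < 1:
            raise ValueError("fore_aft_split_frac must lie in (0, 1)")
        if not 0 < self.ml_split_frac < 1:
            raise ValueError("ml_split_frac must lie in (0, 1)")


def bradypus_defaults(limb: str) -> CohortSpec:
    """Packaged default cohort spec for one limb of *Bradypus variegatus*."""
    payload = yaml.safe_load(
        resources.files("limbkin").joinpath("presets/bradypus.yaml").read_text()
    )
    if limb not in ("forelimb", "hindlimb"):
        raise ValueError("limb must be 'forelimb' or 'hindlimb'")
    limb_cfg = payload[limb]
    return CohortSpec(
        limb=limb,
        n_contacts=int(limb_cfg["n_contacts"]),
        vertical_peak=Dist(**limb_cfg["vertical_peak"]),
        net_impulse=Dist(**limb_cfg["net_impulse"]),
        lateral_peak=Dist(**limb_cfg["lateral_peak"]),
        medial_peak=Dist(**limb_cfg["medial_peak"]),
        minor_fore_aft_peak=Dist(**limb_cfg["minor_fore_aft_peak"]),
        duration_s=Dist(**payload["duration_s"]),
        speed_ms=Dist(**payload["speed_ms"]),
        body_mass_kg=Dist(**payload["body_mass_kg"]),
        n_animals=int(payload["n_animals"]),
        rate_hz=float(payload["rate_hz"]),
        fore_aft_split_frac=float(limb_cfg["fore_aft_split_frac"]),
        ml_split_frac=float(limb_cfg["ml_split_frac"]),
        min_duration_s=float(payload["min_duration_s"]),
    )


_MAX_RESAMPLE_ROUNDS = 100


def sample_cohort_params(
    spec: CohortSpec, rng: np.random.Generator
) -> List[ProfileParams]:
    """Draw per-contact targets and solve the realizing lobe amplitudes.

    The major fore-aft lobe (propulsive for a net-propulsive limb, braking
    otherwise) is solved from the sampled net impulse and the sampled minor
    lobe peak via the half-sine closed form; draws whose solution would need
    a negative amplitude are resampled (capped, with a warning).
    """
    n = spec.n_contacts
    T = truncated_normal(spec.duration_s.mean, spec.duration_s.sd, rng,
                         size=n, lower=spec.min_duration_s)
    vpk = calibrated_zero_truncated(spec.vertical_peak.mean,
                                    spec.vertical_peak.sd, rng, size=n)
    lpk = calibrated_zero_truncated(spec.lateral_peak.mean,
                                    spec.lateral_peak.sd, rng, size=n)
    mpk = calibrated_zero_truncated(spec.medial_peak.mean,
                                    spec.medial_peak.sd, rng, size=n)
    minor = calibrated_zero_truncated(spec.minor_fore_aft_peak.mean,
                                      spec.minor_fore_aft_peak.sd, rng, size=n)
    jnet = rng.normal(spec.net_impulse.mean, spec.net_impulse.sd, size=n)

    tau = spec.fore_aft_split_frac * T
    dp, db = (tau, T - tau) if spec.propulsion_first else (T - tau, tau)
    net_propulsive = spec.net_impulse.mean >= 0

    def solve_major(jn, mn):
        if net_propulsive:  # minor lobe brakes; solve the propulsive amplitude
            return (math.pi * jn / 2.0 + mn * db) / dp
        return (mn * dp - math.pi * jn / 2.0) / db  # braking amplitude

    major = solve_major(jnet, minor)
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = major < 0
        if not np.any(bad):
            break
        warnings.warn(
            f"resampling {int(bad.sum())} infeasible net-impulse draws",
            stacklevel=2,
        )
        jnet[bad] = rng.normal(spec.net_impulse.mean, spec.net_impulse.sd,
                               size=int(bad.sum()))
        minor[bad] = calibrated_zero_truncated(
            spec.minor_fore_aft_peak.mean, spec.minor_fore_aft_peak.sd,
            rng, size=int(bad.sum()),
        )
        major = solve_major(jnet, minor)
    else:
        raise RuntimeError("could not realize the net-impulse targets")

    ppk = major if net_propulsive else minor
    bpk = minor if net_propulsive else major
    return [
        ProfileParams(
            duration_s=float(T[i]),
            vertical_peak=float(vpk[i]),
            fore_aft_split_s=float(tau[i]),
            propulsive_peak=float(ppk[i]),
            braking_peak=float(bpk[i]),
            medial_peak=float(mpk[i]),
            lateral_peak=float(lpk[i]),
            ml_split_s=float(spec.ml_split_frac * T[i]),
            propulsion_first=spec.propulsion_first,
            lateral_first=spec.lateral_first,
        )
        for i in range(n)
    ]


@dataclass
class CohortContact:
    """One synthetic contact: lab-frame true trace plus full ground truth."""

    trace: ForceTrace  # laboratory frame, noiseless true forces, state 'raw'
    canonical: ForceTrace  # same contact in the canonical frame
    animal: AnimalRecord
    truth: LimbKinetics
    params: ProfileParams


def iter_cohort(
    spec: CohortSpec,
    seed: Optional[int | np.random.Generator] = None,
    lead_s: float = 1.0,
    trail_s: float = 1.0,
) -> Iterator[CohortContact]:
    """Stream a cohort of synthetic contacts; deterministic under a fixed seed."""
    rng = np.random.default_rng(seed)
    masses = truncated_normal(spec.body_mass_kg.mean, spec.body_mass_kg.sd,
                              rng, size=spec.n_animals, lower=0.5)
    animals = [
        AnimalRecord(animal_id=f"Bv{i + 1}", body_mass_kg=float(masses[i]))
        for i in range(spec.n_animals)
    ]
    params_list = sample_cohort_params(spec, rng)
    speeds = truncated_normal(spec.speed_ms.mean, spec.speed_ms.sd, rng,
                              size=spec.n_contacts, lower=0.01)
    sides = rng.choice(["left", "right"], size=spec.n_contacts)
    directions = rng.choice([1, -1], size=spec.n_contacts)
    positions = rng.uniform(-5.0, 5.0, size=spec.n_contacts)

    for i, params in enumerate(params_list):
        animal = animals[i % spec.n_animals]
        meta = TrialMeta(
            trial_id=f"{spec.limb[:4]}-{i:04d}",
            animal_id=animal.animal_id,
            limb=spec.limb,
            side=str(sides[i]),
            direction=int(directions[i]),
            foot_position_cm=float(positions[i]),
            body_mass_kg=animal.body_mass_kg,
        )
        canonical = generate_contact_profile(
            params, animal.body_weight_n, rate_hz=spec.rate_hz,
            lead_s=lead_s, trail_s=trail_s, meta=meta,
        )
        truth = replace(canonical.truth, speed_ms=float(speeds[i]))
        canonical.truth = truth
        lab = decanonicalize(canonical, meta)
        yield CohortContact(
            trace=lab, canonical=canonical, animal=animal,
            truth=truth, params=params,
        )


def generate_cohort(
    spec: CohortSpec,
    seed: Optional[int | np.random.Generator] = None,
    lead_s: float = 1.0,
    trail_s: float = 1.0,
) -> List[CohortContact]:
    return list(iter_cohort(spec, seed=seed, lead_s=lead_s, trail_s=trail_s))
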