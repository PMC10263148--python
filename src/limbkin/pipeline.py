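"""End-to-end orchestration: calibrate -> correct -> filter -> canonicalize ->
detect -> extract -> summarize.

The closed-loop entry point :func:`recover_cohort` runs a full synthetic
cohort (ground-truth traces, simulated platform distortion, calibration-based
correction, filtering, canonicalization, contact detection and kinetics
extraction) and returns the tidy per-contact table, which is how the package
validates itself against the published pooled statistics.
"""

from __future__ import annotations

import dataclasses
import json
import platform as _platform
from pathlib import Path
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    CorrectionModel,
    build_correction_model,
    correct_trace,
    fit_calibration,
)
from .config import PipelineConfig
from .constants import (
    DEFAULT_CONTACT_THRESHOLD,
    DEFAULT_CUTOFF_HZ,
    DEFAULT_MIN_CONTACT_SAMPLES,
    DEFAULT_NEUTRAL_TOL,
)
from .kinetics import AnimalRecord, LimbKinetics, contact_kinetics, stride_support
from .signal_processing import canonicalize, detect_contact, fourier_lowpass
from .summary_stats import format_summary, kinetics_table, summarize
from .synthetic import (
    CohortContact,
    PlatformModel,
    apply_platform_distortion,
    bradypus_defaults,
    generate_calibration_dataset,
    iter_cohort,
)
from .trace import ForceTrace, TrialMeta


def build_default_model(
    platform: Optional[PlatformModel] = None,
    seed: Optional[int | np.random.Generator] = None,
    zero_xy_crosstalk: bool = True,
) -> CorrectionModel:
    """Calibrate the (default) platform with the standard static protocol."""
    platform = platform if platform is not None else PlatformModel()
    obs = generate_calibration_dataset(platform, seed=seed)
    return build_correction_model(
        fit_calibration(obs), zero_xy_crosstalk=zero_xy_crosstalk
    )


def analyze_trace(
    raw: ForceTrace,
    model: CorrectionModel,
    animal: AnimalRecord,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    contact_threshold: float = DEFAULT_CONTACT_THRESHOLD,
    min_contact_samples: int = DEFAULT_MIN_CONTACT_SAMPLES,
    neutral_tol: float = DEFAULT_NEUTRAL_TOL,
    speed_ms: Optional[float] = None,
) -> Optional[LimbKinetics]:
    """Run one raw trace through correction, filtering, canonicalization and
    kinetics extraction.  Returns ``None`` when no contact is detected."""
    corrected = correct_trace(raw, model)
    filtered = fourier_lowpass(corrected, cutoff_hz)
    canonical = canonicalize(filtered)
    events = detect_contact(
        canonical,
        body_weight_n=animal.body_weight_n,
        threshold_frac=contact_threshold,
        min_samples=min_contact_samples,
    )
    if not events:
        return None
    event = max(events, key=lambda e: e.offset - e.onset)
    return contact_kinetics(
        canonical, event, animal, neutral_tol=neutral_tol, speed_ms=speed_ms
    )


def recover_cohort(
    spec,
    seed: Optional[int] = None,
    platform: Optional[PlatformModel] = None,
    model: Optional[CorrectionModel] = None,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    contact_threshold: float = DEFAULT_CONTACT_THRESHOLD,
    neutral_tol: float = DEFAULT_NEUTRAL_TOL,
) -> Tuple[pd.DataFrame, pd.DataFrame, List[TrialMeta]]:
    """Closed-loop recovery of a synthetic cohort through the full pipeline.

    Returns ``(recovered, truth, metas)``: tidy tables of pipeline-extracted
    and ground-truth kinetics, row-aligned per contact.
    """
    platform = platform if platform is not None else PlatformModel()
    rng = np.random.default_rng(seed)
    if model is None:
        model = build_default_model(platform, seed=rng)
    recovered: List[LimbKinetics] = []
    truths: List[LimbKinetics] = []
    metas: List[TrialMeta] = []
    for contact in iter_cohort(spec, seed=rng):
        raw = apply_platform_distortion(contact.trace, platform, seed=rng)
        kin = analyze_trace(
            raw, model, contact.animal,
            cutoff_hz=cutoff_hz,
            contact_threshold=contact_threshold,
            neutral_tol=neutral_tol,
            speed_ms=contact.truth.speed_ms,
        )
        if kin is None:  # pragma: no cover - not expected at default settings
            continue
        recovered.append(kin)
        truths.append(contact.truth)
        metas.append(raw.meta)
    return (
        kinetics_table(recovered, metas),
        kinetics_table(truths, metas),
        metas,
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full synthetic pipeline described by ``config``.

    Writes the calibration table and correction model, the per-contact
    kinetics table (and ground truth), stride-level weight-support shares,
    descriptive summaries, and a run log recording every configurable value.
    Deterministic for a fixed seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    platform = PlatformModel()

    obs = generate_calibration_dataset(platform, seed=rng)
    obs.to_csv(out / "calibration_observations.csv", index=False)
    model = build_correction_model(
        fit_calibration(obs), zero_xy_crosstalk=config.zero_xy_crosstalk
    )
    model.save(out / "correction_model.json")

    recovered_parts, truth_parts = [], []
    per_limb: dict[str, list] = {}
    for limb, n_override in (
        ("forelimb", config.n_forelimb),
        ("hindlimb", config.n_hindlimb),
    ):
        spec = bradypus_defaults(limb)
        if n_override is not None:
            spec = dataclasses.replace(spec, n_contacts=n_override)
        rec, truth, metas = recover_cohort(
            spec,
            seed=rng,
            platform=platform,
            model=model,
            cutoff_hz=config.cutoff_hz,
            contact_threshold=config.contact_threshold,
            neutral_tol=config.neutral_tol,
        )
        recovered_parts.append(rec)
        truth_parts.append(truth)
        per_limb[limb] = rec

    kinetics = pd.concat(recovered_parts, ignore_index=True)
    truth = pd.concat(truth_parts, ignore_index=True)
    kinetics.to_csv(out / "kinetics.csv", index=False)
    truth.to_csv(out / "kinetics_truth.csv", index=False)

    strides = _stride_table(per_limb["forelimb"], per_limb["hindlimb"],
                            n_strides=config.n_strides,
                            denominator=config.stride_denominator)
    strides.to_csv(out / "stride_support.csv", index=False)

    summary = summarize(kinetics)
    summary.to_csv(out / "summary.csv", index=False)
    (out / "summary.txt").write_text(format_summary(summary) + "\n")

    log = {
        "limbkin_version": __version__,
        "python": _platform.python_version(),
        "numpy": np.__version__,
        "config": config.to_dict(),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return out


def _stride_table(
    fore: pd.DataFrame,
    hind: pd.DataFrame,
    n_strides: int,
    denominator: str,
) -> pd.DataFrame:
    """Pair consecutive fore/hind contacts into strides and partition support."""
    n = min(len(fore), len(hind), n_strides)
    rows = []
    for i in range(n):
        fk = _row_to_kinetics(fore.iloc[i], "forelimb")
        hk = _row_to_kinetics(hind.iloc[i], "hindlimb")
        support = stride_support(fk, hk, stride_id=f"stride-{i:03d}",
                                 denominator=denominator)
        rows.append(dataclasses.asdict(support))
    return pd.DataFrame(rows)


def _row_to_kinetics(row: pd.Series, limb: str) -> LimbKinetics:
    return LimbKinetics(
        limb=limb,
        vpk=row["Vpk"], ppk=row["Ppk"], bpk=row["Bpk"],
        mpk=row["Mpk"], lpk=row["Lpk"],
        jv=row["JV"], jp=row["JP"], jb=row["JB"],
        jm=row["JM"], jl=row["JL"],
        net_fore_aft=row["net"], role=row["role"],
        duration_s=row["duration_s"], speed_ms=row["speed_ms"],
    )
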