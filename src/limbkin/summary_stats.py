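"""Descriptive tables, rank transformation and the model-ready export.

Magnitude comparisons motivate the descriptive surface: the ten directional
peak/impulse quantities are summarized as absolute values, grouped by limb
(optionally by individual), with the signed net fore-aft impulse kept as is.
Responses destined for external mixed-effects fits (limb and species as
factors, speed as covariate, individual as random effect) can be
rank-transformed with average ranks for ties.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import IMPULSE_FIELDS, PEAK_FIELDS, LimbKinetics
from .trace import TrialMeta

#: tidy per-contact export columns
KINETICS_COLUMNS = (
    "animal", "trial", "limb", "side", "speed_ms",
    "Vpk", "Ppk", "Bpk", "Mpk", "Lpk",
    "JV", "JP", "JB", "JM", "JL",
    "net", "role", "duration_s",
)

_FIELD_TO_COLUMN = dict(
    zip(PEAK_FIELDS + IMPULSE_FIELDS, ("Vpk", "Ppk", "Bpk", "Mpk", "Lpk",
                                       "JV", "JP", "JB", "JM", "JL"))
)

#: columns summarized as magnitudes
MAGNITUDE_COLUMNS = tuple(_FIELD_TO_COLUMN.values())


def rank_transform(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties receiving the average of their rank span."""
    arr = np.asarray(values, float)
    if arr.size == 0:
        raise ValueError("rank_transform needs at least one value")
    if not np.all(np.isfinite(arr)):
        raise ValueError("rank_transform requires finite values")
    return stats.rankdata(arr, method="average")


def kinetics_table(
    records: Iterable[LimbKinetics],
    metas: Optional[Iterable[Optional[TrialMeta]]] = None,
) -> pd.DataFrame:
    """Tidy one-row-per-contact table from kinetics records."""
    records = list(records)
    metas = list(metas) if metas is not None else [None] * len(records)
    if len(metas) != len(records):
        raise ValueError("metas must match records one-to-one")
    rows = []
    for kin, meta in zip(records, metas):
        row = {
            "animal": meta.animal_id if meta else None,
            "trial": meta.trial_id if meta else None,
            "limb": kin.limb,
            "side": meta.side if meta else None,
            "speed_ms": kin.speed_ms,
        }
        for name, col in _FIELD_TO_COLUMN.items():
            row[col] = getattr(kin, name)
        row["net"] = kin.net_fore_aft
        row["role"] = kin.role
        row["duration_s"] = kin.duration_s
        rows.append(row)
    return pd.DataFrame(rows, columns=list(KINETICS_COLUMNS))


def summarize(
    table: pd.DataFrame,
    per_individual: bool = False,
    pooling: str = "contacts",
) -> pd.DataFrame:
    """Long-format descriptive statistics by limb (x variable).

    Directional quantities enter as magnitudes; ``net`` stays signed.  With
    ``pooling='contacts'`` (default) the pooled row is the grand mean across
    contacts; ``pooling='individuals'`` averages per-animal means (sd across
    animals).  ``per_individual`` reports one row per animal instead of the
    pooled row.  Groups of size one report sd as NA.
    """
    if table.empty:
        raise ValueError("cannot summarize an empty kinetics table")
    if pooling not in ("contacts", "individuals"):
        raise ValueError("pooling must be 'contacts' or 'individuals'")
    work = table.copy()
    for col in MAGNITUDE_COLUMNS:
        work[col] = work[col].abs()
    variables = list(MAGNITUDE_COLUMNS) + ["net"]
    group_cols = ["limb", "animal"] if per_individual else ["limb"]

    rows = []
    for keys, group in work.groupby(group_cols, dropna=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        for var in variables:
            if per_individual or pooling == "contacts":
                vals = group[var].dropna()
                mean = vals.mean()
                sd = vals.std(ddof=1) if len(vals) > 1 else np.nan
                n = len(vals)
            else:  # pooled across individual means
                means = group.groupby("animal")[var].mean().dropna()
                mean = means.mean()
                sd = means.std(ddof=1) if len(means) > 1 else np.nan
                n = len(group[var].dropna())
            row = dict(zip(group_cols, keys))
            row.update({"variable": var, "n": n, "mean": mean, "sd": sd})
            rows.append(row)
    return pd.DataFrame(rows)


def export_model_table(
    table: pd.DataFrame,
    speeds: Optional[pd.DataFrame] = None,
    response: str = "Vpk",
    rank_response: bool = False,
    species: str = "Bradypus variegatus",
) -> pd.DataFrame:
    """One row per contact, ready for an external mixed-effects fit.

    Columns: response (magnitude, optionally rank-transformed), ``limb`` and
    ``species`` factors, ``speed_ms`` covariate, ``individual`` random-effect
    key.  ``speeds`` (columns ``trial, speed_ms``) fills speeds missing from
    the kinetics table; contacts still lacking a speed or animal id raise
    ``ValueError`` listing the trials.
    """
    if response not in MAGNITUDE_COLUMNS:
        raise ValueError(f"response must be one of {MAGNITUDE_COLUMNS}")
    work = table.copy()
    if speeds is not None:
        if not {"trial", "speed_ms"} <= set(speeds.columns):
            raise ValueError("speeds table needs 'trial' and 'speed_ms' columns")
        work = work.drop(columns=["speed_ms"]).merge(
            speeds[["trial", "speed_ms"]], on="trial", how="left"
        )
    missing = work.loc[work["speed_ms"].isna() | work["animal"].isna(), "trial"]
    if len(missing):
        raise ValueError(
            "missing speed or individual for trials: "
            + ", ".join(str(t) for t in missing.tolist())
        )
    out = pd.DataFrame(
        {
            "trial": work["trial"],
            "individual": work["animal"],
            "species": species,
            "limb": work["limb"],
            "speed_ms": work["speed_ms"],
            "response": work[response].abs(),
        }
    )
    if rank_response:
        out["response"] = rank_transform(out["response"].to_numpy())
    return out


def format_summary(summary: pd.DataFrame) -> str:
    """Aligned-text report of a :func:`summarize` table."""
    return summary.to_string(
        index=False, float_format=lambda v: f"{v:9.3f}", na_rep="NA"
    )
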