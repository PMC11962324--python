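"""Quality control, standardization, label derivation, and patient splitting.

Operates on tidy one-row-per-patient-day tables with the seven behavioral
feature columns (six continuous plus the binary ``sport`` indicator). Time
denominated features are stored in hours, distance in km, steps and visited
places as counts. No operation ever imputes a missing value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from moodcast.synthetic import BINARY_FEATURE, CONTINUOUS_FEATURES, FEATURES

#: Physical caps applied during QC: time-denominated features cannot exceed a
#: day, steps are capped at 30,000/day and distance at 500 km/day.
QC_CAPS = {"steps": 30000.0, "distance": 500.0, "sleep": 24.0, "app_use": 24.0, "time_home": 24.0}

SUBSETS = ("hmm", "transformer", "classifier")


class SchemaError(ValueError):
    """A required feature column is missing from the input table."""


def _require_columns(df: pd.DataFrame, columns: list[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")


def quality_control(df: pd.DataFrame) -> pd.DataFrame:
    """Clean raw daily summaries.

    Negative values become missing (a negative sensor total is an artifact,
    not evidence of zero activity); values above their physical cap are
    clipped to the cap; the sport indicator is coerced to {0, 1, missing}.
    Idempotent, and never decreases the number of missing values.
    """
    _require_columns(df, ["patient_id", "date"] + FEATURES)
    out = df.copy()
    for col in CONTINUOUS_FEATURES:
        vals = pd.to_numeric(out[col], errors="coerce").astype(float)
        vals[vals < 0] = np.nan
        cap = QC_CAPS.get(col)
        if cap is not None:
            vals = vals.clip(upper=cap)
        out[col] = vals
    sport = pd.to_numeric(out[BINARY_FEATURE], errors="coerce").astype(float)
    sport[sport < 0] = np.nan
    out[BINARY_FEATURE] = (sport > 0).astype(float).where(sport.notna())
    return out


@dataclass
class StandardizationParams:
    """Frozen per-feature location/scale fitted on a designated patient subset."""

    means: pd.Series
    sds: pd.Series
    fitted_on: list[str] = field(default_factory=list)


def fit_standardizer(df: pd.DataFrame, patient_ids: list[str] | None = None) -> StandardizationParams:
    """Fit per-feature mean/SD on the rows of ``patient_ids`` (all if None).

    A feature with zero spread keeps scale 1 (centered only) with a warning.
    """
    _require_columns(df, CONTINUOUS_FEATURES)
    sub = df if patient_ids is None else df[df["patient_id"].isin(patient_ids)]
    means = sub[CONTINUOUS_FEATURES].mean()
    sds = sub[CONTINUOUS_FEATURES].std(ddof=0)
    zero = sds[sds == 0].index.tolist()
    if zero:
        warnings.warn(f"zero-variance features left centered only: {zero}", stacklevel=2)
        sds[zero] = 1.0
    fitted_on = [] if patient_ids is None else list(patient_ids)
    return StandardizationParams(means=means, sds=sds, fitted_on=fitted_on)


def apply_standardizer(params: StandardizationParams, df: pd.DataFrame) -> pd.DataFrame:
    """(x - mean)/SD on continuous features; missing stays missing; the
    binary feature is untouched."""
    out = df.copy()
    out[CONTINUOUS_FEATURES] = (out[CONTINUOUS_FEATURES] - params.means) / params.sds
    return out


def derive_valence(positive: int, negative: int) -> float:
    """Daily valence from signed emotion-report counts.

    0 (negative) if negative reports exceed positive ones, 2 (positive) if the
    reverse, 1 (neutral) on a tie with at least one report, NaN when nothing
    was reported that day.
    """
    if positive < 0 or negative < 0:
        raise ValueError("emotion counts must be non-negative")
    if positive == 0 and negative == 0:
        return np.nan
    diff = positive - negative
    return 0.0 if diff < 0 else (2.0 if diff > 0 else 1.0)


def binarize_phq9(item_score: int) -> int:
    """Collapse the four PHQ-9 frequency classes to two.

    'Not at all' (0) and 'several days' (1) -> 0 (low frequency);
    'more than half the days' (2) and 'nearly every day' (3) -> 1.
    """
    if item_score not in (0, 1, 2, 3):
        raise ValueError(f"PHQ-9 item score must be in 0..3, got {item_score!r}")
    return int(item_score >= 2)


def split_patients(
    patients: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.3, 0.4, 0.3),
    seed: int = 0,
) -> pd.Series:
    """Stratified-by-cohort random patient partition into hmm/transformer/classifier.

    ``patients`` needs columns ``patient_id`` and ``cohort``. Within each
    cohort, patients are shuffled and subset sizes chosen by largest-remainder
    apportionment of ``fractions``, so the partition is disjoint, exhaustive,
    and matches the target proportions per cohort as closely as integer counts
    allow. Cohorts with fewer than 3 patients go wholly to the largest subset
    with a warning. Deterministic under ``seed``.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    _require_columns(patients, ["patient_id", "cohort"])
    if patients["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in split input")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    biggest = SUBSETS[int(np.argmax(fractions))]
    for cohort, group in patients.groupby("cohort", sort=True):
        ids = group["patient_id"].tolist()
        if len(ids) < 3:
            warnings.warn(f"cohort {cohort!r} has <3 patients; assigned wholly to {biggest!r}", stacklevel=2)
            for pid in ids:
                assignment[pid] = biggest
            continue
        order = rng.permutation(len(ids))
        quotas = np.array(fractions) * len(ids)
        counts = np.floor(quotas).astype(int)
        remainder = quotas - counts
        for idx in np.argsort(-remainder)[: len(ids) - counts.sum()]:
            counts[idx] += 1
        bounds = np.cumsum(counts)
        for rank, pos in enumerate(order):
            subset = SUBSETS[int(np.searchsorted(bounds, rank, side="right"))]
            assignment[ids[pos]] = subset
    result = pd.Series(assignment, name="subset")
    result.index.name = "patient_id"
    return result


def regularize_days(df: pd.DataFrame) -> pd.DataFrame:
    """Fill calendar gaps with all-missing rows so daily spacing is uniform.

    Sequences are indexed 0-based from each patient's first observed day.
    """
    _require_columns(df, ["patient_id", "date"])
    out = []
    for pid, group in df.groupby("patient_id", sort=True):
        g = group.sort_values("date").set_index("date")
        full = pd.date_range(g.index.min(), g.index.max(), freq="D")
        g = g.reindex(full)
        g["patient_id"] = pid
        g.index.name = "date"
        out.append(g.reset_index())
    res = pd.concat(out, ignore_index=True)
    return res[["patient_id", "date"] + [c for c in res.columns if c not in ("patient_id", "date")]]


def load_schema(path) -> dict[str, str]:
    """YAML mapping of input column names to canonical roles."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise SchemaError("schema file must contain a mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def apply_schema(df: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    """Rename columns of a foreign export to the canonical daily schema."""
    unknown = [v for v in mapping.values() if v not in ("patient_id", "date", "valence", "cohort", *FEATURES)]
    if unknown:
        raise SchemaError(f"unknown roles in schema: {unknown}")
    return df.rename(columns=mapping)


def feature_matrix(df: pd.DataFrame, patient_id: str) -> np.ndarray:
    """(T, 7) feature array for one patient, rows in date order."""
    sub = df[df["patient_id"] == patient_id].sort_values("date")
    return sub[FEATURES].to_numpy(dtype=float)
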