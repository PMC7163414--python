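"""Clinical time-series featurization and training-set preprocessing.

Every complex (time-stamped) predictor variable is summarized into a fixed,
category-specific feature group so that standard classifiers apply: 35
features per laboratory test and per vital sign, 31 per ventilator setting,
9 per medication administration, 4 per culture and per procedure, and 2 per
intake/output variable; atemporal variables (demographics, diagnosis)
contribute one integer-coded feature each. A case is thereby a fixed-width
vector regardless of how much data it has; variables with no data in a case
fill their group with missing markers.

Preprocessing, applied in a fixed order to a training matrix: drop features
constant across cases, keep one representative of each class of features
identical across cases, then impute missing values two ways (median/mode,
and regression on the remaining features), yielding two complete variants
of the same matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression

from gazerel.config import ATEMPORAL_CATEGORIES, TIME_SERIES_CATEGORIES
from gazerel.errors import InputError, SchemaError
from gazerel.simulate import PatientCase, variable_ids

logger = logging.getLogger(__name__)

#: canonical 35-feature list for numeric series (labs and vital signs).
#: Time features are in hours; "24h" refers to the window ending at the
#: prediction time.
NUMERIC_FEATURES = (
    "first_value",
    "last_value",
    "highest_value",
    "lowest_value",
    "diff_last_two",          # last minus second-to-last
    "ever_measured",
    "n_measurements",
    "n_measurements_24h",
    "hours_since_first",
    "hours_since_last",
    "hours_since_highest",
    "hours_since_lowest",
    "mean_value",
    "median_value",
    "std_value",
    "range_value",
    "slope_overall",          # least-squares slope, value per hour
    "slope_24h",
    "mean_24h",
    "median_24h",
    "std_24h",
    "min_24h",
    "max_24h",
    "first_24h",
    "range_24h",
    "last_minus_first",
    "last_minus_mean",
    "last_minus_mean_24h",
    "max_diff_consecutive",
    "min_diff_consecutive",
    "mean_abs_diff_consecutive",
    "n_mean_crossings",
    "frac_above_mean",
    "hours_span",
    "mean_gap_hours",
)
assert len(NUMERIC_FEATURES) == 35

#: ventilator settings are partly categorical, so the four slope/step
#: features that presume a continuous scale are dropped from the 35-list
_VENTILATOR_DROP = ("slope_overall", "slope_24h", "max_diff_consecutive", "min_diff_consecutive")
VENTILATOR_FEATURES = tuple(f for f in NUMERIC_FEATURES if f not in _VENTILATOR_DROP)
assert len(VENTILATOR_FEATURES) == 31

MEDICATION_FEATURES = (
    "ever_given",
    "n_administrations",
    "n_administrations_24h",
    "hours_since_last_dose",
    "hours_since_first_dose",
    "last_dose_value",
    "cumulative_dose",
    "dose_trend",             # last dose minus first dose
    "n_distinct_days",
)
assert len(MEDICATION_FEATURES) == 9

EVENT_FEATURES = ("ever_recorded", "n_events", "hours_since_last", "any_last_24h")
assert len(EVENT_FEATURES) == 4

IO_FEATURES = ("total_24h", "n_records")
assert len(IO_FEATURES) == 2

ATEMPORAL_FEATURES = ("value",)

CATEGORY_FEATURES: dict[str, tuple[str, ...]] = {
    "vitals": NUMERIC_FEATURES,
    "labs": NUMERIC_FEATURES,
    "ventilator": VENTILATOR_FEATURES,
    "medications": MEDICATION_FEATURES,
    "procedures": EVENT_FEATURES,
    "cultures": EVENT_FEATURES,
    "intake_output": IO_FEATURES,
    "demographics": ATEMPORAL_FEATURES,
    "diagnosis": ATEMPORAL_FEATURES,
}

#: atemporal variables imputed with the mode rather than the median
NOMINAL_VARIABLES = {"sex", "race", "admission_unit", "diagnosis"}

_WINDOW_H = 24.0


@dataclass
class FeatureSchema:
    """Canonical ordered feature layout: variable -> its feature group."""

    variables: list[tuple[str, str]]  # (variable_id, category), canonical order

    def __post_init__(self) -> None:
        seen = set()
        for var, cat in self.variables:
            if cat not in CATEGORY_FEATURES:
                raise SchemaError(f"unknown category {cat!r} for variable {var}")
            if var in seen:
                raise SchemaError(f"duplicate variable {var}")
            seen.add(var)

    @classmethod
    def from_counts(cls, variable_counts: Mapping[str, int]) -> "FeatureSchema":
        inv = variable_ids(variable_counts)
        variables = [
            (var, cat)
            for cat in ATEMPORAL_CATEGORIES + TIME_SERIES_CATEGORIES
            for var in inv[cat]
        ]
        return cls(variables=variables)

    @property
    def columns(self) -> list[str]:
        return [
            f"{var}::{feat}"
            for var, cat in self.variables
            for feat in CATEGORY_FEATURES[cat]
        ]

    @property
    def width(self) -> int:
        return sum(len(CATEGORY_FEATURES[cat]) for _, cat in self.variables)

    def group_columns(self, variable_id: str) -> list[str]:
        for var, cat in self.variables:
            if var == variable_id:
                return [f"{var}::{f}" for f in CATEGORY_FEATURES[cat]]
        raise SchemaError(f"variable {variable_id} not in schema")

    def column_to_variable(self) -> dict[str, str]:
        return {col: col.split("::", 1)[0] for col in self.columns}

    def nominal_columns(self) -> set[str]:
        return {
            f"{var}::value"
            for var, cat in self.variables
            if cat in ATEMPORAL_CATEGORIES and var in NOMINAL_VARIABLES
        }

    def time_series_variables(self) -> list[str]:
        return [v for v, c in self.variables if c in TIME_SERIES_CATEGORIES]

    def to_dict(self) -> dict:
        return {
            "variables": [list(v) for v in self.variables],
            "columns": self.columns,
            "nominal_columns": sorted(self.nominal_columns()),
        }


def _lstsq_slope(t: np.ndarray, v: np.ndarray) -> float:
    if len(t) < 2 or np.ptp(t) == 0:
        return np.nan
    tc = t - t.mean()
    return float(np.dot(tc, v - v.mean()) / np.dot(tc, tc))


def _numeric_features(
    t: np.ndarray, v: np.ndarray, pred: float, include: Sequence[str]
) -> dict[str, float]:
    n = len(v)
    w = t >= pred - _WINDOW_H
    tw, vw = t[w], v[w]
    diffs = np.diff(v) if n >= 2 else np.array([])
    centered = v - v.mean()
    signs = np.sign(centered)
    signs = signs[signs != 0]
    crossings = int(np.sum(signs[1:] != signs[:-1])) if len(signs) >= 2 else 0
    out = {
        "first_value": v[0],
        "last_value": v[-1],
        "highest_value": v.max(),
        "lowest_value": v.min(),
        "diff_last_two": v[-1] - v[-2] if n >= 2 else np.nan,
        "ever_measured": 1.0,
        "n_measurements": float(n),
        "n_measurements_24h": float(w.sum()),
        "hours_since_first": pred - t[0],
        "hours_since_last": pred - t[-1],
        "hours_since_highest": pred - t[int(np.argmax(v))],
        "hours_since_lowest": pred - t[int(np.argmin(v))],
        "mean_value": v.mean(),
        "median_value": float(np.median(v)),
        "std_value": float(np.std(v, ddof=1)) if n >= 2 else np.nan,
        "range_value": float(np.ptp(v)),
        "slope_overall": _lstsq_slope(t, v),
        "slope_24h": _lstsq_slope(tw, vw),
        "mean_24h": vw.mean() if len(vw) else np.nan,
        "median_24h": float(np.median(vw)) if len(vw) else np.nan,
        "std_24h": float(np.std(vw, ddof=1)) if len(vw) >= 2 else np.nan,
        "min_24h": vw.min() if len(vw) else np.nan,
        "max_24h": vw.max() if len(vw) else np.nan,
        "first_24h": vw[0] if len(vw) else np.nan,
        "range_24h": float(np.ptp(vw)) if len(vw) else np.nan,
        "last_minus_first": v[-1] - v[0],
        "last_minus_mean": v[-1] - v.mean(),
        "last_minus_mean_24h": v[-1] - vw.mean() if len(vw) else np.nan,
        "max_diff_consecutive": diffs.max() if len(diffs) else np.nan,
        "min_diff_consecutive": diffs.min() if len(diffs) else np.nan,
        "mean_abs_diff_consecutive": float(np.abs(diffs).mean()) if len(diffs) else np.nan,
        "n_mean_crossings": float(crossings),
        "frac_above_mean": float(np.mean(v > v.mean())),
        "hours_span": t[-1] - t[0],
        "mean_gap_hours": (t[-1] - t[0]) / (n - 1) if n >= 2 else np.nan,
    }
    return {k: float(out[k]) for k in include}


def _medication_features(t: np.ndarray, v: np.ndarray, pred: float, adm: float) -> dict[str, float]:
    w = t >= pred - _WINDOW_H
    days = np.unique(np.floor((t - adm) / 24.0))
    return {
        "ever_given": 1.0,
        "n_administrations": float(len(v)),
        "n_administrations_24h": float(w.sum()),
        "hours_since_last_dose": float(pred - t[-1]),
        "hours_since_first_dose": float(pred - t[0]),
        "last_dose_value": float(v[-1]),
        "cumulative_dose": float(v.sum()),
        "dose_trend": float(v[-1] - v[0]),
        "n_distinct_days": float(len(days)),
    }


def _event_features(t: np.ndarray, pred: float) -> dict[str, float]:
    w = t >= pred - _WINDOW_H
    return {
        "ever_recorded": 1.0,
        "n_events": float(len(t)),
        "hours_since_last": float(pred - t[-1]),
        "any_last_24h": 1.0 if w.any() else 0.0,
    }


def _io_features(t: np.ndarray, v: np.ndarray, pred: float) -> dict[str, float]:
    w = t >= pred - _WINDOW_H
    return {"total_24h": float(v[w].sum()), "n_records": float(len(v))}


def build_feature_group(
    series: Sequence[tuple[float, float]],
    category: str,
    prediction_time_h: float,
    admission_time_h: float = 0.0,
) -> dict[str, float]:
    """Summarize one variable's time series into its fixed feature group.

    Returns exactly the category's feature count of named values, in schema
    order; features undefined for short series (e.g. the last-two difference
    with a single point) are emitted as NaN. The series must be
    time-sorted.
    """
    if category not in CATEGORY_FEATURES:
        raise SchemaError(f"unknown category {category!r}")
    if category in ATEMPORAL_CATEGORIES:
        raise SchemaError("atemporal variables are scalar, not series")
    if not series:
        raise InputError("empty series; omit the variable instead")
    t = np.array([p[0] for p in series], dtype=float)
    v = np.array([p[1] for p in series], dtype=float)
    if np.any(np.diff(t) < 0):
        raise InputError("series timestamps must be nondecreasing")
    if category in ("vitals", "labs"):
        return _numeric_features(t, v, prediction_time_h, NUMERIC_FEATURES)
    if category == "ventilator":
        return _numeric_features(t, v, prediction_time_h, VENTILATOR_FEATURES)
    if category == "medications":
        return _medication_features(t, v, prediction_time_h, admission_time_h)
    if category in ("procedures", "cultures"):
        return _event_features(t, prediction_time_h)
    return _io_features(t, v, prediction_time_h)


@dataclass
class FeatureMatrix:
    """Fixed-width case-by-feature table with explicit missingness (NaN)."""

    values: pd.DataFrame  # index: case_id; columns: schema order
    schema: FeatureSchema

    def __post_init__(self) -> None:
        expected = [c for c in self.schema.columns if c in self.values.columns]
        if list(self.values.columns) != expected:
            raise SchemaError("matrix columns are not in canonical schema order")

    @property
    def case_ids(self) -> list[str]:
        return list(self.values.index)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.values.copy(), self.schema)


def assemble_matrix(cohort: Sequence[PatientCase], schema: FeatureSchema) -> FeatureMatrix:
    """Featurize a cohort into one fixed-width matrix.

    Variables absent in a case fill their whole group with NaN; atemporal
    variables are copied through as single integer-coded features.
    """
    sch_vars = {v for v, _ in schema.variables}
    rows = []
    for case in cohort:
        extra = case.present_items() - sch_vars
        if extra:
            raise SchemaError(
                f"case {case.case_id} has variables outside the schema: {sorted(extra)}"
            )
        row: dict[str, float] = {}
        for var, cat in schema.variables:
            if cat in ATEMPORAL_CATEGORIES:
                if cat == "diagnosis":
                    row[f"{var}::value"] = 1.0 if case.diagnosis == "AKF" else 0.0
                else:
                    row[f"{var}::value"] = float(case.demographics.get(var, np.nan))
                continue
            if var not in case.series:
                for col in schema.group_columns(var):
                    row[col] = np.nan
                continue
            feats = build_feature_group(
                case.series[var], cat, case.prediction_time_h, case.admission_time_h
            )
            for feat, val in feats.items():
                row[f"{var}::{feat}"] = val
        rows.append(row)
    df = pd.DataFrame(rows, index=[c.case_id for c in cohort], columns=schema.columns, dtype=float)
    return FeatureMatrix(values=df, schema=schema)


def _column_key(col: pd.Series) -> bytes:
    arr = col.to_numpy(dtype=float, copy=True)
    arr[np.isnan(arr)] = 1.2345678e308  # sentinel so NaN == NaN for dedup
    return np.ascontiguousarray(arr).tobytes()


def remove_constant_features(matrix: FeatureMatrix) -> tuple[FeatureMatrix, list[str]]:
    """Drop columns with at most one distinct observed value (all-NaN included)."""
    df = matrix.values
    nunique = df.nunique(dropna=True)
    removed = [c for c in df.columns if nunique[c] <= 1]
    out = FeatureMatrix(df.drop(columns=removed), matrix.schema)
    if removed:
        logger.info("removed %d constant features", len(removed))
    return out, removed


def deduplicate_features(matrix: FeatureMatrix) -> tuple[FeatureMatrix, list[list[str]]]:
    """Keep one representative per class of columns identical on every case.

    NaNs compare equal. The canonically-first column of each class (schema
    order) is retained; the returned log lists every class with >1 member.
    """
    df = matrix.values
    classes: dict[bytes, list[str]] = {}
    for col in df.columns:
        classes.setdefault(_column_key(df[col]), []).append(col)
    keep = [members[0] for members in classes.values()]
    keep_set = set(keep)
    kept_in_order = [c for c in df.columns if c in keep_set]
    dup_classes = [m for m in classes.values() if len(m) > 1]
    if dup_classes:
        logger.info("merged %d duplicate feature classes", len(dup_classes))
    return FeatureMatrix(df[kept_in_order], matrix.schema), dup_classes


def _mode_smallest(col: pd.Series) -> float:
    counts = col.dropna().value_counts()
    if counts.empty:
        return 0.0
    top = counts[counts == counts.max()]
    return float(min(top.index))


def impute_median_mode(matrix: FeatureMatrix) -> FeatureMatrix:
    """Fill missing numerics with the column median, nominals with the mode.

    Mode ties break to the smallest value; an all-missing column falls back
    to 0 with a warning. Observed cells are untouched.
    """
    df = matrix.values.copy()
    nominal = matrix.schema.nominal_columns()
    for col in df.columns:
        if not df[col].isna().any():
            continue
        observed = df[col].dropna()
        if observed.empty:
            logger.warning("column %s is entirely missing; imputing 0", col)
            fill = 0.0
        elif col in nominal:
            fill = _mode_smallest(df[col])
        else:
            fill = float(observed.median())
        df[col] = df[col].fillna(fill)
    return FeatureMatrix(df, matrix.schema)


def impute_regression(matrix: FeatureMatrix) -> FeatureMatrix:
    """Model-based imputation: linear regression for continuous columns,
    logistic regression for nominal ones.

    Each incomplete column is regressed, over the cases where it is
    observed, on all other columns (median/mode pre-filled); predictions
    fill only its missing cells. Degenerate fits (constant outcome, too few
    observed rows) fall back to the median/mode fill with a log message.
    """
    base = impute_median_mode(matrix).values
    df = matrix.values.copy()
    nominal = matrix.schema.nominal_columns()
    for col in df.columns:
        miss = df[col].isna()
        if not miss.any():
            continue
        observed = ~miss
        y = df.loc[observed, col]
        X_obs = base.loc[observed, base.columns != col]
        X_mis = base.loc[miss, base.columns != col]
        if observed.sum() < 2 or y.nunique() <= 1 or X_obs.shape[1] == 0:
            logger.info("degenerate imputation fit for %s; median/mode fallback", col)
            df.loc[miss, col] = base.loc[miss, col]
            continue
        if col in nominal:
            model = LogisticRegression(max_iter=500)
            model.fit(X_obs.to_numpy(), y.astype(int).to_numpy())
            pred = model.predict(X_mis.to_numpy()).astype(float)
        else:
            model = LinearRegression()
            model.fit(X_obs.to_numpy(), y.to_numpy())
            pred = model.predict(X_mis.to_numpy())
        df.loc[miss, col] = pred
    return FeatureMatrix(df, matrix.schema)
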