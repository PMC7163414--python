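"""Synthetic ICU cohorts, latent relevance ground truth, and review sessions.

The generator emulates the study conditions end to end with known ground
truth: patient cases with nine variable categories as time-stamped series up
to a prediction time; a latent logistic relevance model linking three named
case summaries (item measured in the last 24 h, latest value abnormal,
admission diagnosis) to the probability a physician seeks each data item;
and review sessions consisting of a ~60 Hz gaze stream over a scrolling
element layout plus checkbox selections.

Gaze is synthesized as fixation bouts: for each present item the intended
dwell is drawn from a lognormal whose log-mean depends on the item's latent
relevance draw (1200 ms for relevant vs 60 ms for irrelevant items by
default, well on either side of the 250 ms labeling threshold), emitted as
consecutive samples inside the item's rectangle, separated by brief
transition samples attributed to no element. Scrolling is simulated as
discrete layout snapshots every 2 s shifting all rectangles vertically, so
dwell accumulation must look up the layout at each sample's timestamp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from gazerel.config import (
    ATEMPORAL_CATEGORIES,
    SimConfig,
    TIME_SERIES_CATEGORIES,
)
from gazerel.errors import SchemaError, SimulationInfeasibleError
from gazerel.gaze import Element, GazeStream, LayoutSnapshot, LayoutStream

ABSENT = "absent"

#: case window: admission at t=0 h, prediction time 48 h later
ADMISSION_H = 0.0
PREDICTION_H = 48.0
RECENT_WINDOW_H = 24.0

#: every simulated numeric series shares this reference range; the latest
#: value is "abnormal" when outside it
NORMAL_RANGE = (90.0, 110.0)

#: default latent logistic coefficients; chosen so that the generative Bayes
#: AUROC of the latent model is ~0.85 under the simulated covariate
#: frequencies P(recent)=0.5, P(abnormal)=0.3, P(AKF)=0.5
DEFAULT_INTERCEPT = -2.4
DEFAULT_COEF_RECENT = 2.4
DEFAULT_COEF_ABNORMAL = 2.8
DEFAULT_COEF_DIAGNOSIS = 1.5  # sign alternates across items

COVARIATE_NAMES = ("recent_measurement", "abnormal_latest", "diagnosis_akf")

#: screen geometry (pixels): four scrollable panels of stacked elements
N_COLUMNS = 4
COLUMN_X0 = (40.0, 520.0, 1000.0, 1480.0)
ELEMENT_W = 400.0
ELEMENT_H = 60.0
ROW_PITCH = 70.0
TOP_Y = 80.0
SCROLL_INTERVAL_MS = 2000.0
SCROLL_STEP_PX = 40.0
OFF_ELEMENT_POINT = (1900.0, 540.0)
N_TRANSITION_SAMPLES = 3

_CATEGORY_PREFIX = {
    "vitals": "vit",
    "ventilator": "vent",
    "labs": "lab",
    "medications": "med",
    "procedures": "proc",
    "cultures": "cult",
    "intake_output": "io",
}

#: typical number of measurements per 48 h window, by category
_CATEGORY_POINTS = {
    "vitals": 24,
    "ventilator": 12,
    "labs": 8,
    "medications": 6,
    "procedures": 2,
    "cultures": 2,
    "intake_output": 12,
}

DEMOGRAPHIC_VARIABLES = ("age", "sex", "height", "weight", "race", "admission_unit")
DIAGNOSIS_VARIABLE = "diagnosis"


def variable_ids(variable_counts: Mapping[str, int]) -> dict[str, list[str]]:
    """Canonical variable inventory per category, e.g. labs -> lab_00..lab_19."""
    inv: dict[str, list[str]] = {}
    for cat in TIME_SERIES_CATEGORIES:
        n = variable_counts.get(cat, 0)
        prefix = _CATEGORY_PREFIX[cat]
        inv[cat] = [f"{prefix}_{i:02d}" for i in range(n)]
    inv["demographics"] = list(DEMOGRAPHIC_VARIABLES[: variable_counts.get("demographics", 0)])
    inv["diagnosis"] = [DIAGNOSIS_VARIABLE] if variable_counts.get("diagnosis", 0) else []
    return inv


@dataclass
class PatientCase:
    """One synthetic ICU patient up to a prediction time.

    ``series`` maps a variable id to its (timestamp_h, value) pairs; a
    variable with no data in this case simply has no entry.
    """

    case_id: str
    diagnosis: str  # "AKF" or "ARF"
    demographics: dict[str, float]
    series: dict[str, list[tuple[float, float]]]
    admission_time_h: float = ADMISSION_H
    prediction_time_h: float = PREDICTION_H

    def __post_init__(self) -> None:
        if self.diagnosis not in ("AKF", "ARF"):
            raise SchemaError(f"diagnosis must be AKF or ARF, got {self.diagnosis!r}")
        for var, pts in self.series.items():
            if not pts:
                raise SchemaError(f"variable {var} has an empty series; omit it instead")
            ts = [t for t, _ in pts]
            if any(b < a for a, b in zip(ts, ts[1:])):
                raise SchemaError(f"series {var} timestamps not nondecreasing")
            if ts[0] < self.admission_time_h or ts[-1] > self.prediction_time_h:
                raise SchemaError(
                    f"series {var} timestamps outside [admission, prediction]"
                )

    def present_items(self) -> set[str]:
        return set(self.series)


@dataclass
class RelevanceModel:
    """Latent ground-truth relevance: per-item logistic over named summaries.

    Covariates, in order: recent_measurement (last timestamp within 24 h of
    the prediction time), abnormal_latest (latest value outside the
    reference range), diagnosis_akf.
    """

    intercepts: dict[str, float]
    coefficients: dict[str, tuple[float, float, float]]
    normal_range: tuple[float, float] = NORMAL_RANGE

    def items(self) -> list[str]:
        return sorted(self.intercepts)


def covariates(case: PatientCase, item_id: str, model: RelevanceModel) -> tuple[float, float, float]:
    """The three named case summaries the latent model scores an item on."""
    pts = case.series[item_id]
    t_last, v_last = pts[-1]
    recent = 1.0 if t_last >= case.prediction_time_h - RECENT_WINDOW_H else 0.0
    lo, hi = model.normal_range
    abnormal = 1.0 if not (lo <= v_last <= hi) else 0.0
    diag = 1.0 if case.diagnosis == "AKF" else 0.0
    return (recent, abnormal, diag)


def _logistic(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def true_relevance(case: PatientCase, model: RelevanceModel) -> dict[str, float | str]:
    """Latent relevance probability per item; absent marker for missing data."""
    unknown = case.present_items() - set(model.intercepts)
    if unknown:
        raise SchemaError(f"case contains items unknown to the model: {sorted(unknown)}")
    out: dict[str, float | str] = {}
    for item in model.items():
        if item not in case.series:
            out[item] = ABSENT
            continue
        x = covariates(case, item, model)
        b = model.coefficients[item]
        z = model.intercepts[item] + sum(bi * xi for bi, xi in zip(b, x))
        out[item] = _logistic(z)
    return out


def _simulate_series(
    rng: np.random.Generator, category: str, admission_h: float, prediction_h: float
) -> list[tuple[float, float]]:
    """One variable's time series with controlled covariate frequencies."""
    n = max(1, rng.poisson(_CATEGORY_POINTS[category]))
    recent = rng.random() < 0.5
    abnormal = rng.random() < 0.3
    span = prediction_h - admission_h
    if recent:
        t_last = prediction_h - rng.uniform(0.0, RECENT_WINDOW_H)
    else:
        t_last = admission_h + rng.uniform(0.0, span - RECENT_WINDOW_H)
    earlier = np.sort(rng.uniform(admission_h, t_last, size=n - 1))
    times = np.append(earlier, t_last)
    lo, hi = NORMAL_RANGE
    values = rng.uniform(lo, hi, size=n)
    if abnormal:
        width = hi - lo
        if rng.random() < 0.5:
            values[-1] = hi + rng.uniform(0.5 * width, 2.0 * width)
        else:
            values[-1] = lo - rng.uniform(0.5 * width, 2.0 * width)
    return [(float(t), float(v)) for t, v in zip(times, values)]


def generate_cohort(config: SimConfig) -> tuple[list[PatientCase], RelevanceModel]:
    """Generate a synthetic cohort plus its latent relevance ground truth.

    Deterministic: the same config (including seed) yields an identical
    cohort. Diagnoses are balanced up to rounding; each time-series variable
    is present in a case with probability ``1 - missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    inv = variable_ids(config.variable_counts)
    ts_items = [v for cat in TIME_SERIES_CATEGORIES for v in inv[cat]]

    intercepts: dict[str, float] = {}
    coefs: dict[str, tuple[float, float, float]] = {}
    for i, item in enumerate(ts_items):
        intercepts[item] = DEFAULT_INTERCEPT + float(rng.normal(0.0, 0.2))
        sign = 1.0 if i % 2 == 0 else -1.0
        coefs[item] = (DEFAULT_COEF_RECENT, DEFAULT_COEF_ABNORMAL, sign * DEFAULT_COEF_DIAGNOSIS)
    model = RelevanceModel(intercepts=intercepts, coefficients=coefs)

    n = config.n_cases
    diagnoses = np.array(["AKF"] * ((n + 1) // 2) + ["ARF"] * (n // 2))
    diagnoses = diagnoses[rng.permutation(n)] if n else diagnoses

    cases: list[PatientCase] = []
    for i in range(n):
        demo = {
            "age": float(rng.integers(25, 91)),
            "sex": float(rng.integers(0, 2)),
            "height": float(np.round(rng.normal(170.0, 10.0), 1)),
            "weight": float(np.round(rng.normal(80.0, 15.0), 1)),
            "race": float(rng.integers(0, 5)),
            "admission_unit": float(rng.integers(0, 3)),
        }
        demo = {k: demo[k] for k in inv["demographics"]}
        series: dict[str, list[tuple[float, float]]] = {}
        for cat in TIME_SERIES_CATEGORIES:
            for var in inv[cat]:
                if rng.random() < config.missing_rate:
                    continue
                series[var] = _simulate_series(rng, cat, ADMISSION_H, PREDICTION_H)
        cases.append(
            PatientCase(
                case_id=f"case_{i:04d}",
                diagnosis=str(diagnoses[i]),
                demographics=demo,
                series=series,
            )
        )
    return cases, model


@dataclass
class SessionSim:
    """One simulated review session with its ground truth retained.

    ``manual_selections`` is ``None`` when the selection task was skipped
    (no record exists), distinct from an empty selection set.
    """

    case_id: str
    gaze_stream: GazeStream
    layout_stream: LayoutStream
    manual_selections: set[str] | None
    qc_flags: set[str] = field(default_factory=set)
    # ground truth (never visible to the labeling pipeline)
    intended_dwell_ms: dict[str, float] = field(default_factory=dict)
    relevant_draw: dict[str, bool] = field(default_factory=dict)


def _element_rect(item_idx: int, snapshot_idx: int) -> tuple[float, float, float, float]:
    col = item_idx % N_COLUMNS
    row = item_idx // N_COLUMNS
    x0 = COLUMN_X0[col]
    y0 = TOP_Y + ROW_PITCH * row - SCROLL_STEP_PX * snapshot_idx
    return (x0, y0, x0 + ELEMENT_W, y0 + ELEMENT_H)


def _build_layout(items: list[str], duration_ms: float) -> LayoutStream:
    n_snaps = max(1, int(math.ceil(duration_ms / SCROLL_INTERVAL_MS)))
    snaps = []
    for k in range(n_snaps):
        elements = [
            Element(item, *_element_rect(i, k)) for i, item in enumerate(items)
        ]
        snaps.append(LayoutSnapshot(timestamp_ms=k * SCROLL_INTERVAL_MS, elements=elements))
    return LayoutStream(snapshots=snaps)


def simulate_session(
    case: PatientCase,
    relevance: Mapping[str, float | str],
    config: SimConfig,
    seed: int,
) -> SessionSim:
    """Synthesize one review session for a case from its latent relevance.

    For each present item a relevance draw ~ Bernoulli(p_item) chooses the
    lognormal dwell mode; the emitted fixation bouts reproduce each intended
    dwell to within one sample period when re-processed by the dwell
    pipeline. Manual selections equal the relevance draws with independent
    flips at ``manual_flip_noise``.
    """
    rng = np.random.default_rng(seed)
    items = sorted(case.present_items())
    period = config.sample_period_ms
    duration_ms = config.session_duration_s * 1000.0

    draws: dict[str, bool] = {}
    dwell: dict[str, float] = {}
    for item in items:
        p = relevance[item]
        if p == ABSENT or not isinstance(p, float):
            raise SchemaError(f"no relevance probability for present item {item}")
        rel = bool(rng.random() < p)
        mu = config.mu_rel_ms if rel else config.mu_irr_ms
        draws[item] = rel
        dwell[item] = float(rng.lognormal(math.log(mu), config.sigma_log))

    order = [items[i] for i in rng.permutation(len(items))]
    n_samples = {it: max(1, int(round(dwell[it] / period))) for it in items}
    total = sum(n_samples.values()) + N_TRANSITION_SAMPLES * len(items)
    if total * period > duration_ms or sum(dwell.values()) > duration_ms:
        raise SimulationInfeasibleError(
            f"intended dwells need {total * period:.0f} ms but the session is "
            f"{duration_ms:.0f} ms; increase session_duration_s"
        )

    layout = _build_layout(items, duration_ms)
    times, xs, ys = [], [], []
    t = 0.0
    for item in order:
        idx = items.index(item)
        for _ in range(n_samples[item]):
            k = min(int(t // SCROLL_INTERVAL_MS), len(layout) - 1)
            x0, y0, x1, y1 = _element_rect(idx, k)
            times.append(t)
            xs.append((x0 + x1) / 2.0)
            ys.append((y0 + y1) / 2.0)
            t += period
        for _ in range(N_TRANSITION_SAMPLES):
            times.append(t)
            xs.append(OFF_ELEMENT_POINT[0])
            ys.append(OFF_ELEMENT_POINT[1])
            t += period

    valid = np.ones(len(times), dtype=bool)
    qc_flags: set[str] = set()
    if rng.random() < config.p_gaze_incomplete:
        qc_flags.add("gaze_incomplete")
        # head left the tracking box: most samples lose validity
        invalid = rng.random(len(times)) < 0.7
        valid &= ~invalid
        if valid.mean() >= 0.5:  # force the degradation to be detectable
            valid[: int(0.6 * len(valid))] = False

    flips = rng.random(len(items)) < config.manual_flip_noise
    selections: set[str] | None = {
        it for it, flip in zip(items, flips) if draws[it] != flip
    }
    if rng.random() < config.p_selection_skipped:
        qc_flags.add("selection_skipped")
        selections = None

    gaze = GazeStream(
        np.asarray(times), np.asarray(xs), np.asarray(ys), valid
    )
    return SessionSim(
        case_id=case.case_id,
        gaze_stream=gaze,
        layout_stream=layout,
        manual_selections=selections,
        qc_flags=qc_flags,
        intended_dwell_ms=dwell,
        relevant_draw=draws,
    )
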