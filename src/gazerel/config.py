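"""Study configuration objects.

``SimConfig`` holds everything the synthetic cohort/session generator needs;
``RunConfig`` adds the numeric constants of the study (dwell threshold,
screening cutoff, minimum positive count, CV and bootstrap settings) plus
paths, so that a whole run is reproducible from one serializable object.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

#: Scaled-down variable inventory. Category names are fixed; counts default to
#: a desk-scale version of an ICU record (the real inventory has hundreds of
#: lab and medication variables).
DEFAULT_VARIABLE_COUNTS: dict[str, int] = {
    "vitals": 14,
    "ventilator": 9,
    "labs": 20,
    "medications": 30,
    "procedures": 10,
    "cultures": 5,
    "intake_output": 7,
    "demographics": 6,
    "diagnosis": 1,
}

TIME_SERIES_CATEGORIES = (
    "vitals",
    "ventilator",
    "labs",
    "medications",
    "procedures",
    "cultures",
    "intake_output",
)
ATEMPORAL_CATEGORIES = ("demographics", "diagnosis")


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid config field '{field_name}': {msg}")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort and review-session generator.

    Dwell-time parameters are the log-scale means/SD of lognormal intended
    dwells, in milliseconds: relevant items draw around ``mu_rel_ms`` (default
    1200 ms) and irrelevant items around ``mu_irr_ms`` (default 60 ms), so the
    two modes sit clearly on either side of the 250 ms labeling threshold.
    """

    n_cases: int = 134
    seed: int = 0
    variable_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_VARIABLE_COUNTS)
    )
    session_duration_s: float = 120.0
    sample_rate_hz: float = 60.0
    mu_rel_ms: float = 1200.0
    mu_irr_ms: float = 60.0
    sigma_log: float = 0.5
    manual_flip_noise: float = 0.05
    missing_rate: float = 0.15
    #: probability a session is emitted with degraded (mostly invalid) gaze
    p_gaze_incomplete: float = 0.0
    #: probability the selection record of a session is missing
    p_selection_skipped: float = 0.0

    def __post_init__(self) -> None:
        _require(self.n_cases >= 0, "n_cases", "must be >= 0")
        _require(self.sample_rate_hz > 0, "sample_rate_hz", "must be > 0")
        _require(self.session_duration_s > 0, "session_duration_s", "must be > 0")
        _require(self.mu_rel_ms > self.mu_irr_ms, "mu_rel_ms", "must exceed mu_irr_ms")
        _require(self.sigma_log > 0, "sigma_log", "must be > 0")
        for name in ("manual_flip_noise", "missing_rate", "p_gaze_incomplete", "p_selection_skipped"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, name, "must be a probability in [0, 1]")
        unknown = set(self.variable_counts) - set(DEFAULT_VARIABLE_COUNTS)
        _require(not unknown, "variable_counts", f"unknown categories {sorted(unknown)}")
        for cat, cnt in self.variable_counts.items():
            _require(cnt >= 0, "variable_counts", f"negative count for {cat}")

    @property
    def sample_period_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        return cls(**d)


@dataclass
class RunConfig:
    """Full study configuration: simulation + every numeric study constant."""

    sim: SimConfig = field(default_factory=SimConfig)
    #: evaluation cohort: distinct patient cases and reviewers per case; the
    #: evaluation unit is one (case x reviewer) session
    n_eval_cases: int = 18
    reviewers_per_case: int = 4
    dwell_threshold_ms: float = 250.0
    max_gap_ms: float = 100.0
    min_valid_fraction: float = 0.5
    screen_auroc_threshold: float = 0.55
    min_positives: int = 3
    cv_folds: int = 5
    bootstrap_b: int = 2000
    alpha: float = 0.05
    seed: int = 0
    #: classifier sizes (documented package defaults, desk-scale)
    rf_n_estimators: int = 50
    screen_rf_n_estimators: int = 25

    def __post_init__(self) -> None:
        _require(self.dwell_threshold_ms > 0, "dwell_threshold_ms", "must be > 0")
        _require(self.cv_folds >= 2, "cv_folds", "must be >= 2")
        _require(0 < self.alpha < 1, "alpha", "must be in (0, 1)")
        _require(self.n_eval_cases >= 0, "n_eval_cases", "must be >= 0")
        _require(self.reviewers_per_case >= 1, "reviewers_per_case", "must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("sim"), dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
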