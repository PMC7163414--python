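"""Per-data-item relevance models: screening, candidate selection, training.

For every eligible target (a data item with more than ``min_positives``
positive training labels, counting only cases where the item is present),
training proceeds in two steps:

1. Feature-group screening, per imputation variant: each predictor
   variable's feature group is evaluated on its own by pooled k-fold CV
   AUROC; groups are kept only if that AUROC strictly exceeds 0.55.
2. Candidate selection: six candidates — {median, regression} imputation
   crossed with {L2-penalized logistic regression, RBF support vector
   classifier, random forest} — are compared by mean k-fold CV AUROC on the
   screened features, with one shared fold assignment; the winner is refit
   on the full training set. Ties break by a fixed preference order
   (median before regression; logistic, SVC, random forest).

Scores are oriented so that higher means more likely relevant. The SVC
scores through its decision function mapped to [0, 1] by fractional rank
among the training decision values (AUROC is rank-based, so calibration is
irrelevant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from gazerel.errors import SchemaError
from gazerel.evaluation import auroc
from gazerel.features import FeatureMatrix
from gazerel.gaze import ABSENT, POSITIVE, LabelSet

logger = logging.getLogger(__name__)

IMPUTATIONS = ("median", "regression")
CLASSIFIERS = ("logistic", "svc", "rf")

DEFAULT_MIN_POSITIVES = 3
DEFAULT_SCREEN_THRESHOLD = 0.55
DEFAULT_CV_FOLDS = 5


@dataclass(frozen=True)
class TargetSpec:
    """One modellable target: a data item under one label source."""

    item_id: str
    source: str
    n_positive: int
    n_negative: int
    n_absent: int

    @property
    def n_labeled(self) -> int:
        return self.n_positive + self.n_negative


@dataclass(frozen=True)
class CandidateConfig:
    imputation: str
    classifier: str

    def __post_init__(self) -> None:
        if self.imputation not in IMPUTATIONS or self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown candidate {self.imputation}/{self.classifier}")


#: fixed preference order used to break CV-score ties
CANDIDATE_ORDER = tuple(
    CandidateConfig(imp, clf) for imp in IMPUTATIONS for clf in CLASSIFIERS
)


def eligible_targets(
    labels: Mapping[str, LabelSet],
    item_universe: Sequence[str],
    min_positives: int = DEFAULT_MIN_POSITIVES,
) -> list[TargetSpec]:
    """Targets with strictly more than ``min_positives`` positive cases.

    ``labels`` maps case_id to that case's LabelSet (one source); cases where
    an item is absent count toward ``n_absent`` and never toward the
    positive/negative totals.
    """
    sources = {ls.source for ls in labels.values()}
    if len(sources) > 1:
        raise SchemaError(f"labels mix sources {sorted(sources)}")
    source = sources.pop() if sources else "manual"
    specs = []
    for item in sorted(item_universe):
        n_pos = n_neg = n_abs = 0
        for ls in labels.values():
            lab = ls.get(item)
            if lab == ABSENT:
                n_abs += 1
            elif lab == POSITIVE:
                n_pos += 1
            else:
                n_neg += 1
        if n_pos > min_positives:
            specs.append(TargetSpec(item, source, n_pos, n_neg, n_abs))
    return specs


def _effective_folds(y: np.ndarray, requested: int) -> int:
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    k = min(requested, n_pos, n_neg)
    if k < requested:
        logger.info("fold count reduced from %d to %d (class sizes %d/%d)",
                    requested, k, n_pos, n_neg)
    return max(k, 2)


def default_screening_learner(seed: int, n_estimators: int = 25):
    """Screening learner: a small random forest (handles mixed features
    without scaling)."""
    return RandomForestClassifier(n_estimators=n_estimators, random_state=seed)


def screen_feature_groups(
    matrix: FeatureMatrix,
    y: pd.Series,
    auroc_threshold: float = DEFAULT_SCREEN_THRESHOLD,
    cv: int = DEFAULT_CV_FOLDS,
    learner=None,
    seed: int = 0,
) -> tuple[list[str], dict[str, float]]:
    """Keep predictor variables whose own feature group predicts the target.

    Each variable's group is fit alone under stratified k-fold CV; the
    pooled out-of-fold scores give one AUROC per group, kept iff strictly
    greater than ``auroc_threshold``. The matrix must be complete
    (post-imputation).
    """
    if matrix.values.isna().any().any():
        raise SchemaError("screening requires a complete (imputed) matrix")
    y_arr = y.loc[matrix.values.index].to_numpy(dtype=int)
    if learner is None:
        learner = default_screening_learner(seed)
    k = _effective_folds(y_arr, cv)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y_arr)), y_arr))

    col_to_var = matrix.schema.column_to_variable()
    groups: dict[str, list[str]] = {}
    for col in matrix.values.columns:
        groups.setdefault(col_to_var[col], []).append(col)

    kept: list[str] = []
    scores: dict[str, float] = {}
    for var, cols in groups.items():
        X = matrix.values[cols].to_numpy()
        pooled = np.empty(len(y_arr))
        for train_idx, test_idx in splits:
            est = clone(learner)
            est.fit(X[train_idx], y_arr[train_idx])
            pooled[test_idx] = est.predict_proba(X[test_idx])[:, 1]
        a = auroc(pooled, y_arr)
        scores[var] = a
        if a > auroc_threshold:
            kept.append(var)
    return kept, scores


class _RankedSVC:
    """SVC whose scores are fractional ranks of the decision function among
    the training decision values (monotone map to [0, 1])."""

    def __init__(self, seed: int):
        self.pipeline = Pipeline(
            [("scale", StandardScaler()), ("svc", SVC(kernel="rbf", C=1.0, random_state=seed))]
        )
        self.train_decisions_: np.ndarray | None = None

    def fit(self, X, y):
        self.pipeline.fit(X, y)
        self.train_decisions_ = np.sort(self.pipeline.decision_function(X))
        return self

    def score_samples(self, X) -> np.ndarray:
        d = self.pipeline.decision_function(X)
        left = np.searchsorted(self.train_decisions_, d, side="left")
        right = np.searchsorted(self.train_decisions_, d, side="right")
        return (left + right) / (2.0 * len(self.train_decisions_))

    def get_params(self, deep=False):  # clone support
        return {"seed": self.pipeline.named_steps["svc"].random_state}


def _make_estimator(classifier: str, seed: int, rf_n_estimators: int):
    if classifier == "logistic":
        return Pipeline(
            [("scale", StandardScaler()),
             ("lr", LogisticRegression(C=1.0, max_iter=2000))]  # L2 penalty (default)
        )
    if classifier == "svc":
        return _RankedSVC(seed)
    return RandomForestClassifier(n_estimators=rf_n_estimators, random_state=seed)


def _fit_and_score(est, X_train, y_train, X_test) -> np.ndarray:
    est.fit(X_train, y_train)
    if isinstance(est, _RankedSVC):
        return est.score_samples(X_test)
    return est.predict_proba(X_test)[:, 1]


@dataclass
class TrainedModel:
    """A fitted per-target relevance scorer (higher = more likely relevant)."""

    item_id: str
    source: str
    config: CandidateConfig | None
    feature_columns: list[str]
    estimator: object | None
    cv_scores: dict[str, float]
    kept_groups: dict[str, list[str]]
    prevalence: float
    seed: int

    @property
    def is_fallback(self) -> bool:
        return self.estimator is None

    def sidecar(self) -> dict:
        return {
            "item_id": self.item_id,
            "source": self.source,
            "imputation": self.config.imputation if self.config else None,
            "classifier": self.config.classifier if self.config else None,
            "cv_scores": self.cv_scores,
            "kept_groups": self.kept_groups,
            "n_features": len(self.feature_columns),
            "fallback": self.is_fallback,
            "prevalence": self.prevalence,
            "seed": self.seed,
        }


def select_and_train(
    median_matrix: FeatureMatrix,
    regression_matrix: FeatureMatrix,
    y: pd.Series,
    kept_groups: Mapping[str, Sequence[str]],
    item_id: str,
    source: str,
    cv: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
    rf_n_estimators: int = 50,
) -> TrainedModel:
    """Select the best (imputation, classifier) pair by CV and refit it.

    ``kept_groups`` maps each imputation variant to the predictor variables
    that survived screening on that variant. All six candidates share one
    stratified fold assignment. If no group survived screening on either
    variant, an intercept-only fallback scoring the training prevalence is
    returned (logged), so that every target still has a model for the
    paired evaluation.
    """
    if list(median_matrix.values.index) != list(regression_matrix.values.index):
        raise SchemaError("imputation variants are not aligned on cases")
    y_arr = y.loc[median_matrix.values.index].to_numpy(dtype=int)
    prevalence = float(y_arr.mean())

    variants = {"median": median_matrix, "regression": regression_matrix}
    cols_by_variant: dict[str, list[str]] = {}
    for imp, fm in variants.items():
        cols: list[str] = []
        col_to_var = fm.schema.column_to_variable()
        keep = set(kept_groups.get(imp, []))
        for col in fm.values.columns:
            if col_to_var[col] in keep:
                cols.append(col)
        cols_by_variant[imp] = cols

    if not any(cols_by_variant.values()):
        logger.info("no feature group survived screening for %s/%s; prevalence fallback",
                    item_id, source)
        return TrainedModel(item_id, source, None, [], None, {},
                            {k: list(v) for k, v in kept_groups.items()}, prevalence, seed)

    k = _effective_folds(y_arr, cv)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y_arr)), y_arr))

    cv_scores: dict[str, float] = {}
    best: tuple[float, CandidateConfig] | None = None
    for cand in CANDIDATE_ORDER:
        cols = cols_by_variant[cand.imputation]
        key = f"{cand.imputation}/{cand.classifier}"
        if not cols:
            cv_scores[key] = float("nan")
            continue
        X = variants[cand.imputation].values[cols].to_numpy()
        fold_aucs = []
        for train_idx, test_idx in splits:
            est = _make_estimator(cand.classifier, seed, rf_n_estimators)
            scores = _fit_and_score(est, X[train_idx], y_arr[train_idx], X[test_idx])
            fold_aucs.append(auroc(scores, y_arr[test_idx]))
        mean_auc = float(np.mean(fold_aucs))
        cv_scores[key] = mean_auc
        if best is None or mean_auc > best[0]:  # strict: earlier candidate wins ties
            best = (mean_auc, cand)

    assert best is not None
    _, winner = best
    cols = cols_by_variant[winner.imputation]
    X = variants[winner.imputation].values[cols].to_numpy()
    est = _make_estimator(winner.classifier, seed, rf_n_estimators)
    est.fit(X, y_arr)
    return TrainedModel(
        item_id=item_id,
        source=source,
        config=winner,
        feature_columns=cols,
        estimator=est,
        cv_scores=cv_scores,
        kept_groups={k: list(v) for k, v in kept_groups.items()},
        prevalence=prevalence,
        seed=seed,
    )


def predict_relevance(model: TrainedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Score cases with a trained model; higher means more likely relevant."""
    if model.is_fallback:
        return np.full(len(matrix.values), model.prevalence)
    missing = [c for c in model.feature_columns if c not in matrix.values.columns]
    if missing:
        raise SchemaError(f"matrix lacks model features: {missing[:5]}"
                          f"{'...' if len(missing) > 5 else ''}")
    X = matrix.values[model.feature_columns].to_numpy()
    est = model.estimator
    if isinstance(est, _RankedSVC):
        return est.score_samples(X)
    return est.predict_proba(X)[:, 1]
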