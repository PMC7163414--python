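"""Paired evaluation of manual-selection vs gaze-derived relevance models.

Per target: AUROC of each model on the evaluation cases (manual selection
is always the evaluation gold standard), percentile bootstrap 95% CIs for
each AUROC and for their paired difference (the same case resample scores
both models), and a per-pair significance flag (difference CI excludes 0,
uncorrected). Across targets: a paired Wilcoxon signed-rank test on the
AUROC pairs.

AUROC is computed as the rank statistic: the probability that a random
positive case scores above a random negative one, ties counted half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, norm

from gazerel.errors import InputError, UndefinedAUROCError

logger = logging.getLogger(__name__)

DEFAULT_B = 2000
DEFAULT_ALPHA = 0.05
#: below this pair count the Wilcoxon null is enumerated exactly
EXACT_WILCOXON_N = 12


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the fraction of (positive, negative) case pairs where the
    positive scores higher, counting ties as half. Raises if only one class
    is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise InputError("scores and labels have different lengths")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUROCError(
            f"AUROC undefined with {n_pos} positives and {n_neg} negatives"
        )
    ranks = rankdata(s)
    pos_rank_sum = float(ranks[y == 1].sum())
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


@dataclass
class PairedBootstrap:
    auroc_manual: float
    auroc_gaze: float
    ci_manual: tuple[float, float]
    ci_gaze: tuple[float, float]
    ci_diff: tuple[float, float]
    n_redraws: int = 0

    @property
    def significant(self) -> bool:
        lo, hi = self.ci_diff
        return not (lo <= 0.0 <= hi)


def bootstrap_paired_ci(
    scores_manual: Sequence[float],
    scores_gaze: Sequence[float],
    labels: Sequence[int],
    b: int = DEFAULT_B,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> PairedBootstrap:
    """Percentile bootstrap CIs for two AUROCs and their paired difference.

    The resampling unit is the evaluation case, and the same resample
    scores both models (the difference distribution is paired). Resamples
    collapsing to a single class are redrawn and counted.
    """
    if b < 100:
        raise InputError("bootstrap with B < 100 gives unstable intervals; refused")
    sm = np.asarray(scores_manual, dtype=float)
    sg = np.asarray(scores_gaze, dtype=float)
    y = np.asarray(labels)
    a_m = auroc(sm, y)
    a_g = auroc(sg, y)
    rng = np.random.default_rng(seed)
    n = len(y)
    boot_m = np.empty(b)
    boot_g = np.empty(b)
    redraws = 0
    for i in range(b):
        while True:
            idx = rng.integers(0, n, size=n)
            yi = y[idx]
            if yi.min() != yi.max():
                break
            redraws += 1
        boot_m[i] = auroc(sm[idx], yi)
        boot_g[i] = auroc(sg[idx], yi)
    if redraws:
        logger.info("redrew %d single-class bootstrap resamples", redraws)
    lo, hi = 100 * alpha / 2.0, 100 * (1 - alpha / 2.0)
    diff = boot_m - boot_g
    return PairedBootstrap(
        auroc_manual=a_m,
        auroc_gaze=a_g,
        ci_manual=tuple(np.percentile(boot_m, [lo, hi])),
        ci_gaze=tuple(np.percentile(boot_g, [lo, hi])),
        ci_diff=tuple(np.percentile(diff, [lo, hi])),
        n_redraws=redraws,
    )


@dataclass
class WilcoxonResult:
    statistic: float  # W+ = rank sum of positive differences
    p_value: float
    n_used: int       # pairs after dropping zero differences
    exact: bool
    degenerate: bool = False
    underpowered: bool = False


def wilcoxon_signed_rank(pairs: Sequence[tuple[float, float]]) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; tied absolute differences receive
    mid-ranks. The null distribution is enumerated exactly over all sign
    assignments for up to 12 nonzero pairs (enumeration is exact even with
    ties), and approximated by a tie-corrected normal with continuity
    correction beyond that. All-zero differences give the degenerate result
    p = 1.
    """
    if len(pairs) < 1:
        raise InputError("wilcoxon requires at least one pair")
    d = np.array([a - b for a, b in pairs], dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, exact=True, degenerate=True,
                              underpowered=len(pairs) < 6)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    underpowered = n < 6
    if n <= EXACT_WILCOXON_N:
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        # two-sided: double the smaller tail (capped at 1)
        p_le = np.mean(sums <= w_plus + 1e-12)
        p_ge = np.mean(sums >= w_plus - 1e-12)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(w_plus, float(p), n, exact=True, underpowered=underpowered)
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(w_plus, 1.0, n, exact=False, degenerate=True)
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return WilcoxonResult(w_plus, min(1.0, p), n, exact=False, underpowered=underpowered)


@dataclass
class PairedResult:
    """Evaluation summary for one target's pair of models."""

    item_id: str
    n_positive: int
    n_evaluated: int
    auroc_manual: float
    auroc_gaze: float
    ci_manual: tuple[float, float]
    ci_gaze: tuple[float, float]
    ci_diff: tuple[float, float]
    significant: bool
    direction: str  # "manual", "gaze", or "none"


@dataclass
class ComparisonReport:
    pairs: list[PairedResult]
    wilcoxon: WilcoxonResult
    n_significant_manual: int
    n_significant_gaze: int
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "item_id": p.item_id,
                "n_pos": p.n_positive,
                "n_eval": p.n_evaluated,
                "auroc_manual": p.auroc_manual,
                "ci_manual_lo": p.ci_manual[0],
                "ci_manual_hi": p.ci_manual[1],
                "auroc_gaze": p.auroc_gaze,
                "ci_gaze_lo": p.ci_gaze[0],
                "ci_gaze_hi": p.ci_gaze[1],
                "diff_lo": p.ci_diff[0],
                "diff_hi": p.ci_diff[1],
                "significant": p.significant,
                "direction": p.direction,
            }
            for p in self.pairs
        ]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "n_pairs": len(self.pairs),
            "wilcoxon_statistic": self.wilcoxon.statistic,
            "wilcoxon_p": self.wilcoxon.p_value,
            "wilcoxon_exact": self.wilcoxon.exact,
            "wilcoxon_underpowered": self.wilcoxon.underpowered,
            "n_significant_manual": self.n_significant_manual,
            "n_significant_gaze": self.n_significant_gaze,
            "n_not_significant": len(self.pairs)
            - self.n_significant_manual
            - self.n_significant_gaze,
            "mean_auroc_manual": float(np.mean([p.auroc_manual for p in self.pairs]))
            if self.pairs else float("nan"),
            "mean_auroc_gaze": float(np.mean([p.auroc_gaze for p in self.pairs]))
            if self.pairs else float("nan"),
            "dropped": [list(d) for d in self.dropped],
        }


def build_report(
    target_data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    b: int = DEFAULT_B,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> ComparisonReport:
    """Assemble the full paired comparison across targets.

    ``target_data`` maps item_id to (scores_manual, scores_gaze, labels)
    over that target's evaluable cases (absent cases already excluded).
    Targets whose evaluation labels are single-class are dropped with a
    logged reason. Rows are sorted by manual AUROC, descending.
    """
    rng = np.random.default_rng(seed)
    pairs: list[PairedResult] = []
    dropped: list[tuple[str, str]] = []
    for item_id in sorted(target_data):
        sm, sg, y = target_data[item_id]
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            dropped.append((item_id, "single-class evaluation labels"))
            logger.info("dropping %s from report: single-class labels", item_id)
            continue
        boot = bootstrap_paired_ci(
            sm, sg, y, b=b, alpha=alpha, seed=int(rng.integers(2**31))
        )
        if boot.significant:
            direction = "manual" if boot.auroc_manual > boot.auroc_gaze else "gaze"
        else:
            direction = "none"
        pairs.append(
            PairedResult(
                item_id=item_id,
                n_positive=int(np.sum(y == 1)),
                n_evaluated=len(y),
                auroc_manual=boot.auroc_manual,
                auroc_gaze=boot.auroc_gaze,
                ci_manual=boot.ci_manual,
                ci_gaze=boot.ci_gaze,
                ci_diff=boot.ci_diff,
                significant=boot.significant,
                direction=direction,
            )
        )
    if not pairs:
        raise InputError("no valid target pairs to report")
    pairs.sort(key=lambda p: (-p.auroc_manual, p.item_id))
    wres = wilcoxon_signed_rank([(p.auroc_manual, p.auroc_gaze) for p in pairs])
    if wres.underpowered:
        logger.warning("Wilcoxon on %d pairs is underpowered", wres.n_used)
    return ComparisonReport(
        pairs=pairs,
        wilcoxon=wres,
        n_significant_manual=sum(1 for p in pairs if p.direction == "manual"),
        n_significant_gaze=sum(1 for p in pairs if p.direction == "gaze"),
        dropped=dropped,
    )
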