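"""Diagnostic performance statistics for a non-responder classifier.

Positive class is NR (non-responder) throughout: sensitivity is the
fraction of non-responders called, specificity the fraction of responders
not called, precision the fraction of calls that are non-responders, and
the positive likelihood ratio LR+ = sensitivity / (1 - specificity) is
the factor by which a positive call raises the odds of true non-response.

Point estimates are computed in exact rational arithmetic and converted
to float only at the end.  Proportion confidence intervals are exact
binomial (Clopper-Pearson); likelihood-ratio intervals use the standard
log method; AUROC intervals for single-shot evaluations use DeLong.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from fractions import Fraction

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "PerformanceReport",
    "confusion_stats",
    "clopper_pearson_ci",
    "lr_ci",
    "auroc",
    "auroc_ci_delong",
    "auroc_pvalue",
    "roc_curve",
    "report_from_scores",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with NR as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise ValueError("all-zero confusion counts")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


def confusion_stats(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, precision and LR+ from confusion counts.

    Precision is NaN when no sample is called positive; LR+ is ``inf``
    when specificity is 1 and sensitivity positive, NaN when both classes
    of error vanish on the positive margin (tp = fp = 0).
    """
    if c.n_positive < 1 or c.n_negative < 1:
        raise ValueError("need at least one sample of each class")
    sens = Fraction(c.tp, c.n_positive)
    spec = Fraction(c.tn, c.n_negative)
    prec = Fraction(c.tp, c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    fpr = 1 - spec
    if fpr == 0:
        lr = math.inf if sens > 0 else math.nan
    else:
        lr = float(sens / fpr)
    return {
        "sensitivity": float(sens),
        "specificity": float(spec),
        "precision": float(prec) if prec is not None else math.nan,
        "likelihood_ratio": lr,
    }


def clopper_pearson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) confidence interval for k/n.

    Endpoints are Beta-distribution quantiles; the lower bound is exactly
    0 when k = 0 and the upper exactly 1 when k = n.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    alpha = 1 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def lr_ci(c: ConfusionCounts, level: float = 0.95) -> tuple[float, float] | None:
    """Log-method confidence interval for the positive likelihood ratio.

    ``exp(ln LR +/- z * sqrt(1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn)))``.
    Returns None (reported N/A) when fp = 0 (LR infinite) or tp = 0.
    """
    if c.fp == 0 or c.tp == 0:
        return None
    lr = (c.tp / c.n_positive) / (c.fp / c.n_negative)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    se = math.sqrt(1 / c.tp - 1 / c.n_positive + 1 / c.fp - 1 / c.n_negative)
    return math.exp(math.log(lr) - z * se), math.exp(math.log(lr) + z * se)


def _as_arrays(scores_nr, scores_r) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(scores_nr, dtype=float)
    b = np.asarray(scores_r, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both classes must be non-empty")
    return a, b


def auroc(scores_nr, scores_r) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Probability that a random non-responder scores above a random
    responder, ties counting one half.
    """
    a, b = _as_arrays(scores_nr, scores_r)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # mid-ranks
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2
    return float(u / (a.size * b.size))


def auroc_ci_delong(scores_nr, scores_r, level: float = 0.95) -> tuple[float, float]:
    """DeLong confidence interval for a single-shot AUROC, clipped to [0, 1]."""
    a, b = _as_arrays(scores_nr, scores_r)
    m, n = a.size, b.size
    # placement values: V10[i] = P(b < a_i) + .5 P(b = a_i), V01 analogous
    v10 = np.array([(np.sum(b < x) + 0.5 * np.sum(b == x)) / n for x in a])
    v01 = np.array([(np.sum(a > y) + 0.5 * np.sum(a == y)) / m for y in b])
    theta = v10.mean()
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = stats.norm.ppf(1 - (1 - level) / 2)
    half = z * math.sqrt(var)
    return max(0.0, theta - half), min(1.0, theta + half)


def auroc_pvalue(scores_nr, scores_r) -> float:
    """One-sided Wilcoxon rank-sum p-value (NR stochastically greater).

    Exact null when the pooled size is at most 20 and there are no ties;
    otherwise the normal approximation with tie correction.
    """
    a, b = _as_arrays(scores_nr, scores_r)
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
    return float(res.pvalue)


def roc_curve(scores_nr, scores_r) -> list[tuple[float, float]]:
    """ROC points (fpr, tpr), one per distinct threshold, from (0,0) to (1,1).

    Thresholds descend; the trapezoid area of the returned polyline equals
    :func:`auroc` exactly (half credit for ties).
    """
    a, b = _as_arrays(scores_nr, scores_r)
    thresholds = np.unique(np.concatenate([a, b]))[::-1]
    points = [(0.0, 0.0)]
    for t in thresholds:
        tpr = float(np.mean(a >= t))
        fpr = float(np.mean(b >= t))
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


@dataclass
class PerformanceReport:
    """Confusion statistics with 95% CIs, plus ROC/AUROC, for one evaluation."""

    counts: ConfusionCounts
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    precision: float
    precision_ci: tuple[float, float] | None
    likelihood_ratio: float
    likelihood_ratio_ci: tuple[float, float] | None
    auroc: float
    auroc_ci: tuple[float, float]
    auroc_p: float
    roc: list[tuple[float, float]]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d


def report_from_scores(
    scores_nr, scores_r, predicted_nr, predicted_r
) -> PerformanceReport:
    """Build a full report from per-class scores and boolean NR calls.

    ``predicted_nr`` / ``predicted_r`` are boolean arrays aligned with the
    score arrays, True where the classifier called the sample NR.
    """
    a, b = _as_arrays(scores_nr, scores_r)
    pn = np.asarray(predicted_nr, dtype=bool)
    pr = np.asarray(predicted_r, dtype=bool)
    c = ConfusionCounts(
        tp=int(pn.sum()), fn=int((~pn).sum()),
        fp=int(pr.sum()), tn=int((~pr).sum()),
    )
    s = confusion_stats(c)
    prec_ci = (
        clopper_pearson_ci(c.tp, c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    )
    return PerformanceReport(
        counts=c,
        sensitivity=s["sensitivity"],
        sensitivity_ci=clopper_pearson_ci(c.tp, c.n_positive),
        specificity=s["specificity"],
        specificity_ci=clopper_pearson_ci(c.tn, c.n_negative),
        precision=s["precision"],
        precision_ci=prec_ci,
        likelihood_ratio=s["likelihood_ratio"],
        likelihood_ratio_ci=lr_ci(c),
        auroc=auroc(a, b),
        auroc_ci=auroc_ci_delong(a, b),
        auroc_p=auroc_pvalue(a, b),
        roc=roc_curve(a, b),
    )
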