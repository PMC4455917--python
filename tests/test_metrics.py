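"""Confusion statistics, exact binomial CIs, likelihood-ratio CIs, AUROC.

The printed-table worked examples (confusion counts with their likelihood
ratios and interval endpoints) double as exact regression values; the
remaining tests check the estimators against independent brute-force
oracles.
"""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from mechsig.metrics import (
    ConfusionCounts,
    auroc,
    auroc_pvalue,
    clopper_pearson_ci,
    confusion_stats,
    lr_ci,
    report_from_scores,
    roc_curve,
)


def _pct(x: float) -> int:
    """Round a proportion to a whole percentage, half away from zero."""
    return int(math.floor(x * 100 + 0.5))


class TestConfusionStats:
    @pytest.mark.parametrize(
        "counts, sens, spec, prec, lr",
        [
            # leave-one-batch-out rows: (tp, fp, fn, tn)
            ((3, 2, 4, 21), 43, 91, 60, 4.93),
            ((1, 1, 6, 36), 14, 97, 50, 5.29),
            ((4, 2, 9, 12), 31, 86, 67, 2.15),
        ],
    )
    def test_printed_rows(self, counts, sens, spec, prec, lr):
        s = confusion_stats(ConfusionCounts(*counts))
        assert _pct(s["sensitivity"]) == sens
        assert _pct(s["specificity"]) == spec
        assert _pct(s["precision"]) == prec
        assert round(s["likelihood_ratio"], 2) == lr

    def test_infinite_lr_when_no_false_positives(self):
        s = confusion_stats(ConfusionCounts(tp=2, fp=0, fn=3, tn=10))
        assert s["likelihood_ratio"] == math.inf

    def test_precision_nan_when_nothing_called(self):
        s = confusion_stats(ConfusionCounts(tp=0, fp=0, fn=3, tn=10))
        assert math.isnan(s["precision"])

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            confusion_stats(ConfusionCounts(tp=1, fp=0, fn=1, tn=0))
        with pytest.raises(ValueError):
            ConfusionCounts(0, 0, 0, 0)


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k, n, lo_pct, hi_pct",
        [
            (1, 7, 0, 58),
            (3, 5, 15, 95),
            (1, 2, 1, 99),
            (2, 2, 16, 100),
            (0, 5, 0, 52),
        ],
    )
    def test_printed_interval_cells(self, k, n, lo_pct, hi_pct):
        lo, hi = clopper_pearson_ci(k, n)
        assert (_pct(lo), _pct(hi)) == (lo_pct, hi_pct)

    def test_degenerate_endpoints_exact(self):
        assert clopper_pearson_ci(0, 5)[0] == 0.0
        assert clopper_pearson_ci(5, 5)[1] == 1.0

    def test_level_validation(self):
        with pytest.raises(ValueError):
            clopper_pearson_ci(1, 2, level=1.0)

    def test_matches_binomial_tail_bisection(self):
        """Beta-quantile endpoints equal direct tail inversion by bisection."""

        def invert(tail, target, increasing):
            lo, hi = 0.0, 1.0
            for _ in range(80):
                mid = (lo + hi) / 2
                if (tail(mid) > target) == increasing:
                    hi = mid
                else:
                    lo = mid
            return (lo + hi) / 2

        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(1, 40))
            k = int(rng.integers(0, n + 1))
            lo, hi = clopper_pearson_ci(k, n)
            if k > 0:
                # lower: p with P(X >= k) = alpha/2 (tail increasing in p)
                want = invert(lambda p: 1 - stats.binom.cdf(k - 1, n, p), 0.025, True)
                assert lo == pytest.approx(want, abs=1e-9)
            if k < n:
                # upper: p with P(X <= k) = alpha/2 (tail decreasing in p)
                want = invert(lambda p: stats.binom.cdf(k, n, p), 0.025, False)
                assert hi == pytest.approx(want, abs=1e-9)


class TestLikelihoodRatioCI:
    @pytest.mark.parametrize(
        "counts, lo, hi",
        [
            ((3, 2, 4, 21), 1.0, 23.8),
            ((4, 2, 9, 12), 0.5, 9.9),
        ],
    )
    def test_printed_log_method_intervals(self, counts, lo, hi):
        got = lr_ci(ConfusionCounts(*counts))
        assert round(got[0], 1) == lo
        assert round(got[1], 1) == hi

    def test_na_when_no_false_positives(self):
        assert lr_ci(ConfusionCounts(tp=2, fp=0, fn=3, tn=10)) is None


def auroc_oracle(a, b):
    wins = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)
    return wins / (len(a) * len(b))


class TestAuroc:
    @pytest.mark.parametrize(
        "nr, r, expected",
        [
            ([3, 4], [1, 2], 1.0),
            ([2, 4], [1, 3], 0.75),
            ([1], [1], 0.5),
        ],
    )
    def test_examples(self, nr, r, expected):
        assert auroc(nr, r) == pytest.approx(expected)

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            m, n = int(rng.integers(1, 25)), int(rng.integers(1, 25))
            a = rng.integers(0, 10, m).astype(float)  # many ties
            b = rng.integers(0, 10, n).astype(float)
            assert auroc(a, b) == pytest.approx(auroc_oracle(a, b), abs=1e-12)

    def test_complement_identity(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=10), rng.normal(size=13)
        assert auroc(a, b) + auroc(b, a) == pytest.approx(1.0)

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            auroc([], [1.0])


def wilcoxon_exact_oracle(a, b):
    """One-sided p by full enumeration of rank assignments (no ties)."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in a)
    total = 0
    at_least = 0
    for subset in combinations(range(1, len(pooled) + 1), len(a)):
        total += 1
        if sum(subset) >= observed:
            at_least += 1
    return at_least / total


class TestAurocPvalue:
    def test_fully_separated_small(self):
        assert auroc_pvalue([3, 4], [1, 2]) == pytest.approx(1 / 6)

    def test_single_pair_reversed(self):
        assert auroc_pvalue([1], [2]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        """Exact p equals full enumeration for pooled n <= 10, no ties."""
        rng = np.random.default_rng(5)
        for _ in range(30):
            m = int(rng.integers(1, 6))
            n = int(rng.integers(1, 11 - m))
            pooled = rng.choice(100, size=m + n, replace=False).astype(float)
            a, b = list(pooled[:m]), list(pooled[m:])
            assert auroc_pvalue(a, b) == pytest.approx(
                wilcoxon_exact_oracle(a, b), abs=1e-12
            )

    def test_super_uniform_under_null(self):
        """Null p-values never undershoot the uniform law (2000 simulations)."""
        rng = np.random.default_rng(6)
        ps = np.array([
            auroc_pvalue(rng.normal(size=12), rng.normal(size=18))
            for _ in range(2000)
        ])
        grid = np.linspace(0.05, 0.95, 19)
        for u in grid:
            assert (ps <= u).mean() <= u + 0.035  # Monte-Carlo slack at n=2000


class TestRocCurve:
    def test_single_pair(self):
        assert roc_curve([2], [1]) == [(0.0, 0.0), (0.0, 1.0), (1.0, 1.0)]

    def test_all_tied_scores_diagonal(self):
        pts = roc_curve([1, 1], [1, 1])
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
        assert np.trapezoid([p[1] for p in pts], [p[0] for p in pts]) == pytest.approx(0.5)

    def test_trapezoid_area_equals_auroc(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.integers(0, 6, int(rng.integers(1, 15))).astype(float)
            b = rng.integers(0, 6, int(rng.integers(1, 15))).astype(float)
            pts = roc_curve(a, b)
            area = np.trapezoid([p[1] for p in pts], [p[0] for p in pts])
            assert area == pytest.approx(auroc(a, b), abs=1e-12)

    def test_monotone_points(self):
        rng = np.random.default_rng(8)
        pts = roc_curve(rng.normal(size=20), rng.normal(size=20))
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        assert xs == sorted(xs) and ys == sorted(ys)


def test_report_from_scores_consistency():
    rng = np.random.default_rng(9)
    nr = rng.normal(1.0, 1.0, 12)
    r = rng.normal(0.0, 1.0, 30)
    rep = report_from_scores(nr, r, nr > 0.5, r > 0.5)
    assert rep.counts.n_positive == 12 and rep.counts.n_negative == 30
    assert 0 <= rep.sensitivity <= 1
    assert rep.sensitivity_ci[0] <= rep.sensitivity <= rep.sensitivity_ci[1]
    assert rep.specificity_ci[0] <= rep.specificity <= rep.specificity_ci[1]
    assert rep.auroc == pytest.approx(auroc(nr, r))
    assert rep.auroc_ci[0] <= rep.auroc <= rep.auroc_ci[1]
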