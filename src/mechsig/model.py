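"""Penalized logistic non-response classifier over mechanism strengths.

The model is an L1-penalized (lasso) logistic regression of the
non-responder label on mechanism strength scores pooled across training
cohorts.  After fitting, the linear predictor is affinely rescaled so
training scores span exactly [0.5, 9.5]; test scores are clipped to
[0, 10]; and the decision threshold is set so a target fraction (60% by
default) of training non-responders score strictly above it — a rule
that trades sensitivity for the high specificity wanted when the call
redirects a patient away from first-line therapy.

Use either the statsmodels-style surface::

    model = NonResponseModel(strengths, labels)      # samples x mechanisms
    res = model.fit(seed=0)
    res.summary()
    table = res.score(test_strengths)

or the underlying functions (:func:`fit_lasso`, :func:`rescale_model`,
:func:`score`, :func:`select_threshold`, :func:`gene_contributions`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from mechsig.genesets import MechanismCollection
from mechsig.strength import StrengthMatrix

__all__ = [
    "RawLogitModel",
    "MechanismClassifier",
    "NonResponseModel",
    "NonResponseResults",
    "fit_lasso",
    "rescale_model",
    "score",
    "select_threshold",
    "gene_contributions",
    "stack_strengths",
]

POSITIVE_CLASS = "NR"
SCORE_LO, SCORE_HI = 0.0, 10.0
TRAIN_LO, TRAIN_HI = 0.5, 9.5


def stack_strengths(strengths: list[StrengthMatrix]) -> tuple[pd.DataFrame, pd.Series]:
    """Stack per-cohort strength matrices into one samples x mechanisms frame.

    Only mechanisms scored in every cohort are kept (names must align;
    per-cohort gene support may differ).  Returns the frame and a Series
    mapping sample id -> cohort id.
    """
    if not strengths:
        raise ValueError("no strength matrices")
    common = set(strengths[0].mechanisms)
    for s in strengths[1:]:
        common &= set(s.mechanisms)
    if not common:
        raise ValueError("no mechanism scored in every cohort")
    order = [m for m in strengths[0].mechanisms if m in common]
    frames, cohort_of = [], {}
    for s in strengths:
        frames.append(s.matrix.loc[order].T)
        for samp in s.matrix.columns:
            cohort_of[samp] = s.cohort_id
    X = pd.concat(frames, axis=0)
    if X.index.duplicated().any():
        raise ValueError("duplicate sample ids across cohorts")
    return X, pd.Series(cohort_of, name="cohort").loc[X.index]


@dataclass
class RawLogitModel:
    """Lasso logistic fit on the logit scale, before rescaling."""

    coefficients: pd.Series  # per mechanism, zeros for unselected
    intercept: float
    penalty: float  # lambda in the (1/n) * loss + lambda * ||b||_1 objective
    seed: int | None = None

    @property
    def selected(self) -> pd.Index:
        return self.coefficients.index[self.coefficients != 0.0]

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        return self.intercept + X[self.coefficients.index].to_numpy() @ self.coefficients.to_numpy()


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int, min_ratio: float) -> np.ndarray:
    n = X.shape[0]
    p0 = y.mean()
    lam_max = np.abs(X.T @ (y - p0)).max() / n
    lam_max = max(lam_max, 1e-10)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _fit_at_lambda(X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-6) -> LogisticRegression:
    n = X.shape[0]
    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear",
        tol=tol, max_iter=1000, fit_intercept=True,
        intercept_scaling=100.0, random_state=0,
    )
    clf.fit(X, y)
    if not np.any(clf.coef_):
        # null model: the exact unpenalized-intercept solution is the
        # log-odds of the prevalence (liblinear shrinks the intercept too)
        p = y.mean()
        clf.intercept_ = np.array([math.log(p / (1 - p))])
    return clf


def _binomial_deviance(clf: LogisticRegression, X: np.ndarray, y: np.ndarray) -> float:
    eta = clf.decision_function(X)
    # mean deviance: 2 * mean log-loss
    return float(2.0 * np.mean(np.logaddexp(0.0, eta) - y * eta))


def fit_lasso(
    strengths: pd.DataFrame | list[StrengthMatrix],
    labels,
    penalty: float | str = "cv_1se",
    seed: int | None = None,
    n_lambda: int = 20,
    lambda_min_ratio: float = 0.01,
    standardize: bool = False,
) -> RawLogitModel:
    """Fit the L1-penalized logistic regression of NR status on strengths.

    Parameters
    ----------
    strengths : DataFrame (samples x mechanisms) or list of StrengthMatrix
        Training features; mechanism names must align across cohorts.
    labels : sequence of "NR"/"R" (or booleans, True = NR)
        Non-responder is the positive class.
    penalty : float or {"cv_1se", "cv_min"}
        Fixed penalty strength (lambda, on the mean-loss scale), or a
        selection policy: stratified 5-fold cross-validation over a
        geometric lambda grid, minimizing binomial deviance, taking
        either the minimizer ("cv_min") or the sparsest model within one
        standard error of it ("cv_1se", default).
    seed : int, optional
        Seeds the internal cross-validation fold assignment.
    standardize : bool
        Standardize columns before fitting (coefficients are returned on
        the original scale).  Off by default: strength scores already
        share log2-fold-change units.
    """
    if isinstance(strengths, list):
        X, _ = stack_strengths(strengths)
    else:
        X = strengths
    y = np.asarray(
        [1 if (v is True or v == POSITIVE_CLASS or v == 1) else 0 for v in labels],
        dtype=float,
    )
    if len(y) != X.shape[0]:
        raise ValueError("labels length does not match number of samples")
    Xv = X.to_numpy(dtype=float)
    if not np.isfinite(Xv).all():
        raise ValueError("strength matrix contains non-finite values")
    if y.min() == y.max():
        raise ValueError("training labels contain a single class")

    scale = np.ones(Xv.shape[1])
    if standardize:
        scale = Xv.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
        Xv = (Xv - Xv.mean(axis=0)) / scale

    if isinstance(penalty, str):
        grid = _lambda_grid(Xv, y, n_lambda, lambda_min_ratio)
        n_splits = int(min(5, y.sum(), (1 - y).sum()))
        if n_splits < 2:
            raise ValueError("need >= 2 samples per class for penalty selection")
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        dev = np.zeros((n_splits, grid.size))
        for i, (tr, te) in enumerate(cv.split(Xv, y)):
            for j, lam in enumerate(grid):
                clf = _fit_at_lambda(Xv[tr], y[tr], lam)
                dev[i, j] = _binomial_deviance(clf, Xv[te], y[te])
        mean_dev = dev.mean(axis=0)
        j_min = int(np.argmin(mean_dev))
        if penalty == "cv_min":
            j_pick = j_min
        elif penalty == "cv_1se":
            se = dev[:, j_min].std(ddof=1) / math.sqrt(n_splits)
            # grid descends in lambda: earliest index within 1 SE is sparsest
            j_pick = int(np.argmax(mean_dev <= mean_dev[j_min] + se))
        else:
            raise ValueError(f"unknown penalty policy {penalty!r}")
        lam = float(grid[j_pick])
    else:
        lam = float(penalty)
        if lam < 0:
            raise ValueError("penalty must be >= 0")
        if lam == 0:
            lam = 1e-10  # effectively unpenalized

    clf = _fit_at_lambda(Xv, y, lam)
    coef = clf.coef_.ravel() / scale
    return RawLogitModel(
        coefficients=pd.Series(coef, index=X.columns),
        intercept=float(clf.intercept_[0]),
        penalty=lam,
        seed=seed,
    )


@dataclass
class MechanismClassifier:
    """Fitted classifier on the 0-10 score scale.

    ``score = constant + sum_m coefficients[m] * strength[m]``, clipped to
    [0, 10]; pre-clip training scores span exactly [0.5, 9.5] by the
    rescaling construction.  Samples scoring strictly above ``threshold``
    are predicted non-responders.
    """

    coefficients: pd.Series
    constant: float
    raw_coefficients: pd.Series
    raw_intercept: float
    rescale: tuple[float, float]  # (slope a > 0, offset b)
    threshold: float = math.nan
    target_sensitivity: float = 0.6
    penalty: float = math.nan
    seed: int | None = None
    training_cohorts: list[str] = field(default_factory=list)
    degenerate: bool = False

    @property
    def selected(self) -> pd.Index:
        return self.coefficients.index[self.coefficients != 0.0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coefficients": {m: float(v) for m, v in self.coefficients.items()},
            "constant": self.constant,
            "raw_coefficients": {m: float(v) for m, v in self.raw_coefficients.items()},
            "raw_intercept": self.raw_intercept,
            "rescale": list(self.rescale),
            "threshold": self.threshold,
            "target_sensitivity": self.target_sensitivity,
            "penalty": self.penalty,
            "seed": self.seed,
            "training_cohorts": self.training_cohorts,
            "degenerate": self.degenerate,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MechanismClassifier":
        d = json.loads(Path(path).read_text())
        return cls(
            coefficients=pd.Series(d["coefficients"], dtype=float),
            constant=d["constant"],
            raw_coefficients=pd.Series(d["raw_coefficients"], dtype=float),
            raw_intercept=d["raw_intercept"],
            rescale=tuple(d["rescale"]),
            threshold=d["threshold"],
            target_sensitivity=d["target_sensitivity"],
            penalty=d["penalty"],
            seed=d["seed"],
            training_cohorts=list(d["training_cohorts"]),
            degenerate=d["degenerate"],
        )


def rescale_model(raw: RawLogitModel, training: pd.DataFrame) -> MechanismClassifier:
    """Affinely map the training linear predictor onto [0.5, 9.5].

    The map sends the minimum training predictor to 0.5 and the maximum
    to 9.5 (positive slope), and is absorbed into the coefficients and
    constant so scoring stays a single affine form.
    """
    eta = raw.linear_predictor(training)
    lo, hi = float(eta.min()), float(eta.max())
    if hi <= lo:
        raise ValueError("training linear predictor is constant; degenerate fit")
    a = (TRAIN_HI - TRAIN_LO) / (hi - lo)
    b = TRAIN_LO - a * lo
    return MechanismClassifier(
        coefficients=raw.coefficients * a,
        constant=raw.intercept * a + b,
        raw_coefficients=raw.coefficients.copy(),
        raw_intercept=raw.intercept,
        rescale=(a, b),
        penalty=raw.penalty,
        seed=raw.seed,
    )


def score(model: MechanismClassifier, strengths: pd.DataFrame | StrengthMatrix) -> pd.DataFrame:
    """Score samples on the 0-10 scale and call non-responders.

    Returns a DataFrame indexed by sample id with columns ``score``
    (clipped to [0, 10]) and ``predicted`` ("NR" iff score > threshold;
    all-NaN if no threshold is set).  Every mechanism with a nonzero
    coefficient must be present in ``strengths``.
    """
    X = strengths.matrix.T if isinstance(strengths, StrengthMatrix) else strengths
    needed = model.selected
    missing = [m for m in needed if m not in X.columns]
    if missing:
        raise ValueError(f"strength matrix missing classifier mechanisms: {missing}")
    if len(needed):
        linear = model.constant + X[list(needed)].to_numpy() @ model.coefficients[needed].to_numpy()
    else:
        linear = np.full(X.shape[0], model.constant)
    clipped = np.clip(linear, SCORE_LO, SCORE_HI)
    out = pd.DataFrame({"score": clipped}, index=X.index)
    if math.isnan(model.threshold):
        out["predicted"] = pd.NA
    else:
        out["predicted"] = np.where(clipped > model.threshold, "NR", "R")
    return out


def select_threshold(
    training_scores_nr, target_sensitivity: float = 0.6
) -> float:
    """Decision threshold from training non-responder scores.

    With the n NR training scores sorted ascending and
    ``k = floor((1 - target) * n)``, the threshold is the k-th order
    statistic, which leaves at least ``target`` of the NR strictly above
    when scores are distinct.  Ties are resolved toward higher
    sensitivity (lower threshold); k = 0 places the threshold just below
    the minimum score.
    """
    s = np.sort(np.asarray(training_scores_nr, dtype=float))
    n = s.size
    if n < 1:
        raise ValueError("no non-responder training scores")
    if not 0 < target_sensitivity <= 1:
        raise ValueError("target_sensitivity must be in (0, 1]")
    k = math.floor((1.0 - target_sensitivity) * n)
    while k >= 1 and np.sum(s > s[k - 1]) / n < target_sensitivity:
        k -= 1
    if k == 0:
        return float(np.nextafter(s[0], -np.inf))
    return float(s[k - 1])


def gene_contributions(
    model: MechanismClassifier,
    coll: MechanismCollection,
    gene_universe: set[str],
) -> pd.Series:
    """Per-gene contribution to the classifier score.

    A gene g contributes ``sum_m beta_m * sign_{g,m} / |G'_m|`` over the
    selected mechanisms containing it, where G'_m is the mechanism's gene
    support within ``gene_universe`` (the per-gene weight inside the
    strength mean).  Genes in no selected mechanism contribute 0.
    """
    universe = frozenset(gene_universe)
    contrib: dict[str, float] = {}
    for name in model.selected:
        beta = float(model.coefficients[name])
        try:
            gs = coll[name]
        except KeyError:
            continue
        present = [(g, s) for g, s in gs.members.items() if g in universe]
        if not present:
            continue
        k = len(present)
        for g, sign in present:
            contrib[g] = contrib.get(g, 0.0) + beta * sign / k
    return pd.Series(contrib, dtype=float).sort_values(ascending=False)


class NonResponseModel:
    """Non-response classifier model (statsmodels-style entry point).

    Parameters
    ----------
    strengths : DataFrame (samples x mechanisms) or list of StrengthMatrix
        Mechanism strength scores for the training samples.
    labels : sequence of "NR"/"R"
        Clinical response labels aligned with the samples.
    cohorts : Series, optional
        Sample -> cohort/batch id (derived automatically when a list of
        StrengthMatrix is given); used for bookkeeping and summaries.
    """

    def __init__(self, strengths, labels, cohorts: pd.Series | None = None):
        if isinstance(strengths, list):
            self.exog, derived = stack_strengths(strengths)
            self.cohorts = cohorts if cohorts is not None else derived
        else:
            self.exog = strengths
            self.cohorts = cohorts
        self.endog = pd.Series(list(labels), index=self.exog.index, name="response")
        bad = set(self.endog) - {"R", "NR"}
        if bad:
            raise ValueError(f"labels must be R/NR, got {sorted(bad)}")

    @classmethod
    def from_cohorts(cls, strengths: list[StrengthMatrix], labels) -> "NonResponseModel":
        return cls(strengths, labels)

    def fit(
        self,
        penalty: float | str = "cv_1se",
        target_sensitivity: float = 0.6,
        seed: int | None = None,
        standardize: bool = False,
        allow_degenerate: bool = False,
    ) -> "NonResponseResults":
        """Fit, rescale to [0.5, 9.5], and select the decision threshold.

        With ``allow_degenerate`` a fit that selects no mechanism (the
        common outcome under label permutation) yields a constant-score
        classifier at the scale midpoint instead of raising.
        """
        raw = fit_lasso(
            self.exog, self.endog, penalty=penalty, seed=seed, standardize=standardize
        )
        eta = raw.linear_predictor(self.exog)
        if float(eta.max()) <= float(eta.min()):
            if not allow_degenerate:
                raise ValueError(
                    "fit selected no mechanism (constant predictor); "
                    "pass allow_degenerate=True to accept a constant classifier"
                )
            clf = MechanismClassifier(
                coefficients=raw.coefficients * 0.0,
                constant=(TRAIN_LO + TRAIN_HI) / 2,
                raw_coefficients=raw.coefficients.copy(),
                raw_intercept=raw.intercept,
                rescale=(1.0, (TRAIN_LO + TRAIN_HI) / 2 - raw.intercept),
                penalty=raw.penalty,
                seed=seed,
                degenerate=True,
            )
        else:
            clf = rescale_model(raw, self.exog)
        if self.cohorts is not None:
            clf.training_cohorts = sorted(set(self.cohorts))
        clf.target_sensitivity = target_sensitivity
        train_scores = score(clf, self.exog)["score"]
        nr_scores = train_scores[self.endog.to_numpy() == "NR"]
        clf.threshold = select_threshold(nr_scores, target_sensitivity)
        return NonResponseResults(self, clf, train_scores)


class NonResponseResults:
    """Results of :meth:`NonResponseModel.fit`.

    Attributes
    ----------
    params : Series
        Rescaled coefficients of the selected mechanisms (Table-2 scale).
    constant, threshold : float
    classifier : MechanismClassifier
        The full serializable classifier object.
    training_scores : Series
        In-sample 0-10 scores (pre-clip range [0.5, 9.5] by construction).
    """

    def __init__(self, model: NonResponseModel, classifier: MechanismClassifier,
                 training_scores: pd.Series):
        self.model = model
        self.classifier = classifier
        self.training_scores = training_scores

    @property
    def params(self) -> pd.Series:
        return self.classifier.coefficients[self.classifier.selected]

    @property
    def constant(self) -> float:
        return self.classifier.constant

    @property
    def threshold(self) -> float:
        return self.classifier.threshold

    def score(self, strengths) -> pd.DataFrame:
        """Score new samples; see :func:`score`."""
        return score(self.classifier, strengths)

    def predict(self, strengths) -> pd.Series:
        return self.score(strengths)["predicted"]

    def gene_contributions(self, coll: MechanismCollection, gene_universe) -> pd.Series:
        return gene_contributions(self.classifier, coll, gene_universe)

    def training_performance(self):
        """In-sample performance report (optimistic; for diagnostics only)."""
        from mechsig.metrics import report_from_scores

        y = self.model.endog.to_numpy()
        s = self.training_scores.to_numpy()
        pred = s > self.classifier.threshold
        return report_from_scores(
            s[y == "NR"], s[y == "R"], pred[y == "NR"], pred[y == "R"]
        )

    def summary(self) -> str:
        """Plain-text coefficient table in the style of a linear-model report."""
        clf = self.classifier
        lines = [
            "Non-response mechanism classifier (lasso logistic, 0-10 scale)",
            "=" * 62,
            f"Training samples: {len(self.model.endog)}"
            f"  (NR: {int((self.model.endog == 'NR').sum())},"
            f" R: {int((self.model.endog == 'R').sum())})",
            f"Training cohorts: {', '.join(clf.training_cohorts) or 'n/a'}",
            f"Penalty (lambda): {clf.penalty:.6g}   Selected mechanisms: {len(clf.selected)}",
            f"Decision threshold: {clf.threshold:.3f} "
            f"(target training NR sensitivity {clf.target_sensitivity:.0%})",
            "-" * 62,
            f"{'Mechanism':<40}{'Coefficient':>12}",
            f"{'(Constant)':<40}{clf.constant:>12.3f}",
        ]
        for name, beta in self.params.sort_values(key=np.abs, ascending=False).items():
            lines.append(f"{name:<40}{beta:>12.3f}")
        lines.append("=" * 62)
        return "\n".join(lines)
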