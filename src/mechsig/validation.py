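"""Batch-aware resampling schemes for classifier validation.

Cohorts collected on different platforms are treated as batches.  Two
complementary estimates are produced:

- *in-batch*: repeated 10-fold cross-validation in which every batch is
  split approximately equally across the folds, so each training split
  sees every platform;
- *out-of-batch*: leave-one-batch-out, training on all but one cohort and
  testing on the left-out cohort (whose strengths are computed against its
  OWN median reference), estimating generalization to an unseen study.

A label-permutation null re-runs the full in-batch scheme with response
labels shuffled before every repeat, giving the AUROC distribution under
no association.  All randomness derives from one seed via spawned
substreams, so schemes are independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mechsig.metrics import PerformanceReport, auroc, report_from_scores
from mechsig.model import NonResponseModel, score, stack_strengths
from mechsig.strength import StrengthMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "FoldPlan",
    "CVResult",
    "make_folds",
    "repeated_kfold",
    "leave_one_batch_out",
    "leave_one_sample_out",
    "permutation_null",
]

SUMMARY_STATS = ("auroc", "sensitivity", "specificity", "precision", "likelihood_ratio")


@dataclass(frozen=True)
class PipelineConfig:
    """Options for the train-score pipeline run inside each fold."""

    penalty: float | str = "cv_1se"
    target_sensitivity: float = 0.6
    standardize: bool = False


@dataclass
class FoldPlan:
    """A k-fold partition balanced within every cohort."""

    repeat: int
    folds: list[list[str]]  # fold index -> sample ids

    def assignment(self) -> dict[str, int]:
        return {s: i for i, fold in enumerate(self.folds) for s in fold}


def make_folds(cohorts: pd.Series, k: int = 10, seed=None) -> FoldPlan:
    """Deal samples into k folds, splitting each cohort approximately equally.

    Within each cohort, samples are shuffled and dealt round-robin into
    the k folds starting at a random fold, so per-cohort fold sizes
    differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(cohorts):
        raise ValueError(f"k={k} exceeds total sample count {len(cohorts)}")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    for cohort in pd.unique(cohorts):
        members = list(cohorts.index[cohorts == cohort])
        rng.shuffle(members)
        start = int(rng.integers(k))
        for i, s in enumerate(members):
            folds[(start + i) % k].append(s)
    return FoldPlan(repeat=0, folds=folds)


@dataclass
class CVResult:
    """Repeated cross-validation output.

    ``per_repeat`` holds one row of pooled out-of-fold statistics per
    repeat; ``summary`` maps each statistic to its median and 2.5/97.5
    percentiles across repeats.  ``score_table`` is the pooled score/label
    table of the repeat whose AUROC is closest to the median (the
    patient-stratification view).
    """

    per_repeat: pd.DataFrame
    summary: dict[str, dict[str, float]]
    score_table: pd.DataFrame
    k: int
    repeats: int
    redraws: int = 0


def _summarize(per_repeat: pd.DataFrame) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for stat in SUMMARY_STATS:
        v = per_repeat[stat].to_numpy(dtype=float)
        finite = v[np.isfinite(v)]
        if finite.size == 0:
            out[stat] = {"median": float("nan"), "lo": float("nan"), "hi": float("nan")}
            continue
        out[stat] = {
            "median": float(np.median(finite)),
            "lo": float(np.percentile(finite, 2.5)),
            "hi": float(np.percentile(finite, 97.5)),
        }
    return out


def _pooled_stats(table: pd.DataFrame) -> dict[str, float]:
    y = table["label"].to_numpy()
    s = table["score"].to_numpy(dtype=float)
    pred = table["predicted"].to_numpy() == "NR"
    is_nr, is_r = y == "NR", y == "R"
    tp = int(pred[is_nr].sum())
    fn = int((~pred[is_nr]).sum())
    fp = int(pred[is_r].sum())
    tn = int((~pred[is_r]).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (fp + tn) if fp + tn else np.nan
    prec = tp / (tp + fp) if tp + fp else np.nan
    lr = sens / (1 - spec) if spec < 1 else (np.inf if sens > 0 else np.nan)
    return {
        "auroc": auroc(s[is_nr], s[is_r]),
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "likelihood_ratio": lr,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
    }


def _run_one_cv(
    X: pd.DataFrame,
    labels: pd.Series,
    cohorts: pd.Series,
    k: int,
    seed_seq: np.random.SeedSequence,
    config: PipelineConfig,
    max_redraws: int = 100,
) -> tuple[pd.DataFrame, int]:
    """One full k-fold pass; returns the pooled out-of-fold table.

    A fold plan whose training splits do not all contain both classes is
    re-drawn (with a derived seed) up to ``max_redraws`` times.
    """
    y = labels.to_numpy()
    redraws = 0
    for attempt in range(max_redraws):
        plan = make_folds(cohorts, k=k, seed=np.random.default_rng(seed_seq.spawn(1)[0]))
        ok = True
        for fold in plan.folds:
            train_mask = ~labels.index.isin(fold)
            classes = set(y[train_mask])
            if not {"R", "NR"} <= classes:
                ok = False
                break
        if ok:
            break
        redraws += 1
        logger.info("fold plan redrawn (attempt %d): single-class training split", attempt + 1)
    else:
        raise ValueError("could not draw a fold plan with two-class training splits")

    fit_seed = int(seed_seq.generate_state(1)[0] % (2**31 - 1))
    rows = []
    for fold in plan.folds:
        if not fold:
            continue
        test_mask = labels.index.isin(fold)
        X_tr, y_tr = X[~test_mask], labels[~test_mask]
        model = NonResponseModel(X_tr, y_tr, cohorts=cohorts[~test_mask])
        res = model.fit(
            penalty=config.penalty,
            target_sensitivity=config.target_sensitivity,
            seed=fit_seed,
            standardize=config.standardize,
            allow_degenerate=True,
        )
        st = res.score(X[test_mask])
        st["label"] = labels[test_mask]
        st["cohort"] = cohorts[test_mask]
        rows.append(st)
    return pd.concat(rows), redraws


def repeated_kfold(
    X: pd.DataFrame,
    labels: pd.Series,
    cohorts: pd.Series,
    k: int = 10,
    repeats: int = 1000,
    seed: int | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> CVResult:
    """Repeated batch-balanced k-fold cross-validation.

    Per repeat, samples are dealt into k cohort-balanced folds; a full
    pipeline (lasso fit, rescale, threshold) is trained without the
    held-out fold and scores it; out-of-fold scores are pooled and
    summarized.  The summary holds the median and 2.5/97.5 percentiles of
    each statistic across repeats.
    """
    _validate_inputs(X, labels, cohorts)
    root = np.random.SeedSequence(seed)
    per_repeat = []
    tables = []
    total_redraws = 0
    for rep_seq in root.spawn(repeats):
        table, redraws = _run_one_cv(X, labels, cohorts, k, rep_seq, config)
        total_redraws += redraws
        stats = _pooled_stats(table)
        per_repeat.append(stats)
        tables.append(table)
    df = pd.DataFrame(per_repeat)
    summary = _summarize(df)
    med = summary["auroc"]["median"]
    rep_ix = int(np.argmin(np.abs(df["auroc"].to_numpy() - med)))
    return CVResult(
        per_repeat=df,
        summary=summary,
        score_table=tables[rep_ix],
        k=k,
        repeats=repeats,
        redraws=total_redraws,
    )


def leave_one_sample_out(
    X: pd.DataFrame,
    labels: pd.Series,
    cohorts: pd.Series,
    seed: int | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> CVResult:
    """Leave-one-sample-out: k = n, one repeat (same code path as k-fold)."""
    return repeated_kfold(
        X, labels, cohorts, k=len(labels), repeats=1, seed=seed, config=config
    )


def leave_one_batch_out(
    strengths: list[StrengthMatrix],
    labels: pd.Series,
    seed: int | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> dict[str, PerformanceReport | None]:
    """Train on all cohorts but one; test on the left-out cohort.

    Each cohort's strengths are computed against its own median reference
    (self-referenced batches), so the held-out matrix is used as-is.
    Returns one report per left-out cohort (None where the held-out
    cohort has a single class, for which AUROC is undefined), plus a
    ``"mean"`` entry averaging the finite per-cohort statistics.
    """
    if len(strengths) < 2:
        raise ValueError("leave-one-batch-out needs >= 2 cohorts")
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(len(strengths))]
    reports: dict[str, PerformanceReport | None] = {}
    for i, held_out in enumerate(strengths):
        train = [s for j, s in enumerate(strengths) if j != i]
        X_tr, cohorts_tr = stack_strengths(train)
        model = NonResponseModel(X_tr, labels.loc[X_tr.index], cohorts=cohorts_tr)
        res = model.fit(
            penalty=config.penalty,
            target_sensitivity=config.target_sensitivity,
            seed=seeds[i],
            standardize=config.standardize,
        )
        missing = [m for m in res.classifier.selected if m not in held_out.mechanisms]
        if missing:
            raise ValueError(
                f"held-out cohort {held_out.cohort_id} lacks classifier "
                f"mechanisms: {missing}"
            )
        st = res.score(held_out)
        y = labels.loc[st.index].to_numpy()
        is_nr, is_r = y == "NR", y == "R"
        if not is_nr.any() or not is_r.any():
            logger.warning(
                "held-out cohort %s is single-class; AUROC undefined", held_out.cohort_id
            )
            reports[held_out.cohort_id] = None
            continue
        pred = st["predicted"].to_numpy() == "NR"
        reports[held_out.cohort_id] = report_from_scores(
            st["score"].to_numpy()[is_nr], st["score"].to_numpy()[is_r],
            pred[is_nr], pred[is_r],
        )
    return reports


def lobo_mean_summary(reports: dict[str, PerformanceReport | None]) -> dict[str, float]:
    """Mean of each statistic across the defined per-cohort reports."""
    out = {}
    for stat in SUMMARY_STATS:
        vals = [
            getattr(r, stat) for r in reports.values()
            if r is not None and np.isfinite(getattr(r, stat))
        ]
        out[stat] = float(np.mean(vals)) if vals else float("nan")
    return out


def permutation_null(
    X: pd.DataFrame,
    labels: pd.Series,
    cohorts: pd.Series,
    k: int = 10,
    repeats: int = 1000,
    seed: int | None = None,
    config: PipelineConfig = PipelineConfig(),
    reference_auroc: float | None = None,
) -> dict:
    """Label-permutation null distribution of the pooled CV AUROC.

    Per repeat, response labels are permuted across the full pooled
    sample set (class counts preserved), then a complete k-fold
    cross-validation is run and its pooled AUROC recorded.  Returns the
    null AUROCs, their median, and — when ``reference_auroc`` is given —
    the count of null repeats exceeding it and the empirical p-value
    ``(1 + #exceed) / (1 + repeats)``.
    """
    _validate_inputs(X, labels, cohorts)
    root = np.random.SeedSequence(seed)
    null_aurocs = []
    y = labels.to_numpy().copy()
    for rep_seq in root.spawn(repeats):
        rng = np.random.default_rng(rep_seq.spawn(1)[0])
        permuted = pd.Series(rng.permutation(y), index=labels.index)
        table, _ = _run_one_cv(X, permuted, cohorts, k, rep_seq, config)
        null_aurocs.append(_pooled_stats(table)["auroc"])
    arr = np.asarray(null_aurocs)
    out = {"null_aurocs": arr, "median": float(np.median(arr))}
    if reference_auroc is not None:
        exceed = int(np.sum(arr > reference_auroc))
        out["exceedance"] = exceed
        out["p_empirical"] = (1 + exceed) / (1 + repeats)
    return out


def _validate_inputs(X: pd.DataFrame, labels: pd.Series, cohorts: pd.Series) -> None:
    if not (len(X) == len(labels) == len(cohorts)):
        raise ValueError("X, labels and cohorts must be aligned")
    if not (X.index.equals(labels.index) and X.index.equals(cohorts.index)):
        raise ValueError("X, labels and cohorts must share the same sample index")
    bad = set(labels) - {"R", "NR"}
    if bad:
        raise ValueError(f"labels must be R/NR (filter unknowns first), got {sorted(bad)}")
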