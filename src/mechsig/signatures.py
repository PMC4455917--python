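"""Published gene-list classifiers, re-trained as clustering-based scorers.

Earlier anti-TNF response studies published gene lists but no scoring
formula, so each list is re-trained on the evaluation data itself: the
training samples (restricted to the signature genes, median-centered
expression) are split into two clusters, each cluster is assigned the
majority response call of its members, and a test sample is scored by
the difference of its distances to the two cluster medians (higher =
more NR-like), predicting the call of the nearest median.  One published
signature instead uses k-nearest neighbours (k = 3) with 0/1 scores.

Evaluation uses leave-one-sample-out cross-validation over the pooled
cohorts, optionally excluding a signature's original training cohort to
avoid feature-selection bias.

Tie rules (equidistant sample, tied cluster or vote counts) all favour
the NR class, keeping the positive call conservative; each is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from mechsig.metrics import PerformanceReport, report_from_scores

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSignature",
    "ClusterSignatureModel",
    "fit_cluster_signature",
    "score_nearest_median",
    "knn_signature_score",
    "evaluate_signature_loso",
    "read_signatures",
]


@dataclass(frozen=True)
class GeneSignature:
    """A published gene list plus the scorer used to re-train it."""

    name: str
    genes: tuple[str, ...]
    scorer: str = "nearest_cluster_median"  # or "knn"
    k: int = 3
    exclude_cohorts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.scorer not in ("nearest_cluster_median", "knn"):
            raise ValueError(f"unknown scorer {self.scorer!r}")
        if not self.genes:
            raise ValueError(f"signature {self.name}: empty gene list")


def read_signatures(path: str | Path) -> list[GeneSignature]:
    """Read signatures from TSV: ``name<TAB>scorer<TAB>k<TAB>gene1,gene2,...``."""
    sigs = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("name\t"):
            continue
        name, scorer, k, genes = line.split("\t")
        sigs.append(GeneSignature(name, tuple(genes.split(",")), scorer, int(k) if k else 3))
    return sigs


@dataclass
class ClusterSignatureModel:
    """Two cluster medians with their majority response calls."""

    genes: list[str]
    medians: dict[int, np.ndarray]  # cluster id -> median profile
    calls: dict[int, str]           # cluster id -> "R"/"NR"


def _correlation_linkage(X: np.ndarray) -> np.ndarray:
    if X.shape[1] > 1:
        d = pdist(X, metric="correlation")
        if not np.isfinite(d).all():  # constant profiles: fall back to euclidean
            d = pdist(X, metric="euclidean")
    else:
        d = pdist(X, metric="euclidean")
    return linkage(d, method="average")


def fit_cluster_signature(
    expression: pd.DataFrame, labels: pd.Series
) -> ClusterSignatureModel:
    """Cluster training samples into two groups on the signature genes.

    ``expression`` is samples x genes, already restricted to the
    signature genes (raises if any gene column is entirely missing).
    Agglomerative hierarchical clustering with average linkage and
    correlation distance, cut at two clusters; each cluster's call is the
    majority label, ties going to NR.
    """
    if expression.isna().all().any():
        missing = expression.columns[expression.isna().all()].tolist()
        raise ValueError(f"signature genes absent from data: {missing}")
    if expression.shape[0] < 2:
        raise ValueError("need >= 2 training samples")
    y = labels.loc[expression.index]
    if set(y) != {"R", "NR"}:
        raise ValueError("training labels must include both classes")
    X = expression.to_numpy(dtype=float)
    assign = fcluster(_correlation_linkage(X), t=2, criterion="maxclust")
    model = ClusterSignatureModel(genes=list(expression.columns), medians={}, calls={})
    for cl in np.unique(assign):
        members = assign == cl
        model.medians[int(cl)] = np.median(X[members], axis=0)
        n_nr = int((y.to_numpy()[members] == "NR").sum())
        n_r = int(members.sum()) - n_nr
        if n_nr == n_r:
            logger.info("cluster %d: tied label counts, calling NR", cl)
        model.calls[int(cl)] = "NR" if n_nr >= n_r else "R"
    return model


def score_nearest_median(model: ClusterSignatureModel, sample: np.ndarray) -> tuple[float, str]:
    """Score = d(sample, R-ish median) - d(sample, NR-ish median); label of nearest.

    With both clusters carrying the same call the score is the (signed)
    distance difference between them in cluster-id order.  Equidistant
    samples are labelled NR (logged).
    """
    ids = sorted(model.medians)
    dists = {cl: float(np.linalg.norm(sample - model.medians[cl])) for cl in ids}
    nr_clusters = [cl for cl in ids if model.calls[cl] == "NR"]
    r_clusters = [cl for cl in ids if model.calls[cl] == "R"]
    if nr_clusters and r_clusters:
        score = min(dists[cl] for cl in r_clusters) - min(dists[cl] for cl in nr_clusters)
    else:  # degenerate: both clusters share a call
        score = dists[ids[0]] - dists[ids[1]]
    nearest = min(ids, key=lambda cl: (dists[cl], model.calls[cl] != "NR"))
    if len(ids) == 2 and dists[ids[0]] == dists[ids[1]]:
        logger.info("equidistant sample: tie resolved toward NR")
        label = "NR" if nr_clusters else model.calls[nearest]
    else:
        label = model.calls[nearest]
    return score, label


def knn_signature_score(
    training: pd.DataFrame,
    training_labels: pd.Series,
    sample: np.ndarray,
    k: int = 3,
) -> tuple[float, str]:
    """Majority vote of the k nearest training samples; score 1 iff NR.

    Euclidean distance; tied votes go to NR (logged).  Scores are only
    0 or 1, so downstream ROC curves have few distinct thresholds.
    """
    if k > len(training):
        raise ValueError(f"k={k} exceeds training size {len(training)}")
    X = training.to_numpy(dtype=float)
    d = np.linalg.norm(X - sample[None, :], axis=1)
    nearest = np.argsort(d, kind="stable")[:k]
    votes = training_labels.to_numpy()[nearest]
    n_nr = int((votes == "NR").sum())
    if 2 * n_nr == k:
        logger.info("tied k-NN vote: resolved toward NR")
    label = "NR" if 2 * n_nr >= k else "R"
    return (1.0 if label == "NR" else 0.0), label


def evaluate_signature_loso(
    sig: GeneSignature,
    expression: pd.DataFrame,
    labels: pd.Series,
    cohorts: pd.Series,
) -> PerformanceReport:
    """Leave-one-sample-out evaluation of one signature over pooled cohorts.

    ``expression`` is samples x genes median-centered log2 data pooled
    over cohorts; genes absent everywhere raise, genes absent in some
    samples are dropped for this signature.  Cohorts listed in
    ``sig.exclude_cohorts`` (the signature's own training data) are
    removed before evaluation.
    """
    keep = ~cohorts.isin(sig.exclude_cohorts)
    expr = expression.loc[keep]
    y = labels.loc[keep]
    genes = [g for g in sig.genes if g in expr.columns and expr[g].notna().all()]
    if not genes:
        raise ValueError(
            f"signature {sig.name}: none of its genes measured in all samples"
        )
    if len(genes) < len(sig.genes):
        logger.info(
            "signature %s: %d/%d genes measured", sig.name, len(genes), len(sig.genes)
        )
    sub = expr[genes]
    scores, preds = [], []
    for i, sample_id in enumerate(sub.index):
        train = sub.drop(index=sample_id)
        train_y = y.drop(index=sample_id)
        x = sub.loc[sample_id].to_numpy(dtype=float)
        if sig.scorer == "knn":
            s, lab = knn_signature_score(train, train_y, x, k=sig.k)
        else:
            model = fit_cluster_signature(train, train_y)
            s, lab = score_nearest_median(model, x)
        scores.append(s)
        preds.append(lab)
    scores = np.asarray(scores)
    preds = np.asarray(preds) == "NR"
    yv = y.to_numpy()
    is_nr, is_r = yv == "NR", yv == "R"
    return report_from_scores(scores[is_nr], scores[is_r], preds[is_nr], preds[is_r])
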