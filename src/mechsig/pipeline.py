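"""End-to-end orchestration: ingest -> strength -> train/validate -> report.

A run is driven by one YAML (or JSON-equivalent) config; all randomness
flows from a single root seed through named substreams so each stage is
independently reproducible.  Outputs are plain TSV/JSON files; a failed
stage leaves a ``.incomplete`` marker next to the output directory's run
log.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mechsig import __version__
from mechsig.genesets import filter_by_coverage, read_signed_gmt
from mechsig.ingest import ExpressionCohort, median_center, read_annotations, read_matrix
from mechsig.model import NonResponseModel, stack_strengths
from mechsig.strength import strength_scores
from mechsig.validation import (
    PipelineConfig,
    leave_one_batch_out,
    lobo_mean_summary,
    permutation_null,
    repeated_kfold,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = ["RunConfig", "run", "cohorts_to_strengths"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    cohort_paths: dict[str, str] = field(default_factory=dict)  # cohort id -> TSV
    kb_path: str | None = None
    annotation_path: str | None = None
    out_dir: str = "mechsig_run"
    min_genes: int = 4
    target_sensitivity: float = 0.6
    penalty: str | float = "cv_1se"
    standardize: bool = False
    log2_transform: bool = False
    scheme: str = "train"  # train | repeated-kfold | lobo | permutation
    k: int = 10
    repeats: int = 100
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for cid, p in self.cohort_paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"cohort {cid}: {p}")
        for p in (self.kb_path, self.annotation_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.scheme in ("repeated-kfold", "permutation") and self.seed is None:
            raise ValueError(f"scheme {self.scheme!r} requires a seed")


def cohorts_to_strengths(cohorts: list[ExpressionCohort], kb, min_genes: int = 4):
    """Shared front half of every analysis: filter KB, center, score.

    Coverage filtering is done once against all cohorts' gene universes
    (fixed globally, not per CV split).  Returns (list of StrengthMatrix,
    filtered collection).
    """
    universes = [c.gene_universe for c in cohorts]
    kept = filter_by_coverage(kb, universes, min_genes=min_genes)
    if len(kept) == 0:
        raise ValueError(f"no mechanism has >= {min_genes} genes in every cohort")
    strengths = [
        strength_scores(median_center(c), kept, min_genes=min_genes) for c in cohorts
    ]
    return strengths, kept


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    path.write_text(json.dumps({"schema_version": SCHEMA_VERSION, "data": obj},
                               indent=1, default=default))


def run(config: RunConfig) -> Path:
    """Execute the configured pipeline; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "run.incomplete"
    marker.touch()
    logging.basicConfig(level=logging.INFO)
    log_lines = [f"mechsig {__version__} / python {sys.version.split()[0]}",
                 f"config: {config}"]
    try:
        ann = read_annotations(config.annotation_path) if config.annotation_path else None
        cohorts = []
        for cid, path in config.cohort_paths.items():
            samples = None
            if ann is not None:
                samples = ann[ann.get("cohort", pd.Series(dtype=str)) == cid]
            cohorts.append(
                read_matrix(path, cid, samples=samples, log2_transform=config.log2_transform)
            )
        kb = read_signed_gmt(config.kb_path)
        strengths, kept = cohorts_to_strengths(cohorts, kb, config.min_genes)
        for s in strengths:
            s.to_tsv(out / f"strength_{s.cohort_id}.tsv",
                     out / f"strength_{s.cohort_id}.support.tsv")

        X, cohort_of = stack_strengths(strengths)
        labels = pd.concat([c.labels() for c in cohorts]).loc[X.index]
        known = labels.isin(["R", "NR"])
        X, labels, cohort_of = X[known], labels[known], cohort_of[known]

        pc = PipelineConfig(
            penalty=config.penalty,
            target_sensitivity=config.target_sensitivity,
            standardize=config.standardize,
        )
        if config.scheme == "train":
            res = NonResponseModel(X, labels, cohorts=cohort_of).fit(
                penalty=config.penalty,
                target_sensitivity=config.target_sensitivity,
                seed=config.seed,
                standardize=config.standardize,
            )
            res.classifier.to_json(out / "model.json")
            table = res.score(X)
            table["label"] = labels
            table["cohort"] = cohort_of
            table.to_csv(out / "scores.tsv", sep="\t", index_label="sample")
            (out / "summary.txt").write_text(res.summary() + "\n")
        elif config.scheme == "repeated-kfold":
            cv = repeated_kfold(X, labels, cohort_of, k=config.k,
                                repeats=config.repeats, seed=config.seed, config=pc)
            cv.per_repeat.to_csv(out / "cv_per_repeat.tsv", sep="\t", index_label="repeat")
            cv.score_table.to_csv(out / "stratification.tsv", sep="\t",
                                  index_label="sample")
            _write_json(out / "cv_summary.json", cv.summary)
        elif config.scheme == "lobo":
            reports = leave_one_batch_out(strengths, labels, seed=config.seed, config=pc)
            payload = {
                cid: (r.to_dict() if r is not None else None) for cid, r in reports.items()
            }
            payload["mean"] = lobo_mean_summary(reports)
            _write_json(out / "lobo.json", payload)
            for cid, r in reports.items():
                if r is not None:
                    pd.DataFrame(r.roc, columns=["fpr", "tpr"]).to_csv(
                        out / f"roc_{cid}.tsv", sep="\t", index=False
                    )
        elif config.scheme == "permutation":
            null = permutation_null(X, labels, cohort_of, k=config.k,
                                    repeats=config.repeats, seed=config.seed, config=pc)
            _write_json(out / "permutation_null.json",
                        {"median": null["median"],
                         "null_aurocs": null["null_aurocs"]})
        else:
            raise ValueError(f"unknown scheme {config.scheme!r}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        marker.unlink()
    except Exception:
        logger.exception("pipeline failed; outputs flagged incomplete")
        raise
    return out
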