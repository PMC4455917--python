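"""Cohort expression matrices: loading, probe collapse, replicate averaging,
and within-cohort median-referenced differential expression.

Input matrices are assumed already normalized and on the log2 scale; a
``log2_transform`` flag applies log2(x+1) for raw-scale inputs.  Each
cohort (one batch / one platform) is handled independently: differential
expression is always computed against that cohort's own per-gene median,
which is what makes scores comparable across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionCohort",
    "DifferentialMatrix",
    "read_matrix",
    "read_annotations",
    "read_probe_map",
    "collapse_probes",
    "average_technical_replicates",
    "median_center",
]

VALID_LABELS = {"R", "NR", "unknown"}


@dataclass
class ExpressionCohort:
    """One batch: gene x sample log2 expression plus sample annotations.

    ``matrix`` is a DataFrame with gene (or probe, pre-collapse) ids as the
    index and sample ids as columns.  ``samples`` is a DataFrame indexed by
    sample id; recognised columns are ``response`` (R/NR/unknown),
    ``subject``, ``das28_baseline``, ``das28_followup``, ``treatment``.
    """

    cohort_id: str
    matrix: pd.DataFrame
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.matrix.columns.duplicated().any():
            dup = self.matrix.columns[self.matrix.columns.duplicated()].tolist()
            raise ValueError(f"cohort {self.cohort_id}: duplicate sample ids {dup}")
        if self.samples.empty:
            self.samples = pd.DataFrame(index=self.matrix.columns)
        if "response" in self.samples.columns:
            bad = set(self.samples["response"].dropna()) - VALID_LABELS
            if bad:
                raise ValueError(
                    f"cohort {self.cohort_id}: invalid response labels {sorted(bad)}"
                )

    @property
    def gene_universe(self) -> set[str]:
        return set(self.matrix.index)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def labels(self) -> pd.Series:
        """Response labels aligned to matrix columns (NaN -> 'unknown')."""
        if "response" not in self.samples.columns:
            return pd.Series("unknown", index=self.matrix.columns)
        return (
            self.samples["response"].reindex(self.matrix.columns).fillna("unknown")
        )


@dataclass
class DifferentialMatrix:
    """Gene x sample log2 differences against the within-cohort gene median."""

    cohort_id: str
    matrix: pd.DataFrame

    @property
    def gene_universe(self) -> set[str]:
        return set(self.matrix.index)


def read_matrix(
    path: str | Path,
    cohort_id: str,
    samples: pd.DataFrame | None = None,
    log2_transform: bool = False,
) -> ExpressionCohort:
    """Read a genes-x-samples TSV (first column row ids, header sample ids).

    Duplicate row ids are permitted at this stage (probe-level input);
    duplicate sample ids or non-numeric cells raise.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header_tabs = None
        data_tabs = None
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            k = line.rstrip("\n").count("\t")
            if header_tabs is None:
                header_tabs = k
                ids = line.rstrip("\n").split("\t")
                if len(ids) != len(set(ids)):
                    raise ValueError(f"{path}: duplicate sample ids in header")
            elif data_tabs is None:
                # header may or may not carry a label for the id column
                if k not in (header_tabs, header_tabs + 1):
                    raise ValueError(f"{path}: ragged row at line {lineno}")
                data_tabs = k
            elif k != data_tabs:
                raise ValueError(f"{path}: ragged row at line {lineno}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in header")
    try:
        mat = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        # locate the first offending cell for the error message
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.argmax()]
                raise ValueError(
                    f"{path}: non-numeric value {df.loc[row, col]!r} at "
                    f"row {row!r}, column {col!r}"
                ) from exc
        raise
    mat = mat.astype(float)
    if log2_transform:
        mat = np.log2(mat + 1.0)
    if samples is not None:
        samples = samples.reindex(mat.columns)
    return ExpressionCohort(cohort_id, mat, samples if samples is not None else pd.DataFrame())


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the sample-annotation TSV.

    Columns: ``sample``, then any of ``subject``, ``cohort``, ``response``,
    ``das28_baseline``, ``das28_followup``; empty fields allowed.
    """
    ann = pd.read_csv(path, sep="\t", dtype=str).set_index("sample")
    for col in ("das28_baseline", "das28_followup"):
        if col in ann.columns:
            ann[col] = pd.to_numeric(ann[col], errors="coerce")
    return ann


def read_probe_map(path: str | Path) -> dict[str, list[str]]:
    """Read a probe-map TSV: ``probe<TAB>gene1,gene2,...`` (no header).

    An empty second field (or a missing one) marks an unmapped probe.
    """
    mapping: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) not in (1, 2):
            raise ValueError(f"{path}: expected 2 columns at line {lineno}")
        probe = fields[0]
        genes = fields[1].split(",") if len(fields) == 2 and fields[1] else []
        mapping[probe] = [g for g in genes if g]
    return mapping


def collapse_probes(
    cohort: ExpressionCohort, probe_map: dict[str, list[str]]
) -> ExpressionCohort:
    """Collapse probe rows to gene rows.

    Probes mapping to more than one gene are omitted entirely; unmapped
    probes are dropped; where several probes map to one gene, the gene row
    is their arithmetic mean.
    """
    rows: dict[str, list[np.ndarray]] = {}
    mat = cohort.matrix
    for probe in mat.index:
        genes = probe_map.get(probe, [])
        if len(genes) != 1:
            continue  # multi-gene probes excluded; unmapped dropped
        rows.setdefault(genes[0], []).append(mat.loc[probe].to_numpy(dtype=float))
    if not rows:
        raise ValueError(f"cohort {cohort.cohort_id}: no probe maps to a single gene")
    collapsed = pd.DataFrame(
        {g: np.mean(np.vstack(v), axis=0) for g, v in rows.items()},
        index=mat.columns,
    ).T
    # genes left with missing values cannot be median-referenced; drop them
    incomplete = collapsed.index[collapsed.isna().any(axis=1)]
    if len(incomplete):
        logger.warning(
            "cohort %s: dropping %d genes with missing values after collapse",
            cohort.cohort_id, len(incomplete),
        )
        collapsed = collapsed.drop(index=incomplete)
    return ExpressionCohort(cohort.cohort_id, collapsed, cohort.samples)


def average_technical_replicates(
    cohort: ExpressionCohort,
    replicate_groups: dict[str, str],
    exclude: list[str] | None = None,
) -> ExpressionCohort:
    """Drop excluded samples, then average replicates of the same subject.

    ``replicate_groups`` maps sample id -> subject id and must cover every
    retained sample.  Output columns are subject ids, in first-appearance
    order.  Replicates with conflicting response labels raise.
    """
    exclude = set(exclude or [])
    mat = cohort.matrix.drop(columns=[c for c in cohort.matrix.columns if c in exclude])
    missing = [c for c in mat.columns if c not in replicate_groups]
    if missing:
        raise ValueError(f"samples without a replicate group: {missing}")
    subjects: dict[str, list[str]] = {}
    for s in mat.columns:
        subjects.setdefault(replicate_groups[s], []).append(s)

    labels = cohort.labels()
    new_cols = {}
    new_ann_rows = {}
    for subj, members in subjects.items():
        grp_labels = {labels[m] for m in members if labels[m] != "unknown"}
        if len(grp_labels) > 1:
            raise ValueError(
                f"subject {subj}: conflicting response labels {sorted(grp_labels)}"
            )
        new_cols[subj] = mat[members].mean(axis=1)
        if not cohort.samples.empty:
            row = cohort.samples.loc[members[0]].copy()
            if grp_labels and "response" in cohort.samples.columns:
                row["response"] = next(iter(grp_labels))
            new_ann_rows[subj] = row
    new_mat = pd.DataFrame(new_cols, index=mat.index)
    new_ann = (
        pd.DataFrame(new_ann_rows).T if new_ann_rows else pd.DataFrame(index=new_mat.columns)
    )
    return ExpressionCohort(cohort.cohort_id, new_mat, new_ann)


def median_center(cohort: ExpressionCohort) -> DifferentialMatrix:
    """Differential expression against the within-cohort per-gene median.

    ``d[g, j] = x[g, j] - median_j' x[g, j']`` with the standard midpoint
    median for even sample counts.  Rows with missing values raise
    (collapse probes first).
    """
    mat = cohort.matrix
    if mat.shape[1] < 1:
        raise ValueError("median_center needs at least one sample")
    if mat.isna().any().any():
        bad = mat.index[mat.isna().any(axis=1)].tolist()[:5]
        raise ValueError(
            f"cohort {cohort.cohort_id}: missing values in gene rows {bad}; "
            "collapse probes / drop incomplete genes first"
        )
    centered = mat.sub(mat.median(axis=1), axis=0)
    return DifferentialMatrix(cohort.cohort_id, centered)
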