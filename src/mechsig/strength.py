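"""Strength scoring: mechanism activity from signed differential expression.

The strength of mechanism *m* in sample *j* is the sign-weighted mean of
the log2 differential expression of the mechanism's genes,

    Strength(m, j) = (1 / |G'_m|) * sum_{g in G'_m} s_g * d[g, j],

where ``G'_m`` is the subset of the mechanism's genes measured in the
cohort and ``s_g`` is the direction of regulation (+1/-1).  Because each
platform measures a different gene subset, the denominator is the number
of genes actually used in this cohort, and mechanisms supported by fewer
than ``min_genes`` measured genes are omitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mechsig.genesets import MechanismCollection
from mechsig.ingest import DifferentialMatrix

logger = logging.getLogger(__name__)

__all__ = ["StrengthMatrix", "strength_scores"]


@dataclass
class StrengthMatrix:
    """Mechanism x sample strength scores for one cohort.

    ``support`` maps mechanism name -> number of genes used in this
    cohort; every retained mechanism satisfies the coverage floor.
    """

    cohort_id: str
    matrix: pd.DataFrame
    support: dict[str, int]

    @property
    def mechanisms(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def to_tsv(self, path, support_path=None) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="mechanism")
        if support_path is not None:
            pd.Series(self.support, name="n_genes").rename_axis("mechanism").to_csv(
                support_path, sep="\t"
            )


def strength_scores(
    diff: DifferentialMatrix,
    coll: MechanismCollection,
    min_genes: int = 4,
) -> StrengthMatrix:
    """Compute strength scores for every adequately covered mechanism.

    Parameters
    ----------
    diff : DifferentialMatrix
        Complete (no missing values) median-referenced log2 matrix.
    coll : MechanismCollection
        Signed gene sets.
    min_genes : int
        Minimum number of member genes that must be measured in the
        cohort for a mechanism to be scored (default 4).

    Raises
    ------
    ValueError
        If the collection is empty or no mechanism meets the coverage
        floor.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    if len(coll) == 0:
        raise ValueError("empty mechanism collection")
    mat = diff.matrix
    if mat.isna().any().any():
        raise ValueError("differential matrix contains missing values")
    gene_index = {g: i for i, g in enumerate(mat.index)}
    values = mat.to_numpy(dtype=float)

    rows = []
    names = []
    support: dict[str, int] = {}
    skipped = []
    for s in coll:
        idx = []
        signs = []
        for g, sign in s.members.items():
            i = gene_index.get(g)
            if i is not None:
                idx.append(i)
                signs.append(sign)
        if len(idx) < min_genes:
            skipped.append(s.name)
            continue
        w = np.asarray(signs, dtype=float)
        rows.append(w @ values[idx, :] / len(idx))
        names.append(s.name)
        support[s.name] = len(idx)
    if skipped:
        logger.info(
            "cohort %s: %d mechanisms below %d-gene coverage omitted",
            diff.cohort_id, len(skipped), min_genes,
        )
    if not names:
        raise ValueError(
            f"cohort {diff.cohort_id}: no mechanism has >= {min_genes} measured genes"
        )
    return StrengthMatrix(
        diff.cohort_id,
        pd.DataFrame(np.vstack(rows), index=names, columns=mat.columns),
        support,
    )
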