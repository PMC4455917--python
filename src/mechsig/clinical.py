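"""Clinical response calling from DAS28 and the measurement-noise ceiling.

DAS28 is the 28-joint disease activity score for rheumatoid arthritis;
improvement is dDAS28 = baseline - followup (positive = better).  The
EULAR response grid classifies response as good / moderate / none from
the improvement and the attained DAS28:

    good      dDAS28 > 1.2 and followup <= 3.2
    moderate  (dDAS28 > 1.2 and followup > 3.2) or
              (0.6 < dDAS28 <= 1.2 and followup <= 5.1)
    none      otherwise

DAS28 has a known measurement standard deviation of about 0.6.  Even a
classifier that knew each patient's true improvement exactly could not
perfectly predict response calls made from noisy DAS28 measurements;
:func:`das28_noise_ceiling` simulates that ceiling by perturbing the
measurements, re-deriving labels, and scoring patients by their original
improvement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from mechsig.metrics import auroc

logger = logging.getLogger(__name__)

__all__ = [
    "DAS28Record",
    "ResponseLabel",
    "eular_category",
    "response_label",
    "das28_noise_ceiling",
    "CRITERIA",
]

CRITERIA = ("eular_moderate_good", "eular_good_only", "delta_1.2")


@dataclass(frozen=True)
class DAS28Record:
    """Baseline and follow-up DAS28 for one subject."""

    subject: str
    baseline: float
    followup: float

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.followup < 0:
            raise ValueError(f"subject {self.subject}: DAS28 scores must be >= 0")
        if not (math.isfinite(self.baseline) and math.isfinite(self.followup)):
            raise ValueError(f"subject {self.subject}: DAS28 scores must be finite")

    @property
    def delta(self) -> float:
        """Improvement: baseline minus follow-up (positive = better)."""
        return self.baseline - self.followup


@dataclass(frozen=True)
class ResponseLabel:
    subject: str
    label: str  # "R" | "NR" | "unknown"
    criterion: str


def eular_category(baseline: float, followup: float) -> str:
    """EULAR response category (good / moderate / none) from DAS28 scores."""
    if baseline < 0 or followup < 0:
        raise ValueError("DAS28 scores must be >= 0")
    delta = baseline - followup
    if delta > 1.2:
        return "good" if followup <= 3.2 else "moderate"
    if delta > 0.6 and followup <= 5.1:
        return "moderate"
    return "none"


def response_label(
    rec: DAS28Record, criterion: str, delta_strict: bool = True
) -> ResponseLabel:
    """Dichotomize a DAS28 record into responder / non-responder.

    Criteria:

    - ``eular_moderate_good``: NR iff the EULAR category is none
      (moderate and good both count as response).
    - ``eular_good_only``: R iff good, NR iff none; moderate patients get
      label ``unknown`` (excluded from analysis).
    - ``delta_1.2``: improvement threshold only.  With ``delta_strict``
      (default) NR iff dDAS28 < 1.2; some cohorts use the inclusive
      convention NR iff dDAS28 <= 1.2 (``delta_strict=False``).
    """
    if criterion == "eular_moderate_good":
        cat = eular_category(rec.baseline, rec.followup)
        label = "NR" if cat == "none" else "R"
    elif criterion == "eular_good_only":
        cat = eular_category(rec.baseline, rec.followup)
        label = {"good": "R", "none": "NR", "moderate": "unknown"}[cat]
    elif criterion == "delta_1.2":
        if delta_strict:
            label = "NR" if rec.delta < 1.2 else "R"
        else:
            label = "NR" if rec.delta <= 1.2 else "R"
    else:
        raise ValueError(f"unknown response criterion {criterion!r}")
    return ResponseLabel(rec.subject, label, criterion)


def das28_noise_ceiling(
    records: list[DAS28Record],
    sd: float = 0.6,
    reps: int = 1000,
    criterion: str = "eular_moderate_good",
    seed: int | None = None,
    delta_strict: bool = True,
) -> tuple[float, np.ndarray]:
    """Median AUROC ceiling implied by DAS28 measurement noise.

    Per repetition, independent Gaussian noise (mean 0, ``sd``) is added
    to every baseline and follow-up measurement, noisy response labels
    are re-derived under ``criterion``, and each subject is scored by its
    ORIGINAL improvement (negated, so larger score = more NR-like) — a
    perfect classifier for the underlying true disease activity.  The
    AUROC of that classifier against the noisy labels is recorded;
    repetitions yielding a single label class are skipped and logged.

    Returns ``(median_auroc, per_rep_aurocs)``.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if not records:
        raise ValueError("no DAS28 records")
    rng = np.random.default_rng(seed)
    baseline = np.array([r.baseline for r in records])
    followup = np.array([r.followup for r in records])
    score = -(baseline - followup)  # larger = less improvement = NR-like

    aurocs = []
    skipped = 0
    for _ in range(reps):
        nb = np.clip(baseline + rng.normal(0.0, sd, baseline.size), 0.0, None)
        nf = np.clip(followup + rng.normal(0.0, sd, followup.size), 0.0, None)
        labels = np.array([
            response_label(DAS28Record(r.subject, b, f), criterion, delta_strict).label
            for r, b, f in zip(records, nb, nf)
        ])
        is_nr = labels == "NR"
        is_r = labels == "R"
        if not is_nr.any() or not is_r.any():
            skipped += 1
            continue
        aurocs.append(auroc(score[is_nr], score[is_r]))
    if skipped:
        logger.info("das28_noise_ceiling: %d/%d reps single-class, skipped", skipped, reps)
    if not aurocs:
        raise ValueError("every repetition produced a single label class")
    arr = np.asarray(aurocs)
    return float(np.median(arr)), arr
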