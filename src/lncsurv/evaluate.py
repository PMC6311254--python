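"""Evaluation: ROC/AUC for survival prediction and leave-one-out
cross-validation of lncRNA–disease association ranking.

AUC is the area under the ROC curve by the trapezoid rule over all distinct
score thresholds, which equals the Mann–Whitney probability that a random
positive outscores a random negative (ties counting one half).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .errors import EvaluationError
from .survival import survival_coefficients

__all__ = [
    "RocCurve",
    "AssociationDataset",
    "roc_auc",
    "survival_roc",
    "loocv_association",
]

logger = logging.getLogger(__name__)

#: fixed evaluation horizon: five years, in days
FIVE_YEARS_DAYS = 1825

Pair = tuple[Hashable, Hashable]


@dataclass
class RocCurve:
    """ROC points (descending thresholds) and the trapezoid AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class AssociationDataset:
    """Known (lncRNA, disease) pairs and the candidate universe per disease."""

    pairs: tuple[Pair, ...]
    universe: tuple[Hashable, ...]  # candidate lncRNA identifiers
    diseases: tuple[Hashable, ...]

    def __post_init__(self):
        if len(set(self.pairs)) != len(self.pairs):
            raise EvaluationError("duplicate association pairs")
        bad = [p for p in self.pairs if p[0] not in self.universe or p[1] not in self.diseases]
        if bad:
            raise EvaluationError(f"pairs outside universe x diseases: {bad[:5]}")

    def all_pairs(self) -> list[Pair]:
        return [(l, d) for d in self.diseases for l in self.universe]


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """ROC curve and trapezoid AUC of real-valued scores against 0/1 labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise EvaluationError("ROC needs at least one positive and one negative label")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


def survival_roc(
    results,
    led: pd.DataFrame,
    clinical: pd.DataFrame,
    horizon: int = FIVE_YEARS_DAYS,
) -> RocCurve:
    """ROC of predicted survival against the event-within-horizon label.

    A patient labels positive when death occurred within ``horizon`` days
    and negative when observed event-free beyond it.  Patients alive with
    follow-up not exceeding the horizon are indeterminate — the fixed-
    horizon binary label is undefined for them — and are excluded.  The
    score is the negated predicted survival time (shorter predicted
    survival ranks as higher risk).
    """
    if horizon <= 0:
        raise EvaluationError(f"horizon must be positive, got {horizon}")
    pred = results.predict(led)
    records = clinical.set_index("submitter_id")
    scores, labels = [], []
    n_excluded = 0
    for sid in led.index:
        rec = records.loc[sid]
        alpha, _ = survival_coefficients(rec["vital_status"])
        dd = pd.to_numeric(rec["days_to_death"], errors="coerce")
        dl = pd.to_numeric(rec["days_to_last_follow_up"], errors="coerce")
        if alpha == 1:  # dead: event time known either way
            label = 1 if float(dd) <= horizon else 0
        else:  # alive: event-free only demonstrable beyond the horizon
            if pd.isna(dl) or float(dl) <= horizon:
                n_excluded += 1
                continue
            label = 0
        scores.append(-float(pred.loc[sid]))
        labels.append(label)
    if n_excluded:
        logger.info("survival ROC: %d indeterminate censored patients excluded", n_excluded)
    if not scores:
        raise EvaluationError("no determinate patients at this horizon")
    return roc_auc(scores, labels)


def loocv_association(
    dataset: AssociationDataset,
    scorer: Callable[[Sequence[Pair]], Mapping[Pair, float]],
) -> RocCurve:
    """Leave-one-out cross-validation over known association pairs.

    Each known pair is withheld in turn; ``scorer`` is trained on the
    remaining known pairs and must return a score for every candidate
    pair.  The withheld pair contributes a positive observation and every
    never-known pair a negative one; pooled scores give the ROC/AUC.
    """
    known = list(dataset.pairs)
    if len(known) < 2:
        raise EvaluationError("LOOCV needs at least 2 known pairs")
    known_set = set(known)
    negatives = [p for p in dataset.all_pairs() if p not in known_set]

    scores, labels = [], []
    for i, held_out in enumerate(known):
        train = known[:i] + known[i + 1 :]
        try:
            fold_scores = scorer(train)
        except Exception as exc:  # noqa: BLE001 - fold identity matters to the caller
            raise EvaluationError(f"scorer failed on fold {i} (held out {held_out})") from exc
        scores.append(float(fold_scores[held_out]))
        labels.append(1)
        for p in negatives:
            scores.append(float(fold_scores[p]))
            labels.append(0)
    return roc_auc(scores, labels)
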