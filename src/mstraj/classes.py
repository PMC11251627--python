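"""Disease-course severity labelling and beta1-threshold evaluation.

Clinical consensus criteria define the extremes of the MS severity
spectrum: a *mild* (benign) course keeps EDSS at or below 3.0 after at
least ten years of disease, while an *aggressive* course reaches EDSS
6.0 or more within the first ten years.  Patients followed for ten
years who meet neither criterion form the *average* group; patients
with shorter follow-up who never reached 6.0 are ineligible (neither
criterion is decidable yet).

Because beta1 orders patients by progression speed, the three groups
occupy (noisily) increasing beta1 ranges; fitting two cut points on
beta1 turns a beta1 *regressor* into a course *classifier*, which is
how predicted trajectories are evaluated against the consensus labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import accuracy_score, precision_score, recall_score, roc_auc_score

from .cohort import DomainError, EDSSSeries
from .descriptors import DAYS_PER_YEAR, TrajectoryDescriptors

TEN_YEARS_DAYS = 10 * DAYS_PER_YEAR
AGGRESSIVE_EDSS = 6.0
MILD_EDSS = 3.0

MILD, AVERAGE, AGGRESSIVE, INELIGIBLE = "mild", "average", "aggressive", "ineligible"


@dataclass(frozen=True)
class CourseLabel:
    label: str  # mild | average | aggressive | ineligible
    basis: str  # which criterion fired


@dataclass(frozen=True)
class Beta1Thresholds:
    lower: float  # mild / average boundary
    upper: float  # average / aggressive boundary

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise DomainError(f"thresholds out of order: {self.lower} > {self.upper}")

    def classify(self, b1: float) -> str:
        if b1 > self.upper:
            return AGGRESSIVE
        if b1 > self.lower:
            return AVERAGE
        return MILD


def criteria_label(series: EDSSSeries,
                   descriptors: TrajectoryDescriptors | None = None) -> CourseLabel:
    """Apply the consensus severity criteria to one trajectory.

    Aggressive wins over mild when both could apply (reaching 6.0 within
    ten years is decisive regardless of later course).  Disease onset is
    proxied by the first assessment.
    """
    reached_6_early = any(
        s >= AGGRESSIVE_EDSS for d, s in zip(series.days, series.scores)
        if d <= TEN_YEARS_DAYS
    )
    if reached_6_early:
        return CourseLabel(AGGRESSIVE, f"EDSS >= {AGGRESSIVE_EDSS} within 10 years")
    follow_up = series.days[-1] - series.days[0]
    if follow_up < TEN_YEARS_DAYS:
        return CourseLabel(INELIGIBLE, "follow-up < 10 years, never >= 6.0")
    at_10y = None
    if descriptors is not None:
        at_10y = descriptors.edss_t.get(10)
    if at_10y is None:
        # fall back on the last assessment (necessarily at >= 10 years here)
        at_10y = series.scores[-1]
    if at_10y <= MILD_EDSS:
        return CourseLabel(MILD, f"EDSS <= {MILD_EDSS} at >= 10 years")
    return CourseLabel(AVERAGE, "neither extreme criterion met at 10 years")


def _best_split(values: np.ndarray, is_upper_group: np.ndarray) -> float:
    """Exhaustive 1-D split minimizing misclassifications; ties -> smaller
    threshold.  ``is_upper_group`` marks samples that should land above."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    up = is_upper_group[order]
    candidates = [v[0] - 1.0] + [0.5 * (a + b) for a, b in zip(v, v[1:])] + [v[-1] + 1.0]
    best_t, best_err = None, None
    for t in candidates:
        err = int(np.sum((v > t) != up))
        if best_err is None or err < best_err or (err == best_err and t < best_t):
            best_t, best_err = t, err
    return float(best_t)


def fit_beta1_thresholds(beta1_values: Sequence[float],
                         labels: Sequence[str]) -> Beta1Thresholds:
    """Fit the two beta1 cut points separating mild / average / aggressive.

    Cleanly separated groups get the midpoint between adjacent group
    extremes; overlapping groups get the exhaustive 1-D split with the
    fewest training misclassifications (ties resolve to the smaller
    threshold).  The average group may be absent; mild and aggressive
    must both be represented.
    """
    b = np.asarray(beta1_values, dtype=float)
    lab = np.asarray(labels)
    mild = b[lab == MILD]
    avg = b[lab == AVERAGE]
    agg = b[lab == AGGRESSIVE]
    if mild.size == 0 or agg.size == 0:
        raise DomainError("need at least one mild and one aggressive patient")

    not_mild = np.concatenate([avg, agg])
    if mild.max() < not_mild.min():
        lower = 0.5 * (mild.max() + not_mild.min())
    else:
        keep = np.concatenate([mild, not_mild])
        upper_mask = np.concatenate([np.zeros(mild.size, bool), np.ones(not_mild.size, bool)])
        lower = _best_split(keep, upper_mask)

    not_agg = np.concatenate([mild, avg])
    if not_agg.max() < agg.min():
        upper = 0.5 * (not_agg.max() + agg.min())
    else:
        keep = np.concatenate([not_agg, agg])
        upper_mask = np.concatenate([np.zeros(not_agg.size, bool), np.ones(agg.size, bool)])
        upper = _best_split(keep, upper_mask)

    upper = max(upper, lower)
    return Beta1Thresholds(lower=lower, upper=upper)


def evaluate_binary_course(pred_beta1: Sequence[float],
                           true_labels: Sequence[str],
                           thresholds: Beta1Thresholds) -> dict[str, float]:
    """Score predicted beta1 against consensus labels as a binary task.

    Aggressive is the positive class; mild and average pool as negative.
    The continuous predicted beta1 serves as the AUC ranking score; the
    fitted upper threshold produces the hard predictions behind
    sensitivity, accuracy and precision.  Only patients with a decided
    label should be passed in.  With single-class truth the AUC is
    undefined and reported as NaN.
    """
    pred = np.asarray(pred_beta1, dtype=float)
    lab = np.asarray(true_labels)
    if np.any(lab == INELIGIBLE):
        raise DomainError("ineligible patients must be excluded before evaluation")
    y_true = (lab == AGGRESSIVE).astype(int)
    y_pred = (pred > thresholds.upper).astype(int)
    if len(np.unique(y_true)) < 2:
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y_true, pred))
    return {
        "auc_roc": auc,
        "sensitivity": float(recall_score(y_true, y_pred, zero_division=0)),
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
    }
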