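"""Precision-recall analysis and per-classifier decision thresholds.

A fixed cutoff of 0.5 on a one-vs-rest classifier's target score can be
sub-optimal, so each of the four classifiers gets its own decision
threshold chosen on validation tiles: every distinct score value is tried
as a cutoff (predict positive iff score >= cutoff) and the cutoff
maximizing F1 = 2PR/(P+R) is selected, with ties broken toward higher
recall and then toward the lower threshold.

The area under the PR curve uses step-wise (right-continuous)
interpolation — the average-precision rule — which avoids the optimism of
linear interpolation in PR space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PRCurve", "ThresholdSet", "pr_curve", "select_threshold",
           "ThresholdSelector", "f1_at_threshold"]


@dataclass
class PRCurve:
    """PR points ordered by strictly increasing threshold. Recall is
    non-increasing along the curve; ``auprc`` is the step-interpolated
    area."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auprc: float

    @property
    def f1(self) -> np.ndarray:
        p, r = self.precision, self.recall
        denom = p + r
        return np.divide(2 * p * r, denom, out=np.zeros_like(p),
                         where=denom > 0)


@dataclass
class ThresholdSet:
    """One decision threshold per subtype classifier."""

    tau: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for cls, t in self.tau.items():
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"threshold for {cls!r} outside [0, 1]")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.tau, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdSet":
        return cls(tau=json.loads(Path(path).read_text()))


def pr_curve(scores, labels) -> PRCurve:
    """Precision and recall at every distinct score used as a cutoff.

    ``labels`` are binary (1 = target). Both classes must be present.
    Invariant to the ordering of the inputs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    pos = int(labels.sum())
    if pos == 0 or pos == len(labels):
        raise ValueError("both classes must be present for a PR curve")

    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    # Positives/predictions with score >= cutoff, cutoffs = distinct scores
    # ascending: suffix sums.
    suffix_tp = np.cumsum(l_sorted[::-1])[::-1]
    n = len(scores)
    distinct_idx = np.flatnonzero(np.r_[True, np.diff(s_sorted) > 0])
    thresholds = s_sorted[distinct_idx]
    tp = suffix_tp[distinct_idx].astype(float)
    pred_pos = (n - distinct_idx).astype(float)
    precision = tp / pred_pos
    recall = tp / pos

    # Step-wise AUPRC: sum of precision * recall drop, scanning from the
    # lowest cutoff (recall 1) upward, plus the segment down to recall 0.
    rec_ext = np.r_[recall, 0.0]
    auprc = float(np.sum(precision * (rec_ext[:-1] - rec_ext[1:])))
    return PRCurve(thresholds, precision, recall, auprc)


def select_threshold(curve: PRCurve) -> float:
    """The cutoff maximizing F1; ties go to higher recall, then to the
    lower threshold. Raises if every cutoff has F1 = 0."""
    f1 = curve.f1
    if len(f1) == 0:
        raise ValueError("empty PR curve")
    if np.max(f1) <= 0:
        raise ValueError("no informative threshold: all F1 values are zero")
    # Lexicographic argmax over (f1, recall, -threshold).
    best = max(range(len(f1)),
               key=lambda i: (f1[i], curve.recall[i], -curve.thresholds[i]))
    return float(curve.thresholds[best])


def f1_at_threshold(scores, labels, tau: float) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= tau
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    if tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return 2 * p * r / (p + r)


class ThresholdSelector:
    """Estimator-style wrapper: ``fit(scores, labels)`` computes the PR
    curve and the F1-optimal cutoff (``curve_``, ``threshold_``)."""

    def get_params(self, deep=True):
        return {}

    def set_params(self, **params):
        return self

    def fit(self, scores, labels):
        self.curve_ = pr_curve(scores, labels)
        self.threshold_ = select_threshold(self.curve_)
        return self

    def predict(self, scores):
        if not hasattr(self, "threshold_"):
            raise RuntimeError("ThresholdSelector is not fitted")
        return (np.asarray(scores, dtype=float) >= self.threshold_).astype(int)
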