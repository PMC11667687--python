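"""Slide-level evaluation.

Per-class metrics are one-vs-rest reductions of the K-class confusion
matrix: precision = TP/(TP+FP), recall (sensitivity) = TP/(TP+FN),
specificity = TN/(TN+FP), F1 = 2PR/(P+R). Macro averages are unweighted
means across classes — with imbalanced cohorts the macro recall is the
"macro-average accuracy". Confidence intervals are nonparametric
percentile bootstrap over WSIs (the independent units), default B = 1000;
resamples missing a class are redrawn up to a cap and then skipped with a
reported count. PR analysis at the slide level is deliberately preferred
over ROC for imbalanced cohorts.

Displayed metrics are conventionally rounded to 3 decimals; all internal
values keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .thresholds import pr_curve

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "class_metrics",
    "macro_average",
    "bootstrap_ci",
    "collapse_binary",
    "auprc_per_class",
    "metric_report",
    "plot_confusion",
    "plot_pr_curves",
]

METRIC_NAMES = ("f1", "precision", "recall", "specificity")


@dataclass
class ConfusionMatrix:
    """K x K tally; rows are truth, columns are prediction."""

    labels: list[str]
    cells: np.ndarray

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=int)
        k = len(self.labels)
        if self.cells.shape != (k, k):
            raise ValueError("cells must be K x K for K labels")
        if np.any(self.cells < 0):
            raise ValueError("cells must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.labels,
                            columns=self.labels)


def confusion(preds, truths, class_order) -> ConfusionMatrix:
    preds = np.asarray(preds).astype(str)
    truths = np.asarray(truths).astype(str)
    if preds.shape != truths.shape:
        raise ValueError("preds and truths must have equal length")
    known = set(class_order)
    unknown = (set(preds) | set(truths)) - known
    if unknown:
        raise ValueError(f"labels outside class_order: {sorted(unknown)}")
    cells = _sk_confusion(truths, preds, labels=list(class_order)) \
        if len(preds) else np.zeros((len(class_order), len(class_order)), int)
    return ConfusionMatrix(list(class_order), cells)


def class_metrics(cm: ConfusionMatrix, cls: str) -> dict[str, float]:
    """One-vs-rest metrics for one class; zero-denominator metrics return
    0.0 and are listed under the ``zero_division`` flag."""
    if cls not in cm.labels:
        raise ValueError(f"{cls!r} not among confusion labels")
    i = cm.labels.index(cls)
    c = cm.cells
    tp = int(c[i, i])
    fp = int(c[:, i].sum() - tp)
    fn = int(c[i, :].sum() - tp)
    tn = int(c.sum() - tp - fp - fn)
    flags = []

    def safe(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    precision = safe(tp, tp + fp, "precision")
    recall = safe(tp, tp + fn, "recall")
    specificity = safe(tn, tn + fp, "specificity")
    f1 = safe(2 * precision * recall, precision + recall, "f1")
    return {"f1": f1, "precision": precision, "recall": recall,
            "specificity": specificity, "zero_division": flags}


def macro_average(per_class: dict[str, dict[str, float]]) -> dict[str, float]:
    """Unweighted mean of each metric across classes."""
    if not per_class:
        raise ValueError("need at least one class")
    out = {}
    for m in METRIC_NAMES:
        out[m] = float(np.mean([v[m] for v in per_class.values()]))
    return out


def bootstrap_ci(metric_fn, preds, truths, B: int = 1000,
                 level: float = 0.95, seed: int = 0,
                 max_redraw_factor: int = 10):
    """Percentile bootstrap interval(s) for a metric of (preds, truths).

    ``metric_fn(preds, truths)`` may return a scalar or a dict of scalars.
    WSIs are resampled with replacement; a resample on which the metric is
    undefined (raises, or returns NaN) is redrawn up to
    ``max_redraw_factor * B`` total draws, after which it is skipped.
    Returns ``(lo, hi, n_skipped)`` — with dict metrics, ``lo``/``hi`` are
    dicts. Errors out if more than half the resamples are undefined.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    preds = np.asarray(preds)
    truths = np.asarray(truths)
    n = len(preds)
    rng = np.random.default_rng(seed)
    samples = []
    draws = 0
    skipped = 0
    while len(samples) < B and draws < max_redraw_factor * B:
        idx = rng.integers(0, n, n)
        draws += 1
        try:
            val = metric_fn(preds[idx], truths[idx])
        except (ValueError, ZeroDivisionError):
            skipped += 1
            continue
        if np.isscalar(val) and not np.isfinite(val):
            skipped += 1
            continue
        samples.append(val)
    if len(samples) < B / 2:
        raise ValueError(f"metric undefined on {skipped} of {draws} "
                         "bootstrap resamples (> 50%)")
    q = [(1 - level) / 2 * 100, (1 + level) / 2 * 100]
    if isinstance(samples[0], dict):
        keys = samples[0].keys()
        lo, hi = {}, {}
        for k in keys:
            arr = np.array([s[k] for s in samples])
            lo[k], hi[k] = np.percentile(arr, q)
        return lo, hi, skipped
    arr = np.asarray(samples, dtype=float)
    lo, hi = np.percentile(arr, q)
    return float(lo), float(hi), skipped


def collapse_binary(cm: ConfusionMatrix, positive_class: str,
                    ) -> dict[str, float]:
    """Collapse a K-class confusion matrix to positive vs rest (e.g.
    Basal-like vs non-Basal) and report accuracy, sensitivity and
    specificity."""
    if positive_class not in cm.labels:
        raise ValueError(f"{positive_class!r} not among confusion labels")
    i = cm.labels.index(positive_class)
    c = cm.cells
    tp = int(c[i, i])
    fn = int(c[i, :].sum() - tp)
    fp = int(c[:, i].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)
    total = tp + fn + fp + tn
    return {
        "accuracy": (tp + tn) / total if total else 0.0,
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
        "specificity": tn / (tn + fp) if tn + fp else 0.0,
    }


def auprc_per_class(probas: np.ndarray, truths, class_order,
                    ) -> dict[str, float]:
    """One-vs-rest area under the PR curve from slide probability rows."""
    truths = np.asarray(truths).astype(str)
    out = {}
    for j, cls in enumerate(class_order):
        labels = (truths == cls).astype(int)
        out[cls] = pr_curve(probas[:, j], labels).auprc
    return out


def metric_report(preds, truths, class_order, probas: np.ndarray | None = None,
                  B: int = 1000, level: float = 0.95, seed: int = 0) -> dict:
    """Full slide-level report: confusion matrix, per-class metrics with
    bootstrap CIs, macro averages, per-class AUPRC (when probabilities are
    given) and the positive-vs-rest collapse for the last class."""
    preds = np.asarray(preds)
    truths = np.asarray(truths)
    evaluable = preds != "abstain"
    n_abstained = int(np.sum(~evaluable))
    preds_e, truths_e = preds[evaluable], truths[evaluable]
    cm = confusion(preds_e, truths_e, class_order)
    per_class = {c: class_metrics(cm, c) for c in class_order}

    classes = list(class_order)

    def per_class_fn(p, t):
        cmx = confusion(p, t, classes)
        if np.any(cmx.cells.sum(axis=1) == 0):
            raise ValueError("class absent from resample")
        out = {}
        for c in classes:
            m = class_metrics(cmx, c)
            for name in METRIC_NAMES:
                out[f"{c}:{name}"] = m[name]
        return out

    lo, hi, skipped = bootstrap_ci(per_class_fn, preds_e, truths_e,
                                   B=B, level=level, seed=seed)
    report = {
        "n_wsis": int(len(preds)),
        "n_abstained": n_abstained,
        "confusion": cm.to_frame().to_dict(),
        "per_class": {}, "macro": macro_average(per_class),
        "bootstrap": {"B": B, "level": level, "skipped_resamples": skipped},
    }
    for c in class_order:
        entry = {}
        for name in METRIC_NAMES:
            entry[name] = {"value": per_class[c][name],
                           "lo": lo[f"{c}:{name}"], "hi": hi[f"{c}:{name}"]}
        report["per_class"][c] = entry
    if probas is not None:
        report["auprc"] = auprc_per_class(np.asarray(probas)[evaluable],
                                          truths_e, class_order)
    report["binary_collapse"] = {
        cls: collapse_binary(cm, cls) for cls in class_order}
    return report


def plot_confusion(cm: ConfusionMatrix, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.imshow(cm.cells, cmap="Blues")
    k = len(cm.labels)
    ax.set_xticks(range(k), cm.labels, rotation=45)
    ax.set_yticks(range(k), cm.labels)
    ax.set_xlabel("Predicted")
    ax.set_ylabel("True")
    for i in range(k):
        for j in range(k):
            ax.text(j, i, str(cm.cells[i, j]), ha="center", va="center")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pr_curves(probas: np.ndarray, truths, class_order, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    truths = np.asarray(truths).astype(str)
    fig, ax = plt.subplots(figsize=(5, 4))
    for j, cls in enumerate(class_order):
        labels = (truths == cls).astype(int)
        if labels.sum() in (0, len(labels)):
            continue
        curve = pr_curve(probas[:, j], labels)
        order = np.argsort(-curve.recall, kind="stable")
        ax.step(curve.recall[order], curve.precision[order], where="post",
                label=f"{cls} (AUPRC {curve.auprc:.2f})")
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
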