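"""Multi-class evaluation: confusion matrix, per-class and aggregate metrics.

Each class c is scored one-vs-rest from the confusion matrix:

    precision   = TP / (TP + FP)
    sensitivity = recall = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * recall / (precision + recall)

all reported in percent, alongside accuracy = trace / total, the macro
(unweighted) and support-weighted averages, a macro-averaged one-vs-rest
Jaccard index TP / (TP + FP + FN), and a macro-averaged one-vs-rest ROC
AUC by trapezoidal integration.  For single-label data the support-
weighted sensitivity equals the overall accuracy; reports assert this
identity.  Zero-denominator rates are defined as 0 with a warning.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ConfusionMatrix:
    """counts[i][j] = number of items with true class i predicted as j."""

    counts: np.ndarray
    class_labels: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K class labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, label) -> tuple:
        """(TP, FP, FN, TN) for one class."""
        i = self.class_labels.index(label)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, fp, fn, tn

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["true\\pred", *self.class_labels])
            for label, row in zip(self.class_labels, self.counts):
                w.writerow([label, *row.tolist()])


def confusion_matrix(y_true, y_pred, labels) -> ConfusionMatrix:
    labels = tuple(labels)
    index = {c: i for i, c in enumerate(labels)}
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside vocabulary: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, labels)


def _rate(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, reporting 0", RuntimeWarning,
                      stacklevel=3)
        return 0.0
    return num / den


@dataclass(frozen=True)
class ClassMetrics:
    precision: float  # percent
    sensitivity: float
    specificity: float
    f1: float
    support: int


def class_metrics(cm: ConfusionMatrix, label) -> ClassMetrics:
    """One-vs-rest rates for one class, in percent."""
    tp, fp, fn, tn = cm.one_vs_rest(label)
    precision = _rate(tp, tp + fp, f"precision[{label}]")
    recall = _rate(tp, tp + fn, f"sensitivity[{label}]")
    specificity = _rate(tn, tn + fp, f"specificity[{label}]")
    f1 = _rate(2 * precision * recall, precision + recall, f"f1[{label}]")
    return ClassMetrics(
        precision=100.0 * precision,
        sensitivity=100.0 * recall,
        specificity=100.0 * specificity,
        f1=100.0 * f1,
        support=tp + fn,
    )


def f1_from_percent(precision_pct: float, sensitivity_pct: float) -> float:
    """Harmonic mean of precision and sensitivity given in percent."""
    if precision_pct + sensitivity_pct == 0:
        return 0.0
    return 2.0 * precision_pct * sensitivity_pct / (precision_pct + sensitivity_pct)


def aggregate(per_class: dict) -> tuple:
    """(macro_row, weighted_row) over a map label -> ClassMetrics."""
    metrics = list(per_class.values())
    supports = np.array([m.support for m in metrics], dtype=np.float64)
    if supports.sum() <= 0:
        raise ValueError("total support must be positive")
    weights = supports / supports.sum()
    fields = ("precision", "sensitivity", "specificity", "f1")
    macro = {f: float(np.mean([getattr(m, f) for m in metrics])) for f in fields}
    weighted = {
        f: float(np.sum(weights * [getattr(m, f) for m in metrics])) for f in fields
    }
    total = int(supports.sum())
    return (
        ClassMetrics(**macro, support=total),
        ClassMetrics(**weighted, support=total),
    )


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy in percent: correctly classified / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def jaccard(y_true, y_pred, labels) -> float:
    """Macro-averaged one-vs-rest Jaccard index, in percent.

    Per class: |intersection| / |union| of the predicted and true item
    sets = TP / (TP + FP + FN).
    """
    cm = confusion_matrix(y_true, y_pred, labels)
    vals = []
    for label in cm.class_labels:
        tp, fp, fn, _ = cm.one_vs_rest(label)
        vals.append(_rate(tp, tp + fp + fn, f"jaccard[{label}]"))
    return 100.0 * float(np.mean(vals))


def _binary_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUC of the sensitivity vs (1 - specificity) curve, trapezoidal."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    pos = positive[order].astype(np.float64)
    n_pos, n_neg = pos.sum(), len(pos) - pos.sum()
    tp = np.cumsum(pos)
    fp = np.cumsum(1.0 - pos)
    # threshold boundaries: keep the last index of each tied score block
    keep = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tp[keep] / n_pos]
    fpr = np.r_[0.0, fp[keep] / n_neg]
    return float(np.trapezoid(tpr, fpr))


def roc_auc(scores: np.ndarray, y_true, labels) -> float:
    """Macro-averaged one-vs-rest ROC AUC, in percent.

    ``scores`` is N x K row-stochastic class probabilities in the order of
    ``labels``.  Classes absent from ``y_true`` (or covering all of it)
    are skipped with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = tuple(labels)
    y = np.asarray([labels.index(t) for t in y_true])
    if scores.shape != (len(y), len(labels)):
        raise ValueError("scores must be N x K for N items and K labels")
    aucs = []
    for k, label in enumerate(labels):
        pos = y == k
        if pos.all() or not pos.any():
            warnings.warn(
                f"class {label!r} has no positive or no negative items; "
                "skipped in AUC", RuntimeWarning, stacklevel=2,
            )
            continue
        aucs.append(_binary_auc(scores[:, k], pos))
    if not aucs:
        raise ValueError("no class with both positives and negatives")
    return 100.0 * float(np.mean(aucs))


@dataclass
class MetricsReport:
    """Per-class and aggregate metrics in the shape of the results tables."""

    per_class: dict
    accuracy: float
    macro_row: ClassMetrics
    weighted_row: ClassMetrics
    jaccard: float
    auc: float | None
    cm: ConfusionMatrix
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # single-label multiclass identity: support-weighted recall == accuracy
        if abs(self.weighted_row.sensitivity - self.accuracy) > 1e-6:
            raise AssertionError(
                "weighted sensitivity must equal accuracy for single-label data"
            )

    def summary(self) -> str:
        lines = [
            f"{'Class':<18}{'Precision (%)':>14}{'Sensitivity (%)':>17}"
            f"{'Specificity (%)':>17}{'F1 Score (%)':>14}{'Support':>9}"
        ]
        def row(name, m: ClassMetrics, ints: bool = True):
            fmt = (lambda v: f"{v:.0f}") if ints else (lambda v: f"{v:.2f}")
            return (f"{name:<18}{fmt(m.precision):>14}{fmt(m.sensitivity):>17}"
                    f"{m.specificity:>17.2f}{fmt(m.f1):>14}{m.support:>9}")
        for label, m in self.per_class.items():
            lines.append(row(str(label), m))
        lines.append(f"{'Accuracy':<18}{'':>14}{'':>17}{'':>17}"
                     f"{self.accuracy:>14.2f}{self.cm.total:>9}")
        lines.append(row("Macro Average", self.macro_row))
        lines.append(row("Weighted Average", self.weighted_row))
        lines.append(f"Jaccard (%): {self.jaccard:.2f}")
        if self.auc is not None:
            lines.append(f"AUC (%): {self.auc:.2f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        def cm_dict(m: ClassMetrics) -> dict:
            return {"precision": m.precision, "sensitivity": m.sensitivity,
                    "specificity": m.specificity, "f1": m.f1, "support": m.support}
        return json.dumps({
            "per_class": {str(k): cm_dict(v) for k, v in self.per_class.items()},
            "accuracy": self.accuracy,
            "macro": cm_dict(self.macro_row),
            "weighted": cm_dict(self.weighted_row),
            "jaccard": self.jaccard,
            "auc": self.auc,
            "confusion_matrix": self.counts_list(),
            "labels": [str(c) for c in self.cm.class_labels],
            "metadata": self.metadata,
        }, indent=2)

    def counts_list(self):
        return self.cm.counts.tolist()

    def write(self, out_dir) -> None:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(self.to_json())
        self.cm.to_csv(out_dir / "confusion_matrix.csv")
        with open(out_dir / "per_class.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["class", "precision_pct", "sensitivity_pct",
                        "specificity_pct", "f1_pct", "support"])
            for label, m in self.per_class.items():
                w.writerow([label, m.precision, m.sensitivity, m.specificity,
                            m.f1, m.support])
        plot_confusion_matrix(self.cm, out_dir / "confusion_matrix.png")


def build_report(y_true, y_pred, labels, scores=None, metadata=None) -> MetricsReport:
    """Assemble the full report from label sequences (and optional scores)."""
    cm = confusion_matrix(y_true, y_pred, labels)
    per_class = {label: class_metrics(cm, label) for label in cm.class_labels}
    macro, weighted = aggregate(per_class)
    auc = roc_auc(scores, y_true, labels) if scores is not None else None
    meta = {"auc_scheme": "one-vs-rest, macro average",
            "jaccard_scheme": "one-vs-rest, macro average"}
    meta.update(metadata or {})
    return MetricsReport(
        per_class=per_class,
        accuracy=accuracy(cm),
        macro_row=macro,
        weighted_row=weighted,
        jaccard=jaccard(y_true, y_pred, labels),
        auc=auc,
        cm=cm,
        metadata=meta,
    )


def evaluate_model(model, stream, batch_size: int = 16, metadata=None) -> MetricsReport:
    """Run a trained model over an evaluation stream and report metrics."""
    labels = tuple(stream.classes)
    y_true, y_pred, scores = [], [], []
    n = 0
    for x, y in stream.batches(batch_size):
        p = model.predict_proba(x)
        scores.append(p)
        y_true.extend(labels[i] for i in y)
        y_pred.extend(labels[i] for i in p.argmax(axis=1))
        n += len(y)
    if n == 0:
        raise ValueError("empty evaluation stream")
    return build_report(y_true, y_pred, labels, np.vstack(scores), metadata)


def plot_confusion_matrix(cm: ConfusionMatrix, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xticks(range(len(cm.class_labels)), cm.class_labels)
    ax.set_yticks(range(len(cm.class_labels)), cm.class_labels)
    ax.set_xlabel("Predicted class")
    ax.set_ylabel("True class")
    for i in range(len(cm.class_labels)):
        for j in range(len(cm.class_labels)):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center",
                    color="black" if cm.counts[i, j] < cm.counts.max() / 2 else "white")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
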