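"""Binary diagnostic evaluation: confusion counts, metrics, ROC and AUC.

The positive class is *septic* throughout (the symmetric RDS-positive
report is a one-call flip of ``positive_class``). Metrics follow the
usual confusion-count definitions:

    accuracy  = (TP + TN) / (TP + FP + FN + TN) * 100   [percent]
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)          (sensitivity)
    f1        = 2 TP / (2 TP + FP + FN)

Zero denominators report 0 with a degenerate flag rather than raising,
so batch experiments survive pathological splits. The ROC curve sweeps
all distinct score thresholds (ties grouped) plus the (0,0) and (1,1)
endpoints; AUC is the trapezoidal area, which equals the
Mann-Whitney/Wilcoxon pairwise ranking probability
P(score+ > score-) + 0.5 P(tie).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion",
    "metrics",
    "roc_curve",
    "auc",
    "evaluate",
    "plot_roc",
    "plot_confusion_heatmap",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        """2x2 array, rows = true (pos, neg), cols = predicted (pos, neg)."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass(frozen=True)
class EvalReport:
    cm: ConfusionMatrix
    accuracy: float  # percent
    precision: float
    recall: float
    f1: float
    roc_points: np.ndarray | None = None
    auc: float | None = None
    degenerate: tuple = ()
    positive_class: str = "septic"

    def as_dict(self) -> dict:
        d = {
            "tp": self.cm.tp, "fp": self.cm.fp, "fn": self.cm.fn, "tn": self.cm.tn,
            "accuracy_pct": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "positive_class": self.positive_class,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def confusion(y_true, y_pred, positive_class: str = "septic") -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


def _ratio(num, den, flag, degenerate):
    if den == 0:
        degenerate.append(flag)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix):
    """(accuracy %, precision, recall, f1, degenerate flags)."""
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    degenerate: list[str] = []
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision", degenerate)
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall", degenerate)
    f1 = _ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f1", degenerate)
    return accuracy, precision, recall, f1, tuple(degenerate)


def roc_curve(y_true, scores, positive_class: str = "septic") -> np.ndarray:
    """ROC points (FPR, TPR) over all distinct thresholds, ties grouped."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos = y_true == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: y_true contains a single class")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = pos[order]
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(~sorted_pos)
    # keep only the last index of each tied-score group
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = tps[distinct] / n_pos
    fpr = fps[distinct] / n_neg
    return np.column_stack([np.r_[0.0, fpr], np.r_[0.0, tpr]])


def auc(roc_points) -> float:
    """Trapezoidal area under a (FPR, TPR) polyline."""
    pts = np.asarray(roc_points, dtype=np.float64)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def evaluate(y_true, y_pred, scores=None, positive_class: str = "septic") -> EvalReport:
    """Full report: confusion, the four metrics, and ROC/AUC if scored."""
    cm = confusion(y_true, y_pred, positive_class)
    accuracy, precision, recall, f1, degenerate = metrics(cm)
    roc_pts, area = None, None
    if scores is not None:
        roc_pts = roc_curve(y_true, scores, positive_class)
        area = auc(roc_pts)
    return EvalReport(
        cm=cm, accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        roc_points=roc_pts, auc=area, degenerate=degenerate,
        positive_class=positive_class,
    )


def plot_roc(reports: dict, path) -> None:
    """Overlay ROC curves of named reports and save to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, rep in reports.items():
        if rep.roc_points is None:
            continue
        ax.plot(rep.roc_points[:, 0], rep.roc_points[:, 1],
                label=f"{name} (AUC={rep.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="chance")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_confusion_heatmap(report: EvalReport, path, class_names=("septic", "rds")) -> None:
    """Count and row-normalised confusion heatmaps side by side."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = report.cm.as_array().astype(float)
    row_norm = counts / np.maximum(counts.sum(axis=1, keepdims=True), 1.0)
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    for ax, mat, title in zip(axes, [counts, row_norm], ["counts", "row-normalised"]):
        ax.imshow(mat, cmap="Blues")
        for (i, j), v in np.ndenumerate(mat):
            ax.text(j, i, f"{v:.2f}" if title != "counts" else f"{int(v)}",
                    ha="center", va="center")
        ax.set_xticks([0, 1], [f"pred {c}" for c in class_names])
        ax.set_yticks([0, 1], [f"true {c}" for c in class_names])
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
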