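"""Evaluation statistics: confusion matrices, accuracies, F1, size errors.

Conventions: confusion-matrix rows are ground truth, columns are
predictions.  All metrics are computed in full precision; rounding is a
presentation concern, except for the explicit ``round_recalls_first``
mode of ``balanced_accuracy`` which reproduces published computations
that averaged already-rounded per-class recalls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "SizeErrorReport",
    "confusion",
    "overall_accuracy",
    "balanced_accuracy",
    "weighted_f1",
    "size_error_report",
]


@dataclass
class ConfusionMatrix:
    class_names: list[str]
    counts: np.ndarray  # rows = ground truth, cols = prediction
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.class_names)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square and match class_names")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def recalls(self) -> np.ndarray:
        return np.diag(self.counts) / self.supports

    def precisions(self) -> np.ndarray:
        col = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.diag(self.counts) / col
        return np.where(col > 0, p, 0.0)


def confusion(true_labels, predicted_labels, class_names) -> ConfusionMatrix:
    """counts[i][j] = #(ground truth = class i, prediction = class j)."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must align")
    index = {c: i for i, c in enumerate(class_names)}
    counts = np.zeros((len(class_names), len(class_names)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside class_names: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(class_names=list(class_names), counts=counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Correct classifications over total examples (trace / total)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def balanced_accuracy(cm: ConfusionMatrix, round_recalls_first: bool = False) -> float:
    """Mean of per-class recalls.

    With ``round_recalls_first`` each recall is rounded to 2 decimal
    places before averaging, matching computations published in that
    already-rounded form.
    """
    supports = cm.supports
    for name, s in zip(cm.class_names, supports):
        if s == 0:
            raise ValueError(f"class {name!r} has zero support")
    recalls = cm.recalls()
    if round_recalls_first:
        recalls = np.round(recalls, 2)
    return float(recalls.mean())


def weighted_f1(cm: ConfusionMatrix) -> float:
    """Support-weighted mean of per-class F1 (0 where precision+recall=0)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    p = cm.precisions()
    r = cm.recalls()
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = 2 * p * r / (p + r)
    f1 = np.where(p + r > 0, f1, 0.0)
    return float((f1 * cm.supports).sum() / cm.total)


@dataclass
class SizeErrorReport:
    per_image: list[tuple[float, float, float]]  # (measured, estimated, E_i)
    E_bar: float
    RMSD: float
    R2: float
    cc: float
    N: int


def size_error_report(pairs) -> SizeErrorReport:
    """Per-image size-error statistics.

    E_i = |x_i - xhat_i|; E_bar their mean; RMSD the root mean squared
    deviation; R2 = 1 - RSS/TSS with TSS about the mean measured size;
    cc the mean relative accuracy (1/N) * sum (x_i - E_i) / x_i.
    """
    pairs = [(float(x), float(xh)) for x, xh in pairs]
    if len(pairs) < 2:
        raise ValueError("need at least 2 measurement pairs")
    x = np.array([p[0] for p in pairs])
    xh = np.array([p[1] for p in pairs])
    if (x <= 0).any():
        raise ValueError("measured sizes must be positive (cc undefined at 0)")
    e = np.abs(x - xh)
    rss = float(np.sum((x - xh) ** 2))
    tss = float(np.sum((x - x.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else float("-inf"))
    cc = float(np.mean((x - e) / x))
    return SizeErrorReport(
        per_image=[(xi, xhi, ei) for xi, xhi, ei in zip(x, xh, e)],
        E_bar=float(e.mean()),
        RMSD=float(np.sqrt(np.mean((x - xh) ** 2))),
        R2=r2,
        cc=cc,
        N=len(pairs),
    )
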