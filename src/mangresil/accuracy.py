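"""Confusion-matrix accuracy assessment.

Beyond the familiar overall / user's / producer's accuracies, map accuracy
is summarised with the quantity-allocation disagreement index (QADI).  The
total disagreement D = N - trace splits into

* quantity disagreement ``Q`` — mismatch in class totals between the map
  and the reference, Q = (1/2) * sum_g |row_total_g - column_total_g|;
* allocation disagreement ``A = D - Q`` — mislabelling that remains once
  the totals are matched.

QADI combines the two as the root sum of squares of their rates,
``QADI = sqrt((A/N)^2 + (Q/N)^2)``, and is read against a five-band
confidence scale (QADI < 0.07 meaning very high confidence, QADI >= 0.30
meaning a lack of accuracy).  Unlike the kappa coefficient it does not
suffer from chance-agreement paradoxes.

Matrix orientation: rows are the classified (user) classes, columns the
reference classes.  Row and column totals are always recomputed from the
cells, never trusted from an input table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: QADI confidence scale: [low, high) bins and their labels.
QADI_SCALE: tuple[tuple[float, float, str], ...] = (
    (0.00, 0.07, "Very low disagreement (Very high confidence)"),
    (0.07, 0.12, "Low disagreement (High confidence)"),
    (0.12, 0.20, "Moderate disagreement (Moderate confidence)"),
    (0.20, 0.30, "High level of disagreement (Low confidence)"),
    (0.30, np.inf, "Lack of accuracy (Very low confidence)"),
)


@dataclass
class ConfusionMatrix:
    """k x k counts; rows = classified classes, columns = reference classes."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.labels = tuple(self.labels)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if len(self.labels) != self.counts.shape[0]:
            raise ValueError("label count does not match matrix size")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be nonnegative")
        if self.N == 0:
            raise ValueError("confusion matrix is empty (N = 0)")

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def build_confusion(ref_labels, pred_labels, legend: dict[int, str]) -> ConfusionMatrix:
    """Cross-tabulate predicted against reference labels.

    ``counts[i, j]`` counts points predicted as class i whose reference
    label is class j, with classes ordered by legend code.
    """
    ref = np.asarray(ref_labels)
    pred = np.asarray(pred_labels)
    if ref.size == 0:
        raise ValueError("empty label sequences")
    if ref.shape != pred.shape:
        raise ValueError("reference and predicted label sequences differ in length")
    codes = sorted(legend)
    for name, arr in (("reference", ref), ("predicted", pred)):
        unknown = set(arr.tolist()) - set(codes)
        if unknown:
            raise ValueError(f"unknown {name} label(s): {sorted(unknown)}")
    index = {c: i for i, c in enumerate(codes)}
    counts = np.zeros((len(codes), len(codes)), dtype=np.int64)
    for p, r in zip(pred.ravel(), ref.ravel()):
        counts[index[p], index[r]] += 1
    return ConfusionMatrix(counts, tuple(legend[c] for c in codes))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Correctly classified fraction as a percentage, 100 * trace / N."""
    return 100.0 * cm.trace / cm.N


def class_accuracies(cm: ConfusionMatrix) -> pd.DataFrame:
    """User's (commission) and producer's (omission) accuracy per class, %.

    Classes with a zero row (or column) total get NaN for the
    corresponding accuracy.
    """
    diag = np.diag(cm.counts).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        users = 100.0 * diag / cm.row_totals
        producers = 100.0 * diag / cm.column_totals
    users[cm.row_totals == 0] = np.nan
    producers[cm.column_totals == 0] = np.nan
    return pd.DataFrame(
        {"users_accuracy": users, "producers_accuracy": producers}, index=list(cm.labels)
    )


def disagreement(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """Return (Q, A, D): quantity, allocation and total disagreement counts."""
    D = float(cm.N - cm.trace)
    Q = float(np.abs(cm.row_totals - cm.column_totals).sum()) / 2.0
    A = D - Q
    return Q, A, D


def qadi(cm: ConfusionMatrix) -> tuple[float, str]:
    """QADI value and its confidence-scale label."""
    Q, A, _ = disagreement(cm)
    value = float(np.hypot(A / cm.N, Q / cm.N))
    return value, qadi_confidence(value)


def qadi_confidence(value: float) -> str:
    """Map a QADI value onto the five-band confidence scale."""
    if value < 0:
        raise ValueError("QADI cannot be negative")
    for low, high, label in QADI_SCALE:
        if low <= value < high:
            return label
    return QADI_SCALE[-1][2]


@dataclass
class AccuracyReport:
    overall_accuracy: float
    per_class: pd.DataFrame
    quantity_disagreement: float
    allocation_disagreement: float
    total_disagreement: float
    qadi: float
    confidence: str
    N: int

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "overall_accuracy_pct": round(self.overall_accuracy, 1),
            "users_accuracy_pct": {
                k: round(v, 1) for k, v in self.per_class["users_accuracy"].items()
            },
            "producers_accuracy_pct": {
                k: round(v, 1) for k, v in self.per_class["producers_accuracy"].items()
            },
            "quantity_disagreement": self.quantity_disagreement,
            "allocation_disagreement": self.allocation_disagreement,
            "total_disagreement": self.total_disagreement,
            "qadi": round(self.qadi, 5),
            "confidence": self.confidence,
        }


def accuracy_report(cm: ConfusionMatrix) -> AccuracyReport:
    """Full assessment bundle for one confusion matrix."""
    Q, A, D = disagreement(cm)
    value, label = qadi(cm)
    return AccuracyReport(
        overall_accuracy=overall_accuracy(cm),
        per_class=class_accuracies(cm),
        quantity_disagreement=Q,
        allocation_disagreement=A,
        total_disagreement=D,
        qadi=value,
        confidence=label,
        N=cm.N,
    )
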