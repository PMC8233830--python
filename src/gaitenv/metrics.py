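"""Confusion matrices, accuracy, and one-vs-rest sensitivity/specificity.

Rows of a confusion matrix are the actual walking environment, columns the
predicted one, both in the fixed order FGW, US, DS, UW, DW.  The
row-normalized percent matrix has entries a_ij = b_ij / b_total,i x 100.
Accuracy is the correctly classified fraction, trace / total x 100.  For
each environment taken as positive (the other four negative),
sensitivity = TP / (TP + FN) and specificity = TN / (TN + FP).

All metrics are computed on integer counts; percentages are presentation
only.  Printed row-percent matrices can be converted back to counts when
the per-row trial count is known (each cell x n / 100 must land within
0.5 of an integer), which is how the published matrices are re-analyzed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .muscles import ENVIRONMENTS, ENV_LABELS

N_CLASSES = len(ENVIRONMENTS)


class LabelError(ValueError):
    """A label outside the 1..5 environment range."""


class PercentMatrixError(ValueError):
    """A printed percent matrix is inconsistent with the given row count."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """5x5 integer counts; counts[i][j] = #(actual i+1, predicted j+1)."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"counts must be 5x5, got {c.shape}")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)) or np.any(c < 0):
                raise ValueError("counts must be nonnegative integers")
            c = np.round(c).astype(int)
        object.__setattr__(self, "counts", c.astype(int))
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def percent(self) -> np.ndarray:
        """Row-normalized percent matrix (full precision, not rounded)."""
        totals = self.row_totals.astype(float)
        if np.any(totals == 0):
            raise ValueError("cannot row-normalize: some row total is zero")
        return self.counts / totals[:, None] * 100.0

    def percent_rounded(self, decimals: int = 1) -> np.ndarray:
        """Percent matrix rounded for presentation (publication convention)."""
        return np.round(self.percent(), decimals)


def _as_indices(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype.kind in "US":
        try:
            lab = np.array([ENV_LABELS[str(v)] for v in lab])
        except KeyError as exc:
            raise LabelError(f"unknown environment label {exc.args[0]!r}")
    lab = lab.astype(int)
    if np.any((lab < 1) | (lab > N_CLASSES)):
        bad = lab[(lab < 1) | (lab > N_CLASSES)][0]
        raise LabelError(f"label {bad} outside 1..{N_CLASSES}")
    return lab - 1


def confusion_from_predictions(actual, predicted) -> ConfusionMatrix:
    """Tabulate counts[i][j] = #(actual=i, predicted=j).

    Labels may be integers 1..5 or environment names (FGW..DW).
    """
    a, p = _as_indices(actual), _as_indices(predicted)
    if a.shape != p.shape:
        raise ValueError("actual and predicted must have equal length")
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(counts, (a, p), 1)
    return ConfusionMatrix(counts)


def counts_from_percent(percent, per_row_n: int) -> ConfusionMatrix:
    """Recover integer counts from a printed row-percent matrix.

    Each cell times ``per_row_n`` / 100 must lie strictly within 0.5 of an
    integer, and each recovered row must sum to ``per_row_n``; otherwise
    the matrix is inconsistent with the stated row count.
    """
    pct = np.asarray(percent, dtype=float)
    if pct.shape != (N_CLASSES, N_CLASSES):
        raise ValueError(f"percent matrix must be 5x5, got {pct.shape}")
    raw = pct * per_row_n / 100.0
    counts = np.rint(raw)
    off = np.abs(raw - counts)
    if np.any(off >= 0.5 - 1e-9):
        i, j = np.unravel_index(int(np.argmax(off)), raw.shape)
        raise PercentMatrixError(
            f"cell ({ENVIRONMENTS[i]}, {ENVIRONMENTS[j]}) = {pct[i, j]}% "
            f"is not integral at {per_row_n} trials/row "
            f"({raw[i, j]:.3f} counts)")
    counts = counts.astype(int)
    bad_rows = np.flatnonzero(counts.sum(axis=1) != per_row_n)
    if bad_rows.size:
        i = int(bad_rows[0])
        raise PercentMatrixError(
            f"row {ENVIRONMENTS[i]} sums to {counts[i].sum()} counts, "
            f"expected {per_row_n}")
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Correct-classification percentage: trace / total x 100."""
    return float(np.trace(cm.counts)) / cm.total * 100.0


def one_vs_rest_counts(cm: ConfusionMatrix, positive_class: int
                       ) -> tuple[int, int, int, int]:
    """(TP, FN, FP, TN) treating one environment (label 1..5) as positive."""
    c = _as_indices([positive_class])[0]
    tp = int(cm.counts[c, c])
    fn = int(cm.row_totals[c]) - tp
    fp = int(cm.counts[:, c].sum()) - tp
    tn = cm.total - tp - fn - fp
    return tp, fn, fp, tn


def sensitivity_specificity(cm: ConfusionMatrix, positive_class: int
                            ) -> tuple[float, float]:
    """One-vs-rest (sensitivity %, specificity %) for the positive class.

    Degenerate denominators yield NaN (undefined), never 0.
    """
    tp, fn, fp, tn = one_vs_rest_counts(cm, positive_class)
    sens = tp / (tp + fn) * 100.0 if (tp + fn) > 0 else math.nan
    spec = tn / (tn + fp) * 100.0 if (tn + fp) > 0 else math.nan
    return sens, spec


@dataclass
class EvalReport:
    """Full evaluation of one classifier run: counts plus derived metrics."""

    cm: ConfusionMatrix
    muscles: tuple[str, ...] = ()
    seed: int | None = None
    config: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return accuracy(self.cm)

    def per_class(self) -> dict[str, dict[str, float]]:
        out = {}
        for i, env in enumerate(ENVIRONMENTS):
            tp, fn, fp, tn = one_vs_rest_counts(self.cm, i + 1)
            sens, spec = sensitivity_specificity(self.cm, i + 1)
            out[env] = {"TP": tp, "FN": fn, "FP": fp, "TN": tn,
                        "sensitivity": sens, "specificity": spec}
        return out

    def to_dict(self) -> dict:
        """Serializable summary; percentages rounded to 1 decimal here only."""
        per_class = {
            env: {k: (round(v, 1) if isinstance(v, float) else v)
                  for k, v in d.items()}
            for env, d in self.per_class().items()
        }
        return {
            "muscles": list(self.muscles),
            "seed": self.seed,
            "config": dict(self.config),
            "n_total": self.cm.total,
            "n_correct": int(np.trace(self.cm.counts)),
            "accuracy_percent": round(self.accuracy, 1),
            "counts": self.cm.counts.tolist(),
            "percent": np.round(self.cm.percent(), 1).tolist(),
            "class_order": list(ENVIRONMENTS),
            "per_class": per_class,
        }
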