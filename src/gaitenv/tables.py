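"""Published confusion matrices and their re-analysis.

The original study reports its results as row-percent confusion matrices
(27 test trials per environment) plus derived accuracy, sensitivity and
specificity figures.  This module ships those printed matrices as CSV
fixtures and recomputes every derived figure from them: percent -> integer
counts -> metrics, the direction that makes counts authoritative.

Known print issues, handled explicitly rather than silently:

* The published uphill specificity is 100, but the all-muscle matrix shows
  one downhill trial predicted as uphill, which gives 107/108 = 99.1%.
  The count-derived value is reported and the printed cell is flagged as a
  known discrepancy.
* In the individual-muscle table, the VL uphill row sums to 77.7% and the
  VM upstairs row to 103.7% as printed, so their full count matrices
  cannot be reconstructed.  Their accuracies are still recovered from the
  diagonal cells (which are consistent with the published accuracy list);
  the two matrices are flagged as inconsistent in print.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .metrics import (
    ConfusionMatrix,
    PercentMatrixError,
    accuracy,
    counts_from_percent,
    sensitivity_specificity,
)
from .muscles import ENVIRONMENTS

PER_ROW_N = 27  # 20% test split of 135 trials per environment

# Accuracy figures as printed (percent).
PUBLISHED_ACCURACY: dict[str, float] = {
    "all": 96.3,
    # per-joint flexor/extensor groups
    "ankle_extensors": 88.9, "knee_flexors": 75.6, "knee_extensors": 68.1,
    "mtp_flexor": 67.4, "ankle_flexor": 63.0, "mtp_extensor": 45.2,
    # individual muscles
    "MG": 81.5, "LG": 77.0, "ST": 72.6, "VM": 68.9, "Sol": 68.1, "RF": 67.4,
    "FHL": 67.4, "BF": 66.7, "TA": 63.0, "VL": 57.0, "EDL": 45.2,
}

# All-muscle sensitivity/specificity as printed (percent, FGW..DW order).
PUBLISHED_SENSITIVITY = {"FGW": 100.0, "US": 100.0, "DS": 96.3, "UW": 96.3,
                         "DW": 88.9}
PUBLISHED_SPECIFICITY = {"FGW": 99.1, "US": 99.1, "DS": 99.1, "UW": 100.0,
                         "DW": 99.1}

# Cells whose printed value disagrees with the count-derived one.
KNOWN_DISCREPANCIES = {("specificity", "UW")}

# Matrices whose printed rows do not sum to 100% (full counts unrecoverable).
INCONSISTENT_MATRICES = {"VL", "VM"}


def _read(name: str) -> pd.DataFrame:
    with resources.files("gaitenv.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def _to_matrix(df: pd.DataFrame) -> np.ndarray:
    df = df.set_index("actual").loc[list(ENVIRONMENTS), list(ENVIRONMENTS)]
    return df.to_numpy(dtype=float)


def load_published_matrices() -> dict[str, np.ndarray]:
    """All published row-percent matrices keyed by experiment name."""
    out = {"all": _to_matrix(_read("published_confusion_all_muscles.csv"))}
    groups = _read("published_confusion_joint_groups.csv")
    for name, block in groups.groupby("group", sort=False):
        out[name] = _to_matrix(block.drop(columns="group"))
    muscles = _read("published_confusion_individual_muscles.csv")
    for name, block in muscles.groupby("muscle", sort=False):
        out[name] = _to_matrix(block.drop(columns="muscle"))
    return out


def diagonal_accuracy(percent: np.ndarray, per_row_n: int = PER_ROW_N
                      ) -> float:
    """Accuracy from diagonal percent cells alone.

    Each diagonal cell times ``per_row_n``/100 is rounded to the correct
    count; accuracy is their sum over the total test count.  Works even
    when an off-diagonal cell is misprinted.
    """
    diag = np.diag(np.asarray(percent, dtype=float))
    counts = np.rint(diag * per_row_n / 100.0)
    return float(counts.sum()) / (per_row_n * len(ENVIRONMENTS)) * 100.0


@dataclass
class CheckResult:
    name: str          # e.g. "accuracy:MG" or "specificity:UW"
    computed: float
    published: float
    status: str        # "pass" | "fail" | "known_discrepancy"
    note: str = ""


def check_tables(tolerance: float = 0.05) -> list[CheckResult]:
    """Recompute every published figure from the printed matrices.

    Accuracies are compared at the printed precision; the uphill
    specificity cell is flagged as a known discrepancy (printed 100,
    count-derived 99.1), never as a failure.
    """
    results: list[CheckResult] = []
    matrices = load_published_matrices()

    for name, pct in matrices.items():
        pub = PUBLISHED_ACCURACY[name]
        note = ""
        try:
            cm = counts_from_percent(pct, PER_ROW_N)
            acc = accuracy(cm)
        except PercentMatrixError as exc:
            acc = diagonal_accuracy(pct)
            note = f"row-sum inconsistency in print ({exc}); " \
                   "accuracy recovered from diagonal counts"
        status = "pass" if abs(acc - pub) <= tolerance else "fail"
        results.append(CheckResult(f"accuracy:{name}", round(acc, 1), pub,
                                   status, note))

    cm_all = counts_from_percent(matrices["all"], PER_ROW_N)
    for i, env in enumerate(ENVIRONMENTS):
        sens, spec = sensitivity_specificity(cm_all, i + 1)
        for metric, val, pub_map in (
                ("sensitivity", sens, PUBLISHED_SENSITIVITY),
                ("specificity", spec, PUBLISHED_SPECIFICITY)):
            pub = pub_map[env]
            if (metric, env) in KNOWN_DISCREPANCIES:
                status = "known_discrepancy"
                note = (f"printed {pub} but the count-derived value is "
                        f"{val:.1f}; counts are authoritative")
            else:
                status = "pass" if abs(val - pub) <= tolerance else "fail"
                note = ""
            results.append(CheckResult(f"{metric}:{env}", round(val, 1),
                                       pub, status, note))
    return results


def all_muscle_confusion() -> ConfusionMatrix:
    """Integer counts recovered from the published all-muscle matrix."""
    return counts_from_percent(
        load_published_matrices()["all"], PER_ROW_N)
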