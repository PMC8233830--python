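"""Plain-text readers and writers for trials, manifests and reports.

Trial files are TSV: a single ``# rate_hz=<fs>`` header line, a column-name
line starting with ``vgrf`` followed by muscle names, then one row per
sample.  Floats are written with 17 significant digits so a write→read
round trip is bit-exact.  Manifests are CSV with columns
``subject_id, environment, trial_id, path``.  Evaluation reports are YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .muscles import (
    CANONICAL_MUSCLES,
    canonical_sort,
    validate_environment,
    validate_muscles,
)


class TrialFormatError(ValueError):
    """Trial file violates the documented TSV layout."""


@dataclass
class TrialRecording:
    """Raw synchronized vGRF + multi-channel sEMG for one trial.

    ``emg`` maps canonical muscle names to raw voltage traces; every channel
    is sample-aligned with ``vgrf`` and shares its length and sampling rate.
    """

    subject_id: str
    environment: str
    trial_id: str
    vgrf: np.ndarray
    emg: dict[str, np.ndarray]
    sampling_rate: float = 1200.0

    def __post_init__(self):
        validate_environment(self.environment)
        if self.sampling_rate <= 1000.0:
            raise ValueError(
                "sampling_rate must exceed 1000 Hz (2x the 500 Hz band-pass "
                f"upper cutoff); got {self.sampling_rate}")
        self.vgrf = np.asarray(self.vgrf, dtype=float)
        validate_muscles(self.emg)
        # store channels in canonical order regardless of input order
        ordered = canonical_sort(self.emg)
        self.emg = {m: np.asarray(self.emg[m], dtype=float) for m in ordered}
        n = self.vgrf.shape[0]
        for m, x in self.emg.items():
            if x.shape != (n,):
                raise TrialFormatError(
                    f"channel {m} has length {x.shape[0]}, expected {n} "
                    "(all channels must be sample-aligned with vgrf)")

    @property
    def muscles(self) -> tuple[str, ...]:
        return tuple(self.emg)

    @property
    def n_samples(self) -> int:
        return int(self.vgrf.shape[0])


def write_trial(trial: TrialRecording, path) -> Path:
    """Write a trial as TSV (bit-exact round trip with :func:`read_trial`)."""
    path = Path(path)
    cols = [trial.vgrf] + [trial.emg[m] for m in trial.muscles]
    data = np.column_stack(cols)
    header = (f"# rate_hz={trial.sampling_rate:g}\n"
              + "\t".join(["vgrf", *trial.muscles]))
    np.savetxt(path, data, fmt="%.17g", delimiter="\t", header=header,
               comments="")
    return path


def read_trial(path, manifest_row) -> TrialRecording:
    """Read a TSV trial file; identity comes from the manifest row.

    ``manifest_row`` is any mapping (or pandas row) with ``subject_id``,
    ``environment`` and ``trial_id`` entries.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# rate_hz="):
            raise TrialFormatError(
                f"{path}: missing '# rate_hz=' header line")
        fs = float(first.split("=", 1)[1])
        names = fh.readline().strip().split("\t")
        if not names or names[0] != "vgrf":
            raise TrialFormatError(
                f"{path}: first data column must be 'vgrf', got "
                f"{names[0] if names else 'nothing'}")
        muscles = validate_muscles(names[1:])
        try:
            data = np.loadtxt(fh, delimiter="\t", ndmin=2)
        except ValueError as exc:  # ragged rows etc.
            raise TrialFormatError(f"{path}: malformed sample rows: {exc}")
    if data.shape[1] != len(names):
        raise TrialFormatError(
            f"{path}: {data.shape[1]} columns of samples for "
            f"{len(names)} declared channels")
    emg = {m: data[:, i + 1] for i, m in enumerate(muscles)}
    return TrialRecording(
        subject_id=str(manifest_row["subject_id"]),
        environment=str(manifest_row["environment"]),
        trial_id=str(manifest_row["trial_id"]),
        vgrf=data[:, 0],
        emg=emg,
        sampling_rate=fs,
    )


MANIFEST_COLUMNS = ("subject_id", "environment", "trial_id", "path")


def write_manifest(rows: pd.DataFrame, path) -> Path:
    """Write a trial manifest CSV after validating its shape."""
    validate_manifest(rows)
    path = Path(path)
    rows.to_csv(path, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    validate_manifest(df)
    return df


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise TrialFormatError(f"manifest missing columns: {missing}")
    for env in df["environment"].unique():
        validate_environment(env)
    key = df[["subject_id", "environment", "trial_id"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise TrialFormatError(
            "duplicate manifest entry for "
            f"({dup.subject_id}, {dup.environment}, {dup.trial_id})")
    return df


def write_eval_report(report, path) -> Path:
    """Serialize an :class:`~gaitenv.metrics.EvalReport` to YAML.

    Percentages are rounded to one decimal at serialization only; counts are
    written exactly.
    """
    doc = report.to_dict()
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def read_eval_report(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
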