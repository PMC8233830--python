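"""Linear-envelope extraction and stance-profile assembly.

The processing chain for each sEMG channel is the standard offline linear
envelope: zero-phase fourth-order Butterworth band-pass (20-500 Hz),
full-wave rectification, zero-phase fourth-order Butterworth low-pass
(10 Hz), applied to the full trial before cropping to the stance window so
filter edge transients stay outside the window.  Envelopes are normalized
per subject and muscle by the peak stance-phase envelope amplitude from
that subject's flat-ground walking, then linearly interpolated onto a
1000-point grid spanning 0-100% of stance.  A profile is the concatenation
of these 1000-point envelopes over a muscle set in canonical order.

Both filters are zero-phase (forward-backward), so no phase lag
desynchronizes muscles; this doubles the effective filter order.  The
band-pass uses the ``butter(4, [low, high])`` convention, i.e. four poles
per band edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .events import StanceWindow
from .io import TrialRecording
from .muscles import canonical_sort, validate_environment
from .muscles import ENV_LABELS


class FilterParameterError(ValueError):
    """Cutoff frequencies incompatible with the sampling rate."""


class DegenerateReferenceError(ValueError):
    """A normalization reference is non-positive or non-finite."""


@dataclass
class Envelope:
    """Nonnegative linear-envelope samples for one muscle."""

    samples: np.ndarray
    fs: float
    muscle: str

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class StanceProfile:
    """Per-muscle 1000-point normalized envelopes over the stance phase.

    ``data`` has shape ``(len(muscles), 1000)`` with rows in canonical
    muscle order; :meth:`vector` concatenates them into the classifier
    input.
    """

    data: np.ndarray
    muscles: tuple[str, ...]
    subject_id: str
    environment: str
    trial_id: str

    N_POINTS = 1000

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.muscles = canonical_sort(self.muscles)
        validate_environment(self.environment)
        if self.data.shape != (len(self.muscles), self.N_POINTS):
            raise ValueError(
                f"profile data shape {self.data.shape} does not match "
                f"({len(self.muscles)}, {self.N_POINTS})")

    @property
    def label(self) -> int:
        return ENV_LABELS[self.environment]

    def vector(self) -> np.ndarray:
        """Concatenated input vector of length 1000 x n_muscles."""
        return self.data.reshape(-1)

    def restrict(self, muscles) -> "StanceProfile":
        """Profile restricted to a muscle subset (canonical order kept)."""
        keep = canonical_sort(muscles)
        missing = set(keep) - set(self.muscles)
        if missing:
            raise KeyError(f"profile lacks muscles {sorted(missing)}")
        idx = [self.muscles.index(m) for m in keep]
        return StanceProfile(self.data[idx], keep, self.subject_id,
                             self.environment, self.trial_id)


@dataclass
class NormalizationReference:
    """Per-muscle flat-ground peak stance-envelope amplitudes for a subject."""

    subject_id: str
    peaks: dict[str, float]

    def __post_init__(self):
        for m, v in self.peaks.items():
            if not np.isfinite(v) or v <= 0:
                raise DegenerateReferenceError(
                    f"degenerate normalization reference for subject "
                    f"{self.subject_id}, muscle {m}: {v!r}")


def _check_band(fs: float, *cutoffs: float) -> None:
    nyq = fs / 2.0
    for c in cutoffs:
        if not 0 < c < nyq:
            raise FilterParameterError(
                f"cutoff {c} Hz outside (0, Nyquist={nyq} Hz) at fs={fs} Hz")


def bandpass(raw, fs: float, low: float = 20.0, high: float = 500.0,
             order: int = 4):
    """Zero-phase Butterworth band-pass; same length as the input."""
    _check_band(fs, low, high)
    if low >= high:
        raise FilterParameterError(f"low cutoff {low} >= high cutoff {high}")
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(raw, dtype=float))


def rectify(signal):
    """Full-wave rectification (elementwise absolute value)."""
    return np.abs(np.asarray(signal, dtype=float))


def lowpass_envelope(rectified, fs: float, cutoff: float = 10.0,
                     order: int = 4):
    """Zero-phase Butterworth low-pass; negative ringing clamped to 0."""
    _check_band(fs, cutoff)
    sos = butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    out = sosfiltfilt(sos, np.asarray(rectified, dtype=float))
    return np.clip(out, 0.0, None)


def extract_envelope(raw, fs: float, *, low: float = 20.0, high: float = 500.0,
                     band_order: int = 4, lp_cutoff: float = 10.0,
                     lp_order: int = 4):
    """Full chain: band-pass -> rectify -> low-pass on one raw channel."""
    return lowpass_envelope(rectify(bandpass(raw, fs, low, high, band_order)),
                            fs, lp_cutoff, lp_order)


def compute_normalization_reference(flat_trials, subject_id: str
                                    ) -> NormalizationReference:
    """Peak stance-phase envelope per muscle across flat-ground trials.

    Parameters
    ----------
    flat_trials
        Sequence of ``(envelopes, window)`` pairs, one per flat-ground
        trial, where ``envelopes`` maps muscle name to full-trial envelope
        samples and ``window`` is the trial's :class:`StanceWindow`.  The
        reference for each muscle is the maximum envelope value *inside*
        the stance window, maximized across trials.  Passing a single pair
        gives the per-single-trial mode.
    """
    flat_trials = list(flat_trials)
    if not flat_trials:
        raise ValueError("at least one flat-ground trial is required")
    peaks: dict[str, float] = {}
    for envelopes, window in flat_trials:
        for m, samples in envelopes.items():
            samples = np.asarray(samples, dtype=float)
            peak = float(np.max(samples[window.slice()]))
            peaks[m] = max(peaks.get(m, 0.0), peak)
    return NormalizationReference(subject_id=subject_id, peaks=peaks)


def normalize(envelope: Envelope, ref: NormalizationReference) -> Envelope:
    """Divide an envelope by the subject's flat-ground peak for that muscle.

    Values may exceed 1.0 for non-flat environments.
    """
    if envelope.muscle not in ref.peaks:
        raise KeyError(
            f"no normalization reference for muscle {envelope.muscle} "
            f"(subject {ref.subject_id})")
    return Envelope(envelope.samples / ref.peaks[envelope.muscle],
                    envelope.fs, envelope.muscle)


def time_normalize(stance_envelope, n_points: int = 1000):
    """Linear interpolation onto ``n_points`` spanning 0-100% of stance.

    The grid includes both endpoints, so first and last input values are
    preserved exactly; an input already of length ``n_points`` is returned
    unchanged.
    """
    x = np.asarray(stance_envelope, dtype=float)
    if x.ndim != 1 or x.shape[0] < 2:
        raise ValueError("stance envelope must have at least 2 samples")
    grid = np.linspace(0.0, x.shape[0] - 1.0, n_points)
    return np.interp(grid, np.arange(x.shape[0]), x)


def build_profile(trial: TrialRecording, window: StanceWindow,
                  ref: NormalizationReference, muscles=None,
                  **filter_kwargs) -> StanceProfile:
    """Assemble one classifier input profile from a raw trial.

    Per muscle: band-pass -> rectify -> low-pass on the full trial, crop to
    the stance window, normalize by the subject's flat-ground peak, and
    time-normalize to 1000 points.  Rows are stacked in canonical muscle
    order.
    """
    muscles = canonical_sort(muscles if muscles is not None else trial.muscles)
    rows = []
    for m in muscles:
        if m not in trial.emg:
            raise KeyError(
                f"trial ({trial.subject_id}, {trial.environment}, "
                f"{trial.trial_id}) lacks muscle {m}")
        try:
            env = extract_envelope(trial.emg[m], trial.sampling_rate,
                                   **filter_kwargs)
            env = env[window.slice()]
            env = normalize(Envelope(env, trial.sampling_rate, m), ref)
            rows.append(time_normalize(env.samples, StanceProfile.N_POINTS))
        except Exception as exc:
            exc.add_note(
                f"while processing trial {trial.subject_id}/"
                f"{trial.environment}/{trial.trial_id}, muscle {m}")
            raise
    return StanceProfile(np.vstack(rows), muscles, trial.subject_id,
                         trial.environment, trial.trial_id)
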