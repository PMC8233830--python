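"""Stance-phase detection from the vertical ground reaction force.

A stance phase runs from initial heel contact to toe-off.  Heel contact is
the first frame in which the vGRF exceeds the onset threshold (20 N by
default); toe-off is the first frame after the post-heel-strike force peak
in which the vGRF drops back below the offset threshold.  A literal
``strict_zero`` mode (offset fires only when the force returns to exactly
0 N) is provided for noiseless synthetic traces, since on a real force
plate the signal may never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class StanceDetectionError(ValueError):
    """Base class for stance-detection failures."""


class NoStanceError(StanceDetectionError):
    """The force never exceeds the onset threshold."""


class IncompleteStanceError(StanceDetectionError):
    """An onset was found but the force never falls back below the offset."""


class ImplausibleStanceError(StanceDetectionError):
    """Detected window is shorter than the minimum plausible stance."""


@dataclass(frozen=True)
class StanceWindow:
    """Half-open sample-index interval [heel_strike, toe_off) within a trial."""

    heel_strike: int
    toe_off: int

    def __post_init__(self):
        if not 0 <= self.heel_strike < self.toe_off:
            raise ValueError(
                f"invalid stance window [{self.heel_strike}, {self.toe_off})"
            )

    @property
    def n_samples(self) -> int:
        return self.toe_off - self.heel_strike

    def duration(self, fs: float) -> float:
        return self.n_samples / fs

    def slice(self) -> slice:
        return slice(self.heel_strike, self.toe_off)


def detect_stance(
    vgrf,
    fs: float,
    onset_threshold: float = 20.0,
    offset_threshold: float = 20.0,
    *,
    strict_zero: bool = False,
    min_stance_s: float = 0.2,
) -> StanceWindow:
    """Locate the first stance phase in a single-contact vGRF trace.

    Parameters
    ----------
    vgrf
        Vertical ground reaction force in newtons.
    fs
        Sampling rate in Hz.
    onset_threshold, offset_threshold
        Force thresholds in newtons.  Heel strike is the first frame with
        ``vgrf > onset_threshold``; toe-off is the first frame after the
        subsequent force maximum with ``vgrf < offset_threshold``.
    strict_zero
        If true, toe-off instead requires the force to return to exactly
        0 N (``vgrf <= 0``).
    min_stance_s
        Minimum plausible stance duration; shorter windows raise
        :class:`ImplausibleStanceError`.

    Returns
    -------
    StanceWindow
        Half-open window ``[heel_strike, toe_off)`` of load-bearing frames.
    """
    v = np.asarray(vgrf, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("vgrf must be a non-empty 1-D sequence")
    if onset_threshold <= 0 or offset_threshold <= 0:
        raise ValueError("thresholds must be positive")

    above = np.flatnonzero(v > onset_threshold)
    if above.size == 0:
        raise NoStanceError("no stance detected: vGRF never exceeds "
                            f"{onset_threshold} N")
    heel_strike = int(above[0])

    # Search for the offset only after the force maximum following heel
    # strike, so the mid-stance valley of the double bump cannot fire it.
    peak = heel_strike + int(np.argmax(v[heel_strike:]))
    tail = v[peak + 1:]
    below = np.flatnonzero(tail <= 0.0) if strict_zero else np.flatnonzero(
        tail < offset_threshold)
    if below.size == 0:
        raise IncompleteStanceError(
            "incomplete stance: vGRF never falls below the offset threshold "
            "after the force peak")
    toe_off = peak + 1 + int(below[0])

    window = StanceWindow(heel_strike, toe_off)
    if window.duration(fs) < min_stance_s:
        raise ImplausibleStanceError(
            f"implausible stance: {window.duration(fs):.3f} s is shorter than "
            f"the {min_stance_s} s minimum")
    return window
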