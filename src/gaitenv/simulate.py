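"""Synthetic multi-subject gait trials: sEMG channels plus a vGRF trace.

The study's raw recordings are not deposited, so this generator stands in
for them with the statistical structure the downstream pipeline assumes:

* per muscle and environment, a stance-phase activation envelope built
  from Gaussian bursts in normalized stance time;
* a raw sEMG channel formed by amplitude-modulating a zero-mean broadband
  carrier (white noise band-limited to 20-450 Hz, inside the analysis
  band-pass) with that envelope, so the band-pass -> rectify -> 10 Hz
  low-pass chain demodulates it back;
* a double-bump vertical ground reaction force that is exactly zero
  outside stance and crosses the 20 N event threshold within a couple of
  samples of the stance boundaries.

Environment effects scale and shift the bursts relative to flat-ground
walking, controlled by a single ``separation`` scale: at 0 all five
environments are statistically identical (classification should sit at
chance), at the default 1.0 they are well separated.  The largest effects
are placed on the ankle plantarflexors (Sol, MG, LG) — the muscles that
power push-off and whose joint moments differ most across ramps and
stairs — so the qualitative muscle-importance ranking of the real study
(ankle extensors most informative, EDL least) is reproducible on
synthetic data.

Every random draw is keyed by (master_seed, subject, environment, trial,
channel, purpose) through a stable hash, so regeneration is deterministic
and no global random state is used.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .io import TrialRecording, write_manifest, write_trial
from .muscles import (
    CANONICAL_MUSCLES,
    ENVIRONMENTS,
    validate_environment,
    validate_muscles,
)

# ---------------------------------------------------------------------------
# deterministic key-derived RNG


def derive_seed(master_seed: int, *parts) -> int:
    """Stable sub-seed < 2**31 from a master seed and string-able key parts."""
    key = "|".join(str(p) for p in parts).encode()
    digest = hashlib.blake2b(key, digest_size=4).digest()
    return (int.from_bytes(digest, "big") ^ (master_seed & 0x7FFFFFFF)) % (2**31)


def _rng(master_seed: int, *parts) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([master_seed & 0x7FFFFFFF,
                                derive_seed(0, *parts)]))


# ---------------------------------------------------------------------------
# parameters


@dataclass
class SubjectParams:
    """Inter-subject variability knobs for one synthetic participant."""

    subject_id: str
    gains: dict[str, float]          # per-muscle multiplicative gain, > 0
    stance_duration: float = 0.72    # s, typical adult stance ~0.6-0.9 s
    cadence_jitter: float = 0.05     # fractional trial-to-trial duration jitter
    noise_floor: float = 0.05        # resting activation, fraction of peak
    body_weight: float = 677.0       # N (~69 kg)

    def __post_init__(self):
        validate_muscles(self.gains)
        if any(g <= 0 for g in self.gains.values()):
            raise ValueError("subject gains must be positive")
        if self.stance_duration <= 0:
            raise ValueError("stance duration must be positive")
        if not 0 <= self.noise_floor < 0.5:
            raise ValueError("noise floor must lie in [0, 0.5)")


@dataclass(frozen=True)
class Burst:
    """One Gaussian activation burst in normalized stance time."""

    center: float    # fraction of stance in [0, 1]
    width: float     # standard deviation, fraction of stance
    amplitude: float  # relative units, >= 0

    def __post_init__(self):
        if not 0.0 <= self.center <= 1.0:
            raise ValueError(f"burst center {self.center} outside [0, 1]")
        if self.width <= 0:
            raise ValueError("burst width must be positive")
        if self.amplitude < 0:
            raise ValueError("burst amplitude must be nonnegative")


@dataclass
class EnvironmentEffect:
    """Per-muscle, per-environment burst parameters.

    ``bursts[env][muscle]`` is the tuple of Gaussian bursts whose sum (times
    the subject gain, plus the noise floor) is that muscle's mean activation
    envelope in that environment.  ``separation`` records the scale the
    table was built with (0 = all environments identical).
    """

    bursts: dict[str, dict[str, tuple[Burst, ...]]]
    separation: float = 1.0

    def __post_init__(self):
        for env, per_muscle in self.bursts.items():
            validate_environment(env)
            validate_muscles(per_muscle)


# Flat-ground burst templates: (center, width, amplitude) per muscle,
# following textbook gait EMG timing — quadriceps in loading response,
# hamstrings around heel strike, TA biphasic, plantarflexors at push-off.
_BASE_BURSTS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "RF":  ((0.12, 0.08, 0.7), (0.88, 0.10, 0.3)),
    "VL":  ((0.12, 0.08, 0.9),),
    "VM":  ((0.13, 0.08, 0.9),),
    "ST":  ((0.05, 0.06, 0.8), (0.92, 0.08, 0.3)),
    "BF":  ((0.06, 0.06, 0.8),),
    "TA":  ((0.04, 0.05, 1.0), (0.95, 0.06, 0.4)),
    "Sol": ((0.70, 0.12, 1.0),),
    "MG":  ((0.72, 0.10, 1.0),),
    "LG":  ((0.72, 0.10, 0.9),),
    "FHL": ((0.80, 0.08, 0.8),),
    "EDL": ((0.10, 0.07, 0.6),),
}

# How strongly each muscle's bursts respond to a change of environment.
# Ankle plantarflexors respond most (push-off work changes most across
# ramps/stairs); EDL barely responds, making it the least informative
# channel by construction.
_EFFECT_STRENGTH: dict[str, float] = {
    "RF": 0.5, "VL": 0.5, "VM": 0.5, "ST": 0.6, "BF": 0.6,
    "TA": 0.5, "Sol": 1.0, "MG": 1.0, "LG": 1.0, "FHL": 0.55, "EDL": 0.15,
}

# Per-environment (amplitude delta, center shift) signatures relative to
# flat ground, applied in proportion to the muscle's effect strength.
_ENV_SIGNATURE: dict[str, tuple[float, float]] = {
    "FGW": (0.0, 0.0),
    "US":  (+0.45, -0.04),
    "DS":  (-0.30, +0.05),
    "UW":  (+0.25, +0.03),
    "DW":  (-0.15, -0.05),
}


def default_environment_effect(separation: float = 1.0) -> EnvironmentEffect:
    """Build the default burst table at a given environment separation.

    ``separation`` in [0, 1] linearly scales every amplitude delta and
    timing shift away from the flat-ground template; at 0 all environments
    share the flat-ground bursts exactly.
    """
    if not 0.0 <= separation <= 1.0:
        raise ValueError("separation must lie in [0, 1]")
    table: dict[str, dict[str, tuple[Burst, ...]]] = {}
    for env in ENVIRONMENTS:
        d_amp, d_center = _ENV_SIGNATURE[env]
        per_muscle = {}
        for m, bursts in _BASE_BURSTS.items():
            s = _EFFECT_STRENGTH[m] * separation
            per_muscle[m] = tuple(
                Burst(center=float(np.clip(c + s * d_center, 0.0, 1.0)),
                      width=w,
                      amplitude=a * (1.0 + s * d_amp))
                for c, w, a in bursts)
        table[env] = per_muscle
    return EnvironmentEffect(bursts=table, separation=separation)


# ---------------------------------------------------------------------------
# envelopes, carrier, vGRF


def make_envelope(env: str, muscle: str, subject: SubjectParams,
                  effect: EnvironmentEffect, n_samples: int) -> np.ndarray:
    """Mean activation envelope over the stance phase (deterministic).

    Sum of the environment's Gaussian bursts for the muscle, times the
    subject's gain, plus the subject's noise floor.
    """
    validate_environment(env)
    validate_muscles([muscle])
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    try:
        bursts = effect.bursts[env][muscle]
    except KeyError as exc:
        raise KeyError(f"effect table lacks entry for ({env}, {muscle})") \
            from exc
    t = np.linspace(0.0, 1.0, n_samples)
    out = np.full(n_samples, float(subject.noise_floor))
    for b in bursts:
        out += b.amplitude * np.exp(-0.5 * ((t - b.center) / b.width) ** 2)
    return out * subject.gains.get(muscle, 1.0)


CARRIER_BAND = (20.0, 450.0)


def modulate_carrier(envelope, fs: float, seed: int,
                     band: tuple[float, float] = CARRIER_BAND) -> np.ndarray:
    """Amplitude-modulate a unit-variance broadband carrier with an envelope.

    The carrier is Gaussian white noise band-limited to ``band`` (inside
    the 20-500 Hz analysis pass-band) and rescaled to unit standard
    deviation, so rectify+low-pass recovers the envelope up to the
    half-normal factor sqrt(2/pi), which cancels under flat-ground-peak
    normalization.
    """
    env = np.asarray(envelope, dtype=float)
    if fs <= 1000.0:
        raise ValueError(f"fs={fs} Hz too low; need > 1000 Hz")
    if band[1] >= fs / 2:
        raise ValueError(
            f"carrier band {band} exceeds Nyquist at fs={fs} Hz")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(env.shape[0])
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    carrier = sosfiltfilt(sos, white)
    sd = carrier.std()
    if sd > 0:
        carrier = carrier / sd
    return env * carrier


def make_vgrf(stance_duration: float, fs: float, body_weight: float = 677.0,
              pad: float = 0.25) -> np.ndarray:
    """Double-bump stance vGRF, exactly zero in the leading/trailing pads.

    Two smooth bumps (~1.1 and ~1.0 body weight at 27% and 73% of stance)
    with a mid-stance valley; a short linear ramp (0.5% of stance) at each
    end takes the force to exactly zero at the boundaries, so the 20 N
    onset threshold is crossed within ~2 samples of stance start.
    """
    if stance_duration <= 0 or pad <= 0:
        raise ValueError("stance_duration and pad must be positive")
    n_stance = int(round(stance_duration * fs))
    n_pad = int(round(pad * fs))
    s = np.arange(n_stance) / n_stance
    core = (1.1 * np.exp(-0.5 * ((s - 0.27) / 0.15) ** 2)
            + 1.0 * np.exp(-0.5 * ((s - 0.73) / 0.15) ** 2))
    ramp_frac = 0.005
    window = np.clip(s / ramp_frac, 0.0, 1.0) * np.clip(
        (1.0 - s) / ramp_frac, 0.0, 1.0)
    stance = body_weight * core * window
    return np.concatenate([np.zeros(n_pad), stance, np.zeros(n_pad)])


# ---------------------------------------------------------------------------
# whole trials and whole studies


@dataclass
class StudyConfig:
    """Shape and noise settings for a synthetic study.

    Defaults mirror the real protocol: 27 subjects, 5 successful trials per
    environment each (135 trials per environment), 1200 Hz, all 11 muscles.
    """

    n_subjects: int = 27
    trials_per_env: int = 5
    fs: float = 1200.0
    muscles: tuple[str, ...] = CANONICAL_MUSCLES
    pad: float = 0.25                 # s of zero-force lead-in/out
    trial_amp_jitter: float = 0.10    # lognormal sigma of per-trial gain
    gain_sigma: float = 0.15          # lognormal sigma of subject gains
    stance_range: tuple[float, float] = (0.6, 0.9)
    cadence_jitter: float = 0.05
    noise_floor: float = 0.05
    body_mass_mean: float = 69.0      # kg
    body_mass_sd: float = 8.0


def make_subject(master_seed: int, subject_id: str,
                 config: StudyConfig | None = None) -> SubjectParams:
    """Draw one subject's parameters, keyed by (master_seed, subject_id)."""
    config = config or StudyConfig()
    rng = _rng(master_seed, "subject", subject_id)
    gains = {m: float(np.exp(rng.normal(0.0, config.gain_sigma)))
             for m in CANONICAL_MUSCLES}
    stance = float(rng.uniform(*config.stance_range))
    mass = float(np.clip(rng.normal(config.body_mass_mean,
                                    config.body_mass_sd), 45.0, 110.0))
    return SubjectParams(subject_id=subject_id, gains=gains,
                         stance_duration=stance,
                         cadence_jitter=config.cadence_jitter,
                         noise_floor=config.noise_floor,
                         body_weight=mass * 9.81)


def generate_trial(subject: SubjectParams, env: str, trial_id: str,
                   effect: EnvironmentEffect, master_seed: int,
                   config: StudyConfig | None = None) -> TrialRecording:
    """Synthesize one trial: vGRF plus raw sEMG for the configured muscles."""
    config = config or StudyConfig()
    validate_environment(env)
    key = (subject.subject_id, env, trial_id)

    timing = _rng(master_seed, "timing", *key)
    duration = subject.stance_duration * (
        1.0 + subject.cadence_jitter * timing.uniform(-1.0, 1.0))
    vgrf = make_vgrf(duration, config.fs, subject.body_weight, config.pad)
    n_pad = int(round(config.pad * config.fs))
    n_stance = vgrf.shape[0] - 2 * n_pad

    emg = {}
    for m in config.muscles:
        stance_env = make_envelope(env, m, subject, effect, n_stance)
        amp = _rng(master_seed, "amp", *key, m)
        stance_env = stance_env * float(
            np.exp(amp.normal(0.0, config.trial_amp_jitter)))
        floor = subject.noise_floor * subject.gains.get(m, 1.0)
        full_env = np.concatenate([np.full(n_pad, floor), stance_env,
                                   np.full(n_pad, floor)])
        emg[m] = modulate_carrier(full_env, config.fs,
                                  derive_seed(master_seed, "carrier", *key, m))
    return TrialRecording(subject_id=subject.subject_id, environment=env,
                          trial_id=trial_id, vgrf=vgrf, emg=emg,
                          sampling_rate=config.fs)


def generate_trials(master_seed: int = 0,
                    effect: EnvironmentEffect | None = None,
                    config: StudyConfig | None = None):
    """Yield every trial of a synthetic study, in manifest order."""
    config = config or StudyConfig()
    effect = effect if effect is not None else default_environment_effect()
    for i in range(config.n_subjects):
        subject = make_subject(master_seed, f"S{i + 1:02d}", config)
        for env in ENVIRONMENTS:
            for t in range(config.trials_per_env):
                yield generate_trial(subject, env, f"T{t + 1}", effect,
                                     master_seed, config)


def generate_study(out_dir, master_seed: int = 0,
                   effect: EnvironmentEffect | None = None,
                   config: StudyConfig | None = None) -> pd.DataFrame:
    """Write a full synthetic study (trial TSVs + manifest.csv) to disk.

    The default configuration produces 27 subjects x 5 environments x
    5 trials = 675 trial files, 135 per environment.  Returns the manifest.
    """
    config = config or StudyConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in generate_trials(master_seed, effect, config):
        fname = f"{trial.subject_id}_{trial.environment}_{trial.trial_id}.tsv"
        write_trial(trial, out_dir / fname)
        rows.append({"subject_id": trial.subject_id,
                     "environment": trial.environment,
                     "trial_id": trial.trial_id,
                     "path": fname})
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
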