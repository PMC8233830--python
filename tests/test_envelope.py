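import numpy as np
import pytest

import gaitenv as g
from gaitenv.envelope import DegenerateReferenceError, FilterParameterError
from gaitenv.events import StanceWindow

FS = 1200.0


def _fft_amplitude(x, fs, freq):
    """Single-bin FFT amplitude oracle for a windowed sine."""
    n = x.shape[0]
    spec = np.fft.rfft(x * np.hanning(n))
    freqs = np.fft.rfftfreq(n, 1 / fs)
    scale = 2.0 / np.hanning(n).sum()
    return np.abs(spec[np.argmin(np.abs(freqs - freq))]) * scale


class TestBandpass:
    def test_dc_is_rejected(self):
        out = g.bandpass(np.ones(int(2 * FS)), FS)
        edge = int(0.25 * FS)
        assert np.max(np.abs(out[edge:-edge])) < 0.01

    def test_passband_sine_amplitude_preserved(self):
        t = np.arange(int(2 * FS)) / FS
        out = g.bandpass(np.sin(2 * np.pi * 100 * t), FS)
        assert abs(_fft_amplitude(out, FS, 100) - 1.0) < 0.02

    def test_stopband_sine_attenuated(self):
        t = np.arange(int(2 * FS)) / FS
        out = g.bandpass(np.sin(2 * np.pi * 5 * t), FS)
        assert _fft_amplitude(out, FS, 5) < 0.1

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(FilterParameterError):
            g.bandpass(np.zeros(100), fs=900.0, high=500.0)
        # 500 Hz is valid at 1200 Hz
        g.bandpass(np.zeros(100), fs=FS, high=500.0)


class TestRectify:
    def test_elementwise_absolute_value(self):
        np.testing.assert_array_equal(g.rectify([-1, 2, -3]), [1, 2, 3])

    def test_nonnegative_input_unchanged(self):
        x = np.array([0.0, 1.5, 2.0])
        np.testing.assert_array_equal(g.rectify(x), x)

    def test_gaussian_mean_matches_half_normal_closed_form(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        expected = np.sqrt(2 / np.pi)
        assert abs(g.rectify(x).mean() - expected) / expected < 0.02


class TestLowpassEnvelope:
    def test_dc_gain_unity(self):
        out = g.lowpass_envelope(np.full(int(2 * FS), 3.3), FS)
        edge = int(0.25 * FS)
        np.testing.assert_allclose(out[edge:-edge], 3.3, rtol=0.01)

    def test_rectified_sine_gives_two_over_pi(self):
        t = np.arange(int(2 * FS)) / FS
        out = g.lowpass_envelope(np.abs(np.sin(2 * np.pi * 100 * t)), FS)
        edge = int(0.25 * FS)
        expected = 2 / np.pi
        assert np.all(np.abs(out[edge:-edge] - expected) / expected < 0.05)

    def test_slow_amplitude_modulation_survives(self):
        # rectified 100 Hz sine modulated by a 1 Hz raised cosine: the
        # 10 Hz low-pass must keep the modulation intact
        t = np.arange(int(2 * FS)) / FS
        envelope = 0.5 * (1 - np.cos(2 * np.pi * 1.0 * t))
        out = g.lowpass_envelope(
            np.abs(np.sin(2 * np.pi * 100 * t)) * envelope, FS)
        assert np.corrcoef(out, envelope)[0, 1] > 0.99

    def test_output_nonnegative(self):
        x = np.abs(np.random.default_rng(1).standard_normal(2400))
        assert np.min(g.lowpass_envelope(x, FS)) >= 0.0


class TestNormalization:
    def test_reference_uses_stance_window_only(self):
        env = np.zeros(100)
        env[10:20] = 0.8   # inside stance
        env[50] = 1.2      # outside
        ref = g.compute_normalization_reference(
            [({"MG": env}, StanceWindow(5, 30))], "S01")
        assert ref.peaks["MG"] == pytest.approx(0.8)

    def test_reference_is_max_across_flat_trials(self):
        w = StanceWindow(0, 10)
        e1, e2 = np.full(10, 0.7), np.full(10, 0.9)
        ref = g.compute_normalization_reference(
            [({"MG": e1}, w), ({"MG": e2}, w)], "S01")
        assert ref.peaks["MG"] == pytest.approx(0.9)

    def test_all_zero_envelope_is_degenerate(self):
        with pytest.raises(DegenerateReferenceError, match="S01.*MG"):
            g.compute_normalization_reference(
                [({"MG": np.zeros(10)}, StanceWindow(0, 10))], "S01")

    def test_self_normalized_flat_trial_peaks_at_one(self):
        env = np.random.default_rng(2).random(100) + 0.1
        w = StanceWindow(10, 90)
        ref = g.compute_normalization_reference([({"MG": env}, w)], "S01")
        out = g.normalize(g.Envelope(env[w.slice()], FS, "MG"), ref)
        assert out.samples.max() == pytest.approx(1.0)

    def test_scale_invariance(self):
        env = np.random.default_rng(3).random(50) + 0.1
        w = StanceWindow(0, 50)
        out = []
        for c in (1.0, 2.0):
            ref = g.compute_normalization_reference(
                [({"MG": c * env}, w)], "S01")
            out.append(g.normalize(g.Envelope(c * env, FS, "MG"), ref).samples)
        np.testing.assert_allclose(out[0], out[1])

    def test_missing_muscle_in_reference(self):
        ref = g.NormalizationReference("S01", {"MG": 1.0})
        with pytest.raises(KeyError, match="TA"):
            g.normalize(g.Envelope(np.ones(5), FS, "TA"), ref)


class TestTimeNormalize:
    def test_linear_ramp_is_exact(self):
        for L in (2, 17, 555, 3000):
            out = g.time_normalize(np.linspace(0, 1, L))
            np.testing.assert_allclose(out, np.linspace(0, 1, 1000),
                                       atol=1e-12)

    def test_constant_input(self):
        np.testing.assert_array_equal(g.time_normalize(np.full(77, 2.5)),
                                      np.full(1000, 2.5))

    def test_identity_on_1000_point_input(self):
        x = np.random.default_rng(4).random(1000)
        np.testing.assert_array_equal(g.time_normalize(x), x)

    def test_endpoints_preserved(self):
        x = np.random.default_rng(5).random(137)
        out = g.time_normalize(x)
        assert out[0] == x[0] and out[-1] == x[-1]

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            g.time_normalize(np.ones(1))


@pytest.fixture(scope="module")
def trial_and_ref(subject, effect):
    trial = g.generate_trial(subject, "FGW", "T1", effect, master_seed=5)
    w = g.detect_stance(trial.vgrf, trial.sampling_rate)
    envs = {m: g.extract_envelope(trial.emg[m], trial.sampling_rate)
            for m in trial.muscles}
    ref = g.compute_normalization_reference([(envs, w)], subject.subject_id)
    return trial, w, ref


class TestBuildProfile:

    def test_all_muscle_vector_length(self, trial_and_ref):
        trial, w, ref = trial_and_ref
        profile = g.build_profile(trial, w, ref)
        assert profile.vector().shape == (11_000,)

    def test_single_muscle_vector_length(self, trial_and_ref):
        trial, w, ref = trial_and_ref
        assert g.build_profile(trial, w, ref, ("MG",)).vector().shape == (1000,)

    def test_subset_in_canonical_order(self, trial_and_ref):
        trial, w, ref = trial_and_ref
        profile = g.build_profile(trial, w, ref, ("MG", "LG", "Sol"))
        assert profile.muscles == ("Sol", "MG", "LG")
        assert profile.vector().shape == (3000,)

    def test_filter_before_crop_close_to_crop_before_filter(self, trial_and_ref):
        # with >=0.2 s pads the two orders agree to ~1% RMS
        trial, w, ref = trial_and_ref
        fs = trial.sampling_rate
        full = g.extract_envelope(trial.emg["MG"], fs)[w.slice()]
        pad = int(0.24 * fs)
        padded = g.extract_envelope(
            trial.emg["MG"][w.heel_strike - pad:w.toe_off + pad], fs)
        cropped = padded[pad:pad + w.n_samples]
        rms = np.sqrt(np.mean((full - cropped) ** 2))
        assert rms / np.sqrt(np.mean(full ** 2)) < 0.01

    def test_linearity_and_normalization_invariance(self, subject, effect):
        trial = g.generate_trial(subject, "FGW", "T2", effect, master_seed=5)
        fs = trial.sampling_rate
        w = g.detect_stance(trial.vgrf, fs)
        raw = trial.emg["MG"]
        e1 = g.extract_envelope(raw, fs)
        e2 = g.extract_envelope(3.0 * raw, fs)
        np.testing.assert_allclose(e2, 3.0 * e1, atol=1e-9 * np.max(e1))

    def test_recovered_profile_tracks_generator_ground_truth(
            self, trial_and_ref, subject, effect):
        trial, w, ref = trial_and_ref
        profile = g.build_profile(trial, w, ref, ("MG",))
        truth = g.make_envelope("FGW", "MG", subject, effect, w.n_samples)
        truth = g.time_normalize(truth)
        r = np.corrcoef(profile.data[0], truth)[0, 1]
        assert r > 0.95
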