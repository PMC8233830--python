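import numpy as np
import pytest

import gaitenv as g

FS = 1200.0


class TestMakeEnvelope:
    def test_single_centered_burst_peaks_at_middle(self, subject):
        eff = g.EnvironmentEffect(
            bursts={"FGW": {"MG": (g.Burst(0.5, 0.1, 1.0),)}})
        sub = g.SubjectParams("s", {"MG": 1.0}, noise_floor=0.0)
        env = g.make_envelope("FGW", "MG", sub, eff, 101)
        assert np.argmax(env) == 50

    def test_no_bursts_gives_constant_floor_times_gain(self):
        eff = g.EnvironmentEffect(bursts={"FGW": {"MG": ()}})
        sub = g.SubjectParams("s", {"MG": 2.0}, noise_floor=0.1)
        np.testing.assert_allclose(
            g.make_envelope("FGW", "MG", sub, eff, 10), 0.2)

    def test_zero_separation_environments_identical(self, subject):
        eff0 = g.default_environment_effect(0.0)
        envs = [g.make_envelope(e, "MG", subject, eff0, 300)
                for e in g.ENVIRONMENTS]
        for other in envs[1:]:
            np.testing.assert_array_equal(envs[0], other)

    def test_unknown_names_rejected(self, subject, effect):
        with pytest.raises(ValueError):
            g.make_envelope("XX", "MG", subject, effect, 10)
        with pytest.raises(ValueError):
            g.make_envelope("FGW", "GAS", subject, effect, 10)

    def test_deterministic(self, subject, effect):
        a = g.make_envelope("US", "Sol", subject, effect, 500)
        b = g.make_envelope("US", "Sol", subject, effect, 500)
        np.testing.assert_array_equal(a, b)


class TestModulateCarrier:
    def test_zero_envelope_gives_zero_signal(self):
        out = g.modulate_carrier(np.zeros(1000), FS, seed=0)
        np.testing.assert_array_equal(out, np.zeros(1000))

    def test_constant_envelope_mean_abs_matches_carrier(self):
        # Monte-Carlo oracle for E|carrier| on an independent draw
        c = 2.5
        n = 100_000
        out = g.modulate_carrier(np.full(n, c), FS, seed=42)
        oracle = np.abs(g.modulate_carrier(np.ones(n), FS, seed=43)).mean()
        assert abs(np.abs(out).mean() - c * oracle) / (c * oracle) < 0.05

    def test_full_chain_demodulates_single_burst(self):
        n = int(FS)  # 1 s stance
        t = np.linspace(0, 1, n)
        envelope = np.exp(-0.5 * ((t - 0.5) / 0.1) ** 2)
        raw = g.modulate_carrier(envelope, FS, seed=7)
        recovered = g.extract_envelope(raw, FS)
        assert np.corrcoef(envelope, recovered)[0, 1] > 0.95

    def test_reproducible_from_seed(self):
        a = g.modulate_carrier(np.ones(500), FS, seed=9)
        b = g.modulate_carrier(np.ones(500), FS, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            g.modulate_carrier(np.ones(100), 800.0, seed=0)


class TestMakeVgrf:
    def test_onset_index_by_construction(self):
        v = g.make_vgrf(0.72, FS, 700.0, pad=0.2)
        first = int(np.flatnonzero(v > 20.0)[0])
        assert abs(first - 240) <= 2

    def test_zero_in_both_pads_and_minimum_zero(self):
        v = g.make_vgrf(0.72, FS, 700.0, pad=0.2)
        n_pad = int(0.2 * FS)
        assert np.all(v[:n_pad] == 0.0) and np.all(v[-n_pad:] == 0.0)
        assert v.min() == 0.0

    def test_peak_bounded_by_body_weight_multiples(self):
        for bw in (500.0, 700.0, 900.0):
            v = g.make_vgrf(0.8, FS, bw, pad=0.1)
            assert 1.0 * bw <= v.max() <= 1.3 * bw

    def test_above_threshold_through_mid_stance(self):
        v = g.make_vgrf(0.72, FS, 700.0, pad=0.2)
        n_pad, n_st = int(0.2 * FS), int(round(0.72 * FS))
        core = v[n_pad + int(0.02 * n_st):n_pad + int(0.98 * n_st)]
        assert np.all(core > 20.0)

    def test_double_bump_with_valley(self):
        v = g.make_vgrf(0.72, FS, 700.0, pad=0.2)
        n_pad, n_st = int(0.2 * FS), int(round(0.72 * FS))
        stance = v[n_pad:n_pad + n_st]
        early = stance[:n_st // 2].max()
        late = stance[n_st // 2:].max()
        valley = stance[int(0.4 * n_st):int(0.6 * n_st)].min()
        assert valley < 0.8 * min(early, late)


class TestGenerateStudy:
    def test_counts_and_manifest_shape(self, tmp_path):
        cfg = g.StudyConfig(n_subjects=2, trials_per_env=1)
        manifest = g.generate_study(tmp_path, master_seed=3, config=cfg)
        assert len(manifest) == 10  # 2 subjects x 5 environments x 1 trial
        assert (manifest.groupby("environment").size() == 2).all()
        assert (tmp_path / "manifest.csv").exists()
        assert all((tmp_path / p).exists() for p in manifest["path"])

    def test_same_master_seed_gives_byte_identical_files(self, tmp_path):
        cfg = g.StudyConfig(n_subjects=1, trials_per_env=1,
                            muscles=("MG", "TA"))
        a, b = tmp_path / "a", tmp_path / "b"
        ma = g.generate_study(a, master_seed=9, config=cfg)
        g.generate_study(b, master_seed=9, config=cfg)
        for p in list(ma["path"]) + ["manifest.csv"]:
            assert (a / p).read_bytes() == (b / p).read_bytes()

    def test_default_shape_reproduces_study_counts(self):
        cfg = g.StudyConfig()
        n_per_env = cfg.n_subjects * cfg.trials_per_env
        assert n_per_env == 135
        assert n_per_env * len(g.ENVIRONMENTS) == 675

    def test_randomness_keyed_not_global(self, subject, effect):
        # drawing in a different order must not change a trial
        t1 = g.generate_trial(subject, "US", "T1", effect, master_seed=4)
        _ = g.generate_trial(subject, "DW", "T9", effect, master_seed=4)
        t2 = g.generate_trial(subject, "US", "T1", effect, master_seed=4)
        np.testing.assert_array_equal(t1.emg["MG"], t2.emg["MG"])
        np.testing.assert_array_equal(t1.vgrf, t2.vgrf)

    def test_trials_differ_across_seeds_and_ids(self, subject, effect):
        t1 = g.generate_trial(subject, "US", "T1", effect, master_seed=4)
        t2 = g.generate_trial(subject, "US", "T2", effect, master_seed=4)
        t3 = g.generate_trial(subject, "US", "T1", effect, master_seed=5)
        assert not np.array_equal(t1.emg["MG"], t2.emg["MG"])
        assert not np.array_equal(t1.emg["MG"], t3.emg["MG"])


class TestSeparationMonotonicity:
    def test_classification_tracks_environment_separation(self):
        """Accuracy rises from chance to high as separation goes 0 -> 1."""
        accs = {}
        for sep in (0.0, 0.5, 1.0):
            cfg = g.StudyConfig(n_subjects=6, trials_per_env=2,
                                muscles=("Sol", "MG", "LG"))
            eff = g.default_environment_effect(sep)
            pc = g.PipelineConfig(split_seed=21,
                                  ann=g.AnnConfig(seed=21, epochs=60))
            ds = g.build_dataset(g.generate_trials(21, eff, cfg), pc)
            accs[sep], _ = g.evaluate_subset(ds, cfg.muscles, pc)
        assert accs[0.0] <= 45.0          # near chance for 5 classes
        assert accs[1.0] >= 85.0
        assert accs[0.0] - 10 <= accs[0.5] <= accs[1.0] + 10
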