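import numpy as np
import pytest

import gaitenv as g


@pytest.fixture(scope="session")
def small_study():
    """A 4-subject, 2-trials-per-environment synthetic study (40 trials)."""
    cfg = g.StudyConfig(n_subjects=4, trials_per_env=2)
    trials = list(g.generate_trials(master_seed=11, config=cfg))
    return cfg, trials


@pytest.fixture(scope="session")
def small_dataset(small_study):
    """Profiles for the small study plus the pipeline config that built them."""
    _, trials = small_study
    pc = g.PipelineConfig(split_seed=11,
                          ann=g.AnnConfig(seed=11, epochs=80))
    return pc, g.build_dataset(trials, pc)


@pytest.fixture(scope="session")
def subject():
    return g.make_subject(5, "S01")


@pytest.fixture(scope="session")
def effect():
    return g.default_environment_effect()


@pytest.fixture
def simple_trial():
    """Tiny hand-built trial: vGRF plus two muscles, 2400 samples."""
    rng = np.random.default_rng(0)
    n = 2400
    vgrf = g.make_vgrf(1.0, 1200.0, 700.0, pad=0.5)[:n]
    return g.TrialRecording(
        subject_id="S01", environment="FGW", trial_id="T1",
        vgrf=vgrf,
        emg={"MG": rng.standard_normal(n), "TA": rng.standard_normal(n)},
        sampling_rate=1200.0,
    )
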