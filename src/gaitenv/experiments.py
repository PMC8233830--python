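"""End-to-end pipeline: raw trials -> profiles -> trained models -> reports.

``build_dataset`` runs stance detection and envelope extraction over a
collection of trials, computes each subject's flat-ground normalization
reference, and assembles the labeled profile dataset.
``run_subset_experiments`` then reproduces the muscle-ablation grid: one
freshly trained network per muscle subset (all 11 muscles, the six
per-joint flexor/extensor groups, and each individual muscle), all using
the same split seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .ann import AnnConfig, predict, train_ann
from .dataset import ProfileDataset, split_dataset
from .envelope import (
    build_profile,
    compute_normalization_reference,
    extract_envelope,
)
from .events import detect_stance
from .io import TrialRecording, read_manifest, read_trial
from .metrics import ConfusionMatrix, EvalReport, accuracy, \
    confusion_from_predictions
from .muscles import CANONICAL_MUSCLES, MUSCLE_GROUPS, canonical_sort


def default_subset_grid() -> dict[str, tuple[str, ...]]:
    """The 18-experiment grid: all muscles, 6 joint groups, 11 singles."""
    grid: dict[str, tuple[str, ...]] = {"all": CANONICAL_MUSCLES}
    grid.update(MUSCLE_GROUPS)
    for m in CANONICAL_MUSCLES:
        grid[m] = (m,)
    return grid


@dataclass
class PipelineConfig:
    """Settings for the full analysis, echoed into every report."""

    onset_threshold: float = 20.0
    offset_threshold: float = 20.0
    strict_zero_offset: bool = False
    min_stance_s: float = 0.2
    band: tuple[float, float] = (20.0, 500.0)
    band_order: int = 4
    lp_cutoff: float = 10.0
    lp_order: int = 4
    test_fraction: float = 0.2
    split_mode: str = "trial"
    split_seed: int = 0
    ann: AnnConfig = field(default_factory=AnnConfig)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("onset_threshold", "offset_threshold", "strict_zero_offset",
              "min_stance_s", "band", "band_order", "lp_cutoff", "lp_order",
              "test_fraction", "split_mode", "split_seed")}
        d["band"] = list(self.band)
        d["ann"] = self.ann.to_dict()
        return d


def _stance(trial: TrialRecording, config: PipelineConfig):
    return detect_stance(trial.vgrf, trial.sampling_rate,
                         config.onset_threshold, config.offset_threshold,
                         strict_zero=config.strict_zero_offset,
                         min_stance_s=config.min_stance_s)


def build_dataset(trials, config: PipelineConfig | None = None,
                  muscles=None) -> ProfileDataset:
    """Profiles for every trial, normalized per subject by flat-ground peaks.

    ``trials`` is any iterable of :class:`TrialRecording`; it must include
    at least one flat-ground (FGW) trial for every subject, from which the
    per-subject, per-muscle normalization references are computed (maximum
    stance-phase envelope across all of that subject's FGW trials).
    """
    config = config or PipelineConfig()
    trials = list(trials)
    if muscles is None:
        muscles = trials[0].muscles
    muscles = canonical_sort(muscles)
    fk = dict(low=config.band[0], high=config.band[1],
              band_order=config.band_order, lp_cutoff=config.lp_cutoff,
              lp_order=config.lp_order)

    windows = [_stance(t, config) for t in trials]

    flat: dict[str, list] = {}
    for trial, window in zip(trials, windows):
        if trial.environment == "FGW":
            envs = {m: extract_envelope(trial.emg[m], trial.sampling_rate,
                                        **fk) for m in muscles}
            flat.setdefault(trial.subject_id, []).append((envs, window))

    refs = {}
    for subject_id, pairs in flat.items():
        refs[subject_id] = compute_normalization_reference(pairs, subject_id)

    profiles = []
    for trial, window in zip(trials, windows):
        if trial.subject_id not in refs:
            raise ValueError(
                f"subject {trial.subject_id} has no flat-ground trial to "
                "normalize against")
        profiles.append(build_profile(trial, window, refs[trial.subject_id],
                                      muscles, **fk))
    return ProfileDataset(profiles)


def load_trials(manifest_path) -> list[TrialRecording]:
    """Read every trial referenced by a manifest CSV (paths are relative)."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    return [read_trial(base / row["path"], row)
            for _, row in manifest.iterrows()]


@dataclass
class SubsetResult:
    name: str
    muscles: tuple[str, ...]
    accuracy: float
    cm: ConfusionMatrix
    report: EvalReport


def evaluate_subset(dataset: ProfileDataset, muscles,
                    config: PipelineConfig) -> tuple[float, ConfusionMatrix]:
    """Restrict, re-split with the configured seed, train fresh, evaluate."""
    sub = split_dataset(dataset.restrict(muscles), config.test_fraction,
                        config.split_seed, config.split_mode)
    X_train, y_train = sub.train_arrays()
    X_test, y_test = sub.test_arrays()
    model = train_ann(X_train, y_train, config.ann)
    cm = confusion_from_predictions(y_test, predict(model, X_test))
    return accuracy(cm), cm


def run_subset_experiments(dataset: ProfileDataset,
                           subsets: dict[str, tuple[str, ...]] | None = None,
                           config: PipelineConfig | None = None
                           ) -> list[SubsetResult]:
    """Train and evaluate one fresh model per named muscle subset.

    Every subset re-splits the restricted dataset with the same seed, so
    the same trials land in the test set across subsets.
    """
    config = config or PipelineConfig()
    subsets = subsets if subsets is not None else default_subset_grid()
    if not subsets:
        raise ValueError("subset grid is empty")
    results = []
    for name, muscles in subsets.items():
        muscles = canonical_sort(muscles)
        acc, cm = evaluate_subset(dataset, muscles, config)
        report = EvalReport(cm=cm, muscles=muscles, seed=config.split_seed,
                            config=config.to_dict())
        results.append(SubsetResult(name=name, muscles=muscles, accuracy=acc,
                                    cm=cm, report=report))
    return results
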