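"""Labeled profile collections and train/test partitioning.

The default split is trial-level and stratified: each environment
contributes the same fraction of its trials to the test set (with 135
trials per environment and a 0.2 test fraction, 27 test and 108 training
trials per environment).  Trial-level splitting leaks subject identity
between train and test — the same participant appears on both sides — so a
subject-wise mode that holds out whole subjects is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .envelope import StanceProfile
from .muscles import canonical_sort

TRAIN, TEST = "train", "test"


@dataclass
class ProfileDataset:
    """Stance profiles with environment labels and an optional partition."""

    profiles: list[StanceProfile]
    partition: np.ndarray | None = None  # TRAIN/TEST per profile

    def __post_init__(self):
        if not self.profiles:
            raise ValueError("dataset must contain at least one profile")
        muscle_sets = {p.muscles for p in self.profiles}
        if len(muscle_sets) != 1:
            raise ValueError(
                f"profiles mix muscle sets: {sorted(muscle_sets)}")
        if self.partition is not None:
            self.partition = np.asarray(self.partition)
            if self.partition.shape[0] != len(self.profiles):
                raise ValueError("partition length mismatch")

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def muscles(self) -> tuple[str, ...]:
        return self.profiles[0].muscles

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.profiles])

    @property
    def subject_ids(self) -> np.ndarray:
        return np.array([p.subject_id for p in self.profiles])

    def matrix(self) -> np.ndarray:
        """(n_profiles, 1000 x n_muscles) input matrix."""
        return np.vstack([p.vector() for p in self.profiles])

    def restrict(self, muscles) -> "ProfileDataset":
        """Dataset restricted to a muscle subset; partition is preserved."""
        muscles = canonical_sort(muscles)
        return ProfileDataset([p.restrict(muscles) for p in self.profiles],
                              None if self.partition is None
                              else self.partition.copy())

    def _part(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        if self.partition is None:
            raise ValueError("dataset has no partition; call split_dataset")
        mask = self.partition == which
        return self.matrix()[mask], self.labels[mask]

    def train_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self._part(TRAIN)

    def test_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self._part(TEST)


def split_dataset(dataset: ProfileDataset, test_fraction: float = 0.2,
                  seed: int = 0, mode: str = "trial") -> ProfileDataset:
    """Assign a train/test partition; deterministic given the seed.

    ``mode="trial"`` stratifies by environment so each class contributes
    ``test_fraction`` of its trials to the test set.  ``mode="subject"``
    holds out whole subjects (all their trials in every environment).
    """
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must lie in [0, 1)")
    n = len(dataset)
    part = np.array([TRAIN] * n, dtype=object)
    rng = np.random.default_rng(seed)
    if mode == "trial":
        labels = dataset.labels
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            if test_fraction > 0 and idx.size < 2:
                raise ValueError(
                    f"class {lab} has {idx.size} trial(s); need >= 2 to split")
            n_test = int(round(test_fraction * idx.size))
            take = rng.permutation(idx)[:n_test]
            part[take] = TEST
    elif mode == "subject":
        subjects = dataset.subject_ids
        uniq = np.array(sorted(set(subjects)))
        n_test = max(1, int(round(test_fraction * uniq.size))) \
            if test_fraction > 0 else 0
        held_out = rng.permutation(uniq)[:n_test]
        part[np.isin(subjects, held_out)] = TEST
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    return ProfileDataset(list(dataset.profiles), part)
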