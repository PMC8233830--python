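"""Train the walking-environment classifier on a synthetic study.

Runs the full pipeline on a reduced study (8 subjects, 2 trials per
environment), then trains one model on all 11 muscles and one on the
ankle plantarflexors only, reporting test accuracy and the all-muscle
confusion matrix.
"""

import gaitenv as g

config = g.StudyConfig(n_subjects=8, trials_per_env=2)
pipeline = g.PipelineConfig(split_seed=1, ann=g.AnnConfig(seed=1))

trials = g.generate_trials(master_seed=1, config=config)
dataset = g.build_dataset(trials, pipeline)
print(f"dataset: {len(dataset)} profiles, "
      f"input width {dataset.matrix().shape[1]}")

for name, muscles in [("all 11 muscles", g.CANONICAL_MUSCLES),
                      ("ankle extensors (Sol, MG, LG)", ("Sol", "MG", "LG")),
                      ("EDL only", ("EDL",))]:
    acc, cm = g.evaluate_subset(dataset, muscles, pipeline)
    print(f"{name:32s} test accuracy {acc:5.1f}%  (n={cm.total})")

acc, cm = g.evaluate_subset(dataset, g.CANONICAL_MUSCLES, pipeline)
print("\nall-muscle confusion counts (rows actual, cols predicted, "
      "FGW US DS UW DW):")
print(cm.counts)
# With the default environment separation the all-muscle and
# ankle-extensor models approach 100% on synthetic data, while EDL-only
# stays far lower -- the same qualitative ranking the method shows on
# real recordings.
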