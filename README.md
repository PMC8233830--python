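# gaitenv

Classify the environment a person is walking in — flat ground, upstairs,
downstairs, uphill or downhill — from lower-extremity surface EMG alone.

`gaitenv` implements the complete analysis pipeline as a reusable Python
library: stance-phase segmentation from the vertical ground reaction force
(vGRF), sEMG linear-envelope extraction and normalization, assembly of
whole-stance muscle-activation profiles, a single-hidden-layer neural-network
classifier of the five walking environments, and confusion-matrix evaluation.
Because the original study's raw recordings are not publicly deposited, the
package also ships a synthetic gait-signal generator that emulates the
statistical structure the pipeline assumes, so every stage is testable end to
end, plus the study's printed confusion matrices for exact re-analysis.

It is aimed at researchers in gait biomechanics and assistive-device control
(exoskeletons, prostheses) who want a documented, tested reference
implementation of this terrain-recognition approach.

## Method

Per trial (one force-plate contact, up to 11 sEMG channels at 1200 Hz):

1. **Stance detection.** Heel strike is the first frame with vGRF > 20 N;
   toe-off is the first frame after the post-heel-strike force peak with
   vGRF back below threshold (a strict return-to-0 N mode is available).
2. **Linear envelopes.** Each raw channel is band-pass filtered
   (fourth-order Butterworth, 20–500 Hz, zero-phase), full-wave rectified,
   and low-pass filtered (fourth-order Butterworth, 10 Hz, zero-phase).
3. **Normalization.** Envelopes are divided, per subject and muscle, by the
   peak stance-phase envelope amplitude from that subject's flat-ground
   trials, then linearly interpolated to 1000 points spanning 0–100% of
   stance.
4. **Classification.** The concatenated profile (1000 points × muscles, in
   the fixed order RF, VL, VM, ST, BF, TA, Sol, MG, LG, FHL, EDL) feeds a
   network with one ReLU hidden layer and a 5-way softmax output, trained
   with Adam on softmax cross-entropy over an 80/20 stratified split.
5. **Evaluation.** Accuracy = N_correct/N_total × 100; row-normalized
   confusion matrices a_ij = b_ij/b_total,i × 100; one-vs-rest
   sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP) per environment.
   A muscle-ablation grid (all muscles, six per-joint flexor/extensor
   groups, each single muscle) trains one fresh model per subset.

## Worked example

```python
import gaitenv as g

config = g.StudyConfig(n_subjects=8, trials_per_env=2)
pipeline = g.PipelineConfig(split_seed=1, ann=g.AnnConfig(seed=1))
dataset = g.build_dataset(g.generate_trials(master_seed=1, config=config),
                          pipeline)
for name, muscles in [("all 11 muscles", g.CANONICAL_MUSCLES),
                      ("ankle extensors", ("Sol", "MG", "LG")),
                      ("EDL only", ("EDL",))]:
    acc, cm = g.evaluate_subset(dataset, muscles, pipeline)
    print(f"{name:16s} test accuracy {acc:5.1f}%  (n={cm.total})")
```

prints

```
all 11 muscles   test accuracy 100.0%  (n=15)
ankle extensors  test accuracy 100.0%  (n=15)
EDL only         test accuracy  20.0%  (n=15)
```

i.e. with the default synthetic environment separation, profiles from all
muscles (or from the ankle plantarflexors, the most environment-sensitive
channels) identify the walking environment essentially perfectly, while the
least informative channel (EDL) falls toward the 20% chance level of five
balanced classes.  Longer narrative scripts live in `examples/`; a thin CLI
(`gaitenv simulate|run|train|evaluate|check-tables`) wraps the same calls.

Re-analysis of the study's printed confusion matrices:

```
$ gaitenv check-tables
accuracy:all             computed   96.3 published   96.3  PASS
accuracy:knee_flexors    computed   75.6 published   75.6  PASS
...
specificity:UW           computed   99.1 published  100.0  KNOWN DISCREPANCY
```

(the published uphill-specificity cell disagrees with the published
confusion matrix it derives from; counts are treated as authoritative).

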