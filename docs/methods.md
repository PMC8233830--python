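# Methods

## The analysis

`gaitenv` classifies the walking environment (flat ground FGW, upstairs US,
downstairs DS, uphill UW, downhill DW; labels 1–5) from the whole
stance-phase activation profile of lower-extremity muscles, with no
handcrafted time- or frequency-domain features: the time-normalized linear
envelopes themselves are the classifier input.

### Stance detection

Heel strike is the first frame with vGRF > 20 N.  The literal offset
criterion "force returns to 0 N" is not robust on a real force plate (noise
may keep the signal from ever reaching exactly zero), so the default
toe-off is the first frame *after the post-heel-strike force maximum* with
vGRF below a symmetric 20 N threshold; restricting the search to after the
peak keeps the mid-stance valley of the double-bump profile from firing it.
A `strict_zero` mode implements the literal 0 N rule for noiseless traces.
Windows are half-open `[heel_strike, toe_off)` in 0-based sample indices,
so concatenated windows never double-count a frame; windows shorter than a
configurable 0.2 s minimum are rejected as implausible.  Only the first
stance per trial is extracted (one force-plate contact per trial).

### Envelope extraction

Per channel: fourth-order Butterworth band-pass 20–500 Hz, full-wave
rectification, fourth-order Butterworth low-pass 10 Hz.  Both filters are
applied zero-phase (forward–backward, `sosfiltfilt`), because offline
envelope extraction must not introduce phase lag that would desynchronize
muscles; this doubles the effective order, which we accept and document
rather than compensate.  The band-pass passes the order parameter to the
design routine directly (the `butter(4, [20 500])` convention, four poles
per band edge).  Filtering runs on the full trial *before* cropping to the
stance window, so filter edge transients stay in the zero-force pads; with
≥ 0.2 s pads, filter-then-crop and crop-then-filter agree to better than
1% RMS.  Small negative low-pass ringing is clamped to 0 so envelope
nonnegativity is an enforceable invariant.

### Normalization and time normalization

Each subject's reference per muscle is the **maximum stance-phase envelope
amplitude across all of that subject's flat-ground trials** (a
per-single-trial mode exists: pass one trial).  The reference is taken
inside the stance window only.  Non-flat environments may therefore exceed
1.0 after normalization, as real uphill/stair data would.  A non-positive
or non-finite reference raises an error naming subject and muscle rather
than propagating silently.  Normalized stance envelopes are linearly
interpolated onto 1000 points spanning 0–100% of stance inclusive of both
endpoints; a length-1000 input is reproduced exactly.  Profiles concatenate
muscles in the fixed canonical order RF, VL, VM, ST, BF, TA, Sol, MG, LG,
FHL, EDL, giving an input width of 1000 × |muscle set| (11 000 for all
channels).

### Classifier

A single-hidden-layer network in plain numpy: input → 100 ReLU units →
5 logits, mean softmax cross-entropy, Adam (β₁ 0.9, β₂ 0.999, ε 1e-8),
learning rate 1e-3, mini-batches of 32, He-uniform initialization, 300
epochs by default.  The source study states none of these values, so they
are package choices, exposed in `AnnConfig` and echoed into every report;
300 epochs trains the full synthetic study comfortably past convergence on
one CPU.  Training is exactly reproducible from the seed (one
`default_rng` drives initialization and batch shuffling).  Argmax ties
break toward the lowest label index.  The analytic gradients are verified
against central finite differences in the test suite.

The default split is trial-level, stratified by environment (80/20; with
135 trials per environment that is 108 train / 27 test per class, matching
the study's design).  Trial-level splitting leaks subject identity across
the split — the same person contributes to both sides — so a subject-wise
mode that holds out whole subjects is provided and flagged, not silently
substituted.  The muscle-ablation grid trains one *fresh* model per subset
(all 11; knee flexors ST+BF; knee extensors VL+VM+RF; ankle flexor TA;
ankle extensors Sol+MG+LG; MTP flexor FHL; MTP extensor EDL; each single
muscle — 18 experiments), every subset re-splitting with the same seed.

### Evaluation

All metrics are computed on integer counts; percentages are presentation
only (averaging printed rounded percentages gives 68.16 for the quadriceps
block where counts give the published 68.1).  Row-normalized percent
matrices, accuracy, and one-vs-rest sensitivity/specificity follow the
standard definitions; degenerate denominators return NaN ("undefined"),
never 0.  Printed percent matrices are converted back to counts by
requiring each cell × n/100 to land strictly within 0.5 of an integer and
each row to sum to n.

### Published-table re-analysis

The packaged CSV fixtures transcribe the study's printed row-percent
confusion matrices (27 test trials per row).  Three print defects are
handled explicitly: the published uphill specificity (100) contradicts the
published all-muscle matrix (one DW→UW error ⇒ 107/108 = 99.1%) and is
flagged as a known discrepancy; the joint-group table's MTP-extensor
block disagrees in one cell with the identical single-muscle EDL block
(which sums correctly) and the consistent value is used; and the VL uphill
and VM upstairs rows do not sum to 100% as printed, so those two matrices'
full counts are unrecoverable — their accuracies are still re-derived from
the diagonal cells, which are consistent with the published accuracy list.

## The synthetic generator

No raw data are deposited, so the generator is an explicit stand-in with
documented structure, not a physiological simulation.

* **Envelopes.** Per muscle, activation over normalized stance time is a
  sum of Gaussian bursts.  Flat-ground templates follow textbook gait EMG
  timing (quadriceps burst in loading response, hamstrings around heel
  strike, TA biphasic, plantarflexors and FHL at push-off, EDL early).
  Each environment scales burst amplitudes and shifts burst centers
  relative to flat ground with a distinct signature (e.g. upstairs
  +45% amplitude / earlier peak, downstairs −30% / later), in proportion
  to a per-muscle sensitivity: largest for Sol/MG/LG (push-off work
  changes most across terrains, which is also the joint-moment rationale
  the field offers for ankle-extensor importance), smallest for EDL
  (0.15).  A single `separation` scale in [0, 1] multiplies all of these
  deltas; at 0 the five environments are statistically identical.
* **Carrier.** Raw sEMG is the envelope times Gaussian white noise
  band-limited to 20–450 Hz (inside the analysis pass-band and below
  Nyquist at 1200 Hz, so the band-pass is nearly transparent and envelope
  recovery is isolated from roll-off effects) and scaled to unit standard
  deviation.  Rectify + low-pass then recovers the envelope up to the
  half-normal factor √(2/π), which cancels under flat-ground-peak
  normalization.
* **vGRF.** Two Gaussian bumps (1.1 and 1.0 × body weight at 27% and 73%
  of stance, width 0.15) with a mid-stance valley, multiplied by a linear
  ramp over 0.5% of stance at each end so the trace is exactly zero in the
  0.25 s pads and crosses 20 N within ~2 samples of the true boundary.
* **Variability.**  Per subject (keyed by subject id): lognormal per-muscle
  gains (σ 0.15), stance duration uniform on 0.6–0.9 s, body mass
  N(69, 8) kg.  Per trial: ±5% uniform cadence jitter and lognormal
  (σ 0.10) per-muscle amplitude jitter; plus a resting noise floor at 5%
  of peak activation.  The study reports no variance figures, so these are
  the package's own choices of what plausible inter-subject and
  trial-to-trial variability looks like; they were fixed when the
  generator was designed.
* **Determinism.**  Every draw is keyed by
  (master_seed, purpose, subject, environment, trial, channel) through a
  BLAKE2 hash, so trials are reproducible individually and independent of
  generation order; no global random state is used.

Default study shape mirrors the real protocol: 27 subjects × 5
environments × 5 trials = 675 trials, 135 per environment, 1200 Hz.

**What passing on synthetic data does and does not show.**  The generator
realizes the structure the pipeline assumes — amplitude-modulated broadband
sEMG, clean vGRF threshold crossings, environment-dependent envelope
shapes with ankle-extensor dominance.  Passing tests therefore validate
the *implementation* (demodulation fidelity, event recovery, classifier
capacity and chance floor, the qualitative muscle-importance ranking), not
the real-world claim: real sEMG has electrode noise, crosstalk,
non-Gaussian carriers, fatigue drift and subject idiosyncrasies the
generator omits, and real accuracies (e.g. 96.3% with all muscles) cannot
be re-derived without the undeposited recordings.  On synthetic data the
all-muscle and ankle-extensor models saturate near 100% while EDL-only
falls toward chance — the published ordering, compressed at the top.

## Problem sizes used in checks

The test suite and the acceptance script run the full 675-trial synthetic
study for the headline end-to-end numbers (all-muscle, ankle-extensor and
EDL models at 150 epochs; label-shuffled control at 60 epochs, test n =
135), and reduced studies (2–8 subjects, 1–2 trials per environment,
30–100 epochs) for determinism, monotonicity and plumbing checks — sizes
chosen to keep a full run in minutes on one CPU while preserving the
study's per-environment balance.

## Known limitations

* The ANN hyperparameters and the trial-level split are under-specified in
  the source; results under subject-wise splitting are expected to be
  lower and are not part of any packaged claim.
* The generator's environment signatures are stylized; it cannot be used
  to estimate real-world classification accuracy, only to exercise the
  pipeline.
* `counts_from_percent` requires consistent printed matrices; genuinely
  inconsistent prints (two of the 18 published matrices) are only
  recoverable at the diagonal.
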