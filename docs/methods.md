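# Methods

`physioload` implements a complete analysis chain for multimodal assessment
of mental workload in an n-back experiment: a synthetic-recording generator
that reproduces the experiment's block design, per-segment feature
extraction for EEG, peripheral physiology and eye measures, individually
trained classifiers evaluated under a simulated-online protocol, and exact
binomial group statistics. This note records the model assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Experimental structure emulated by the generator

Each of 14 simulated participants completes 4 sessions. A session opens
with a 2-min fixation baseline and continues with six 2-min workload
blocks: two repetitions each of 0-back, 1-back and 2-back in pseudorandom
order, constrained so that every condition occurs once in each half of the
session and equal conditions are never adjacent. A workload block presents
48 consonants at a 2.5 s stimulus-onset asynchrony; exactly one third are
targets under the n-back rule of the block's condition (in 0-back the
target letter is `x`). This gives 28 blocks and 56 min of task time in
total. Blocks are separated by a 10 s gap standing in for the rating
periods of a real experiment; gaps and baselines do not advance the
workload-task clock used by the `time` feature, so the first workload block
has mid-time 60 s and the second 180 s.

## Signal models

The generators are deliberately minimal surrogates — they reproduce the
statistical structure the feature extractors and classifiers consume, not
biophysics:

* **EEG** (7 channels, 256 Hz, µV): 1/f-shaped Gaussian background
  (9 µV RMS), a 10 Hz alpha oscillation whose amplitude shrinks with
  workload (largest over Pz), a 6 Hz theta oscillation growing with
  workload (largest over Fz), and a stimulus-locked P300-like deflection
  (one-cycle raised cosine spanning 0.3–0.5 s, largest at Pz) attenuating
  with workload. Oscillation phase follows a random walk
  (2.5 rad²/s) because real cortical rhythms decohere within about a
  second; without this, a fixed SOA phase-locks the oscillation to every
  stimulus and its amplitude leaks coherently into the trial-averaged ERP.
  About 1% of trials receive a high-amplitude artifact (SD 200 µV) that
  the rejection rule must remove.
* **ECG** (300 Hz, mV): raised-cosine QRS-like pulses at cumulative
  inter-beat intervals. The interval is 0.80 s at rest, shortens by 15 ms
  at full workload and by 8 µs per second of time on task, and is modulated
  at 0.10 Hz and 0.30 Hz (mid- and high-band HRV) with a depth that
  workload suppresses by 30%. The exact R-peak times are retained as ground
  truth for validating the detector.
* **Respiration** (300 Hz): a phase-integrated oscillation at 0.25 Hz
  base rate, +10% at full workload, with additive noise.
* **Skin conductance** (300 Hz, µS): tonic level 5 µS, +0.5 µS at full
  workload, upward time drift, slow noise, and an exponentially decaying
  1.5 µS peak at every block onset (which is why the block minimum is a
  feature distinct from the mean).
* **Gaze** (60 Hz): per-eye pupil diameter around 3.2 mm, +0.3 mm at full
  workload; blinks are Poisson events (18/min at rest, −40% at full
  workload) realized as runs of 2–25 frames in which both eyes are invalid,
  plus rarer tracking-loss runs longer than 25 frames that exercise the
  detector's upper bound. Injected events are kept as ground truth.

Workload enters every effect through a per-condition weight
(0-back = 0, 1-back = 0.45, 2-back = 1); the asymmetric spacing encodes
that a 2-back step costs more than a 1-back step, which yields the
difficulty ordering 2v0 > 2v1 > 1v0 downstream. Between-block variability —
the quantity that actually limits block-level classification — is injected
as per-block random offsets (peripheral levels) and per-block lognormal
amplitude jitter (EEG components, HRV depth).

The effect sizes and jitters are free parameters: the study this package
models does not quantify them. The defaults were tuned once so that
default-settings accuracies are realistic for this kind of data (EEG group
near 0.86, eye near 0.8, peripheral physiology clearly weaker but above
chance) and then frozen; they are calibration, not ground truth. What
passing tests show is therefore that the *pipeline* behaves correctly and
that the *orderings* among modalities and contrasts are as configured — not
that real recordings would yield these numbers. Features of real data the
generator does not emulate include eye-movement and ocular EEG artifacts,
ectopic beats, electrode drift and nonstationary noise, and any
trial-by-trial coupling between modalities.

## Feature definitions

* **EEG.** Epochs span −0.5 to +2.0 s around each stimulus and are shifted
  so the mean of the first 500 ms is zero. A trial is rejected when its SD
  exceeds 100 µV on *any* channel (the conservative reading of whole-trial
  discarding; whether the original analysis pooled channels is unstated).
  No ocular-artifact correction is applied. Per block: the trial-averaged
  ERP resampled to 100 Hz (anti-aliased polyphase; the 0.01 s grid contains
  both 0 and 1.0 s, hence 101 samples per channel), and single-Hanning-taper
  power at 2.0–20.0 Hz in 0.5 Hz steps. A 2.5 s epoch natively gives
  0.4 Hz bins, so each tapered epoch is zero-padded to 4 s (0.25 Hz bins)
  and every second bin kept — the stated grid is hit exactly without
  interpolation. Alpha is the mean natural-log power over the 8.0–13.0 Hz
  bins (11 bins, inclusive); theta over 4.0–7.5 Hz (8 bins, half-open at
  8 Hz so the bands do not share a bin). Power is floored at 1e-30 µV²
  before the log so degenerate all-zero signals stay finite. Feature sets
  that include alpha or theta never also include the raw power columns.
* **Cardiac.** R-peaks: 5–30 Hz band-pass, squaring, threshold at half the
  rolling 2 s maximum, 250 ms refractory period, refinement to the local
  raw maximum — validated against generator truth to within one sample.
  Mean RRI and RMSSD are computed from the within-segment intervals;
  band powers (0.07–0.15 and 0.15–0.5 Hz, ms²) from a cubic-spline
  interpolation of the tachogram onto a 4 Hz grid (a common convention;
  Nyquist well above 0.5 Hz), linear detrend, and a Hann Welch estimate
  (60 s segments at 50% overlap; a single full-length window when the
  segment is shorter). A band is reported missing when the segment is
  shorter than two cycles of its lower edge — which flags mid-band HRV on
  30 s segments as unreliable. Spectra are not normalized by total power.
* **Respiration.** Gaussian smoothing with kernel width 0.39 s, read as
  the SD (the most literal reading; an FWHM interpretation is available via
  an argument); peaks/troughs from sign changes of the first difference
  with a 1 s minimum separation to suppress noise-induced micro-peaks. The
  "respiration frequency" feature is, as defined, the mean peak-to-peak
  *interval* in seconds; the naming inconsistency is preserved. Modulation
  depth is the mean peak-minus-following-trough difference of the smoothed
  signal.
* **Skin conductance.** Mean and minimum of the raw segment samples.
* **Eye.** A blink is a maximal run of 2–25 consecutive frames with both
  eyes invalid; 1-frame runs are noise and longer runs tracking loss. Runs
  are detected on the whole session and assigned to segments by their first
  frame, so a run straddling a 30 s sub-segment boundary is counted once.
  Pupil size averages the valid eyes per frame (both when both are valid);
  blink duration is missing in segments without blinks.

## Classification protocol

Segments are full 2-min blocks or 30 s quarters (in 30 s mode both training
and test use 30 s segments, with EEG averages over the 12 letters of the
sub-segment). Sessions 1–3 train, session 4 tests. Features are z-scored
with training statistics only; training-constant columns map to zero rather
than being dropped, keeping dimensions stable. Models are per participant:
a linear SVM (C = 1, no class weighting — classes are balanced by design)
and elastic-net logistic regression (mixing 0.5; strength from a 20-point
log grid by leave-one-block-out cross-validation on the training rows, ties
broken toward stronger regularization — the original hyperparameters are
not published, so results match in kind, not to the decimal). Feature-level
fusion concatenates column blocks in the order EEG, physiology, eye, time;
decision-level fusion trains one elastic-net model per atomic feature and
averages the probabilities, labelling high workload when the mean strictly
exceeds 0.5 (a tie maps to low — any deterministic rule suffices; this one
is consistent with the worked example in which mean probability 0.43 is
assessed as low workload). The SVM participates only in feature-level
fusion since it emits no probabilities.

A participant is excluded from a configuration when any selected feature is
missing in any of their rows (the realistic case: undefined blink duration
in a 30 s segment without blinks). This keeps the per-participant test
count k equal across participants, which the pooled binomial test assumes;
the report records the reduced n.

## Group statistics

With n_total = k × participants pooled test segments, the group mean
accuracy under a random classifier is distributed as Binomial(n_total,
0.5)/n_total; significance is the exact one-tailed tail probability
P(X ≥ k), computed by integer summation. For the default design
(n_total = 56) the smallest significant level at α = 0.05 is 35/56 ≈ 0.625;
the commonly quoted 0.61 for this design is not an attainable exact
crossing (34/56 ≈ 0.607 has p = 0.068), and the implementation reports the
exact value. The s.e.m. of an accuracy a is √(a(1−a)/n_total). Pairwise
configuration comparisons use an exact sign-flip permutation test on
per-participant accuracy differences, exhaustive up to 20 participants (the
original report does not name its pairwise test; a paired exact permutation
is the assumption-free choice at n = 14). No multiple-testing correction is
applied by default.

## Problem sizes used by the test suite

The full default conditions (14 participants, all five streams, 120 s
segments) back the ordering checks and the worked example. The replicated
statistical checks use scaled-down conditions chosen by the package: null
calibration runs 200 replicates of 6 participants with 30 s blocks
(12 letters at the same SOA) generating only the skin-conductance and gaze
streams, classified with the SVM on sc + pupil features; effect-size
monotonicity uses 20 such participants at three pupil-effect grid points.
These sizes keep every replicate's pipeline identical in structure to the
full run while making hundreds of replicates cheap.

## Known limitations

* The generator's per-block offsets are independent across blocks; real
  tonic levels are autocorrelated, so the simulated-online split is, if
  anything, kinder here than in reality (session-4 drift is still shifted
  relative to training).
* Elastic-net selection at 12 training rows is noisy; cross-validated
  strength can sit at either end of the grid for near-separable data.
* `significance_threshold` returns None when no attainable level exists
  (e.g. 4 test segments at α = 0.05), rather than a forced 1.0.
* The exact sign-flip pairwise test operates on participant-level
  accuracies; a block-level exchangeable test would differ.
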