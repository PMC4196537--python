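# physioload

Multimodal assessment of mental workload from physiological recordings.

Operators, pilots or drivers cannot be interrupted to ask how loaded they
are; their physiology can be read continuously instead. This package
implements, end to end, the standard individual-level analysis for that
question in a controlled working-memory (n-back) experiment: which signals
— EEG, peripheral physiology (ECG, skin conductance, respiration) or eye
measures (pupil size, blinks) — best classify a person's momentary workload
level, and whether combining them helps. Because datasets of this kind are
rarely shared, the package ships a seeded synthetic-recording generator
that reproduces the experiment's block design and the expected directions
of every workload effect, so the whole pipeline is testable and
demonstrable without any download. It is aimed at researchers in
physiological computing and neuroergonomics who want a tested reference
implementation of the feature definitions, the simulated-online protocol
and its exact statistics.

## The analysis

Per participant, 4 sessions each contain a 2-min baseline and six 2-min
workload blocks (0-, 1-, 2-back, two of each; 48 letters per block at a
2.5 s SOA, one third targets). Per data segment (a block, or a 30 s
quarter) the features of Table-style groups are extracted:

* **EEG** (7 channels): trial-averaged ERP at 100 Hz over 0–1 s
  (101 × 7 = 707 values), single-Hanning-taper spectral power at 2–20 Hz in
  0.5 Hz steps (37 × 7 = 259), and mean log alpha (8–13 Hz) and theta
  (4–8 Hz) power per channel; epochs span −0.5 to 2 s, are baseline-shifted
  on the first 500 ms, and trials with SD > 100 µV are discarded.
* **Physiology**: mean and minimum skin conductance; respiration interval
  and modulation depth after 0.39 s Gaussian smoothing; mean RRI, RMSSD,
  and mid-band (0.07–0.15 Hz) / high-band (0.15–0.5 Hz) HRV power from a
  Welch spectrum of the spline-interpolated R-peak series.
* **Eye**: mean pupil diameter, blink rate, mean blink duration, with a
  blink defined as 2–25 consecutive 60 Hz frames in which both eyes are
  invalid.
* **time**: the segment's mid-time on the cumulative workload-task clock.

Classification is individually tuned and simulated online: sessions 1–3
train, session 4 tests; features are z-scored with training statistics
(x − μ_train)/σ_train; models are a linear SVM (C = 1) and elastic-net
logistic regression (α = 0.5, strength by leave-one-block-out CV). Sensor
groups combine either by feature concatenation or by decision-level fusion
(averaging the elastic nets' P(high workload); mean > 0.5 ⇒ high). Group
accuracy ā over N = k·participants pooled test segments is tested against
chance with the exact one-tailed binomial tail P(X ≥ āN), X ~ Bin(N, ½),
reported with s.e.m. √(ā(1−ā)/N); configurations are compared with an
exact paired sign-flip permutation test.

## Worked example

```python
from physioload import SimulationConfig, build_feature_table, WorkloadClassification

table = build_feature_table(SimulationConfig(), seed=1)   # 14 participants
res = WorkloadClassification(table, features="eeg", model="svm", pair="2v0").fit()
print(res.summary())
```

```
Workload classification (simulated online)
============================================
features:        eeg
model / fusion:  svm / feature
contrast:        2v0   segments: 120 s
participants:    14
test segments:   56 pooled (4 per participant)
--------------------------------------------
mean accuracy:   0.857  (s.e.m. 0.047)
binomial p:      2.344e-08  (one-tailed, chance 0.5)
alpha=0.05 level: 0.625   alpha=0.01 level: 0.679
```

Reading: pooling 4 test blocks from each of 14 participants, the EEG-group
model classifies 48 of 56 held-out 2-min segments correctly (85.7%). Under
a random classifier that score has probability 2.3e-08, far beyond the
0.625 accuracy needed for significance at α = 0.05. `res.compare(other)`
gives the exact paired permutation p-value against another configuration,
and `physioload.report_table(table, "groups")` reproduces the full
sensor-group × model × fusion grid. On these default synthetic conditions
the modality ordering is EEG > eye > peripheral physiology and contrast
difficulty orders 2v0 > 2v1 > 1v0.

A CLI wraps the same functions: `physioload simulate --out dir --seed 1`
writes TSV recordings; `physioload run --features eeg --pair 2v0` runs one
configuration.

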