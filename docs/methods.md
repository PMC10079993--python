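# Methods

`plinet` implements a complete analysis chain for task-state EEG group
comparison: phase-lag-index (PLI) network construction from auditory-oddball
epochs, graph-theoretic characterization of the thresholded networks,
one-way ANOVA with Tukey post-hoc on network strength, and a compact
convolutional classifier applied both to raw epochs and to connectivity
matrices. Because clinical EEG of this kind is rarely shareable, the package
ships a synthetic cohort generator that reproduces the *structure* the
analysis is sensitive to; every stage is validated against that generator.

## Analysis montage and epoching

All stages operate on 22 scalp channels of the 10–20 system (FP1, FP2, F3,
F4, F7, F8, FC1, FC2, FC5, FC6, C3, C4, CP1, CP2, CP5, CP6, Pz, P3, P4, Oz,
O1, O2), recorded against Cz, sampled at 250 Hz. Epochs are cut around
target-tone onsets on the half-open window [−0.2 s, 0.8 s), i.e. exactly 250
samples, and baseline-corrected by subtracting the per-channel pre-stimulus
mean. Only target-stimulus epochs enter the analysis; standards exist in the
event schedule but are not epoched.

Band decomposition uses conventional EEG bands — delta 1–4, theta 4–8,
alpha 8–13, beta 13–30, gamma 30–45, wide 1–45 Hz (all configurable).
Filters are zero-phase (forward–backward) Hamming-window FIR with a
transition width of 25 % of the low band edge. Zero phase matters: any
filter phase distortion would masquerade as inter-channel lag and bias the
PLI. Filtering and the Hilbert transform are both applied to the
*continuous* record before epoching, so neither filter transients nor the
FFT edge distortion of the analytic signal ever falls inside a 1-s trial
(per-epoch Hilbert costs roughly 5 % of PLI on a perfectly coupled pair —
measurable with the constant-lag generator).

Artifact handling is a per-trial peak-to-peak amplitude threshold (default
300 µV): a trial is dropped if any channel exceeds the limit. Independent
component analysis is out of scope; the synthetic data contains no ocular
or muscle sources.

## PLI networks

For channels x and y with instantaneous phases φx(t), φy(t) from the
analytic signal,

    PLI = | ⟨ sign( wrap(φx − φy) ) ⟩ |,

the expectation taken over time samples within a trial. The difference is
wrapped to (−π, π] before taking the sign (the raw difference of wrapped
phases flips sign at the ±π branch cut); sign(0) contributes 0, so zero-lag
(volume-conduction-like) coupling is invisible by construction. Per-trial
matrices are averaged to a subject matrix, subject matrices to a group
matrix.

Sparsification is a proportional (consistency) threshold: the strongest 30 %
of the 231 channel pairs are retained — ⌊0.30 · 231⌋ = 69 edges — and ties
are broken deterministically by ascending (row, column) index. Group
contrasts are signed difference matrices with the same top-30 %-magnitude
retention. The retained network is binarized for graph analysis.

## Graph metrics

On the binary graph: degree centrality k/(N−1); betweenness centrality as
the normalized pair-dependency sum 2/((N−1)(N−2)) Σ g_hj(i)/g_hj; clustering
coefficient 2t/(k(k−1)); local efficiency as the efficiency of each node's
neighborhood subgraph; global efficiency as the mean inverse shortest-path
length with 1/∞ = 0 for unreachable pairs. Shortest paths are unweighted hop
counts. Nodes of degree < 2 take clustering 0 and local efficiency 0
(standard convention for degenerate neighborhoods). Computation is delegated
to networkx; the test-suite cross-checks every metric against brute-force
enumeration on all graphs up to 8 nodes over 20 seeds. Metrics are computed
on per-subject thresholded graphs and then averaged per group; group-level
graphs are also exposed.

## Group statistics

The dependent variable is channel-mean connection strength: the row mean of
a subject's PLI matrix excluding the diagonal, one observation per
subject × channel (a per-subject-mean variant is available behind
`per_subject=True`; channel means within a subject are correlated, so the
per-subject unit is the one whose independence assumption is clean). Group
is the single factor of a classical one-way ANOVA; Tukey's HSD supplies
pairwise post-hoc p-values. No multiple-testing correction is applied
across bands. Type-I-error calibration of the ANOVA path is checked by
simulation: i.i.d. per-subject strengths from one common Gaussian, 1000
replicates, rejection rate at α = 0.05 required to sit in [0.03, 0.07].

## Compact CNN

Two variants of an EEGNet-style compact network (~2.1 k trainable
parameters in total):

* **eeg** — input 1 × 22 × 250 raw band-filtered epoch; pooling widths 4
  then 8, trailing global average;
* **pli** — input 1 × 22 × 22 connectivity matrix; the first pooling kernel
  and stride are halved (2) so the narrow input survives to the classifier.

Both share: a bias-free temporal convolution (8 filters, kernel 125 — half
the sampling rate), batch normalization, a depthwise convolution across all
22 electrodes (depth multiplier 2, per-filter L2 max-norm constraint 1.0),
ELU, average pooling, dropout 0.5, a separable block (depthwise kernel 22,
then 1 × 1 pointwise, 16 filters), a second pooling/dropout stage, and a
1 × 1 classification convolution with log-softmax over 3 classes. For the
pli variant the layer output shapes and per-layer trainable-parameter counts
(1000 / 16 / 352 / 32 / 352 / 256 / 32 / 51) are pinned by tests.

The implementation is pure NumPy with hand-written backward passes
(im2col/col2im for narrow traces, FFT convolution for wide ones), verified
end-to-end by finite-difference gradient checks. Training is therefore
bitwise reproducible from (seed, config) on any machine.

Optimization is Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8, learning rate 1e−4,
batch 32) with *decoupled* weight decay λ = 0.2 applied to convolution
weights only — θ ← (1 − αλ)θ − α·m̂/(√v̂ + ε). A decay term divided by
√v̂ + ε degenerates as v̂ → 0, so the decoupled form is used. Bias
correction is the standard m̂ = m/(1−β₁ᵗ), v̂ = v/(1−β₂ᵗ). The loss is
class-weighted negative log-likelihood on the log-softmax outputs (uniform
weights by default).

Cross-validation is subject-exclusive: subjects are dealt into 10 folds so
per-fold group counts differ by at most one and all trials of a subject
share a fold; a split uses 1 fold for test, the next 2 for validation, 7
for training (1:2:7). Subject exclusivity is asserted structurally on every
run. The checkpoint with the best validation accuracy is kept; evaluation
reports accuracy, per-class precision/recall/F1 and Macro-F1 (unweighted
mean of per-class F1; a class absent from the test labels is excluded with
a warning).

## Synthetic cohorts

Each subject is a continuous 22-channel record:

* **1/f background** — pink noise, per-channel, SD `noise_sd` (default
  10 µV);
* **band rhythms** — per band, each channel carries an oscillator
  cos(2π∫f(t)dt + w(t)) whose centre frequency is re-drawn inside the band
  every ~4 s (interpolated) and whose phase carries a random walk of
  0.08 rad/sample. The frequency drift prevents two independent oscillators
  from staying spuriously phase-locked for a whole session — without it,
  channel pairs that draw nearly equal frequencies produce stable fake
  "couplings"; the walk keeps each oscillator narrow-band enough that
  zero-phase filtering preserves imposed lags. Default amplitudes: delta 6,
  theta 6, alpha 8, beta 3, gamma 2 µV;
* **coupling** — a rule (pair, band, mean_lag, jitter_concentration) makes
  both channels share one oscillator, the second offset by `mean_lag` plus
  slowly varying (0.25-s blocks, interpolated) von Mises jitter with the
  given concentration κ. κ → ∞ gives a deterministic lag and downstream
  PLI → 1; κ = 0 gives uniform jitter and PLI → 0; achieved PLI is monotone
  in κ (property-tested on a 5-point grid);
* **evoked response** — a Gaussian-windowed half-sine peaking ~300 ms after
  each target, parietal-maximal topography, amplitude 8 µV at Pz. It gives
  the epochs a realistic P300-like waveform; the connectivity analysis does
  not depend on it.

The oddball schedule is 30 target + 200 standard tones in pseudo-random
order with uniform 1000–1500 ms inter-stimulus intervals.

Default group profiles encode the qualitative contrast pattern under study:
the pain-like group (`cpp`) has strongly concentrated theta coupling on the
frontoparietal pairs FP1–P3 and FP2–O2 (κ = 10) plus weak FC2–F4; the
control group (`hc`) moderate CP5–O2 and FC2–F4 coupling (κ = 6); the
depression-like group (`dd`) the same pairs suppressed (κ = 0.5) and reduced
theta amplitude (4 µV). `separable_cohort_spec` additionally provides a
deliberately easy benchmark — disjoint near-deterministic coupling sets per
group at high oscillator-to-noise ratio — used only to verify that the
classifier can learn; it makes no claim about realistic effect sizes.

What the generator does **not** emulate: volume conduction / leadfield
mixing (couplings are placed directly on electrode pairs), ocular and
muscle artifacts, non-stationary arousal effects, and realistic
inter-subject topography variability. Passing tests therefore demonstrate
correctness of the estimators and trainability of the models under the
stated coupling model — not clinical-level effect sizes or classification
accuracy on real patients.

## Problem sizes used in validation

Statistical detection runs at 15 subjects/group (the scale at which the
default theta contrast is required to reach p < 0.01); classifier
validation at 8 subjects/group × 30 trials (720 samples) for 150 epochs;
ANOVA calibration at 1000 simulated null cohorts; graph-metric oracles at
N ≤ 8 over 20 seeds. These sizes were chosen to make the full validation
suite runnable on a single CPU core while keeping every statistical margin
comfortable.

## Numerical and degenerate-input conventions

* sign(0) = 0 in the PLI (exact phase ties arise in constructed fixtures);
* all-zero channels have undefined phase and are rejected;
* proportional-threshold ties: ascending (row, column), deterministic;
* zero within-group variance in the ANOVA is flagged `degenerate` with
  p = 0;
* epochs whose window exceeds the record are dropped with a logged warning;
  rejection of *all* trials by the artifact limit is an error;
* upsampling requests to `resample` are refused (the pipeline only
  down-samples);
* non-finite gradients abort training with the offending parameter named.

## Known limitations

The eeg-variant training step is ~20× more expensive than the pli variant
(width 250 vs 22) and is exercised at small scale in tests. EDF import /
export is not supported; the on-disk container is the package's own
(manifest JSON + little-endian float32 blobs + JSON sidecars), chosen so
cohorts regenerate byte-identically from (seed, manifest) alone. Weighted
graph metrics, other coupling estimators (wPLI, PLV, coherence) and
source-space analysis are out of scope.
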