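# Methods

`ecogdecode` implements a decoding analysis for coarsely labeled
naturalistic behavioral states (e.g. *Talking* vs. *WatchingTV*) from
multichannel intracranial recordings, together with a synthetic-data
generator that plants known spectro-spatial effects so that every
stage of the pipeline has a parameter-recovery test surface.

## Pipeline model

**Preprocessing.** Raw voltage traces (channels × samples, µV) are
cleaned in a fixed order: per-channel median subtraction (robust DC
removal), 1–200 Hz Butterworth bandpass (order 4) with IIR notches
(Q = 30) at 60 Hz and harmonics below Nyquist, decimation to 500 Hz
through a 120-dB Kaiser-windowed FIR, and common-median
re-referencing (per-sample median over good channels subtracted from
every channel). Filters run forward–backward (zero phase) by default:
phase handling is a free choice here, and zero-phase
filtering avoids band-dependent envelope lags that would misalign the
10-s feature bins. Channel count never changes; all operations are
pure.

**Band-envelope features.** Each cleaned channel is filtered into five
bands — θ (4–8), α (8–12), β (8–32), low γ (32–55), high γ
(70–110 Hz) — and the Hilbert envelope (instantaneous amplitude) is
averaged over 10-s bins. The β band is kept at its full 8–32 Hz
definition even though it overlaps α; the overlap is a property of the
band table, not a bug, and it means an α-band carrier also contributes
to β-band envelopes. Two envelope implementations are provided and
cross-checked: a time-domain path (`sosfiltfilt` + `hilbert`) and the
default spectral path, which applies the squared Butterworth magnitude
response in the frequency domain (the exact transfer function of
forward–backward filtering) and reconstructs the band-limited analytic
signal from its folded spectral support on a decimated grid. The
decimated samples are exact values of the full-rate envelope; bin
means agree with the time-domain path to < 0.5 % on interior bins and
differ only at the recording edges (reflection padding vs. periodic
extension), which the 10-s bins absorb. The spectral path shares one
forward FFT across all five bands and is several-fold faster, which is
what makes the twenty-seed acceptance sweeps desk-scale.

**Artifact rejection.** A two-minute segment is dropped when ≥ 10 % of
usable channels spend more than 2 s beyond 3× their whole-recording
standard deviation. "More than 2 s" is read as *cumulative*
supra-threshold time on |signal| within the segment (a contiguous-run
variant is available via `ArtifactRule(contiguous=True)`); cumulative
is the stricter and simpler reading. The SD is computed on the
preprocessed broadband signal over the whole recording — "the standard
deviation of the channel" most plausibly refers to the channel as a
whole. Zero-variance channels are excluded from the fraction's
denominator and logged.

**Electrode-to-ROI mapping.** Electrode *i* receives weight
`exp(−‖pos_i − centroid_j‖² / 2σ²)` toward ROI *j* (an electrode at a
centroid scores 1). Electrodes are assigned to their argmax-weight ROI
when the weight clears a threshold (ties break by ROI list order, for
determinism); ROIs retaining fewer than 3 electrodes are discarded and
their electrodes unassigned, iterating to a fixed point. σ (10 mm)
and the threshold (exp(−2), a ≈ 2σ radius) are conventional defaults
rather than principled constants; both are configuration-exposed and
recorded in output metadata. The eight default ROI names and approximate left-hemisphere
centroids (precentral, postcentral, inferior parietal, supramarginal,
superior/middle/inferior temporal, frontal middle) are plain
configurable strings/coordinates — no atlas parsing.

**Decoding.** Kept bins are ordered in time and split into 7
contiguous folds. For each test fold, folds within one fold of it on
*either* side are excluded from training (the buffer is symmetric — a
conservative reading, since slow autocorrelation is bidirectional).
Per fold, training and test sets are independently balanced by seeded
random downsampling to the minority class and independently z-scored
(sample SD, n−1; constant features map to 0 with a warning). The
classifier is a shared-covariance LDA: per-class means plus one pooled
within-class covariance with a ridge `λI` (λ = 1e−3; features are
z-scored, so unit scale), making the class-mean difference the only
discriminative parameter. Predictions are the argmax of the usual
linear discriminant score; ties go to the first class. The per-fold
mean difference is reported per electrode and summarized as the
electrode average (one scalar per (ROI, band) fold); the alternative —
projecting onto the discriminant direction — is not used because the
reported result surface is one value per feature and electrode
averaging keeps z-units interpretable.

**Group statistics.** Fold accuracies are pooled across participants
(5 × 7 = 35 points per feature when no fold is skipped). The chance
reference is the finite-sample binomial threshold: the smallest k/n
with P(Bin(n, 1/c) ≥ k) ≤ α, computed at the median per-fold test size
(α = 0.05). Accuracies are compared to this threshold and mean
differences to zero with two-sided one-sample t-tests;
Benjamini–Hochberg FDR (α = 0.01) is applied separately to the
40-feature accuracy family and the 40-feature mean-difference family,
and a feature is *jointly* significant only when both survive. The
accuracy flag additionally requires the mean accuracy to *exceed* the
threshold: a two-sided test also fires for features significantly
below the elevated finite-sample threshold (a null feature sits at
0.5, below it), which is not evidence of decodability. A two-way
fixed-effects ANOVA with interaction (statsmodels OLS) tests ROI and
band effects on fold-level accuracies; participant identity is not
modeled as a random effect; the analysis reports single pooled
p-values per factor.
Degenerate inputs (zero-variance accuracy lists, constant ANOVA
response) yield flagged non-results (NaN p, F = 0) rather than
exceptions, so a 40-feature sweep never dies on one edge case.

**Incremental-ROI analysis.** ROIs are ranked by validation accuracy:
within each test fold's training partition, the training fold most
distant in time from the test fold is held out as validation;
single-ROI models trained on the remainder are scored on it, and ranks
use the fold-averaged validation accuracy. The reported curve is the
buffered test accuracy (validation fold excluded from training) as
electrodes from the top-1, top-2, … ROIs are concatenated. The placement of the validation split is an open design choice; the
most-distant fold preserves the temporal-buffer logic between
validation and test.

## Synthetic generator

Each channel is a sum of per-band sinusoidal carriers at the
geometric-mean frequency of each band (well inside the analysis
passband on a log axis), pink (1/f) background noise generated by
spectral shaping, and a slow sinusoidal drift that exercises
z-scoring and the temporal buffer. Carrier phases are drawn per
channel, so the common-median reference does not cancel the carriers.
Randomness is one stream per recording split into per-channel
substreams keyed by channel index: changing the channel count never
reshuffles other channels' noise.

Planted effects multiply the carrier amplitude of configured (ROI,
band, state) combinations, so the ground-truth envelope-mean ratio
between states is known exactly. In addition, each carrier's amplitude
carries a slow multiplicative fluctuation (`NoiseSpec.am_cv`, default
0.25 coefficient of variation, smoothed over ~30 s). This term is
essential realism, not decoration: real cortical band power fluctuates
by tens of percent between 10-s bins, whereas deterministic carriers
give within-state envelope CVs of ~0.5 %. Without the fluctuation
every planted effect saturates at accuracy 1.0 (zero-variance t-tests)
and even the ~0.3 % state-locked coupling that the common-median
reference induces in unmapped channels becomes "significant". With
`am_cv = 0` the generator reduces to the deterministic model used by
the exact-envelope tests.

What the generator does *not* emulate: realistic cortical geometry,
volume conduction, cross-channel correlation beyond the reference
coupling, non-Gaussian artifacts other than square bursts, label
noise, and non-stationarity beyond drift + slow amplitude modulation.
Passing tests therefore demonstrate correctness of the measurement and
inference machinery under a controlled model, not performance on
clinical recordings.

## Problem sizes used in tests

The test suite runs the full chain at reduced but statistically
adequate sizes, chosen once as the package's reference conditions:

* recovery/calibration sweeps: 5 participants × 12 two-minute blocks
  (144 bins each) at 500 Hz, 8 ROIs × 3 electrodes, 20 seeds,
  planted multiplier 1.5, noise SD 5 µV, amplitude CV 0.25 — about
  16 balanced test bins per fold (finite chance ≈ 0.75);
* additivity fixtures: 1 participant, 4 ROIs × 3 electrodes, 40–60
  blocks; the additive fixture uses multiplier 1.25 on two ROIs,
  placing single-ROI accuracy near 0.75–0.80 where the theoretical
  size-2 gain of two equal independent features peaks (~8 points);
  gains are averaged over five fixed seeds because single-dataset gain
  estimates carry ~3-point spread;
* 2 mm electrode jitter in the sweeps so every participant retains all
  eight ROIs (at 4 mm, the default, electrodes occasionally flip to a
  neighboring ROI ~17 mm away and the density rule drops an ROI —
  realistic, but it breaks the exact 35-points-per-feature bookkeeping
  the sweeps assert).

## Numerical choices

* Butterworth order 4 everywhere (effective order 8 after
  forward–backward); notch Q = 30.
* Decimation FIR: Kaiser window sized for 120 dB stopband with a
  transition band of 8 % of the new Nyquist — in-band tones survive to
  ~1e−6 relative error away from edges.
* LDA ridge λ = 1e−3 on z-scored features; raising λ is the documented
  remedy if a pooled covariance is still singular.
* Spectral envelope support is truncated where the squared response
  falls below 1e−5 of its peak; the folded inverse-FFT length must
  exceed the support width (with ~12 % margin), guaranteeing
  alias-free exact envelope samples.
* The finite-chance threshold is not exactly monotone in n (binomial
  discreteness); property tests allow one-count jitter.
* BH-FDR ignores NaN p-values (they are never rejected and do not
  count toward the family size).

## Known limitations

* Real-data (NWB) support is a thin, import-guarded adapter; it is
  untested against actual files in this repository.
* The artifact-rule SD is always whole-recording; per-day or
  per-segment variants are not implemented.
* The ANOVA treats folds as independent replicates; temporal
  correlation between folds (mitigated but not removed by the buffer)
  makes its p-values anticonservative.
* Multiclass decoding reuses the two-class machinery with k-way
  balancing; no per-class performance breakdown is reported.
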