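# Methods

This note documents the models and procedures implemented in `prestim`, the
parameters that matter, the numerical conventions, and what the synthetic
validation studies do and do not establish.

## Data model

An `EpochSet` holds epoched EEG as a `trial × channel × sample` tensor in
microvolt, with per-trial binary labels (*face* / *no-face*), ordered 10–10
channel labels, sampling rate, and the onset sample index.  The reference
geometry is 512 Hz with epochs from −738 ms to +369 ms: 738 ms is not an
integer number of samples at 512 Hz, so the prestimulus part is fixed at
`round(0.738 · fs)` = 378 samples with the onset sample at its end, and the
poststimulus part at `round(0.369 · fs)` = 189 samples.  The on-disk
container is a plain directory (`header.json` + little-endian float32
`data.f32`, trial-major); computation is always in float64, storage in
float32.  EDF+ files can be imported; annotations matching the class names
delimit epochs.

The montage pairing table splits the 64-channel 10–10 layout into the 10
midline electrodes (Fpz, AFz, Fz, FCz, Cz, CPz, Pz, POz, Oz, Iz) and 27
homologous (left, right) pairs (Fp1–Fp2, AF7–AF8, … O1–O2).  Only the
midline exclusions and the canonical mirror-image pairing are assumed; the
table is fixed rather than configurable because every hemispheric feature
set depends on it.

## Time–frequency decomposition

Each channel is convolved with unit-energy complex Morlet wavelets: a
Gaussian-windowed complex exponential with temporal standard deviation
σ_t = n / (2π f_c), n = 4 cycles, truncated at ±5 σ_t and L2-normalized,
at center frequencies 1–40 Hz in 1-Hz steps.  Squared magnitudes give
instantaneous power.  Samples within a kernel half-length of an epoch edge
are computed against zero padding and can be flagged via `edge_mask`; the
full prestimulus window is used without trimming, matching the analysis
design this package implements (the 1-Hz wavelet spans the whole epoch, so
low-frequency power near the edges is attenuated rather than discarded).

Convolution is exact linear convolution evaluated with real FFTs (the
complex kernel split into real and imaginary parts); frequencies sharing a
padded FFT length reuse one forward transform.  The implementation is
checked in the test suite against a brute-force time-domain convolution sum
at relative tolerance 1e−9.

**Bands and segments.**  Power is averaged into δ 1–4, θ 4–8, α 8–13,
β 13–30, γ 30–40 Hz.  Shared edges belong to the upper band (half-open
`[low, high)`), except 40 Hz, which closes γ — so every grid frequency
belongs to exactly one band.  The prestimulus window is tiled by 10-ms
segments laid out from the window start; the final segment is truncated at
the onset side (73 full segments + one 8-ms segment = 74).  Truncating at
the onset side keeps the early segments exact; which end the original
analysis truncated is not documented, and the choice only moves one 8-ms
segment.  Segment boundaries are converted to sample indices by rounding,
so the sample axis is partitioned exactly (each 10-ms segment holds 5–6
samples at 512 Hz).

## Feature sets

* `build_tfps` — one feature per (electrode, band, segment) cell:
  64 × 5 × 74 = 23,680 for the full montage, 370 per electrode, 9,990 per
  hemisphere (27 electrodes).
* `build_datfps` — raw power subtraction `power(left) − power(right)` per
  homologous pair and (band, segment) cell: 9,990 for all 27 pairs.  The
  asymmetry is a subtraction, not a log-ratio, and is exactly antisymmetric
  under hemisphere exchange.
* `subset_features` — column subsets by electrode or pair (e.g. a 17-pair
  common set gives 6,290 features), preserving column order.

Columns are ordered electrode-major → band → segment and each carries a
descriptor `(site, band, segment, segment-ms)`; occurrence histograms and
the commonality analysis operate on these descriptors, so feature identity
is stable across runs and subjects.

## Decoding

**Balancing.**  The majority class is randomly downsampled without
replacement to `floor(min_class / n_folds) · n_folds` per class (67/193
trials under sixfold CV → 66 per class, 132 trials).  The subsample is
redrawn `n_reps` = 25 times (150 models in the reference layout); reported
accuracy is the mean over models, with the SD over models and the SEM over
repetition means both available.

**Nested CV.**  Per repetition, a seeded stratified 6-fold split.  Within
each fold the non-test trials are split stratified 80/20 into training and
validation (the original three-subset proportions are not documented; 1/5
validation is this package's choice).  Feature selection — pooled-variance
two-sample t-test per feature, uncorrected, keep `p < threshold` strictly —
min–max normalization to [0, 1] (parameters from the training set only;
out-of-range validation/test values clipped; constant training features map
to 0.5), and early stopping are all fitted inside the fold; an `audit` hook
exposes the index sets so tests assert structurally that test trials never
reach any fitting step.  If no feature passes the threshold the 10
smallest-p features are used as a fallback (a classifier needs at least one
input; this is logged loudly).  Degenerate t-tests (zero pooled variance)
give p = 1 for equal means and p = 0 otherwise.

**Classifier.**  A two-layer feedforward network: selected features → 10
tanh hidden units → 2 linear outputs, trained on mean squared error against
one-hot targets by Møller's scaled conjugate gradient (full batch).  SCG is
implemented in the package because no installed library offers this
training regime (SCG + MSE/tanh + validation-minimum restore).  Training
stops at `max_epochs` (10,000 by default), at training MSE ≤ 1e−5, or when
validation error has not improved for 6 consecutive epochs (`patience`;
validation is evaluated after every accepted SCG step), and the weights at
the validation minimum are returned.  Weight initialization is seeded
(normal / √fan-in); all seeds derive from one `SeedSequence`, so runs are
bit-reproducible.

**Metrics and chance.**  Sensitivity = fraction of face trials classified
face; specificity likewise for no-face; with balanced test folds, accuracy
is exactly their mean.  The empirical chance level is exact-binomial: the
smallest accuracy k/n such that a random guesser exceeds k correct out of n
with probability < α (default α = 0.05, n = the balanced trial count; 132
trials → 56.8%).  The tail convention is `P(X > k) < α` — "strictly more
correct answers than k is rare" — which is also well defined for tiny n
(n = 1 gives 100%).  Accuracies are called significant only when they
exceed this level; no below-chance significance is claimed.

**p-threshold.**  The selection threshold is swept in the reference design
(0.001, then 0.005…0.05 in 0.005 steps; `P_THRESHOLD_SWEEP`); the package
default is 0.05, the value also used by the moving-window analysis.

## Consistency and commonality

Occurrence histograms count, per feature, how many of the trained models
selected it.  A feature is *dominant* when its count reaches a fraction of
the maximum count — inclusive (≥), since the rule is "at least";
0.6 is the within-subject default and 0.75 the cross-subject one.  Dominant
features are localized by band and by time window (eight windows: seven of
100 ms plus a final 38-ms window before onset; a feature belongs to the
window containing its segment start, which places the truncated 8-ms
segment in the last window).  The commonality index C_i of a feature is the
number of subjects in which it is dominant (0…7 in a seven-subject study);
features with C_i ≥ 5 form the common feature set, and
`common_electrode_set` extracts their electrodes/pairs for re-decoding with
`subset_features`.  Commonality is computed on whatever feature kind the
masks describe; pair features contribute both electrodes.  How midline
electrodes could enter a common set derived from pair features is not
derivable from pair masks alone — single-electrode commonality is supported
separately for TFPS runs rather than guessed.

## Moving-window analysis

Windows of 246, 369, 492, 615 and 738 ms are stepped by 123 ms across the
prestimulus span; each placement is re-segmented (10-ms sub-segments, final
one truncated — a 246-ms window gives 24 full + one 6-ms segment = 25) and
re-decoded with the same configuration and seed.  The 246-ms floor comes
from the slowest wavelet: σ_t(2.6 Hz, 4 cycles) ≈ 244.9 ms, so shorter
windows trigger a warning.  The wavelet transform itself is always computed
over the full epoch (windows select segments, not raw samples), so window
edges introduce no extra spectral leakage.  All placements are enumerated
and reported; the profile's SEM is over repetition means.

## Synthetic data: what it emulates, and what it does not

`generate` produces, per trial and channel: spectrally shaped white noise
with power ∝ 1/f^exponent (exponent 1.0, per-channel RMS 10 µV — a standard
EEG background model), plus band-limited oscillations (θ 4–8 Hz at 2 µV,
α 8–13 Hz at 5 µV, β 13–30 Hz at 1.5 µV; frequency drawn uniformly in-band,
phase uniform, ±20% amplitude jitter per trial/channel).  On *face* trials
only, oscillations whose frequency falls in `effect_band` have their
amplitude multiplied by `1 + effect_size` on the left member and
`1 − effect_size` (floored at zero) on the right member of each effect
pair, inside `effect_window` with a 10-ms cosine taper against edge
artifacts.  Defaults mirror the reference study conditions: 67/193 trials,
alpha band, window −615…−369 ms, pairs P7–P8 and PO7–PO8.  With
`effect_size = 0` the labels never influence the signal, so the null
configuration is label-exchangeable by construction.

The generator deliberately omits: volume conduction and leadfields (channels
are independent up to the injected asymmetry), evoked poststimulus
responses, artifacts (blinks, muscle), non-stationary background, and any
principled model of between-subject variability (simulated "subjects" are
independent seeds of the same configuration).  Passing the recovery suites
therefore shows that the pipeline detects and localizes the class-conditional
asymmetry it assumes, under realistic 1/f noise and imbalance — not that
real-data accuracies are reproduced.  The reference study's recordings are
not publicly deposited, so its headline accuracy tables cannot be and are
not regenerated here.

## Validation studies and problem sizes

The stochastic suites in the test battery run the full pipeline
(generate → band power → DATFPS → balanced nested CV) on a reduced
14-channel montage (six homologous pairs, two carrying the effect, plus two
midline channels), with 5 CV repetitions and a 200-epoch training budget —
sizes chosen so the whole battery runs comfortably on one CPU while keeping
the trial counts of the reference design where it matters:

* **Null calibration** — 20 seeds at effect 0, 67/193 trials: the fraction
  of runs whose mean accuracy exceeds the empirical chance level must be
  ≤ 15%.
* **Effect recovery** — 20 seeds at effect 0.8: accuracy above chance in
  ≥ 18/20 seeds; alpha must be the top band among dominant features.
* **Monotonicity** — mean accuracy non-decreasing over effect sizes
  0 → 0.4 → 0.8 (10 seeds each).
* **Commonality recovery** — 10 replications of a 7-subject study (40/80
  trials per subject, 3 repetitions each): an injected pair must enter the
  C_i ≥ 5 common set in ≥ 8/10 replications.
* **Moving-window localization** — 246-ms windows, 123-ms shift (30/60
  trials, 2 repetitions): on null data every window stays within chance in
  ≥ 85% of 20 seeds; with the effect, the best window overlaps the injected
  −615…−369 ms interval in the majority of 10 seeds.

## Known limitations

* The SCG optimizer is full-batch; very large selected-feature counts with
  very many trials would train slowly (irrelevant at this design's scale).
* `morlet_power` materializes the full trial × channel × freq × sample
  tensor; use `compute_band_power` (chunked, accumulates band/segment means
  directly) for large recordings.
* The two convolution entry points share kernels and padding but may differ
  in the last float bit when trial batches differ; tests that require exact
  agreement use a single code path.
* EDF import trusts the file's annotation onsets; no artifact handling or
  re-referencing is performed (preprocessing is out of scope).
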