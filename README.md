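# prestim

Single-trial decoding of perceptual decisions from **prestimulus** EEG.

`prestim` is a tested, reusable implementation of a classical EEG decoding
design for *face pareidolia*: participants view pure-noise images after being
told that faces may be hidden in them, and report on each trial whether they
saw a face.  The question the analysis answers is whether the brain state
*before* stimulus onset already predicts that report.  The package is aimed
at EEG researchers who want to run (or stress-test) this style of pipeline on
their own epoched recordings, and at methodologists who want a fully
synthetic, ground-truth testbed for it.

## The analysis

Given epoched EEG (trial × channel × sample, 64-channel 10–10 montage,
512 Hz, epochs −738…+369 ms around onset) with binary labels
(*face* / *no-face*):

1. **Time–frequency power** — each channel is convolved with unit-energy
   complex Morlet wavelets (n = 4 cycles, 1–40 Hz in 1-Hz steps; temporal
   resolution σ_t = n / (2π f_c)).  Power is averaged into the five classical
   bands (δ 1–4, θ 4–8, α 8–13, β 13–30, γ 30–40 Hz) and into non-overlapping
   10-ms segments tiling the 738-ms prestimulus window (73 full segments plus
   one truncated 8-ms segment → 74).
2. **Feature sets** — per-electrode band/segment power (TFPS; 64 electrodes
   × 5 bands × 74 segments = 23,680 features; hemispheric subsets TFPSL/TFPSR
   with 27 electrodes each = 9,990), and hemispheric **differential
   asymmetry** (DATFPS): power(left) − power(right) for the 27 homologous
   pairs (9,990 features).
3. **Decoding** — class-balanced repeated nested cross-validation: the
   majority class is randomly downsampled to the minority count (rounded to
   fold divisibility; 67/193 trials → 66 per class), 25 repetitions × 6
   stratified folds = 150 models.  Within each fold, features are ranked by a
   pooled-variance two-sample t-test and kept at p < threshold, min–max
   normalized to [0, 1], and fed to a feedforward network (10 tanh hidden
   units, 2 outputs, scaled-conjugate-gradient training on MSE with early
   stopping at the validation minimum).  Selection, normalization and early
   stopping never see the test fold.  Accuracy, sensitivity and specificity
   are reported against the exact-binomial **empirical chance level**.
4. **Consistency** — occurrence histograms of selected features over the 150
   models; features at ≥ 60% (within subject) or ≥ 75% (across subjects) of
   the maximum count are *dominant*; the **commonality index** C_i counts the
   subjects in which a feature is dominant, and features with C_i ≥ 5 (of 7)
   form the common feature set.
5. **Moving windows** — windows of 246–738 ms stepped by 123 ms are
   re-decoded independently to localize the predictive interval in time.

A synthetic-EEG generator (`prestim.synthetic`) produces 1/f background
noise plus band-limited oscillations with a class-conditional left-minus-right
alpha-amplitude asymmetry injected into a configurable prestimulus window and
electrode-pair subset — so every stage of the pipeline can be validated
against known ground truth.

## Worked example

```python
import prestim as ps

# 67 face / 193 no-face trials; alpha asymmetry at P7/P8 and PO7/PO8
config = ps.SyntheticConfig(
    montage=("P7", "P8", "PO7", "PO8", "Pz"),
    effect_pairs=(("P7", "P8"), ("PO7", "PO8")),
    effect_size=0.8, seed=3,
)
epochs = ps.generate(config)
bp = ps.compute_band_power(epochs, picks=("P7", "P8", "PO7", "PO8"))
features = ps.build_datfps(bp, config.effect_pairs)
result = ps.nested_cv_run(
    features,
    ps.DecodingConfig(n_reps=5, p_threshold=0.05, max_epochs=200, seed=11),
)
print(f"{result.model_count} models, "
      f"accuracy {result.mean_accuracy:.1f} +- {result.sd_accuracy:.1f}%")
print(f"chance level: {ps.empirical_chance(result.n_balanced):.1f}%")
```

Output:

```
30 models, accuracy 75.9 +- 9.1%
chance level: 56.8%
```

30 models is 5 repetitions × 6 folds; 75.9% mean test accuracy is far above
the 56.8% empirical chance level for 132 balanced trials at α = 0.05, so the
injected asymmetry is decodable.  With `effect_size=0` the same pipeline
stays near 50%.

The same pipeline is available from the shell:

```bash
prestim simulate --config sim.yaml --out epochs/
prestim decode --epochs epochs/ --feature-type datfps --p-threshold 0.035 \
               --reps 25 --folds 6 --seed 1 --out results.json
prestim consistency --models results.selected.csv --fraction 0.6 --out hist.csv
prestim sweep --epochs epochs/ --sizes 246,369,492,615,738 --shift 123 \
              --p-threshold 0.05 --out profile.csv
```

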