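# ridephysio

Physiological analysis pipeline for in-vehicle passenger experiments with
unexpected road events. The pipeline turns multichannel recordings from one
ride (EEG, binocular gaze, head displacement) into per-segment measures and
within-subject statistics:

- **EEG indices** — 7–48 Hz band-pass (9th-order Butterworth, zero-phase),
  2 s / 1 s-overlap epochs, ±100 µV amplitude rejection, Welch band powers,
  frontal alpha asymmetry (log10 F4 − log10 F3 alpha power) and arousal
  ((beta + gamma) / alpha at the F3/F4 mean), 3-SD outlier removal, and
  averaging into four route segments anchored on the obstacle positions.
- **Oculomotor cleaning** — pupil-ellipse fitting, pixel→degree conversion
  on a spherical eyeball model, a 500 °/s velocity rule, linear
  interpolation of gaps ≤ 20 ms, blink labeling from matching binocular
  error runs, a final Butterworth low-pass, and blink counts per event
  window.
- **Multifractal spectrum width** — direct estimation of the singularity
  spectrum (α(q), f(q)) from q-weighted normalized box measures regressed
  across dyadic scales, with the width Δα = max α − min α as the summary
  measure for eye and head displacement windows.
- **Statistics** — two-way repeated-measures ANOVA (Condition × Route
  event) implemented from scratch, generalized eta-squared, Tukey-adjusted
  paired post hocs, and mean ± 95 % CI summary tables.
- **Synthetic cohorts** — every input can be generated with known ground
  truth: binomial multiplicative cascades (closed-form spectra), exact
  fractional Gaussian noise via circulant embedding, band-structured EEG
  with a controllable alpha-power asymmetry, gaze traces with scheduled
  blinks/saccades/dropouts, and cascade-modulated displacement series, all
  fully seeded.

## CLI

```bash
# write a seeded synthetic cohort (CSV/JSON fixture bundles)
ride-physio generate --n-subjects 8 --duration 120 --window-length 16 \
    --seed 1 --out cohort/

# full pipeline on that cohort: measures -> ANOVA -> post hocs -> summary
ride-physio run --input-dir cohort/ --out results/

# single stages
ride-physio eeg cohort/S001_human/eeg.csv --layout cohort/layout.json
ride-physio gaze cohort/S001_human --layout cohort/layout.json
ride-physio mfsw series.csv --column x_deg
ride-physio stats results/measures.csv --measure faa
```

Outputs are long-format RFC-4180 CSVs (`measures.csv`, `anova.csv`,
`posthoc.csv`, `summary.csv`) plus a `manifest.json` with the config hash
and seed; re-running from the same manifest reproduces the tables
bit-identically.

## Notes

- A 60 Hz low-pass is not realizable at a 120 Hz gaze sampling rate; the
  default falls back to 50 Hz with a logged warning, and an explicit
  at-or-above-Nyquist cutoff raises.
- The multifractal q-range (±5, step 0.25), dyadic scale ladder (8 … N/8)
  and the absolute-increment box measure are configurable via `MFConfig`.
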