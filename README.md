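# gaitvar

Gait-variability metrics from a single lower-back (lumbar) accelerometer,
with an optional foot sensor for stride-interval analysis.

From raw 3-axis acceleration records sampled at 256 Hz, the package
computes, per walking segment:

- **basic gait parameters** — step frequency via the FFT of the vertical
  axis;
- **linear variability metrics** — movement intensity (RMS of the
  gravity-free vector norm), RMS ratio (ML / norm), and step/stride
  regularity from the unbiased autocorrelation function
  (Fisher-transformed);
- **nonlinear metrics** — local dynamic stability (short-range slope of
  the mean log-divergence curve of a delay-embedded axis, 0–0.5 strides)
  and the attractor complexity index (long-range slope, 5–12 strides),
  both via nearest-neighbour trajectory divergence; and the detrended
  fluctuation analysis (DFA) scaling exponent of foot-derived
  stride-interval series;
- **cohort statistics** — segment aggregation, Hedges' g with 99%
  bias-corrected bootstrap confidence intervals, relative condition
  changes, and tidy summary tables.

Analysis segments are standardized to 250 steps resampled onto 18,750
samples (75 per step, 150 per stride), so autocorrelation lags and
divergence-curve time axes are cadence-independent. Sensor tilt is
corrected by rotating the per-bout mean gravity vector onto the vertical
axis (two successive planar rotations). No prefiltering is applied
anywhere.

A fully seed-deterministic synthetic generator
(`gaitvar.synthetic`) produces ground-truthed inputs — stride-interval
series with a controllable scaling exponent (circulant-embedding
fractional Gaussian noise, power-law spectral synthesis for the
nonstationary range), gait-like 3-axis lumbar waveforms with known tilt
and noise, foot traces with impact spikes, and a chaotic benchmark
trajectory with an independent variational Lyapunov oracle — so every
stage is testable without downloads.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes property tests (hypothesis), simulation-based oracle
checks, and `tests/test_acceptance.py` with one test per acceptance
criterion. The heavier divergence-curve simulations make a full run take
roughly 10–15 minutes on one CPU.

## Command line

```sh
# synthetic trial: lumbar + foot traces and a ground-truth sidecar
gaitvar simulate --out sim/ --seed 7 --alpha 0.9 --alpha 0.25

# full pipeline over a trial manifest (CSV: path, site, participant,
# group, condition, segment[, speed_m_s])
gaitvar analyze --manifest manifest.csv --out results/ --config config.yaml

# cohort summary with effect sizes from the tidy metric table
gaitvar compare --table results/metrics.csv --out summary/

# standalone DFA on a two-column (index, interval_s) series
gaitvar dfa --intervals intervals.tsv
```

`analyze` isolates failures per trial (exit code 2 signals partial
success) and writes a config snapshot with a content hash next to its
outputs. The YAML config accepts `axis_map` (anatomical-to-channel
mapping), `segmentation` options (activity threshold, frequency band,
minimum bout length, explicit index ranges as a manual override),
`nonlinear_axes`, and schema options for the delimited input files.

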