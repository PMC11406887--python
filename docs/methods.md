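# Methods

This note documents the models, defaults and design choices behind
`libsionome`: what the synthetic spectra emulate, how intensities are
extracted, and how the statistical stages are defined.  Nothing here states
a result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Study design

Two fungal species (*H. finlandica* "Hf", *M. hiemalis* "Mh") × two growth
media (PDB, GMM), five biological replicates per condition, each sample shot
on a 4 × 4 grid (16 shots per mount).  Two named presets resolve the
replicate-count ambiguity in the original description:

- `paper_n80` — one mount per biological replicate: 20 mounts × 16 shots
  → 320 raw shots → **80** analysis spectra after 4-shot averaging.  This
  matches the n = 80 used by the classifier experiment and is the default.
- `specimen20` — five technical mounts per biological replicate: each
  specimen yields 5 × 16 / 4 = **20** analysis spectra (400 in total).

## Signal model of the simulator

Per shot, on a regular grid (178–1,022 nm, 0.1 nm step):

```
I(λ) = B(λ) + m · b · Σ_lines c_e · w_l · G(λ; λ_l, FWHM) + ε(λ),  clipped at 0
```

- `G` is a unit-peak Gaussian, FWHM 0.15 nm — an idealised instrument
  profile; no Stark broadening or self-absorption.
- `B(λ) = 20·exp(−(λ−178)/250 nm) + 2` counts — a smooth decaying
  continuum standing in for bremsstrahlung/recombination background.
- `c_e` — element abundance; `w_l` — relative line strength from the
  packaged library.
- `m ~ lognormal(σ=0.55)` per shot — ablation-mass/coupling variation.
  Shot-to-shot intensity RSD of ~60% is realistic for LIBS on rough
  lyophilised biomass and is the mechanism that makes 4-shot vs 8-shot
  averaging matter downstream.
- `b ~ lognormal(σ=0.1)` per biological replicate, shared by all its shots.
- `ε(λ) ~ N(0, 0.05 + 0.001·signal)` — heteroscedastic detector noise.

At zero noise the background-corrected peak response is exactly linear in
concentration (verified to r > 0.999 on a 10-point ladder).

**Planted class structure.**  Base abundances span roughly an order of
magnitude (Li 15 … C 100, arbitrary units).  Each reported contrast is a
multiplicative fold (default 2.0) applied to the favoured class: Zn, P, Mn,
Mg, Fe, H, O, Al ×2 in Hf; Li, Ca ×2 in Mh; Ca, Al ×2 in PDB; C ×2 in GMM;
effects compose multiplicatively (Ca in Mh/PDB = 4× base).  H, N, O receive
a class-independent additive baseline (30/25/35) representing sample
moisture and ambient air, since measurements are not made under cover gas.

**Calibration.**  The noise defaults were tuned once against the study-level
conditions (five PCs ≥ 99.11% variance; 100% single-factor classification;
essential-element correlation structure) and then frozen; they are not
per-experiment knobs.  What the simulator does *not* emulate: matrix
effects, self-absorption, plasma temperature physics, detector stitching
artefacts, wavelength drift.  Passing tests therefore demonstrate that the
analysis pipeline recovers known planted structure — not that the
instrument model is physically complete.

## Preprocessing

Fixed order **crop → aggregate → normalize**, each applied exactly once:

1. Crop to the 190–900 nm parse range (closed interval).
2. Average disjoint groups of k = 4 consecutive shots per mount (k = 8 for
   the ablation), in acquisition order.  Averaging raw counts before
   normalization matches the stated acquisition protocol; the alternative
   order is available but not default.
3. Per-spectrum total-area normalization over the cropped grid (intensities
   sum to 1).  The normalization method was unspecified in the original
   protocol; total area removes shot-energy variation without privileging
   any single line.  `max_peak` and `none` are selectable.

## Peak extraction

The line library ships as a versioned TSV of NIST ASD strong persistent
lines (1–3 per element), with the CN violet-system band represented as one
pseudo-line at its 388.34 nm band head.  Line choices avoid known collisions
(Mg is represented by Mg I 285.21/518.36 rather than Mg II 279.55, which
sits 0.07 nm from Mn 279.48); the Ca II 393.37/396.85 doublet is retained
despite Al I 394.40/396.15 nearby because the median-flank baseline is
robust to a neighbouring peak occupying a minority of a flank window.

Baseline: medians of two 1.0 nm flank windows separated from the line centre
by a 0.45 nm exclusion half-width, joined linearly and evaluated at the peak
wavelength.  Intensity: maximum within ±0.3 nm of the centre minus the
baseline there, floored at zero ("peak intensity", not area; integrated area
is a config alternative).  Multi-line elements use the strongest-line (max)
rule.  These tolerances are artifact decisions, testable in closed form:
flat and linear continua are recovered exactly, and a constant detector
offset cancels.

Element identification declares a feature present when its background-
corrected intensity exceeds `snr_threshold` (default 3.0) times the local
noise sigma (1.4826 × median absolute deviation of the flank residuals).
A 3σ threshold on a max-statistic admits occasional false positives on
single noisy shots; identification is intended for averaged spectra (the
class means in the acceptance run), where the noise floor is far below any
real line.

## Correlation analysis

Pearson matrices over the 16 feature columns, computed per species with
media pooled (per-medium subsets available).  Magnitude categories follow
the stated bins, made total and deterministic as half-open intervals:
none [0, 0.1), small [0.1, 0.3), medium [0.3, 0.5), large [0.5, 1.0].
Zero-variance columns yield an explicit undefined marker, never a silent 0.
Group-mean profiles and pairwise fold changes per species, medium, or
species × medium reproduce the relative-intensity comparisons.

## PCA and classification

PCA of the full preprocessed spectrum matrix (80 × 7,101), five components,
mean-centred, unscaled; loading signs fixed by the largest-magnitude-
element-positive convention so runs are reproducible across linear-algebra
backends.  PC scores can be appended to the feature table and correlated
against emission intensities (`pc_correlations`).

The "linear classification model" is an equal-prior linear discriminant
with shared within-class covariance fitted on the training PC scores — the
canonical zero-hyperparameter linear classifier on PCA scores.  A singular
pooled covariance is ridge-regularised (warning surfaced); a fully
degenerate one falls back to nearest class mean.  The train/test split is
stratified (per class, round(count/3) rows to train, minimum 1), seeded,
disjoint and exhaustive; with 80 spectra in 4 classes this gives 28 train /
52 test.  Stratification is a declared convention — the original text says
only "randomly split into thirds" — and guarantees every class appears in
training.

The shot-averaging ablation re-runs preprocess → PCA → split → classify on
the same raw shots with k = 8, halving the number of analysis spectra and
the per-row variance of the ablation-mass term.

## Numerical and degenerate-input conventions

- Closed crop intervals tolerate float accumulation on regular grids (1e-9
  relative epsilon at the endpoints).
- All-zero spectra cannot be normalized (error), and produce all-zero
  intensity rows when extracted.
- Correlation requires ≥ 3 rows; categories reject |r| > 1.
- Discriminant ties break toward the first class in sorted label order.
- All randomness flows from explicit integer seeds (study seed for
  generation, split seed for partitioning); identical configuration and
  seeds give byte-identical pipeline outputs.

## Problem sizes

The default acceptance run generates 320 shots × 8,441 grid points, analyses
80 spectra × 7,101 points, and completes in a few seconds; the test suite
re-generates studies across ~20 seeds for the stochastic recovery
properties.  These sizes match the emulated study design rather than being
scaled-down stand-ins.

## Known limitations

- LIBS here is qualitative: intensities are relative, never calibrated to
  concentrations (no matrix-matched standards or standard addition).
- The classifier protocol is the single thirds split of the original
  experiment; no cross-validation or nonlinear models.
- Overlapping lines are handled by tolerance and robust baselines, not
  deconvolution; heavily blended spectra would need profile fitting.
- The correlation structure of real within-species biology is reduced to
  one shared biological multiplier plus planted folds; real ionomes have
  richer covariance than the simulator plants.
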