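# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `adulterspec`, in the order the pipeline runs.

## Synthetic study design

The generator emulates a blending experiment: four cheaper oils (soybean,
rapeseed, corn, peanut) mixed into camellia oil at ratios
{1, 3, 5, 7, 10, 15, 20, 30, 40, 50, 60, 70, 80, 90} %, four replicates per
ratio plus four replicates of each pure endpoint — 64 samples per adulterant
set, 256 in total — on a uniform 2068-point grid over 200–1100 nm. The real
instrument grid is slightly pixel-nonlinear; a uniform grid is the neutral
stand-in and no operation assumes uniform spacing.

**Pure-oil curves.** Each oil is a sum of five Gaussian bands (centres
250, 430, 660, 930, 1050 nm; widths 16–22 nm) over a shared smooth baseline
(constant 0.25 plus a decaying UV absorption edge). Gaussians are the
minimal shape satisfying what is known qualitatively about the pure-oil
spectra: band positions and amplitude orderings. The per-oil amplitude
tables (`synthetic_data.AMPLITUDES`) encode the discriminative structure:

* camellia differs most from soybean/rapeseed/corn at the 430 nm band and
  from peanut at the 660 nm band;
* for soybean the |camellia − adulterant| ordering is Vis(430) > NIR(930) >
  UV(250), so the absorbance–content correlation strengths order
  Vis ≥ NIR ≥ UV;
* rapeseed and peanut sit *above* camellia in the UV (and peanut in the
  Vis), giving positive correlations there and negative ones elsewhere.

**Mixing.** Absorbances mix linearly, A = y·a(λ) + (1−y)·c(λ)
(Beer–Lambert additivity for non-interacting mixtures); chemical
nonlinearity is out of scope. With zero noise the content is therefore
exactly recoverable from any single discriminative wavelength, which the
tests use as a closed-form oracle.

**Noise.** Each sample receives i.i.d. Gaussian noise per wavelength
(`noise_sd = 0.005` absorbance) plus a smooth per-sample baseline drift
(constant + tilt + curvature, `baseline_drift_sd = 0.01`). These two
defaults are a tuning choice, not a measured quantity: they place the
default pipeline's prediction R² in the 0.95–0.999 regime typical of
transmission measurements of clear oils. The generator does **not** emulate
scattering, temperature effects, cuvette artefacts or wavelength-dependent
detector noise — so passing tests demonstrate the pipeline's statistical
machinery, not robustness to every real-world artefact.

A `share_camellia` flag makes the four sets reuse one measured camellia
block (one camellia batch measured once); the default keeps the sets fully
independent.

## Preprocessing

* **Savitzky–Golay**: window 15, polynomial degree 2 (smaller windows
  under-smooth, larger ones blunt the bands). Derivatives are returned in
  per-index units — no division by Δλ — which is scale-invariant for the
  downstream regressions and avoids assuming a uniform grid. Edges are
  handled by polynomial extrapolation of the terminal windows
  (scipy's `mode="interp"`), so the 2068-point length is preserved.
* **CWT**: a single-scale continuous transform at dyadic scale a = 2^L,
  L ∈ 1..9, L1-normalised: c[n] = (1/a) Σ x[k] ψ((k−n)/a) over a symmetric
  boundary extension. L1 (rather than L2) normalisation makes the transform
  a genuine smoother — white-noise coefficient variance decreases
  monotonically with scale — matching the role the method plays here. The
  mother wavelet defaults to the Mexican hat, the usual choice for
  peak-shaped spectra; any real continuous wavelet known to PyWavelets can
  be configured. One coefficient vector per spectrum (no scalogram): the
  downstream models consume one vector per sample.
* "SG-CWT" applies SG smoothing first, then the CWT, as the name order
  suggests.

## Chemometric core

* **PLS** is a compact univariate-y SIMPLS. The selectors fit 10⁴–10⁵ tiny
  PLS sub-models, so per-fit overhead matters; the implementation is
  cross-checked in the tests against an independent NIPALS implementation
  and against ordinary least squares at full rank.
* **RMSECV** is the RMSE over concatenated out-of-fold predictions of a
  seeded 10-fold split (contiguous blocks of a seeded shuffle). Within the
  selectors the component count per fold is min(10, p_subset, n_train − 1) —
  a deterministic cap rather than a nested CV search. The cap keeps every
  subset evaluated anywhere in a selector run scored by exactly the same
  rule and folds (which the IVSO guarantee "returned subset is never worse
  than the full pool on the same folds" requires) and avoids multiplying
  every sub-model fit by another factor of ~100.
* **Kennard–Stone** is the classic max-min procedure on Euclidean distances
  over the (preprocessed) rows, seeded with the most distant pair; the
  calibration size is round(ratio·n) with banker's rounding (64 samples at
  2:1 → 43/21). Ties break to the lowest row index, making the split fully
  deterministic.
* **Correlation strength labels**: |R| ≥ 0.8 "very strong", ≥ 0.7 "strong",
  ≥ 0.4 "moderate", else "weak"; significance by the exact t-test
  t = R√((n−2)/(1−R²)) on n−2 df.

## Wavelength selectors

All four return the subset whose RMSECV is the minimum of their trace, are
deterministic given the seed, and break ties by lowest wavelength index.

* **CARS** (defaults: 100 Monte-Carlo runs, 80 % calibration sampling): the
  retained-count schedule r_i = a·e^(−k·i) is pinned at r₁ = p and
  r_N = 2 (a = p·(p/2)^(1/(N−1)), k = ln(p/2)/(N−1)); the lower endpoint is
  2, not 1, so a PLS model is always fittable. Each run keeps the top-|b|
  variables, resamples them with probability ∝ |b| (adaptive reweighted
  sampling), and scores survivors by RMSECV on the full sample set.
* **SPA** (chain lengths 1–40): projection chains are built on the
  Kennard–Stone calibration block and scored by multiple-linear-regression
  RMSE on the held-out block. The chain construction is y-blind by design —
  which is exactly why SPA underperforms on data whose informative
  variables are not mutually orthogonal.
* **BOSS** (default 1000 bootstrap subsets, best 10 %): weighted bootstrap
  variable sampling, soft shrinkage of weights from the normalised |PLS
  coefficients| of the best sub-models, elimination of zero-weight
  variables. Elimination typically lags one round behind the first weight
  update (the union of the best sub-models initially covers the whole
  pool), so iteration stops only after two consecutive updates fail to
  shrink the pool.
* **IVSO** (default 1000 WBMS rows, best 10 %): each binary-matrix row
  includes variable v with probability w_v (initially 0.5); degenerate rows
  with fewer than two variables are replaced by the two heaviest ones.
  Sequential addition evaluates every nested prefix of the weight ranking,
  keeps the best prefix as the next pool and rescales its weights to a
  maximum of 1.

The 10 % best-sub-model fraction for BOSS/IVSO follows the model-population-
analysis convention and is configurable.

## Models and tuning

* **SVR**: ε-insensitive RBF regression on column-standardised features
  (z-scores fitted on the training rows of each fold — no leakage);
  ε = 0.01, small against y ∈ [0, 1]; solver tolerance 1e−7 (free at these
  sample sizes and keeps training residuals inside the ε-tube). The grid
  search is 17 × 17 log₂-spaced points 2⁻⁸…2⁸ for both c and γ, followed by
  a ×10 finer log₂ lattice within ±1 octave of the coarse optimum — so the
  tuned optimum need not be a power of two. Untuned baselines use the
  library defaults (C = 1, γ = "scale").
* **Random Forest**: tree count tuned by canonical global-best PSO
  (dimension 2, swarm 30, 100 iterations by default; inertia 0.7298,
  cognitive = social = 1.49618) minimising 10-fold CV RMSE; bounds
  n ∈ [5, 200]. The second PSO dimension is the feature-subsampling
  fraction, the next most influential RF parameter; reports surface only n.
  Trees are scale-invariant, so RF consumes unstandardised features.
* **Evaluation protocol**: wavelength subset → Kennard–Stone 2:1 split →
  tuning by 10-fold CV on the calibration rows only → fit on calibration →
  R²/RMSE/MAE on both splits.

## Pipeline conventions

* The preprocessing winner is the minimum-RMSE row (ties: higher R², then
  earlier method order), evaluated with the full-spectrum SVR under the
  Kennard–Stone protocol on the soybean set.
* Band boundaries: UV/Vis at 400 nm, Vis/NIR at 780 nm (CIE convention).
* The representative wavelength per band is the selected wavelength in that
  band's densest cluster of selections (count within ±10 nm, ties to the
  lowest wavelength); bands with no selection are skipped with a warning.
* Every derived percentage in the study report is stored with its two
  operands, so reports are self-auditing; reports are byte-identical across
  reruns of the same (config, seed).

## Problem sizes

The generator defaults keep the study design faithful (2068 wavelengths,
64 samples per set, CARS 100 runs, BOSS/IVSO 1000 samples, PSO 30 × 100).
The analysis drivers, the test suite and `scripts/acceptance.py` run the
selector and tuner stages at reduced scale — every 10th wavelength enters
selection, 100 bootstrap/WBMS samples, a 10 × 10 PSO — chosen so the whole
chain completes in minutes on a single CPU while every algorithmic path is
still exercised end to end. Selector recall and model accuracy at this
scale are properties of the reduced problem; the defaults remain available
for full-scale runs.

## Known limitations

* Wavelet-domain selection can legitimately choose band *flanks* (where
  CWT coefficients discriminate) rather than band centres; raw-absorbance
  correlations at such picks can be weak even when the selection is good —
  visible for the soybean set in `analysis/05_validate_correlations.py`.
  The planted band centres are therefore reported alongside as the
  design-level reference.
* Which CWT scale wins the preprocessing comparison is data-dependent
  (mid scales L5–L6 on the synthetic sets); only the comparison logic, not
  a particular winner, is a stable property.
* The generator's simplifications listed above mean quantitative agreement
  with any particular real instrument is out of scope; the package's
  claims are about the pipeline's correctness and statistical behaviour.
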