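# Methods

`nirselect` implements a wavelength-selection and calibration workflow
for near-infrared (NIR) spectroscopy of food composition, centred on a
multi-learner ensemble importance score, with classical selectors
(CARS, SPA, UVE), spectral preprocessing, Monte-Carlo cross-validation
(MCCV) outlier screening, a PLS1 regression core, and exact Shapley
attribution of the fitted linear model.

## PLS core

Single-response PLS is fitted by NIPALS with X-deflation. The rotation
matrix `R = W (P'W)^-1` is accumulated by Gram–Schmidt so that one fit
yields the regression vector at *every* latent-variable (LV) count
`1..A`; all cross-validation loops in the package (PRESS curves, k-fold
RMSECV, MCCV, CARS, forward selection) exploit this to evaluate a full
LV path at the cost of one fit per fold. At the rank of centred `X` the
fitted values coincide with ordinary least squares, which the tests
assert against an OLS oracle, and predictions are cross-checked against
an independent NIPALS implementation (scikit-learn's `PLSRegression`).

LV counts are selected by minimising accumulated PRESS: either over
Monte-Carlo splits (default 50 random 80/20 splits) or over k-fold
partitions. Ties go to the smaller count (parsimony). Rank-deficient
splits pad the PRESS curve with the last attainable value, so deeper LV
counts can never appear spuriously better there.

Model-quality metrics: `R2`, `RMSE` (% protein), `rRMSE = 100·RMSE/ȳ`
(percent of the evaluation-set mean) and `RPD = sd(y)/RMSE` computed on
the same set, which makes `RPD = (1 − R2)^{−1/2}` an exact identity —
asserted to 1e−12 on every evaluation. VIP scores follow
`VIP_j = sqrt(p Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)` with
`SSY_a = q_a² t_a't_a`; `mean(VIP²) = 1` is asserted as the defining
normalisation.

## Importance learners

Five linear learners score every wavelength on internally autoscaled
copies of `X` (and standardized `y`); constant columns score 0:

* **FSR** — forward stagewise regression, step `ν = 0.01`, at most 5000
  steps, stopping when the largest |correlation| of any column with the
  residual drops below 1e−3; ties go to the lowest channel index. Score
  = |final coefficient|.
* **Huber** — an independent robust line `y ~ a_j + b_j x_j` per
  wavelength, fitted by IRLS with Huber weights at `ε = 1.345` and
  MAD-based scale re-estimated each pass; all p fits run as one
  vectorised iteration. Score = |slope|. Checked against
  `statsmodels` RLM on single columns.
* **LASSO** — penalty chosen on a 100-point log grid descending from the
  data-driven `λ_max` by k-fold CV (shared folds), refit on all samples.
  Score = |coefficient|. The orthonormal-design soft-threshold closed
  form is a test oracle.
* **Ridge** — same CV protocol; coefficients for the whole grid come
  from one SVD per fold. Score = |coefficient|; the `β/(1+λ)`
  orthonormal closed form and scikit-learn's `Ridge` are test oracles.
* **PLS-VIP** — LV count by 10-fold PRESS, refit, score = VIP.

The three cross-validated learners share fold assignments derived from
one seed so that differences reflect their criteria rather than fold
luck.

## Ensemble selection

Raw scores are min-max normalised to [0, 1] per learner (a constant
score vector degenerates to zeros, with a warning), then summed into an
integrated ensemble score in [0, K], K = 5. Wavelengths are ranked by
descending score, ties broken by ascending channel index.

Forward selection introduces candidates in rank order. After every
addition the PLS model is refitted with its LV count re-searched by
10-fold CV on a fixed fold partition (the same partition for every
subset, so comparisons are paired); a candidate is retained only if
RMSECV strictly decreases. Two stopping disciplines are exposed:

* `forward_select(..., patience=0)` — the strict rule: the scan ends at
  the first candidate that fails to improve.
* `ensemble_select(...)` (the orchestrator) defaults to `patience=25`:
  the trajectory is evaluated past local plateaus, up to 25 consecutive
  failures, and the subset at the global RMSECV minimum (the turning
  point of the trajectory curve) is returned.

The second default is a deliberate design choice. With the strict rule,
a single chance non-improvement — typically a redundant neighbour of an
already-selected channel — terminates the scan after a handful of
channels, long before the error approaches what the subset family can
achieve; trajectory curves on synthetic data show the error still
falling steeply past such plateaus. Evaluating through plateaus and
taking the turning point of the whole curve reproduces the intended
behaviour of a selection trajectory that declines through tens of
additions before rising. The strict rule remains available (and is the
low-level default) for contexts where the one-failure stop is wanted.

## Classical baselines

* **CARS** — 50 Monte-Carlo runs; per run a random 80 % of samples is
  fitted, variables are ranked by |PLS coefficient|, the keep count
  follows the exponentially decreasing schedule `r(i) = a e^{−k i}`
  with constants pinned by `r(1) = 1`, `r(N) = 2/p`, and survivors are
  resampled with probability ∝ |coefficient| (adaptive reweighted
  sampling, deduplicated). Every run's subset is scored by 10-fold
  RMSECV with the LV count searched up to 20; the argmin subset wins.
* **SPA** — on autoscaled data, chains grow from candidate start
  channels by repeatedly adding the variable with the largest residual
  norm after projection onto the orthogonal complement of the chosen
  set; every chain prefix is scored by k-fold CV of a multiple linear
  regression (not PLS, matching the method's definition). Default
  starts are the 10 channels most correlated with y and prefixes up to
  30 variables; both are configurable up to the `< n_train` bound — the
  exhaustive all-starts search is O(p²·folds) least-squares fits.
* **UVE** — p uniform-noise columns are appended; over 150 row
  resamples a PLS model with a fixed LV count (chosen once by MCCV on
  the augmented matrix) is fitted and per-variable coefficient
  stabilities (mean/sd) collected. Real variables whose |stability|
  does not exceed the maximum noise-variable stability are eliminated;
  a 99th-percentile cutoff is available behind a flag.

## Outlier screening

1000 (default) random 80/20 train/monitor splits; per iteration the LV
count is chosen in 5..20 by PRESS on an inner 80/20 split of the train
part, and monitor-sample absolute residuals are accumulated. Samples
whose residual mean exceeds 0.6 % protein or residual variance exceeds
0.01 %² are flagged (OR rule). The thresholds are scale-dependent
conventions, not universal constants: they assume residuals of a
well-behaved calibration on the protein-percent scale, and both are
configurable. The pipeline refuses to proceed if the rule flags more
than half the samples, which signals mis-scaled thresholds rather than
genuinely bad data. Samples that never landed in a monitor set carry
undefined statistics and are excluded from flagging rather than being
silently treated as clean.

## Shapley attribution

For the fitted PLS model (linear in its inputs) under the
interventional feature-independence convention the Shapley value has
the closed form `φ_j(x) = β_j (x_j − μ_j)` with μ the background mean —
the training set of the final model. The subset-enumeration definition
with weights `|S|!(M−|S|−1)!/M!` is implemented as a brute-force oracle
(≤ 12 features) and the closed form is asserted against it; efficiency
(`Σφ + base = prediction`), symmetry and the null-player property are
asserted on randomised models. Attribution is computed only over the
selected-wavelength subset, the model's actual inputs.

## Preprocessing operators

Seven row-wise operators with conventional parameters: Savitzky–Golay
(window 7, cubic, zeroth derivative; polynomial-interpolated edges so
polynomials are reproduced exactly), MSC against the mean spectrum,
SNV, wavelet shrinkage (coif3, level 10 capped to feasibility,
universal threshold `σ̂ sqrt(2 ln p)` with MAD-estimated σ̂, soft
shrinkage), Fourier low-pass at 0.1 of Nyquist on the channel-index
axis, regularised inverse Gaussian filtering (kernel 10, σ 1,
Wiener-style division with ridge `ε = 1e−3·max|H|²`, DC gain
normalised to one; the even kernel implies an inherent half-channel
phase shift), and a centred 3-point moving average with shrinking
edges. Ordered pairs apply left-to-right and record their lineage. The
evaluation grid scores RAW + 7 singles + 21 ordered pairs = 29
configurations by repeated k-fold PLS cross-validation, with the LV
count fixed once per configuration by MCCV/PRESS beforehand.

## Synthetic data generator

The generator emulates diffuse-reflectance FT-NIR absorbance spectra of
ground seed powder on a 11,542–3946 cm⁻¹ axis (acquired descending,
stored ascending; 400 channels by default, a 1845-channel profile is
available). Components, in order of construction:

* a smooth background with per-sample quadratic drift (coefficient sd
  1 mAU);
* five protein absorption regions (C–H third/second/first overtones,
  N–H second overtone, C–H combinations), each modelled as three
  overlapping Gaussian sub-bands whose amplitudes are linear in the
  reference protein content; each sub-band also carries independent
  per-sample amplitude jitter (sd 1 mAU) — within-region channels are
  informative but not perfectly collinear, as in real composite bands;
* three fixed interferent bands with independent factors, plus ~80
  nuisance constituents with Gaussian signatures at random positions
  kept clear of the protein regions (factor sd 10 mAU) — a high-rank
  structured background representing the other constituents of the
  matrix;
* mild per-sample multiplicative scatter (slope 0.995–1.005, offset
  ±2 mAU) and white detector noise (sd 2 mAU).

Reference values are truncated-normal, mean 37.2 %, sd 2.0 %, range
33–42 %. Ground truth records the channels whose protein signal
exceeds 5 % of the strongest peak, per sub-band and per region, before
noise is added.

Design intent: the conditions realise the regime in which wavelength
selection is useful — informative channels concentrated in known
regions, uninformative channels carrying *structured* variance that a
full-spectrum model must spend latent directions on. Two regimes that
defeat that purpose were deliberately avoided: dominant iid white noise
(full-spectrum PLS then wins purely by averaging) and purely rank-one
bands (sparse learners then collapse each region to a single channel).
Scatter is kept mild on the evidence that scatter correction can hurt
rather than help such data. What the generator does **not** emulate:
nonlinear detector response, wavelength-dependent noise, water-vapour
artefacts, particle-size-dependent effective path length, or any
physically rigorous radiative transfer — so passing recovery tests
demonstrate correct method behaviour under the stated linear-mixing
conditions, not performance on any particular real instrument.

On this benchmark, UVE characteristically lands at the full-spectrum
error level rather than below it (it removes variables but keeps most
informative and stable nuisance-cancelling channels), and SPA performs
worse than the full spectrum: its anti-collinearity criterion refuses
second picks from a band whose channels are mutually correlated, which
is precisely the structure protein information has here. Both
behaviours are documented outcomes of the benchmark, not tuning
targets.

## Problem sizes used by the test suites

Unit and property tests run on 20–150 samples × 4–200 channels.
Recovery suites: ensemble region recovery at 120 × 200 with three
planted regions over 25 seeds; outlier recovery at 60 samples with
+5 % reference shifts over 25 seeds (300 MCCV iterations — the
injected shift is an order of magnitude above the detection floor at
that count); LV recovery on three-factor data over 20 seeds; the
selector-vs-full-spectrum ordering benchmark at the default 150 × 400
over 15 seeds, a count chosen because the UVE-vs-full margin is a few
percent either way and a handful of seeds cannot estimate a majority
reliably.

## Known limitations

* The ensemble fuses learners with uniform weights; no weighted fusion
  or backward-elimination refinement.
* SPA's default restricted start set trades a small risk of missing the
  global optimum for tractability; pass `n_starts=None` for the
  exhaustive search.
* The outlier thresholds and the preprocessing grid's repeated-CV
  protocol assume a single-response calibration on the percent scale.
* Serialized models store only what prediction needs (coefficients,
  means, subset); scores/weights needed for VIP are not round-tripped.
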