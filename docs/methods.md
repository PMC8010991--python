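# Methods

This note documents the models implemented in `leafspec`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## The half-sib trait model

Traits are modeled as

    y_ijk = mu + r_j + f_i + e_ijk

for tree k of family i in replication (block) j: `r_j` fixed block effects,
`f_i ~ N(0, sigma2_f)` random family effects, `e_ijk ~ N(0, sigma2_e)`
residuals. For the three traits jointly, family effects come from a 3×3
covariance `cov_f` and residuals from `cov_e`.

**Estimation.** REML with the replication as a fixed effect. Because the
single random effect has an indicator incidence matrix, the REML
log-likelihood is profiled to a one-dimensional bounded search over
`log(sigma2_f/sigma2_e)`; all per-evaluation algebra reduces to family
counts and small fixed-effect cross-products, so one fit costs ~1 ms at
n = 1500. The boundary `sigma2_f = 0` is evaluated explicitly and the
estimate is truncated (and flagged) there when the interior optimum is
worse. On balanced designs this reproduces the expected-mean-squares ANOVA
estimator to ≤1e-4 (tested), and it agrees with `statsmodels` MixedLM on
shared fits (tested); unbalanced tables — e.g. the lab-measured subset —
are handled by the same code path.

**Heritability.** `h² = k·sigma2_f/(sigma2_f + sigma2_e)` with `k`
configurable, default 2.5. Classic half-sib theory uses 4 (family variance
= 1/4 of additive variance); 2.5 is the conservative choice for
open-pollinated families where part-sibs and inbreeding inflate the family
variance. With k = 2.5, h² of a perfectly family-determined trait is 2.5,
so h² lives in [0, k].

**Correlations.** Bivariate family/residual covariances come from the
sum-trait identity `cov(i,j) = (var(i+j) − var(i) − var(j))/2` applied to
three univariate REML fits — exactly equivalent to a bivariate fit when the
two traits share the design, and far simpler. The genetic correlation uses
the product-form denominator `sqrt(sigma2_fi · sigma2_fj)`; the sum-form
variant that sometimes appears in print fails the self-correlation identity
r_g(t, t) = 1 and is not offered. The phenotypic correlation is
`(cov_f + cov_e)/sqrt(total_i · total_j)`.

**Standard errors.** Delete-one-family jackknife for h², r_g and r_p —
families are the independent genetic units, so resampling trees would
understate the error. Subsets on which a statistic is undefined (e.g. a
zero family variance after deletion) are skipped with a warning.

**Breeding values and gain.** BLUPs of the family effect:
`BV_f = shrink · (family mean − grand mean)` with
`shrink = sigma2_f/(sigma2_f + sigma2_e/n_f)`. Realized gain
`ΔG_R(q)` is the mean BV of the top `ceil(qF)` families minus the mean BV
of all families; it is reported on the BV scale (the phenotype scale only
adds the grand mean to both terms, which cancels). Multi-trait selection
intersects per-trait above-mean rules on BVs.

## PLSR calibration

PLS1 by NIPALS on mean-centered X and y (no autoscaling: NIR band variance
is informative; an autoscale flag is not offered because none of the
pipeline's contracts need it). Components whose residual covariance with y
is numerically zero are not extracted, so duplicate/collinear bands are
safe. The regression vector is `W(PᵀW)⁻¹q`; at full rank it equals ordinary
least squares (tested to 1e-6), and coefficients match scikit-learn's
PLSRegression to machine precision (tested).

**Component choice.** Exact leave-one-out CV. Each held-out fit is
reconstructed from rank-one downdates of the uncentered cross-products
X'X, X'y with exact re-centering, then run through the cross-product
(Dayal–MacGregor) coefficient recursion, giving the whole 0..K coefficient
path in O(K p²) per held-out sample instead of O(K n p). The curve equals
brute-force refits to float precision (tested). The chosen rank is the
*smallest* k with RMSECV ≤ 1.02 × min RMSECV — a parsimony rule that avoids
chasing noise-level differences; `max_ncomp` defaults to 20 for standalone
use and 8 inside the full-pipeline default configuration (signal rank in
the synthetic spectra is small; the grid search re-verifies this choice
per split). k-fold CV (for the Rep and Ga selectors) uses the same
downdating with seeded, shareable fold assignments.

## Spectral preprocessing

Six methods: `raw`, `snv`, `d1`, `d2`, `snv_d1`, `snv_d2`. SNV standardizes
each spectrum to mean 0 / sample SD (n−1) 1. Derivatives are Savitzky–Golay
(scipy implementation), window 15 points, polynomial order 2 — order 2 is
the common chemometrics default for both derivative orders and is
configurable. Derivatives are divided by the grid step so values are per nm
and step-independent, and the output is trimmed to the interior bands where
the full window fits (234 → 220 bands): padding would fabricate signal at
the spectrum edges, where informative bands can sit. Combined methods apply
SNV first (a flag swaps the order). Averaging of the per-tree probe scans
happens at simulation time, before any preprocessing.

## Wavelength selection

All four selectors run *inside* every calibration split of the evaluation
protocol, never on the full dataset, so validation rows cannot leak into
selection. Each returns per-band scores, a boolean mask (never empty) and
its hyperparameters.

* **sMC.** Each centered band is regressed on the unit vector u along the
  PLSR prediction direction Xb/‖Xb‖; the statistic
  `SSreg/(SSres/(n−2))` is referred to F(1, n−2) at alpha = 0.05. The
  direction is taken from a PLS fit at the full `max_ncomp` rank, not a
  CV-chosen rank: with a low-rank direction u is dominated by single-band
  covariances and the null selected fraction runs ~3× above alpha
  (measured 0.146 at rank 1 vs 0.049 at rank 10 for n=100, p=200); at
  adequate rank the null calibration is within Monte-Carlo error of alpha
  (tested over 500 pure-noise replicates).
* **Ipw.** Iteratively refit PLSR on weight-multiplied bands; per-iteration
  importance is |coefficient|·band SD normalized to mean 1; weights
  multiply across ≤10 iterations or until the kept set stabilizes; kept =
  weight > 0.1 × max weight.
* **Rep.** Backward elimination dropping the lowest-VIP 10% per step
  (VIP normalized so mean VIP² = 1, tested), recording 10-fold CV RMSE of
  every intermediate set on shared folds, returning the CV-minimizing set;
  floor of 10 bands.
* **Ga.** Binary chromosomes over contiguous 4-band windows (cuts the
  search space ~4×), fitness = −5-fold RMSECV on fixed folds, tournament
  selection (k=2), uniform crossover, per-bit mutation 0.01, elitism 1
  (best fitness provably non-decreasing, tested), memoized fitness.
  Defaults pop 64 × 100 generations for standalone use; tests use reduced
  populations/generations, which suffice on the planted-band fixtures.

## Evaluation protocol

Per repetition: draw an unstratified random 80/20 split, select bands on
calibration rows only, choose the PLS rank by LOO on calibration rows only,
fit, and score both partitions with R² (never clamped below zero) and RMSE.
Repetition r of master seed s uses `SeedSequence(s, spawn_key=(r,))`, so a
single repetition is re-runnable in isolation and all cells of a
preprocessing × selector grid share the identical split sequence — the grid
is paired by construction. Figures-style summaries report mean, min, max
and the empirical 2.5/97.5 percentiles of the repetition distribution (the
interpretation of "95% confidence intervals" used throughout). The best
grid cell maximizes mean validation R², ties broken by lower validation
RMSE and then by list order (simpler preprocessing first). Ensemble
prediction averages the per-repetition models and reports the per-sample SD
across them. Failed repetitions are recorded with their reason, never
dropped silently.

The default `run-all` configuration evaluates the six preprocessing methods
without selection, then refines the winning method with sMC (the selector
the reference workflow settled on); the full 6 × 5 grid including Ga inside
every split is available through the config but is not a default a
desk-scale run would choose.

## Synthetic data: what it emulates, what it does not

The generator realizes exactly the model the estimators assume — that is
the point: it makes parameter recovery a sharp test. Defaults are the
study conditions: 50 families × 5 replications × 6 trees, 500 measured;
family-variance ratios 0.312/0.232/0.244 (back-solved from target
heritabilities 0.78/0.58/0.61 via q = h²/2.5 on unit total variance);
family correlation 0.36 (ANTH–FLAV; 0.11 and 0.09 for the NBI pairs);
residual covariances set so phenotypic correlations are 0.16/0.09/0.12.
NBI is simulated directly as the third correlated trait so its variance
components are controllable, and chlorophyll is emitted as
`chl = nbi × flav` for the spectral mixing. Concentrations are kept
positive by redrawing the residual (≤100 attempts) rather than clipping,
avoiding a point mass at zero. Trait units are nominal percent mass
fraction with means 3.0/3.5/5.0 and unit total variance — chosen so
truncation is a ≈3σ event — and are not claimed to match any particular
assay.

Spectra: absorbance = linear baseline + per-analyte amplitude × sum of
unit Gaussians at the reported influential band positions (ANTH
2060–2440 nm; FLAV 1130/1235/1950/2220 nm, the first center moved up from
1070 nm onto the 1100 nm grid start; chlorophyll
1100/1220/1465/1950/2220 nm), widths 25–35 nm. Each of 3 scans applies
multiplicative scatter (1+a) and offset b (a, b ~ N(0, 0.08)) plus
N(0, 0.02) band noise; the stored spectrum is the scan mean. The grid is
234 points, 1100–2498 nm: 2500 nm is not reachable by a 6 nm step from
1100, so the grid truncates below it. Amplitudes (0.030/0.010/0.004 for
anth/flav/chl) were calibrated once so that a default run orders validation
R² as ANTH > FLAV > NBI — ANTH has strong exclusive bands, FLAV shares two
regions with chlorophyll, and NBI is only observable through the nonlinear
chl/flav ratio — and then frozen.

Not emulated: radiative-transfer leaf optics, spatial field
autocorrelation, assay measurement error in the lab traits, instrument
drift, and genotype×environment interaction. Passing tests therefore
demonstrate correctness of the estimators and protocol under the assumed
model, not performance on any real spectrometer's output.

## Numerical choices and degenerate inputs

* Ties in RMSECV resolve toward fewer components; ties in the grid toward
  the earlier (simpler) method.
* Zero-variance spectra (SNV), constant responses (R², PLSR), single-family
  designs (REML), zero family variances (r_g) all raise typed errors naming
  the offending sample where applicable; the sMC/Ipw selectors degrade to a
  single-band selection with a warning rather than returning an empty mask.
* Negative REML variance solutions are truncated at zero and flagged.
* All stochastic components take explicit seeds; nothing reads global RNG
  state or the clock.

## Problem sizes used by the shipped tests

Oracle and formula tests run on toy sizes (n ≤ 60). Null calibration uses
500 replicates of n=100, p=200. Parameter recovery uses 100 replicates of
the full 1500-tree design (trait level only). The end-to-end test and the
acceptance script run the complete default pipeline with 50 repetitions
per grid cell — the repetition count is the one knob reduced from the
200-repetition reference protocol, which changes only the Monte-Carlo
resolution of the summary distributions, not any estimator.

## Known limitations

* The GA explores 4-band windows; isolated single-band signals narrower
  than a window are selected together with up to 3 neighbors.
* The sum-trait covariance identity assumes both traits are observed on the
  same trees; partially overlapping trait tables are not supported.
* `h²` with k=2.5 can exceed 1 for strongly family-structured traits; this
  is a property of the coefficient convention, not a bug.
* The evaluation harness preprocesses once per grid cell, which is valid
  only because all six methods are row-wise transforms; adding a
  training-set-fitted method (e.g. MSC against a mean calibration spectrum)
  would require moving preprocessing inside the split loop.
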