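# Methods

This note records the models implemented, the generative model behind the
synthetic stands, the numerical choices, and the known limits of what the
test suite demonstrates.

## Models

### Variable-exponent taper equations

A taper equation predicts stem diameter `d` (cm) at height `h` from DBH
(cm, at 1.3 m) and total height `H` (m), with `T = h/H`. Three Kozak-family
forms are implemented (`kozak1988`, `kozakI2004`, `kozakII2004`); the
closed forms are given in the `larchbiomass.taper` docstring. The
selected working model is `kozakII2004`,

    d = b1 DBH^b2 H^b3 X^e,
    X = (1 − T^(1/3)) / (1 − (1.3/H)^(1/3)),
    e = b4 T^4 + b5 e^(−DBH/H) + b6 X^0.1 + b7/DBH + b8 H^(1−T^(1/3)) + b9 X.

Two exact structural facts are used as test anchors: at `h = 1.3` the
ratio `X = 1`, so the prediction collapses to `b1 DBH^b2 H^b3` regardless
of the exponent; and at the tip `T = 1` the numerator of `X` vanishes, so
`d = 0`.

The `kozak1988` and `kozakI2004` forms follow the canonical published
model structures (lower anchors `√0.01` and `0.01^(1/4)`; the 1988 form
uses `ln(T + 0.001)`). They exist for model comparison; nothing downstream
depends on them.

### Power-law allometry on DRH

Component dry mass follows `W = a D^c + ε` where `D` is DBH or the
diameter at relative height `i` (DRH, `D_i`) predicted by the taper
equation. Fitting is **unweighted nonlinear least squares on the natural
scale** (the convention of PROC-NLIN-style forestry fits), started from
log–log OLS. The 95 % interval for `c` is the symmetric t-based Wald
interval with `n − 2` degrees of freedom. Two theoretical exponents serve
as references: 8/3 (metabolic scaling, woody components) and 7/3
(geometric similarity, foliage). A weighting option is easy to add to
`fit_power_law` via residual scaling but is deliberately not a default —
the reference estimates this package is validated against were produced
by unweighted fits.

### Additive NSUR system

The three component equations (stem on `D_0.2`, branch and foliage on
`D_0.5` by default) are estimated jointly by nonlinear seemingly
unrelated regression: stage-1 independent NLS, cross-equation residual
covariance `Σ̂ = R'R/n`, then iterated feasible GLS minimising
`r'(Σ̂⁻¹ ⊗ I)r` until the largest relative parameter change is below
1e-6 (cap 50). Predicted AGB is the *structural* sum of the component
predictions, so additivity holds to machine precision — there is no
fourth fitted equation. When observed AGB is itself the sum of the
observed components, a four-equation system has a singular residual
covariance by construction; `include_total_equation` therefore guards
against exactly-summed AGB and is meant only for data where the total was
measured independently.

Degenerate-input handling: a numerically perfect stage-1 fit (zero-noise
data) makes `Σ̂` the zero matrix, so GLS is skipped and the stage-1
estimates (already exact) are returned; a near-singular `Σ̂` (condition
number > 1e10) raises with a message naming the structure. `Σ̂` uses
divisor `n` (configurable to `n − λ`).

### Goodness of fit and cross-validation

R², adjusted R² (`λ` = parameter count), MAB, MPB = `100·Σ|e|/Σy`, and
RMSE with divisor `n − 1` — the forestry-convention variant, kept as the
default deliberately; `rmse_divisor="n"` gives the conventional value.
Cross-validation is leave-one-*tree*-out: all of a tree's records leave
together, which is the conservative fold unit when one sampled tree
represents one plot. Held-out statistics pool all held-out predictions
and reuse the full-model `λ`.

## Synthetic stand generator

The generator emulates a managed *Larix principis-rupprechtii* plantation
stand of 114 destructively sampled trees (DBH mean 17.4 cm, SD 5.6, range
5.1–26.8; H mean 13.6 m, range 3.5–21.9):

* **DBH**: normal truncated to [5.1, 26.8], mean 17.4, SD 5.6.
* **Height**: Chapman–Richards-type curve `H = 1.3 + a(1 − e^(−b·DBH))^c`
  with `a = 26 m`, `b = 0.04 cm⁻¹`, `c = 1.1`, plus N(0, 1.2 m) noise,
  clipped above breast height. The curve parameters were chosen once so
  the default stand reproduces the calibration means and ranges above
  (13.5 m at DBH 17.4; ~5.4 m at DBH 5.1; ~17.7 m at DBH 26.8).
* **Section diameters**: the 15-point relative-height grid (0.00, 0.02,
  0.04, 0.06, 0.08, 0.10, 0.15, 0.20, 0.30, …, 0.90) from the Kozak II
  reference vector, plus additive N(0, 0.6 cm) measurement error
  truncated at zero. 0.6 cm is the order of the best reported taper MAB
  for this stand type. (The source description of the sectioning is
  internally inconsistent — "11 sections" vs 15 listed points; the
  explicit 15-point list is implemented and the grid is configurable.)
* **Component biomass**: `W_k = a_k D_{i_k}^{c_k} exp(ε_k)` with the DRH
  taken from the *noise-free* taper curve and `(ε)` multivariate normal
  on the log scale — per-component SD 0.15, cross-component correlation
  0.5. The error structure of the original fits was never reported;
  multiplicative lognormal with a Gaussian copula is this package's
  choice, because biomass residuals scale with tree size and a
  cross-equation correlation is precisely what makes seemingly-unrelated
  estimation worthwhile. Observed AGB is the exact component sum.

Seeding: one master seed, with independent child streams for the three
stages via `SeedSequence.spawn`, so regenerating one stage never perturbs
another.

## What the synthetic stands can and cannot show

Passing recovery tests demonstrate that the estimators return the
generating parameters under the assumed error structure at the study's
sample sizes. Two real-data phenomena are *outside* what this generator
can reproduce, by construction:

* **Exponent attenuation toward the tip.** On the real calibration data
  the fitted exponent collapses for upper-stem predictors (D_0.6–D_0.9).
  In the generator, every `D_i` is a near-deterministic function of
  (DBH, H), so all DRH predictors are almost collinear in logs across
  trees and the fitted exponent is nearly flat over the grid (it drifts
  mildly *upward* toward the tip). Attenuation in real stands is driven
  by independent per-tree stem-form variability, which a two-driver
  generator does not contain.
* **Selection of the best predictor height.** For the same reason, the
  nearest-to-theory predictor pick is sampling-noise-driven on synthetic
  stands and does not consistently reproduce the (0.2, 0.5, 0.5)
  structure the generating model uses. The generating *exponents* are
  recovered at the generating predictors; the *identity* of the best
  predictor is not identifiable from these stands.

A related caveat: under the generator's multiplicative errors the
classical Wald intervals from unweighted NLS undercover (measured ≈ 87 %
at nominal 95 %, n = 114, σ = 0.15) because the residual SD grows with
the mean. Coverage is 92 % under the additive homoscedastic errors the
Wald construction assumes, which is what the coverage test exercises;
on real data the same caveat applies to any unweighted-NLS interval.

## Numerical choices

* Taper fitting: `scipy.optimize.least_squares` (trust-region
  reflective), bounds `b1 > 0` (and `b3 > 0` for `kozak1988`), tolerances
  `ftol = xtol = 1e-10`, `gtol = 1e-8`. Two starts by default — the
  published reference vector and a data heuristic (`b1` from mean
  d/DBH) — keeping the lower SSE. Parameter covariance
  `(J'J)⁻¹·SSE/(n − λ)`; plain approximate SEs, no sandwich correction.
* Power-law fitting: analytic Jacobian, bounds `a > 0`, start from
  log–log OLS.
* NSUR: whitening by the Cholesky factor of `Σ̂⁻¹` turns the GLS
  criterion into an ordinary least-squares problem per iteration;
  parameter covariance is the GLS information matrix `(J_w'J_w)⁻¹` at the
  optimum (no extra scale factor).
* Ties in nearest-to-theory selection break toward the lower relative
  height (DBH ordered lowest), via a stable sort.
* Result CSVs are written with a fixed `%.10g` float format so repeated
  runs with one seed are byte-identical.

## Problem sizes

The self-validation experiments use 20 Monte-Carlo replicates per
quantity — n = 114 trees (taper, NSUR; matching the calibration stand)
and n = 1000 (single-equation allometry, where the question of interest
is estimator bias rather than stand-size noise) — and 500 replicates for
interval coverage. These sizes put every Monte-Carlo standard error well
below the scale of the effects being checked while keeping the whole
suite interactive.
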