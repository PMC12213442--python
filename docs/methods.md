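# Methods

## Model

Egg volume (mm³) is computed from length and breadth as v = 0.4673·L·B² +
0.042 (species-specific constants for the great tit; both are overridable for
other species), standard-scored over the whole dataset (sample sd, n−1
denominator), and modelled with a Gaussian identity-link penalized-smooth
additive mixed model:

- **Main smooths** — cubic regression splines of within-clutch laying-position
  score *z*, dataset-scaled clutch size, and the dataset-scaled mean daily
  minimum temperature over the 3 calendar days strictly before laying (the
  formation window; the laying day is excluded). Laying position is scored
  within each clutch ((position − mean)/sample sd of 1..n) so clutches of
  different sizes share one functional scale; for sizes 4–10 the score spans
  about ±1.16 to ±1.49.
- **Interactions** — isotropic bivariate smooths of (z, clutch size) and
  (temperature, clutch size); isotropy is appropriate because both inputs are
  in standard-deviation units. An order×temperature surface and a per-clutch
  random slope in *z* (a first-order factor smooth) are available but off by
  default.
- **Random intercepts** — clutch identity and year, represented as
  identity-penalized indicator blocks, equivalent to i.i.d. Gaussian effects.
- **Residuals** — optional AR(1) within clutch, independent across clutches,
  handled by exact whitening: e₁ = r₁, e_t = (r_t − ρ·r_{t−1})/√(1−ρ²).
  This transform has constant variance, so penalized least squares on the
  whitened data is the exact GLS fit; the same transform defines the
  "AR-standardized" residuals reported by diagnostics.

Laying date is computed but excluded from the default design: under a
seasonal temperature trend it is nearly collinear with the formation-window
temperature, which the Pearson collinearity screen (default |r| threshold
0.7) reports.

## Bases and penalties

Univariate smooths are cubic B-splines (boundary knots at the data range,
interior knots at quantiles) with the integrated squared second derivative as
penalty, computed exactly by 2-point Gauss–Legendre quadrature per knot
interval (the integrand is piecewise quadratic). Default basis dimensions:
k = 5 for position (at most 10 distinct values), k = 5 for clutch size (7
distinct values), k = 8 for temperature; always clipped to the number of
unique covariate values.

Bivariate interactions use the thin-plate radial basis η(r) = r²·log r at up
to k = 25 knots chosen as an evenly spaced subset of the sorted unique
covariate pairs (deterministic; no clustering step). The {1, x, y} polynomial
null space is projected out before fitting: it exactly duplicates the
univariate terms' unpenalized spaces and the global intercept, and keeping it
would make the joint design rank-deficient. Interaction terms are therefore
fully penalized and shrink to zero when unsupported. The radial part can
still represent additive non-linear functions of either covariate, so single-
term deviance attributions between a main effect and the interactions that
contain it are not separable — the deviance partition offers grouped drops
for exactly this reason.

Every smooth is sum-to-zero centered over the observed covariate values via a
null-space reparameterization; the global intercept is the only unconstrained
constant. A consequence worth remembering: a partial-effect curve is
identified only up to an additive constant, and the intercept absorbs the
dataset mean of the true effect (for the default generator's quadratic,
about +0.5% of mean volume). Recovery comparisons must align that constant
before computing errors; `predict_order_effect` reports the curve anchored at
intercept + smooth, i.e. as deviation from the dataset mean volume.

## Smoothing selection and computation

Smoothing parameters minimize the restricted-likelihood criterion of the
Gaussian model with the scale profiled out:

    V(λ) = (n − M_p)(1 + log 2πσ̂²) + log|XᵀX + S_λ| − log|S_λ|₊,
    σ̂² = (‖y − Xβ̂‖² + β̂ᵀS_λβ̂)/(n − M_p),

with M_p the total penalty null-space dimension (computed on the whitened
data when ρ is set). Optimization is Nelder–Mead on log λ from a
deterministic all-zeros start with a polish restart (tolerance 1e-8 on the
criterion, log λ clipped to ±18), so fits are exactly reproducible without
seeds. Per-term effective degrees of freedom are the block traces of
(XᵀX + S_λ)⁻¹XᵀX; the coefficient covariance is the Bayesian σ̂²(XᵀX+S_λ)⁻¹.
On a univariate test problem the fit agrees with an independent reference GAM
implementation to ~3% of the response sd in the curve and ~0.5% in the scale
estimate; exact equality with any particular external implementation is not a
design goal.

## Diagnostics

- **Flatness tests** — Wald-like: the term's fitted values f̂ against their
  covariance X_jVX_jᵀ, pseudo-inverted at rank ⌊edf⌋ (+1 if the fractional
  part exceeds 0.05), referenced to F(rank, n − total edf). Calibration is
  checked by simulation; type-I error at α = 0.05 sits near 0.06–0.07 for
  n = 250–500, within the accepted (0.02, 0.09) band.
- **Deviance partition** — drop-one (full minus reduced explained deviance)
  and add-one (term alone) shares of null deviance, every sub-model refit
  under the same fixed ρ; optional grouped drops (e.g. all terms containing
  laying position), mirroring how interaction-capable designs must be
  reported.
- **Concurvity** — observed: the share of a term's fitted contribution lying
  in the column span of all other terms; worst-case: the largest squared
  singular value between orthonormalized spans. Clutch intercepts versus
  covariates that vary mostly between clutches (temperature, clutch size)
  show high values by construction.
- **Basis adequacy** — per-term edf/k usage (flagging edf within 0.1 of the
  basis dimension) and a k-index: mean squared nearest-neighbour residual
  difference, ordered by the term's covariate, over twice the residual
  variance (≈1 for white noise, <1 when structure remains).

## Two-pass AR(1) and the residual-dependence profile

Pass 1 fits without an AR structure; the pooled lag-1 estimator forms all
within-clutch consecutive residual pairs, pools them across clutches (plain
Pearson on the pooled pairs, cross-clutch pairs excluded; t = ρ√df/√(1−ρ²),
df = #pairs − 2); pass 2 refits with that ρ fixed.

A caveat established by simulation and by a variance calculation: with a
near-saturated clutch random intercept (shrinkage factor ≈ 0.99 under the
default generator), model residuals are effectively clutch-demeaned, and the
lag-1 correlation of a demeaned AR(1) segment of mean length n̄ ≈ 7.7 is
biased downward by roughly Var(ε̄)/σ² ≈ 0.18. The pooled estimator is
unbiased on the raw process (it recovers ρ = 0.19 on the generator's latent
residuals) but centers near zero on pass-1 residuals from the same data. An
observed residual lag-1 correlation of ~0.19 therefore implies substantially
stronger raw within-clutch dependence. The two-pass machinery is faithful to
standard practice; interpret pass-1 ρ as a residual-dependence index, not an
unbiased estimate of the generative AR parameter.

Per-clutch ACF uses the standard estimator (per-series mean centering by
default, global centering by flag; lag-0 normalization); PACF is the
Durbin–Levinson solution of the empirical-autocovariance normal equations —
the least-squares autoregression under the empirical second moments — which
guarantees PACF(1) ≡ ACF(1). Clutches contribute at lag ℓ only when their
size is ≥ ℓ + 2; the maximum lag defaults to (largest clutch − 2). Per lag,
the mean ± sd over clutches is compared with the white-noise band ±2/√n̄ and
with zero. Lags equal days because exactly one egg is laid per day; a strict
date-gap validation enforces this on input data.

## Synthetic generator

The generator emulates the study population: 5 years × 29 clutches, clutch
sizes 4–10 with mean ≈ 7.7 (configurable probability vector), first-egg dates
uniform over a 45-day window from day-of-year 80, one egg per day. Relative
volume is 1 + b_year + b_clutch + f(z) + β_T·T̃ + γ·z·T̃ + ε with
b_year ~ N(0, 0.015²), b_clutch ~ N(0, 0.0769²), f the quadratic through
(−1.4, −2.5%), (0.25, +2%), (1.4, 0) — the hump reported for this system —
temperature effects off by default, and ε an AR(1) process (ρ = 0.19,
stationary sd 2% of the mean, stationary initialization so marginal variance
is constant, independent restart per clutch). The within-clutch residual sd
is not reported for the study population; 2% of the mean is this package's
choice and is configurable. Daily minimum temperature is a linear seasonal
trend (6 °C + 0.12 °C/day) plus N(0, 1.8²) noise — plausible for a western
Mediterranean early spring. Length and breadth are back-solved from volume
under a sphericity profile 0.76 + 0.005·z (sphericity increases along the
sequence), exercising the geometry formulas end to end; the truth record
stores every latent effect.

What the generator does **not** emulate: laying gaps and interrupted
clutches, measurement error in callipers distinct from biological residual
variation, year-specific temperature regimes beyond a shared trend,
female identity across years, or any post-laying biology. Passing recovery
tests therefore demonstrate correctness of the estimation machinery under
the model's own assumptions, not robustness to real-data violations of them.

## The D statistic

D = 100·(v_last − v̄)/v̄ per clutch, v̄ over all eggs including the last
(the convention excluding the last egg is available, since the original
literature is ambiguous). The first/late clutch classification uses the
inclusive 30-day rule: clutches starting ≤ 30 days after the year's earliest
clutch are "first". Under the default hump-shaped order effect with all noise
off, every clutch size 4–10 yields |D| < 1% while the true effect spans 4.5
points of mean volume — the quantitative form of the argument against
single-egg summaries.

## Numerical choices and edge cases

- Sample (n−1) sd everywhere a scaling is computed; scalings are recorded and
  exactly invertible.
- Degenerate inputs signal errors rather than propagate: constant columns in
  scaling or correlation, singleton clutches, series too short for a lag,
  |pooled lag-1| = 1, non-invertible geometry back-solve (volume below the
  formula constant), duplicated quadratic anchors.
- PACF orders with a singular Durbin–Levinson step are omitted (NaN) and
  skipped in aggregation.
- Thin-plate penalty eigenvalues are clipped at zero for numerical safety;
  Cholesky failures inside smoothing-parameter search score the candidate as
  infeasible rather than aborting.
- The analysis sizes used throughout tests and the acceptance script are the
  study-scale defaults (145 clutches, ~1100 eggs); calibration simulations
  use single-smooth designs at n = 500.

## Known limitations

- Deviance shares of terms connected through interactions are not separable
  term-by-term (see bases); grouped shares are the reliable quantity.
- The drop-one share of the clutch random intercept understates the
  config-implied intraclass correlation when flexible between-clutch
  surfaces (temperature × clutch size) remain in the reduced model; this
  matches the behavior of reference GAM implementations on the same data.
- Pass-1 ρ is attenuated under strong clutch effects (see two-pass section).
- The factor smooth is a random-slope (first-order) analogue, not a full
  spline per clutch.
- Gaussian identity-link only; no tensor-product (anisotropic) interactions.
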