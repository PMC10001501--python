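# Methods

## Model and assumptions

The outcome is binary: a crash either kills the rider or it does not.  A
latent fatal propensity `S_m = β_m' x_m + ε_m` with i.i.d. type-I
extreme-value errors yields the logit form; the non-fatal utility is
normalized to zero.  The likelihood is implemented directly as the
two-outcome special case (a logistic of the fatal utility), which is the
numerically cheapest form and the only one the fatality question needs; a
multinomial severity scale would require generalizing the kernel to a
softmax over per-outcome utilities.

Selected coefficients are random across crashes:

    β_rm = β_r + Θ_r' z_m + σ_r · exp(ω_r' w_m) · ν_m,   ν_m ~ N(0,1).

Assumptions this encodes:

- the mixing distribution is normal (no lognormal/triangular option);
- mean heterogeneity is linear in the shifters z; SD heterogeneity is
  log-linear in w, so the SD is always positive;
- random coefficients are mutually independent (no correlation terms);
- each crash is an independent decision unit — there is no panel structure,
  so each observation gets its own block of draws.

`σ` is estimated unconstrained and reported as `|σ|`: the normal mixing
makes the likelihood an even function of σ, and leaving it unconstrained
(rather than using a positivity transform) keeps the standard error directly
comparable to the reported coefficient tables.

## Simulation of the integral

Halton sequences: the radical inverse in base p, skipping the index-0 term
(exactly 0) and discarding the first `halton_burn` (default 50) non-zero
terms, which are the most strongly correlated across bases.  The k-th random
coefficient uses the k-th prime (2, 3, 5, …); no scrambling or leaping.
Draws are transformed through Φ⁻¹ and laid out per observation row-by-row:
with R draws (default 500), observation i integrates over sequence positions
iR…(i+1)R−1.  Everything is deterministic given the model spec, so refits
and common-draw counterfactuals are exactly reproducible.

## Estimation

Simulated maximum likelihood.  Per-record probabilities are averaged over
draws and floored at 1e-30 before the log.  Starting values: plain-logit
estimates (statsmodels) for the constant, fixed coefficients and random-
coefficient means; 0.1 for each σ; 0 for all Θ and ω.

The gradient of the simulated log-likelihood is computed analytically (the
standard closed form: a probability-weighted average of logit-kernel
derivatives over draws) and is verified against central finite differences
in the test suite.  Optimization is bounded quasi-Newton (L-BFGS-B, gradient
tolerance 1e-5, iteration cap 500).  The heterogeneity-in-variance
coefficients are bounded at |ω| ≤ 15 (exp(±15) spans six orders of magnitude
of SD): without the bound, realizations whose likelihood favors σ → 0 send ω
along an unidentified ridge to infinity.

Convergence is accepted when the gradient max-norm is below 1e-2 absolutely
or below 1e-4·(1 + |LL|) relatively; the relative criterion covers the same
σ ≈ 0 ridge, where the variance shifter is unidentified and the likelihood
is flat to machine precision although the projected gradient never reaches
the absolute target.  A failed first attempt is restarted once from its
endpoint with fresh curvature memory; a fit that still fails raises an
estimation error with diagnostics rather than returning a bad optimum.

Standard errors: inverse negative Hessian at the optimum, the Hessian
obtained by central finite differences of the analytic gradient (step
1e-5·max(1, |θ|)); a singular Hessian falls back to the pseudo-inverse and
negative variances surface as NaN standard errors rather than being masked.
t = estimate/SE.  LL(0) is the closed-form constants-only log-likelihood
n₁ln p̂ + n₀ln(1−p̂), which the intercept-only optimizer reproduces to 1e-6.

## Fit statistics, marginal effects, sign shares

McFadden ρ² = 1 − LL(β)/LL(0); adjusted ρ² = 1 − (LL(β) − k)/LL(0) with k
the number of estimated parameters.

The average marginal effect of an indicator v is the mean over all records
of P(fatal | v:=1) − P(fatal | v:=0), both probabilities simulated under
common draws.  v is toggled *everywhere* it appears — main effect and any
mean- or variance-shifter role — which is the coherent reading of a one-unit
increase for an indicator that plays several roles; the alternative
(toggling only the main effect) would describe a variable that changes in
one equation but not another.

Sign shares default to the marginal split Φ(−β_r/σ_r) at zero shifter
values, the quantity usually quoted as "X% of such crashes had a lower
probability of death"; a sample-averaged variant (mean and SD evaluated per
record, including the shifters, then averaged) is provided as a separate
function.  For coefficients with active mean shifters the two can differ
substantially and published splits do not always state which convention was
used, so the reporting pipeline emits both and asserts neither against the
other.

## Temporal-stability battery

For each ordered pair (donor m₂, recipient m₁):

1. the donor's converged fit is reduced to its *retained specification*:
   the constant always; fixed covariates with |t| ≥ 1.645 (configurable);
   random covariates stay random when their SD is significant, are demoted
   to fixed when only their mean is, and are dropped when neither;
   individual Θ/ω shifter terms are kept by their own t-statistics;
2. that specification is re-estimated on the recipient's data (estimated
   afresh, not frozen at donor values — "at convergence" forces this);
3. χ² = −2[LL(transfer) − LL(recipient's own fit)], with df equal to the
   transferred specification's parameter count and confidence = 100·F_χ²(χ²; df).

The recipient's own fit uses the full candidate specification, which nests
every retained donor spec, so the statistic is non-negative up to numerical
noise; values within 1e-4 of zero are clamped, anything more negative raises
(it signals a specification mismatch, not noise).  Because the df convention
follows the donor's retained parameter count (the convention used in the
road-safety transferability literature) rather than the dimension of the
actual nesting restriction, the test is conservative under the null; the
test suite's size check asserts the empirical rejection rate at the 95%
level stays at or below nominal-plus-Monte-Carlo-slack rather than exactly
at 5%.  Reported df is exposed per cell so users can apply a different
bookkeeping if they prefer.

The pooled-vs-separate test is χ² = −2[LL(pooled) − Σ_y LL(y)] with
df = Σ_y k_y − k_pooled.

## Synthetic generator

The generator draws each indicator covariate independently at configured
prevalences and simulates the outcome from the exact process above: per
record, random coefficients are drawn as fresh pseudo-random normals (never
Halton, so estimation with quasi-random draws is a genuine out-of-sample
integration test), and the outcome is Bernoulli with the logistic
probability — distributionally identical to explicit extreme-value utility
draws for two outcomes.

Two bundled scenarios:

- `study_scenario()`: per-year prevalences and crash counts matching the
  2018–2020 Thai local-road motorcycle-crash records this package emulates
  (e.g. helmet use falling from 0.517 to 0.375; 16,772/15,117/10,176
  crashes), with truth regimes echoing the published yearly coefficient
  tables, including their random coefficients and shifters;
- `demo_scenario()`: 3 years × 2,000 crashes, six covariates, two random
  coefficients, with deliberate regime shifts (the speeding effect vanishes
  in the middle year; the helmet coefficient flips sign) so the stability
  battery has real signal at smoke-test scale.

What the generator does *not* emulate — and hence what passing tests do not
establish about real crash data: covariate dependence (real indicators are
correlated; here they are independent, with the screen still run), spatial
or multi-vehicle clustering, reporting and selection artifacts, and any
pandemic-era shift in exposure.  Recovering the truth here shows the
estimator and battery are correct under their own assumptions, not that
those assumptions hold in any registry.

## Problem sizes in the test suite

Monte-Carlo checks are sized to run on one CPU in a few minutes, as the
package's own choice of test scale:

- full-structure parameter recovery: n = 5,000 records, 250 Halton draws,
  50 replicates; asserts all six true parameters inside their 95% Wald
  intervals in the majority of replicates;
- battery size: 200 replicates of identical-regime 3-year data
  (n = 1,000/year) under a fixed-coefficient candidate spec with two null
  covariates; asserts the 95%-level rejection rate ≤ 10%;
- fixed-coefficient recovery: n = 4,000, 100 seeds, per-coefficient
  2-SE coverage ≥ 90%;
- quadrature oracles use 64-node Gauss–Hermite; the marginal-effect oracle
  uses 10⁶ pseudo-random draws.

## Known limitations

- Lognormal/triangular mixing, correlated random parameters, and panel draw
  structure are out of scope.
- Numeric-Hessian standard errors can be unstable when σ is estimated near
  zero (the ω directions are then unidentified); the wide intervals this
  produces are honest but uninformative.
- The retention rule treats significance covariate-wise; other software may
  retain or drop whole blocks differently, which changes transferred-spec
  df and hence confidence levels.
- Quasi-random integration error at 500 draws is of order 1e-3 in the
  log-likelihood on toy problems; draw counts are configurable where that
  matters.
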