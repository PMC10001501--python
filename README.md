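# crashlogit

Random-parameters (mixed) logit modelling of crash fatalities, with
covariate-driven heterogeneity in the means and variances of the random
coefficients, and a likelihood-ratio battery for temporal instability.

The package is built for road-safety and injury-epidemiology analysts who
model binary crash outcomes (1 = the rider was killed, 0 = any lesser
injury) on binary-coded covariates — rider characteristics, pre-crash
manoeuvres, temporal/environmental conditions, road attributes — and who
need to ask two questions the standard logit cannot answer: *do covariate
effects vary across crashes in ways we cannot observe?* and *are those
effects stable across years?*  The motivating setting is motorcycle crashes
on Thai local roads in 2018–2020; since such crash registries are
restricted, the package ships a synthetic generator that emulates their
covariate structure, so every method is exercised end-to-end on data whose
truth is known.

## Model

The latent fatal propensity of crash *m* is

    S_m = β_m' x_m + ε_m,          ε_m  i.i.d. type-I extreme value,

giving the binary logit probability with the non-fatal utility normalized
to zero.  Each random coefficient varies across crashes as

    β_rm = β_r + Θ_r' z_m + σ_r · exp(ω_r' w_m) · ν_m,     ν_m ~ N(0, 1),

where **z** shifts the coefficient's mean (through Θ) and **w** scales its
standard deviation (through ω).  The choice probability is the integral of
the logit kernel over the normal mixing distribution; it is simulated by
averaging over inverse-normal-transformed Halton draws (one prime base per
random coefficient, 500 draws by default), and the simulated log-likelihood
is maximized by quasi-Newton iteration.  Reported alongside the estimates:

- McFadden ρ² = 1 − LL(β)/LL(0) and its adjusted form 1 − (LL(β) − k)/LL(0);
- average marginal effects: the mean change in the fatal probability when an
  indicator flips 0 → 1, simulated under common draws;
- sign shares Φ(−β_r/σ_r): the fraction of the mixing distribution below zero;
- the temporal battery: for every ordered year pair (donor m₂, recipient m₁),
  χ² = −2[LL(β_{m₂m₁}) − LL(β_{m₁})] with the donor's significant
  specification re-estimated on the recipient's data, plus the
  pooled-vs-separate test χ² = −2[LL(pooled) − Σ_y LL(y)].

## Worked example

The `analysis/` scripts run the whole workflow on the bundled three-year
demo scenario (2,000 crashes/year, two random coefficients, regimes that
shift by construction):

```bash
python analysis/01_simulate.py     # generate + descriptives + collinearity screen
python analysis/02_fit_models.py   # yearly and pooled mixed-logit fits
python analysis/03_stability.py    # transferability matrix, pooled-vs-separate
python analysis/04_effects.py      # marginal effects, sign shares
```

`02_fit_models.py` prints the goodness-of-fit block:

```
   model     LL(beta)        LL(0)   k   rho2    adj
    2018    -1145.289    -1236.596  10  0.074  0.066
    2019    -1108.827    -1131.214  10  0.020  0.011
    2020     -745.378     -780.342  10  0.045  0.032
  pooled    -3184.540    -3245.294  10  0.019  0.016
```

and `03_stability.py` the battery (cells as `χ² (df) [confidence %]`):

```
m1\m2   2018                    2019                    2020
2018    -                       164.30 (3) [100.00%]    104.06 (3) [100.00%]
2019    3.49 (9) [5.85%]        -                       42.96 (3) [100.00%]
2020    0.24 (9) [0.00%]        68.73 (3) [100.00%]     -
pooled-vs-separate: chi2=370.093, df=20, confidence=100.00%
```

Four of six ordered pairs reject at the 95% level and the pooled model is
soundly rejected: the per-year regimes really are different, which is
exactly how the generator was configured.  `04_effects.py` shows the helmet
marginal effect moving from +0.17 (2018) to −0.08 (2020) — the sign flip
built into the demo truth — and the helmet coefficient's below-zero mass
rising from 30% to 84% across the three years.

The same workflow is available as a console tool
(`crashlogit simulate|fit|stability|report|all`) and as one call,
`crashlogit.run_analysis(RunConfig(...))`, which writes the full report
bundle (descriptives, coefficient tables, goodness of fit, stability
matrix, marginal effects, sign shares) deterministically for a given seed.

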