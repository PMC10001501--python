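"""Simulated-likelihood estimator: coefficient arithmetic, quadrature
oracles, degenerate-mixing equivalence with plain logit, and fitting."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

import crashlogit as cl
from crashlogit.mixed_logit import (
    EstimationError,
    ParameterVector,
    RandomCoef,
    _Likelihood,
)


def gauss_hermite_prob(mean, sd, offset=0.0, nodes=64):
    """Independent quadrature value of E_nu[logistic(offset + mean + sd*nu)]."""
    x, w = np.polynomial.hermite.hermgauss(nodes)
    return float(np.sum(w * expit(offset + mean + sd * np.sqrt(2) * x)) / np.sqrt(np.pi))


# ---------------------------------------------------------------------------
# random-coefficient construction


@pytest.mark.parametrize(
    "rc, record, nu, expected",
    [
        (RandomCoef(beta=1.0, sigma=0.5), {"x": 1}, 0.0, 1.0),
        (RandomCoef(beta=1.0, theta={"z": 0.5}, sigma=0.0), {"x": 1, "z": 1}, 0.7, 1.5),
        (
            RandomCoef(beta=1.0, sigma=0.5, omega={"w": np.log(2.0)}),
            {"x": 1, "w": 1},
            1.0,
            2.0,
        ),
    ],
)
def test_random_coefficient_arithmetic(rc, record, nu, expected):
    params = ParameterVector(constant=0.0, fixed={}, random={"x": rc})
    out = cl.random_coefficients(params, record, {"x": np.array([nu])})
    assert out["x"][0] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# simulated probability and log-likelihood


def test_probability_closed_forms():
    flat = ParameterVector(constant=0.0, fixed={"x": 0.0})
    assert cl.simulated_probability(flat, {"x": 1}) == pytest.approx(0.5)
    fixed = ParameterVector(constant=-1.386, fixed={})
    assert cl.simulated_probability(fixed, {}) == pytest.approx(0.2001, abs=5e-4)


def test_probability_matches_quadrature(single_random_setup):
    params, spec, _ = single_random_setup
    draws = cl.normal_draw_matrix(spec, 1)
    p = cl.simulated_probability(params, {"x": 1}, {"x": draws["x"][0]})
    assert abs(p - gauss_hermite_prob(0.8, 1.2)) < 5e-3


def test_loglik_single_record_closed_form():
    frame = pd.DataFrame({"x": [1], "fatal": [1], "year": [1]})
    params = ParameterVector(constant=0.0, fixed={"x": 0.0})
    ll = cl.simulated_loglik(params, cl.CrashTable(frame))
    assert ll == pytest.approx(np.log(0.5), abs=1e-12)


def test_loglik_matches_quadrature_on_toy(single_random_setup):
    params, spec, table = single_random_setup
    draws = cl.normal_draw_matrix(spec, table.n)
    ll = cl.simulated_loglik(params, table, draws)
    p1 = gauss_hermite_prob(0.8, 1.2)
    ll_exact = 2 * np.log(p1) + np.log(1 - expit(0.0))
    assert abs(ll - ll_exact) < 1e-3


def test_degenerate_mixing_equals_plain_logit(demo_table):
    """sigma = Theta = omega = 0 collapses the simulated likelihood onto the
    plain binary-logit likelihood exactly."""
    cols = ["gender", "speeding", "helmet"]
    beta = {"gender": 0.3, "speeding": 0.8, "helmet": -0.4}
    degenerate = ParameterVector(
        constant=-1.5,
        fixed={"gender": 0.3, "speeding": 0.8},
        random={"helmet": RandomCoef(beta=-0.4, sigma=0.0, theta={"drunk": 0.0})},
    )
    spec = cl.ModelSpec(
        fixed=("gender", "speeding"),
        random=(cl.RandomSpec("helmet", z=("drunk",)),),
        n_draws=25,
    )
    draws = cl.normal_draw_matrix(spec, demo_table.n)
    ll = cl.simulated_loglik(degenerate, demo_table, draws)
    X = sm.add_constant(demo_table.design(cols))
    eta = X @ np.array([-1.5, *beta.values()])
    ll_plain = float(
        np.sum(np.where(demo_table.outcome() == 1, -np.log1p(np.exp(-eta)), -np.log1p(np.exp(eta))))
    )
    assert ll == pytest.approx(ll_plain, abs=1e-9)


def test_loglik_invariant_to_sigma_sign(single_random_setup):
    params, _, table = single_random_setup
    flipped = ParameterVector(
        constant=0.0, fixed={}, random={"x": RandomCoef(beta=0.8, sigma=-1.2)}
    )
    spec = cl.ModelSpec(random=(cl.RandomSpec("x"),), n_draws=500)
    draws = cl.normal_draw_matrix(spec, table.n)
    # exact identity: flipping sigma equals mirroring the draws
    mirrored = cl.DrawSet(draws={"x": -draws["x"]}, n_draws=draws.n_draws)
    assert cl.simulated_loglik(params, table, draws) == pytest.approx(
        cl.simulated_loglik(flipped, table, mirrored), abs=1e-12
    )
    # with common draws the two agree up to quasi-Monte-Carlo integration
    # error, which shrinks as the draw count grows
    fine = cl.ModelSpec(random=(cl.RandomSpec("x"),), n_draws=5000)
    fine_draws = cl.normal_draw_matrix(fine, table.n)
    assert cl.simulated_loglik(params, table, fine_draws) == pytest.approx(
        cl.simulated_loglik(flipped, table, fine_draws), abs=1e-3
    )


def test_outcome_probabilities_sum_to_one(single_random_setup):
    params, spec, table = single_random_setup
    draws = cl.normal_draw_matrix(spec, table.n)
    lik = _Likelihood(params, table, draws)
    V, _ = lik._utilities(params.flatten())
    assert np.allclose(expit(V) + expit(-V), 1.0)


def test_analytic_gradient_matches_finite_differences(demo_table):
    spec = cl.demo_modelspec(n_draws=30)
    table = demo_table.subset_year(2019)
    draws = cl.normal_draw_matrix(spec, table.n)
    template = ParameterVector.template(spec)
    x0 = np.array([-1.4, 0.3, 0.7, 0.2, 0.5, -0.3, 0.4, 0.3, -0.4, 0.25])
    lik = _Likelihood(template, table, draws)
    g = lik.grad(x0)
    for j in range(len(x0)):
        e = np.zeros_like(x0)
        e[j] = 1e-6
        fd = (lik.loglik(x0 + e) - lik.loglik(x0 - e)) / 2e-6
        assert g[j] == pytest.approx(fd, rel=1e-4, abs=1e-5)


# ---------------------------------------------------------------------------
# constants-only log-likelihood


def test_constants_only_closed_forms(toy_table):
    assert cl.constants_only_loglik(toy_table) == pytest.approx(4 * np.log(0.5))
    all_fatal = pd.DataFrame({"x": [1, 0], "fatal": [1, 1], "year": [1, 1]})
    with pytest.warns(UserWarning, match="single-class"):
        assert cl.constants_only_loglik(cl.CrashTable(all_fatal)) == 0.0


def test_constants_only_matches_interceptonly_fit(demo_table):
    spec = cl.ModelSpec(fixed=(), random=())
    fit = cl.fit_model(spec, demo_table)
    assert fit.ll_beta == pytest.approx(cl.constants_only_loglik(demo_table), abs=1e-6)
    share = demo_table.outcome().mean()
    assert fit.estimates[0] == pytest.approx(np.log(share / (1 - share)), abs=1e-5)


def test_interceptonly_closed_form_25_percent():
    frame = pd.DataFrame({"x": [1, 0, 1, 0], "fatal": [1, 0, 0, 0], "year": [1] * 4})
    fit = cl.fit_model(cl.ModelSpec(), cl.CrashTable(frame))
    assert fit.estimates[0] == pytest.approx(np.log(0.25 / 0.75), abs=1e-5)


# ---------------------------------------------------------------------------
# fitting


def test_fixed_only_fit_matches_statsmodels(demo_table):
    cols = ("gender", "speeding", "darkness", "helmet", "drunk", "festival")
    fit = cl.fit_model(cl.ModelSpec(fixed=cols), demo_table)
    X = sm.add_constant(demo_table.design(list(cols)))
    ref = sm.Logit(demo_table.outcome(), X).fit(disp=False)
    assert np.allclose(fit.estimates, ref.params, atol=1e-5)
    assert np.allclose(fit.se, ref.bse, atol=1e-4)
    assert fit.ll_beta == pytest.approx(ref.llf, abs=1e-6)


def test_fixed_coefficient_recovery_sigma_zero():
    """With no random structure in the truth, each fixed coefficient lands
    within 2 SEs of truth in at least 90% of seeds."""
    truth = ParameterVector(constant=-1.2, fixed={"a": 0.7, "b": -0.5})
    spec = cl.ModelSpec(fixed=("a", "b"))
    true_vec = np.array([-1.2, 0.7, -0.5])
    hits = np.zeros(3)
    n_seeds = 100
    for seed in range(n_seeds):
        cov = cl.generate_covariates(4000, {"a": 0.4, "b": 0.5}, seed=seed)
        y = cl.simulate_outcomes(cov, truth, seed=10_000 + seed)
        frame = cov.copy()
        frame["fatal"] = y
        frame["year"] = 1
        fit = cl.fit_model(spec, cl.CrashTable(frame))
        hits += np.abs(fit.estimates - true_vec) <= 2 * fit.se
    assert np.all(hits / n_seeds >= 0.90)


def test_restricted_model_never_beats_nesting_model(demo_table):
    full = cl.fit_model(cl.ModelSpec(fixed=("gender", "speeding", "darkness")), demo_table)
    restricted = cl.fit_model(cl.ModelSpec(fixed=("gender",)), demo_table)
    assert restricted.ll_beta <= full.ll_beta + 1e-4
    assert full.ll_beta >= full.ll_zero - 1e-4  # nests the constants-only model


def test_draw_count_refinement_shrinks(demo_table):
    """Quasi-Monte-Carlo convergence: the LL change from 500 to 1000 draws is
    smaller than from 50 to 100 draws at a fixed parameter point."""
    table = demo_table.subset_year(2018)
    template = ParameterVector(
        constant=-1.5,
        fixed={"gender": 0.3},
        random={"helmet": RandomCoef(beta=0.6, sigma=0.7)},
    )

    def ll_at(n_draws):
        spec = cl.ModelSpec(fixed=("gender",), random=(cl.RandomSpec("helmet"),), n_draws=n_draws)
        return cl.simulated_loglik(template, table, cl.normal_draw_matrix(spec, table.n))

    coarse = abs(ll_at(100) - ll_at(50))
    fine = abs(ll_at(1000) - ll_at(500))
    assert fine < coarse


def test_estimation_errors():
    one_class = pd.DataFrame({"x": [1, 0], "fatal": [1, 1], "year": [1, 1]})
    with pytest.raises(EstimationError, match="single class"):
        cl.fit_model(cl.ModelSpec(fixed=("x",)), cl.CrashTable(one_class))
    flat = pd.DataFrame({"x": [1, 1, 1, 1], "fatal": [1, 0, 1, 0], "year": [1] * 4})
    with pytest.raises(EstimationError, match="zero-variance"):
        cl.fit_model(cl.ModelSpec(fixed=("x",)), cl.CrashTable(flat))


def test_spec_validation():
    with pytest.raises(ValueError, match="both fixed and random"):
        cl.ModelSpec(fixed=("x",), random=(cl.RandomSpec("x"),))
    with pytest.raises(ValueError, match="n_draws"):
        cl.ModelSpec(n_draws=0)
    spec = cl.demo_modelspec()
    assert spec.n_parameters() == 10


def test_fit_serialization_roundtrip(demo_table):
    spec = cl.demo_modelspec(n_draws=40)
    fit = cl.fit_model(spec, demo_table.subset_year(2020))
    back = cl.FitResult.from_json_dict(fit.to_json_dict())
    assert back.spec == fit.spec
    assert np.allclose(back.estimates, fit.estimates)
    assert back.labels() == fit.labels()
    assert back.ll_beta == pytest.approx(fit.ll_beta)
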