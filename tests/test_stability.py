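"""Likelihood-ratio temporal-instability battery."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import chi2 as chi2_dist

import crashlogit as cl
from crashlogit.mixed_logit import ParameterVector


@pytest.fixture(scope="module")
def two_year_setup():
    """Two synthetic years under different fixed-coefficient regimes: 'c' is
    active only in year 1, 'd' only in year 2."""
    prev = {"a": 0.4, "b": 0.5, "c": 0.3, "d": 0.5}
    mk = lambda fx: ParameterVector(constant=-1.3, fixed=fx)
    years = {
        1: cl.YearRegime(n=4000, prevalences=prev, truth=mk({"a": 0.8, "b": -0.8, "c": 1.0, "d": 0.0})),
        2: cl.YearRegime(n=4000, prevalences=prev, truth=mk({"a": 0.8, "b": -0.8, "c": 0.0, "d": 1.0})),
    }
    table = cl.make_temporal_dataset(cl.SyntheticScenario(years=years, seed=1))
    tables = {y: table.subset_year(y) for y in table.years}
    spec = cl.ModelSpec(fixed=("a", "b", "c", "d"))
    fits = {y: cl.fit_model(spec, tables[y]) for y in table.years}
    return spec, tables, fits


def test_lr_chi2_arithmetic_and_clamping():
    assert cl.lr_transfer_chi2(-100.0, -100.0) == 0.0
    assert cl.lr_transfer_chi2(-105.5, -100.0) == pytest.approx(11.0)
    assert cl.lr_transfer_chi2(-99.99999, -100.0) == 0.0  # noise clamped
    with pytest.raises(ValueError, match="nesting"):
        cl.lr_transfer_chi2(-95.0, -100.0)


@pytest.mark.parametrize(
    "chi2, df, expected",
    [
        (54.97, 34, 98.71),
        (43.33, 29, 95.76),
        (48.67, 29, 98.75),
        (0.0, 12, 0.0),
    ],
)
def test_chi2_confidence_published_cells(chi2, df, expected):
    assert cl.chi2_confidence(chi2, df) == pytest.approx(expected, abs=5e-3)


def test_chi2_confidence_monotone_and_matches_quadrature():
    grid = [1.0, 5.0, 20.0, 43.94, 80.0]
    last = -1.0
    for c in grid:
        conf = cl.chi2_confidence(c, 30)
        assert conf > last
        last = conf
        integral, _ = quad(lambda t: chi2_dist.pdf(t, 30), 0, c)
        assert conf == pytest.approx(100 * integral, abs=1e-6)


def test_transfer_fit_identity_and_nesting(two_year_setup):
    spec, tables, fits = two_year_setup
    own = cl.transfer_fit(spec, tables[1])
    assert own.ll_beta == pytest.approx(fits[1].ll_beta, abs=1e-4)
    restricted = cl.transfer_fit(cl.ModelSpec(fixed=("a",)), tables[1])
    assert restricted.ll_beta <= fits[1].ll_beta + 1e-4


def test_transfer_chi2_matches_independent_refit(two_year_setup):
    """The battery's chi-square equals one computed from a by-hand refit of
    the donor's retained spec, done outside the battery code."""
    spec, tables, fits = two_year_setup
    report = cl.stability_matrix(fits, tables, retention_t=1.645)
    donor_spec = cl.retained_spec(fits[2], 1.645)
    by_hand = cl.fit_model(donor_spec, tables[1])
    expected = -2.0 * (by_hand.ll_beta - fits[1].ll_beta)
    assert report.cell(2, 1).chi2 == pytest.approx(max(0.0, expected), abs=1e-3)
    assert report.cell(2, 1).df == by_hand.k


def test_matrix_shape_and_power(two_year_setup):
    spec, tables, fits = two_year_setup
    report = cl.stability_matrix(fits, tables, retention_t=1.645)
    assert len(report.cells) == 2  # ordered pairs for 2 years
    for cell in report.cells:
        assert cell.chi2 >= 0.0
        assert cell.df >= 1
        assert 0.0 <= cell.confidence <= 100.0
    # regimes differ by one strong coefficient per year: both directions reject
    assert report.cell(1, 2).confidence > 95.0
    assert report.cell(2, 1).confidence > 95.0


def test_three_identical_years_give_near_zero_chi2():
    frame = pd.DataFrame(
        {
            "a": np.tile([1, 0, 1, 0, 1, 1, 0, 0], 40),
            "fatal": np.tile([1, 0, 0, 0, 1, 0, 1, 0], 40),
        }
    )
    pieces = []
    for year in (1, 2, 3):
        p = frame.copy()
        p["year"] = year
        pieces.append(p)
    table = cl.CrashTable(pd.concat(pieces, ignore_index=True))
    tables = {y: table.subset_year(y) for y in (1, 2, 3)}
    spec = cl.ModelSpec(fixed=("a",))
    fits = {y: cl.fit_model(spec, tables[y]) for y in (1, 2, 3)}
    report = cl.stability_matrix(fits, tables)
    assert len(report.cells) == 6  # Y(Y-1) ordered pairs for 3 years
    for cell in report.cells:
        assert cell.chi2 == pytest.approx(0.0, abs=1e-6)


def test_matrix_regenerates_from_serialized_fits(two_year_setup):
    spec, tables, fits = two_year_setup
    live = cl.stability_matrix(fits, tables, retention_t=1.645)
    revived = {y: cl.FitResult.from_json_dict(f.to_json_dict()) for y, f in fits.items()}
    again = cl.stability_matrix(revived, tables, retention_t=1.645)
    for a, b in zip(live.cells, again.cells):
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-6)
        assert (a.donor, a.recipient, a.df) == (b.donor, b.recipient, b.df)


def test_pooled_separation_published_numbers():
    cell = cl.pooled_separation_test(
        ll_pooled=-17151.65,
        ll_years=[-6368.001, -6193.171, -4202.207],
        k_pooled=31,
        k_years=[29, 30, 34],
    )
    assert cell.chi2 == pytest.approx(776.542, abs=1e-9)
    assert cell.df == 62
    assert cell.confidence > 99.0


def test_pooled_separation_degenerate_and_errors():
    cell = cl.pooled_separation_test(-500.0, [-500.0], 10, [10])
    assert cell.chi2 == 0.0
    with pytest.raises(ValueError, match="invalid df"):
        cl.pooled_separation_test(-100.0, [-40.0, -50.0], 20, [5, 5])


def test_retained_spec_drops_null_covariates(two_year_setup):
    spec, tables, fits = two_year_setup
    kept = cl.retained_spec(fits[1], 1.645)
    assert "a" in kept.fixed and "b" in kept.fixed and "c" in kept.fixed
    assert "d" not in kept.fixed  # truly zero in year 1's regime
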