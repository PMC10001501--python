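"""Synthetic crash-table generator.

Generates data from exactly the process the estimator assumes: independent
Bernoulli indicator covariates at configurable prevalences, and a binary
outcome whose latent fatal propensity carries fixed coefficients plus normal
random coefficients with covariate-shifted means and variances.  The outcome
uses the logistic-probability shortcut (distributionally identical to
explicit extreme-value utility draws for a two-outcome model), and the true
random coefficients are fresh pseudo-random normals per record — never Halton
— so estimating with quasi-random draws is a genuine out-of-sample
integration test.

Year-specific regimes emulate the 2018-2020 Thai local-road motorcycle-crash
setting the package is built around: per-year covariate prevalences follow
the published descriptive statistics of those data, and the bundled truth
regimes echo the published yearly coefficient tables, so the generated panel
exhibits the same kind of temporal instability the stability battery is
meant to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import CrashTable
from .mixed_logit import ParameterVector, RandomCoef

__all__ = [
    "YearRegime",
    "SyntheticScenario",
    "generate_covariates",
    "simulate_outcomes",
    "make_temporal_dataset",
    "study_scenario",
    "demo_scenario",
    "STUDY_PREVALENCES",
    "STUDY_N",
]


@dataclass
class YearRegime:
    """One year's generating regime: covariate prevalences, the true
    parameter vector, and the number of crashes."""

    n: int
    prevalences: dict[str, float]
    truth: ParameterVector

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        bad = {k: p for k, p in self.prevalences.items() if not 0.0 <= p <= 1.0}
        if bad:
            raise ValueError(f"prevalence outside [0, 1]: {bad}")


@dataclass
class SyntheticScenario:
    """Per-year regimes plus the root seed; identical seed, identical data."""

    years: dict[int, YearRegime]
    seed: int = 0
    outcome_col: str = "fatal"
    year_col: str = "year"

    def __post_init__(self):
        if len(self.years) < 1:
            raise ValueError("scenario needs at least one year")


def generate_covariates(n: int, prevalences: dict[str, float], seed: int) -> pd.DataFrame:
    """Independent Bernoulli indicator columns, reproducible per seed."""
    bad = {k: p for k, p in prevalences.items() if not 0.0 <= p <= 1.0}
    if bad:
        raise ValueError(f"prevalence outside [0, 1]: {bad}")
    rng = np.random.default_rng(seed)
    data = {name: (rng.random(n) < p).astype(np.int64) for name, p in prevalences.items()}
    return pd.DataFrame(data)


def simulate_outcomes(covariates: pd.DataFrame, truth: ParameterVector, seed: int) -> np.ndarray:
    """Bernoulli fatal indicator from the realized per-record utility.

    Each record's random coefficients are drawn as independent normals
    (mean ``beta + Theta'z``, SD ``|sigma| exp(omega'w)``); the outcome is then
    Bernoulli with probability ``logistic(utility)``.
    """
    referenced = list(truth.fixed) + [
        c
        for name, rc in truth.random.items()
        for c in [name, *rc.theta, *rc.omega]
    ]
    unknown = sorted(set(referenced) - set(covariates.columns))
    if unknown:
        raise KeyError(f"truth references unknown column(s): {unknown}")

    n = len(covariates)
    rng = np.random.default_rng(seed)
    v = np.full(n, truth.constant if truth.constant is not None else 0.0, dtype=float)
    for c, b in truth.fixed.items():
        v += b * covariates[c].to_numpy(dtype=float)
    for name, rc in truth.random.items():
        mean = np.full(n, rc.beta)
        for z, th in rc.theta.items():
            mean += th * covariates[z].to_numpy(dtype=float)
        scale = np.full(n, abs(rc.sigma))
        for w, om in rc.omega.items():
            scale *= np.exp(om * covariates[w].to_numpy(dtype=float))
        beta_m = mean + scale * rng.standard_normal(n)
        v += beta_m * covariates[name].to_numpy(dtype=float)
    return (rng.random(n) < expit(v)).astype(np.int64)


def make_temporal_dataset(scenario: SyntheticScenario) -> CrashTable:
    """Concatenated per-year tables, each generated under its own regime.

    Every year draws from its own substream of the scenario seed, so any
    single year can be regenerated in isolation.
    """
    if len(scenario.years) < 2:
        raise ValueError("temporal dataset needs at least two years")
    pieces = []
    years = sorted(scenario.years)
    child_seeds = np.random.SeedSequence(scenario.seed).spawn(2 * len(years))
    for i, year in enumerate(years):
        regime = scenario.years[year]
        cov = generate_covariates(regime.n, regime.prevalences, child_seeds[2 * i])
        y = simulate_outcomes(cov, regime.truth, child_seeds[2 * i + 1])
        frame = cov.copy()
        frame[scenario.outcome_col] = y
        frame[scenario.year_col] = year
        pieces.append(frame)
    frame = pd.concat(pieces, ignore_index=True)
    return CrashTable(frame, scenario.outcome_col, scenario.year_col)


# ---------------------------------------------------------------------------
# bundled scenarios

_COVARIATES = (
    "gender", "young", "old", "local_address", "foreign", "helmet", "license",
    "speeding", "sign_violation", "wrong_direction", "overtaking", "mobile_use",
    "asleep", "sudden_cut", "drunk",
    "festival", "morning_peak", "afternoon_peak", "daytime", "night_lit",
    "darkness", "smoke", "raining",
    "maintenance", "rough", "curve", "dry", "wet",
)

# Observed indicator prevalences in the 2018-2020 Thai local-road
# motorcycle-crash records this generator emulates.
STUDY_PREVALENCES: dict[int, dict[str, float]] = {
    2018: dict(zip(_COVARIATES, (
        0.742, 0.366, 0.253, 0.747, 0.025, 0.517, 0.969,
        0.286, 0.005, 0.003, 0.011, 0.001, 0.004, 0.148, 0.181,
        0.185, 0.076, 0.144, 0.563, 0.186, 0.199, 0.028, 0.038,
        0.001, 0.030, 0.142, 0.852, 0.046,
    ))),
    2019: dict(zip(_COVARIATES, (
        0.748, 0.338, 0.302, 0.700, 0.023, 0.519, 0.969,
        0.318, 0.008, 0.003, 0.006, 0.011, 0.005, 0.197, 0.151,
        0.180, 0.068, 0.139, 0.534, 0.185, 0.170, 0.028, 0.017,
        0.001, 0.024, 0.129, 0.833, 0.024,
    ))),
    2020: dict(zip(_COVARIATES, (
        0.754, 0.327, 0.299, 0.748, 0.027, 0.375, 0.964,
        0.250, 0.006, 0.003, 0.005, 0.002, 0.006, 0.114, 0.176,
        0.173, 0.079, 0.132, 0.549, 0.215, 0.190, 0.029, 0.031,
        0.002, 0.027, 0.145, 0.877, 0.033,
    ))),
}

# Crash counts per year in the emulated data.
STUDY_N = {2018: 16772, 2019: 15117, 2020: 10176}


def _rc(beta, sigma=0.0, theta=None, omega=None) -> RandomCoef:
    return RandomCoef(beta=beta, sigma=sigma, theta=dict(theta or {}), omega=dict(omega or {}))


def _study_truths() -> dict[int, ParameterVector]:
    """Year-specific coefficient regimes echoing the published yearly
    fatality models (fixed effects, normal random coefficients, and their
    mean/variance shifters)."""
    t2018 = ParameterVector(
        constant=-1.708,
        fixed={
            "young": -0.186, "old": 0.346, "foreign": 0.229, "helmet": 1.117,
            "speeding": 0.966, "sign_violation": 0.738, "wrong_direction": 0.581,
            "asleep": 0.734, "sudden_cut": -0.136, "morning_peak": 0.111,
            "afternoon_peak": -0.139, "daytime": -0.331, "smoke": -0.912,
            "rough": -0.841, "curve": 0.089, "wet": -0.526,
        },
        random={
            "gender": _rc(0.285, 0.076, theta={"drunk": -0.432, "license": 0.729, "dry": -0.400}),
            "local_address": _rc(-0.729, 0.234, theta={"dry": 0.424}, omega={"afternoon_peak": 3.061}),
            "festival": _rc(-0.443, 0.234, theta={"license": -0.528}),
        },
    )
    t2019 = ParameterVector(
        constant=-1.537,
        fixed={
            "gender": 0.541, "young": -0.137, "local_address": -0.062,
            "mobile_use": -2.487, "sudden_cut": -0.477, "morning_peak": 0.154,
            "afternoon_peak": -0.093, "night_lit": 0.736, "darkness": 0.771,
            "rough": -0.439,
        },
        random={
            "foreign": _rc(-0.530, 0.938, theta={"drunk": -0.741}),
            "festival": _rc(-0.561, 0.229, theta={"wet": -0.993, "helmet": 0.285, "daytime": 0.285}),
            "dry": _rc(
                -1.854, 0.326,
                theta={"drunk": -0.618, "helmet": -0.229, "license": 1.537,
                       "daytime": 0.242, "old": 0.318},
                omega={"young": -0.748},
            ),
        },
    )
    t2020 = ParameterVector(
        constant=-2.108,
        fixed={
            "young": -0.299, "old": 0.142, "local_address": -0.942,
            "foreign": 0.290, "speeding": 0.891, "sign_violation": 0.435,
            "overtaking": 1.488, "sudden_cut": -0.194, "night_lit": 0.299,
            "maintenance": 1.555, "rough": 0.798, "dry": 0.455,
        },
        random={
            "gender": _rc(0.191, 0.163, theta={"license": 0.583}),
            "helmet": _rc(
                -1.131, 1.260,
                theta={"mobile_use": -2.912, "curve": 0.248, "raining": -0.887, "smoke": -0.655},
                omega={"local_address": 0.698, "afternoon_peak": -6.263, "darkness": 0.407},
            ),
            "drunk": _rc(-0.975, 0.428, theta={"daytime": 0.401, "wet": 1.546, "raining": -1.358}),
            "festival": _rc(-0.092, 1.176, theta={"license": -1.380, "smoke": 0.592}),
        },
    )
    return {2018: t2018, 2019: t2019, 2020: t2020}


def study_scenario(seed: int = 0, n_per_year: dict[int, int] | None = None) -> SyntheticScenario:
    """Full-scale scenario emulating the 2018-2020 study conditions: observed
    prevalences, published-coefficient regimes, and the study's yearly crash
    counts (override ``n_per_year`` to scale)."""
    ns = dict(STUDY_N if n_per_year is None else n_per_year)
    truths = _study_truths()
    years = {
        year: YearRegime(n=ns[year], prevalences=dict(STUDY_PREVALENCES[year]), truth=truths[year])
        for year in sorted(ns)
    }
    return SyntheticScenario(years=years, seed=seed)


_DEMO_PREVALENCES = {
    "gender": 0.742, "speeding": 0.286, "drunk": 0.181,
    "helmet": 0.517, "festival": 0.185, "darkness": 0.199,
}


def demo_scenario(seed: int = 0, n_per_year: int = 2000) -> SyntheticScenario:
    """Small three-year scenario with two random coefficients, used by the
    end-to-end smoke pipeline.  Regimes shift across years (helmet flips
    sign, speeding strengthens) so the stability battery has real signal."""
    def regime(const, speeding, helmet, helmet_sigma, darkness):
        truth = ParameterVector(
            constant=const,
            fixed={"gender": 0.3, "speeding": speeding, "darkness": darkness},
            random={
                "helmet": _rc(helmet, helmet_sigma, theta={"drunk": -0.4}, omega={"festival": 0.5}),
                "festival": _rc(-0.5, 0.3),
            },
        )
        return YearRegime(n=n_per_year, prevalences=dict(_DEMO_PREVALENCES), truth=truth)

    years = {
        2018: regime(-1.7, 0.9, 0.8, 0.6, 0.2),
        2019: regime(-1.5, 0.0, 0.0, 0.8, 0.8),
        2020: regime(-2.1, 0.9, -1.0, 1.0, 0.3),
    }
    return SyntheticScenario(years=years, seed=seed)
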