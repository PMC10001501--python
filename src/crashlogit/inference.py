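"""Fit statistics, average marginal effects, and random-coefficient sign shares."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, ndtr

from .data import CrashTable
from .mixed_logit import DrawSet, FitResult, ParameterVector, _Likelihood, normal_draw_matrix

__all__ = [
    "mcfadden_rho2",
    "adjusted_rho2",
    "average_marginal_effect",
    "SignShare",
    "sign_share",
]


def mcfadden_rho2(ll_beta: float, ll_zero: float) -> float:
    """McFadden pseudo-R^2: ``1 - LL(beta)/LL(0)``."""
    if ll_zero == 0.0:
        raise ZeroDivisionError("constants-only log-likelihood is zero; rho^2 undefined")
    return 1.0 - ll_beta / ll_zero


def adjusted_rho2(ll_beta: float, ll_zero: float, k: int) -> float:
    """Parameter-count-adjusted McFadden pseudo-R^2: ``1 - (LL(beta)-k)/LL(0)``."""
    if ll_zero == 0.0:
        raise ZeroDivisionError("constants-only log-likelihood is zero; rho^2 undefined")
    if k < 0:
        raise ValueError("k must be non-negative")
    return 1.0 - (ll_beta - k) / ll_zero


def _fatal_probabilities(params: ParameterVector, table: CrashTable, draws: DrawSet | None) -> np.ndarray:
    lik = _Likelihood(params, table, draws)
    V, _ = lik._utilities(params.flatten())
    return expit(V).mean(axis=1)


def average_marginal_effect(
    fit: FitResult | ParameterVector,
    table: CrashTable,
    variable: str,
    draws: DrawSet | None = None,
) -> float:
    """Average marginal effect of an indicator on the fatal probability.

    The mean over all records of ``P(fatal | v:=1) - P(fatal | v:=0)``, with
    both counterfactual probabilities simulated under common draws.  The
    variable is toggled everywhere it appears — as a main effect and in any
    mean- or variance-shifter role — the coherent reading of a one-unit
    increase for an indicator.
    """
    params = fit.params if isinstance(fit, FitResult) else fit
    if variable not in table.frame.columns:
        raise KeyError(f"unknown variable {variable!r}")
    if params.random and draws is None:
        if not isinstance(fit, FitResult):
            raise ValueError("draws required for a model with random coefficients")
        draws = normal_draw_matrix(fit.spec, table.n)
    out = []
    for value in (1, 0):
        frame = table.frame.copy()
        frame[variable] = value
        toggled = CrashTable(frame, table.outcome_col, table.year_col)
        out.append(_fatal_probabilities(params, toggled, draws))
    return float(np.mean(out[0] - out[1]))


@dataclass(frozen=True)
class SignShare:
    """Mass of a normal random coefficient below and above zero."""

    variable: str
    below_zero: float
    above_zero: float


def sign_share(mean: float, sd: float, variable: str = "") -> SignShare:
    """Share of the normal mixing distribution on each side of zero.

    ``Phi(-mean/sd)`` below zero for ``sd > 0``; a step function for the
    degenerate ``sd = 0`` case (0.5/0.5 exactly at mean zero).  This is the
    marginal split at zero shifter values, the quantity usually quoted as
    "X% of such crashes had a lower probability of death".
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        below = 0.5 if mean == 0 else float(mean < 0)
    else:
        below = float(ndtr(-mean / sd))
    return SignShare(variable=variable, below_zero=below, above_zero=1.0 - below)


def sample_averaged_sign_share(
    params: ParameterVector, table: CrashTable, variable: str
) -> SignShare:
    """Sign share with the coefficient mean evaluated per record (including
    its Theta.z mean shifters), averaged over the sample."""
    rc = params.random[variable]
    n = table.n
    mean = np.full(n, rc.beta)
    if rc.theta:
        mean = mean + table.design(list(rc.theta)) @ np.asarray(list(rc.theta.values()))
    scale = np.full(n, abs(rc.sigma))
    if rc.omega:
        scale = scale * np.exp(table.design(list(rc.omega)) @ np.asarray(list(rc.omega.values())))
    with np.errstate(divide="ignore", invalid="ignore"):
        below = np.where(scale > 0, ndtr(-mean / np.maximum(scale, 1e-300)), (mean < 0).astype(float))
    below = float(np.mean(below))
    return SignShare(variable=variable, below_zero=below, above_zero=1.0 - below)
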