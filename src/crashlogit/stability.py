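"""Likelihood-ratio temporal-instability battery.

Pairwise transferability: for each ordered pair of years (donor m2, recipient
m1), the donor's significant specification is re-estimated on the recipient's
data and compared with the recipient's own converged model,

    chi2 = -2 * [ LL(beta_m2|m1) - LL(beta_m1) ],

read against a chi-square with degrees of freedom equal to the transferred
specification's parameter count.  The pooled-vs-separate test compares a
single all-years model against the sum of per-year models.  Large statistics
indicate that the covariate effects shift over time, so per-year models are
preferred over a pooled one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .data import CrashTable
from .mixed_logit import (
    EstimationError,
    FitResult,
    ModelSpec,
    RandomSpec,
    fit_model,
)

__all__ = [
    "StabilityCell",
    "StabilityReport",
    "retained_spec",
    "transfer_fit",
    "lr_transfer_chi2",
    "chi2_confidence",
    "stability_matrix",
    "pooled_separation_test",
]

NEG_TOL = 1e-4  # chi2 this far below zero is numerical noise, clamped


@dataclass(frozen=True)
class StabilityCell:
    """One transferability result: donor spec m2 applied to recipient data m1."""

    donor: int | None
    recipient: int | None
    chi2: float
    df: int
    confidence: float  # percent

    def render(self) -> str:
        return f"{self.chi2:.2f} ({self.df}) [{self.confidence:.2f}%]"


@dataclass
class StabilityReport:
    """All ordered-pair cells plus the pooled-vs-separate test."""

    cells: list[StabilityCell] = field(default_factory=list)
    pooled: StabilityCell | None = None

    def cell(self, donor: int, recipient: int) -> StabilityCell:
        for c in self.cells:
            if c.donor == donor and c.recipient == recipient:
                return c
        raise KeyError(f"no cell for donor {donor}, recipient {recipient}")

    def to_json_dict(self) -> dict:
        out = {
            "pairwise": [
                {
                    "donor": c.donor,
                    "recipient": c.recipient,
                    "chi2": float(c.chi2),
                    "df": int(c.df),
                    "confidence_pct": float(c.confidence),
                }
                for c in self.cells
            ]
        }
        if self.pooled is not None:
            out["pooled_vs_separate"] = {
                "chi2": float(self.pooled.chi2),
                "df": int(self.pooled.df),
                "confidence_pct": float(self.pooled.confidence),
            }
        return out

    def render_matrix(self) -> str:
        """Recipient-by-donor text matrix, cells as 'chi2 (df) [conf%]'."""
        years = sorted({c.recipient for c in self.cells})
        donors = sorted({c.donor for c in self.cells})
        width = 24
        lines = ["m1\\m2".ljust(8) + "".join(str(d).ljust(width) for d in donors)]
        for r in years:
            row = [str(r).ljust(8)]
            for d in donors:
                row.append(("-" if d == r else self.cell(d, r).render()).ljust(width))
            lines.append("".join(row))
        return "\n".join(lines)


def retained_spec(fit: FitResult, retention_t: float = 1.645) -> ModelSpec:
    """Donor specification restricted to its significant parameters.

    Convention: the constant is always kept; a fixed covariate is kept when
    ``|t| >= retention_t``; a random covariate stays random when its SD is
    significant, is demoted to fixed when only its mean is, and is dropped
    when neither; individual mean/variance shifter terms are kept by their
    own t-statistics.
    """
    t = dict(zip(fit.labels(), np.nan_to_num(fit.tstat)))
    keep = lambda label: abs(t[label]) >= retention_t
    fixed = [c for c in fit.spec.fixed if keep(c)]
    random = []
    for r in fit.spec.random:
        sd_sig = keep(f"sd({r.name})")
        mean_sig = keep(r.name)
        if sd_sig:
            z = tuple(s for s in r.z if keep(f"{r.name}: {s} (mean)"))
            w = tuple(s for s in r.w if keep(f"{r.name}: {s} (variance)"))
            random.append(RandomSpec(r.name, z=z, w=w))
        elif mean_sig:
            fixed.append(r.name)
    if not fixed and not random and not fit.spec.include_constant:
        raise EstimationError("retained specification is empty")
    return ModelSpec(
        fixed=tuple(fixed),
        random=tuple(random),
        outcome=fit.spec.outcome,
        include_constant=fit.spec.include_constant,
        n_draws=fit.spec.n_draws,
        halton_burn=fit.spec.halton_burn,
        seed=fit.spec.seed,
    )


def transfer_fit(spec_m2: ModelSpec, table_m1: CrashTable) -> FitResult:
    """Re-estimate the donor's retained specification on the recipient's data
    (parameters are estimated afresh, not frozen at donor values)."""
    if not spec_m2.fixed and not spec_m2.random and not spec_m2.include_constant:
        raise EstimationError("transferred specification is empty")
    return fit_model(spec_m2, table_m1)


def lr_transfer_chi2(ll_transfer: float, ll_own: float, tol: float = NEG_TOL) -> float:
    """Transferability statistic ``-2 (LL_transfer - LL_own)``.

    Negative values within ``tol`` are numerical noise and clamp to zero; a
    transfer log-likelihood materially above the recipient's own signals that
    the specifications are not nested and raises.
    """
    if ll_transfer > ll_own + tol:
        raise ValueError(
            f"nesting violation: transfer LL {ll_transfer:.6f} exceeds own LL {ll_own:.6f}"
        )
    return max(0.0, -2.0 * (ll_transfer - ll_own))


def chi2_confidence(chi2: float, df: int) -> float:
    """Confidence level in percent: 100 x chi-square CDF at the statistic."""
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return 100.0 * float(chi2_dist.cdf(chi2, df))


def stability_matrix(
    fits_by_year: dict[int, FitResult],
    tables_by_year: dict[int, CrashTable],
    retention_t: float = 1.645,
) -> StabilityReport:
    """All ordered (donor, recipient) transferability cells.

    ``fits_by_year`` holds each year's own converged fit of the candidate
    specification; the donor's retained spec is re-estimated on the recipient
    year, and df is the transferred specification's parameter count.
    """
    years = sorted(fits_by_year)
    if len(years) < 2:
        raise ValueError("need at least two years")
    report = StabilityReport()
    for m2 in years:
        spec_m2 = retained_spec(fits_by_year[m2], retention_t)
        for m1 in years:
            if m1 == m2:
                continue
            try:
                tfit = transfer_fit(spec_m2, tables_by_year[m1])
            except EstimationError as exc:
                raise EstimationError(f"transfer {m2}->{m1} failed: {exc}") from exc
            stat = lr_transfer_chi2(tfit.ll_beta, fits_by_year[m1].ll_beta)
            df = tfit.k
            report.cells.append(
                StabilityCell(
                    donor=m2,
                    recipient=m1,
                    chi2=stat,
                    df=df,
                    confidence=chi2_confidence(stat, df),
                )
            )
    return report


def pooled_separation_test(
    ll_pooled: float,
    ll_years: list[float],
    k_pooled: int,
    k_years: list[int],
) -> StabilityCell:
    """Pooled-vs-separate likelihood-ratio test.

    ``chi2 = -2 (LL_pooled - sum LL_years)``; df is the summed per-year
    parameter count minus the pooled model's.
    """
    df = int(sum(k_years) - k_pooled)
    if len(ll_years) > 1 and df < 1:
        raise ValueError(f"invalid df {df}: sum of yearly k must exceed pooled k")
    stat = -2.0 * (ll_pooled - sum(ll_years))
    if stat < -NEG_TOL:
        raise ValueError(f"pooled LL exceeds summed yearly LLs (chi2 = {stat:.6f})")
    stat = max(0.0, stat)
    df = max(df, 1)
    return StabilityCell(
        donor=None, recipient=None, chi2=stat, df=df, confidence=chi2_confidence(stat, df)
    )
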