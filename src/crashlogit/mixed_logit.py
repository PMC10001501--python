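"""Mixed (random-parameters) logit with heterogeneity in means and variances.

The latent propensity of crash ``m`` ending fatally is ``S_m = beta_m' x_m +
eps_m`` with i.i.d. type-I extreme-value errors, which yields the logit
probability.  Each random coefficient varies across crashes as

    beta_rm = beta_r + Theta_r' z_m + sigma_r * exp(omega_r' w_m) * nu_m,

where ``z_m`` shifts the coefficient's mean, ``w_m`` scales its standard
deviation, and ``nu_m`` is a standard-normal disturbance.  The likelihood
integrates the logit probability over the normal mixing distribution; the
integral is approximated by averaging over inverse-normal-transformed Halton
draws, and the simulated log-likelihood is maximized by quasi-Newton (BFGS)
iteration with an analytic gradient.  Standard errors come from the inverse
negative Hessian, obtained by central differencing of the gradient at the
optimum.

The model is binary (fatal vs non-fatal) with the non-fatal utility
normalized to zero; the simulated probabilities for the two outcomes sum to
one record by record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, ndtri

import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .data import CrashTable

__all__ = [
    "ModelSpec",
    "RandomSpec",
    "RandomCoef",
    "ParameterVector",
    "DrawSet",
    "FitResult",
    "EstimationError",
    "halton_draws",
    "normal_draw_matrix",
    "random_coefficients",
    "simulated_probability",
    "simulated_loglik",
    "constants_only_loglik",
    "fit_model",
]

PROB_FLOOR = 1e-30  # floor before log(), guards extreme draws
GRAD_TOL = 1e-5  # BFGS gradient max-norm target
GRAD_ACCEPT = 1e-2  # accept an optimizer exit if the gradient is this small
MAX_ITER = 500
OMEGA_BOUND = 15.0  # |omega| cap; exp(+-15) spans 6 orders of magnitude of SD


class EstimationError(RuntimeError):
    """Estimation failed (separation, non-convergence, degenerate inputs)."""


# ---------------------------------------------------------------------------
# specification and parameter containers


@dataclass(frozen=True)
class RandomSpec:
    """One random coefficient: its covariate, mixing family, and shifters."""

    name: str
    distribution: str = "normal"
    z: tuple[str, ...] = ()  # heterogeneity-in-mean shifters
    w: tuple[str, ...] = ()  # heterogeneity-in-variance shifters

    def __post_init__(self):
        if self.distribution != "normal":
            raise ValueError(f"unsupported mixing distribution {self.distribution!r}")
        object.__setattr__(self, "z", tuple(self.z))
        object.__setattr__(self, "w", tuple(self.w))


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter fixed vs random, and how the integral is drawn."""

    fixed: tuple[str, ...] = ()
    random: tuple[RandomSpec, ...] = ()
    outcome: str = "fatal"
    include_constant: bool = True
    n_draws: int = 500
    halton_burn: int = 50
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "fixed", tuple(self.fixed))
        rnd = tuple(r if isinstance(r, RandomSpec) else RandomSpec(**r) for r in self.random)
        object.__setattr__(self, "random", rnd)
        dup = set(self.fixed) & {r.name for r in rnd}
        if dup:
            raise ValueError(f"covariate(s) both fixed and random: {sorted(dup)}")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")

    @property
    def random_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.random)

    def to_dict(self) -> dict:
        return {
            "fixed": list(self.fixed),
            "random": [
                {"name": r.name, "distribution": r.distribution, "z": list(r.z), "w": list(r.w)}
                for r in self.random
            ],
            "outcome": self.outcome,
            "include_constant": self.include_constant,
            "n_draws": self.n_draws,
            "halton_burn": self.halton_burn,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            fixed=tuple(d.get("fixed", ())),
            random=tuple(
                RandomSpec(r["name"], distribution=r.get("distribution", "normal"),
                           z=tuple(r.get("z", ())), w=tuple(r.get("w", ())))
                for r in d.get("random", ())
            ),
            outcome=d.get("outcome", "fatal"),
            include_constant=bool(d.get("include_constant", True)),
            n_draws=int(d.get("n_draws", 500)),
            halton_burn=int(d.get("halton_burn", 50)),
            seed=int(d.get("seed", 0)),
        )

    def n_parameters(self) -> int:
        k = int(self.include_constant) + len(self.fixed)
        for r in self.random:
            k += 2 + len(r.z) + len(r.w)
        return k


@dataclass
class RandomCoef:
    """Estimated pieces of one random coefficient."""

    beta: float = 0.0
    theta: dict[str, float] = field(default_factory=dict)  # mean shifters
    sigma: float = 0.0
    omega: dict[str, float] = field(default_factory=dict)  # variance shifters


@dataclass
class ParameterVector:
    """All estimable quantities: fixed betas plus (beta, Theta, sigma, omega)
    per random coefficient.  ``sigma`` is sign-invariant under normal mixing
    and is reported as its magnitude."""

    constant: float | None = 0.0
    fixed: dict[str, float] = field(default_factory=dict)
    random: dict[str, RandomCoef] = field(default_factory=dict)

    @classmethod
    def template(cls, spec: ModelSpec) -> "ParameterVector":
        return cls(
            constant=0.0 if spec.include_constant else None,
            fixed={c: 0.0 for c in spec.fixed},
            random={
                r.name: RandomCoef(theta={z: 0.0 for z in r.z}, omega={w: 0.0 for w in r.w})
                for r in spec.random
            },
        )

    def labels(self) -> list[str]:
        out = []
        if self.constant is not None:
            out.append("constant")
        out.extend(self.fixed)
        for name, rc in self.random.items():
            out.append(name)
            out.extend(f"{name}: {z} (mean)" for z in rc.theta)
            out.append(f"sd({name})")
            out.extend(f"{name}: {w} (variance)" for w in rc.omega)
        return out

    def flatten(self) -> np.ndarray:
        vals = []
        if self.constant is not None:
            vals.append(self.constant)
        vals.extend(self.fixed.values())
        for rc in self.random.values():
            vals.append(rc.beta)
            vals.extend(rc.theta.values())
            vals.append(rc.sigma)
            vals.extend(rc.omega.values())
        return np.asarray(vals, dtype=float)

    def unflatten(self, x: np.ndarray) -> "ParameterVector":
        x = np.asarray(x, dtype=float)
        i = 0
        const = None
        if self.constant is not None:
            const = float(x[i]); i += 1
        fixed = {}
        for c in self.fixed:
            fixed[c] = float(x[i]); i += 1
        random = {}
        for name, rc in self.random.items():
            beta = float(x[i]); i += 1
            theta = {}
            for z in rc.theta:
                theta[z] = float(x[i]); i += 1
            sigma = float(x[i]); i += 1
            omega = {}
            for w in rc.omega:
                omega[w] = float(x[i]); i += 1
            random[name] = RandomCoef(beta=beta, theta=theta, sigma=sigma, omega=omega)
        if i != len(x):
            raise ValueError(f"parameter vector length {len(x)} != template size {i}")
        return ParameterVector(constant=const, fixed=fixed, random=random)

    @property
    def k(self) -> int:
        return len(self.flatten())


# ---------------------------------------------------------------------------
# Halton draw engine


def _is_prime(p: int) -> bool:
    if p < 2:
        return False
    return all(p % d for d in range(2, int(p**0.5) + 1))


def _primes(count: int) -> list[int]:
    out, p = [], 2
    while len(out) < count:
        if _is_prime(p):
            out.append(p)
        p += 1
    return out


def halton_draws(prime: int, n: int, burn: int = 0) -> np.ndarray:
    """Radical-inverse (van der Corput) sequence in base ``prime``.

    Returns ``n`` values strictly inside (0, 1), skipping the first ``burn``
    non-zero terms of the sequence (the index-0 term, which is exactly 0, is
    never emitted).
    """
    if not _is_prime(prime):
        raise ValueError(f"Halton base must be prime, got {prime}")
    if n < 1:
        raise ValueError("n must be >= 1")
    idx = np.arange(burn + 1, burn + n + 1, dtype=np.int64)
    out = np.zeros(n, dtype=float)
    f = 1.0 / prime
    while idx.any():
        out += f * (idx % prime)
        idx //= prime
        f /= prime
    return out


@dataclass
class DrawSet:
    """Standard-normal quasi-random draws, one (n_obs, n_draws) matrix per
    random coefficient.  Deterministic given the spec: the k-th random
    coefficient uses the k-th prime base (2, 3, 5, ...)."""

    draws: dict[str, np.ndarray]
    n_draws: int

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[name]


def normal_draw_matrix(spec: ModelSpec, n_obs: int) -> DrawSet:
    """Inverse-normal-transformed Halton draws laid out per observation.

    Each observation's block of ``n_draws`` consecutive sequence values forms
    its row, so every crash integrates over its own stretch of the sequence.
    """
    if not spec.random:
        raise ValueError("spec has no random coefficients")
    total = n_obs * spec.n_draws
    if total > 500_000_000:
        raise MemoryError(f"draw matrix of {total} values exceeds the resource guard")
    primes = _primes(len(spec.random))
    draws = {}
    for r, p in zip(spec.random, primes):
        u = halton_draws(p, total, burn=spec.halton_burn)
        draws[r.name] = ndtri(u).reshape(n_obs, spec.n_draws)
    return DrawSet(draws=draws, n_draws=spec.n_draws)


# ---------------------------------------------------------------------------
# likelihood internals


def _as_row(record) -> dict[str, float]:
    if isinstance(record, pd.Series):
        return record.to_dict()
    return dict(record)


def random_coefficients(params: ParameterVector, record, draws_row) -> dict[str, np.ndarray]:
    """Per-draw realized coefficient values for one record.

    ``draws_row`` maps each random covariate to its vector of nu draws.
    """
    row = _as_row(record)
    out = {}
    for name, rc in params.random.items():
        mean = rc.beta + sum(th * row[z] for z, th in rc.theta.items())
        scale = rc.sigma * np.exp(sum(om * row[w] for w, om in rc.omega.items()))
        nu = np.atleast_1d(np.asarray(draws_row[name], dtype=float))
        out[name] = mean + scale * nu
    return out


def simulated_probability(params: ParameterVector, record, draws_row=None) -> float:
    """Simulated probability of the fatal outcome for one record: the average
    over draws of the logistic of the realized utility."""
    row = _as_row(record)
    v = (params.constant or 0.0) + sum(b * row[c] for c, b in params.fixed.items())
    if params.random:
        if draws_row is None:
            raise ValueError("draws required for a model with random coefficients")
        coefs = random_coefficients(params, row, draws_row)
        v = v + sum(coefs[name] * row[name] for name in params.random)
    return float(np.mean(expit(v)))


class _Likelihood:
    """Vectorized simulated log-likelihood and its analytic gradient.

    Precomputes the design blocks and nu-draw matrices once; every call works
    on the flat parameter vector laid out by ``ParameterVector.flatten``.
    """

    def __init__(self, template: ParameterVector, table: CrashTable, draws: DrawSet | None):
        self.template = template
        self.y = table.outcome().astype(float)
        n = table.n
        self.n = n
        self.has_const = template.constant is not None
        self.fixed_names = list(template.fixed)
        self.Xf = table.design(self.fixed_names) if self.fixed_names else np.zeros((n, 0))
        self.rand = []
        for name, rc in template.random.items():
            if draws is None:
                raise ValueError("draws required for a model with random coefficients")
            self.rand.append(
                dict(
                    name=name,
                    x=table.design([name])[:, 0],
                    Z=table.design(list(rc.theta)) if rc.theta else np.zeros((n, 0)),
                    W=table.design(list(rc.omega)) if rc.omega else np.zeros((n, 0)),
                    nu=draws[name],
                )
            )
        self.R = draws.n_draws if self.rand else 1

    def _split(self, x: np.ndarray):
        i = 0
        const = 0.0
        if self.has_const:
            const = x[i]; i += 1
        bf = x[i : i + len(self.fixed_names)]; i += len(self.fixed_names)
        parts = []
        for r in self.rand:
            q, s = r["Z"].shape[1], r["W"].shape[1]
            beta = x[i]; i += 1
            theta = x[i : i + q]; i += q
            sigma = x[i]; i += 1
            omega = x[i : i + s]; i += s
            parts.append((beta, theta, sigma, omega))
        return const, bf, parts

    def _utilities(self, x: np.ndarray):
        """Returns V (n, R), plus per-random (mean, scale=sigma*e^{omega w}) arrays."""
        const, bf, parts = self._split(x)
        base = const + (self.Xf @ bf if bf.size else 0.0)
        base = np.broadcast_to(np.asarray(base, dtype=float), (self.n,)).copy()
        V = np.repeat(base[:, None], self.R, axis=1) if self.rand else base[:, None]
        scales = []
        for r, (beta, theta, sigma, omega) in zip(self.rand, parts):
            mean = beta + (r["Z"] @ theta if theta.size else 0.0)
            escale = np.exp(r["W"] @ omega) if omega.size else np.ones(self.n)
            scale = sigma * escale
            V += (mean * r["x"])[:, None] + (scale * r["x"])[:, None] * r["nu"]
            scales.append((mean, escale, scale))
        return V, scales

    def prob_obs(self, x: np.ndarray):
        V, scales = self._utilities(x)
        s = expit(V)
        sbar = s.mean(axis=1)
        pobs = np.where(self.y == 1, sbar, 1.0 - sbar)
        return np.maximum(pobs, PROB_FLOOR), s, scales

    def loglik(self, x: np.ndarray) -> float:
        pobs, _, _ = self.prob_obs(x)
        return float(np.log(pobs).sum())

    def value_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Log-likelihood and gradient from one pass over the draw matrix
        (cached on x, so scipy's separate fun/jac calls cost one evaluation)."""
        key = x.tobytes()
        if getattr(self, "_cache_key", None) != key:
            pobs, s, scales = self.prob_obs(x)
            f = float(np.log(pobs).sum())
            g = self._grad_from(x, pobs, s, scales)
            self._cache_key, self._cache_val = key, (f, g)
        return self._cache_val

    def grad(self, x: np.ndarray) -> np.ndarray:
        pobs, s, scales = self.prob_obs(x)
        return self._grad_from(x, pobs, s, scales)

    def _grad_from(self, x, pobs, s, scales) -> np.ndarray:
        D = s * (1.0 - s)  # (n, R)
        g = (2.0 * self.y - 1.0) / pobs  # (n,)
        Dbar = D.mean(axis=1)
        a = g * Dbar  # weight for draw-free utility derivatives
        out = []
        if self.has_const:
            out.append(a.sum())
        if self.fixed_names:
            out.extend(a @ self.Xf)
        _, _, parts = self._split(x)
        for r, (beta, theta, sigma, omega), (mean, escale, scale) in zip(
            self.rand, parts, scales
        ):
            xr = r["x"]
            t = (D * r["nu"]).mean(axis=1)  # (n,)
            out.append(float((a * xr).sum()))  # d/d beta
            if theta.size:
                out.extend((a * xr) @ r["Z"])  # d/d Theta
            u = g * xr * escale * t
            out.append(float(u.sum()))  # d/d sigma
            if omega.size:
                out.extend((sigma * u) @ r["W"])  # d/d omega
        return np.asarray(out, dtype=float)


def simulated_loglik(params: ParameterVector, table: CrashTable, draws: DrawSet | None = None) -> float:
    """Sum over records of the log simulated probability of the observed
    outcome, with probabilities floored at a tiny positive constant."""
    lik = _Likelihood(params, table, draws)
    return lik.loglik(params.flatten())


def constants_only_loglik(table: CrashTable) -> float:
    """Closed-form log-likelihood of the intercept-only binary logit:
    ``n1*log(p) + n0*log(1-p)`` with ``p`` the observed fatal share."""
    if table.n == 0:
        raise ValueError("empty crash table")
    y = table.outcome()
    n1 = int(y.sum())
    n0 = table.n - n1
    if n1 == 0 or n0 == 0:
        warnings.warn("single-class outcome: constants-only log-likelihood is degenerate")
        return 0.0
    p = n1 / table.n
    return n1 * np.log(p) + n0 * np.log(1.0 - p)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Estimates with inference and fit statistics.

    The summary layout mirrors the field's reporting convention: each random
    coefficient's mean row is followed by its SD row, then its
    heterogeneity-in-mean and heterogeneity-in-variance shifter rows.
    """

    spec: ModelSpec
    params: ParameterVector
    estimates: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    ll_beta: float
    ll_zero: float
    k: int
    n: int
    converged: bool
    n_iter: int
    mcfadden_rho2: float
    adjusted_rho2: float

    def labels(self) -> list[str]:
        return self.params.labels()

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.labels(),
                "estimate": np.round(self.estimates, 6),
                "std_error": np.round(self.se, 6),
                "t_stat": np.round(self.tstat, 4),
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "parameters": self.labels(),
            "estimates": [float(v) for v in self.estimates],
            "std_errors": [float(v) for v in self.se],
            "t_stats": [float(v) for v in self.tstat],
            "ll_beta": float(self.ll_beta),
            "ll_zero": float(self.ll_zero),
            "k": int(self.k),
            "n": int(self.n),
            "converged": bool(self.converged),
            "mcfadden_rho2": float(self.mcfadden_rho2),
            "adjusted_rho2": float(self.adjusted_rho2),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "FitResult":
        """Rebuild a fit from its serialized form (enough to rerun the
        stability battery: spec, estimates, t-stats, log-likelihoods)."""
        spec = ModelSpec.from_dict(d["spec"])
        template = ParameterVector.template(spec)
        est = np.asarray(d["estimates"], dtype=float)
        se = np.asarray(d["std_errors"], dtype=float)
        return cls(
            spec=spec,
            params=template.unflatten(est),
            estimates=est,
            se=se,
            tstat=np.asarray(d["t_stats"], dtype=float),
            ll_beta=float(d["ll_beta"]),
            ll_zero=float(d["ll_zero"]),
            k=int(d["k"]),
            n=int(d["n"]),
            converged=bool(d["converged"]),
            n_iter=0,
            mcfadden_rho2=float(d["mcfadden_rho2"]),
            adjusted_rho2=float(d["adjusted_rho2"]),
        )


def _start_values(spec: ModelSpec, table: CrashTable) -> ParameterVector:
    """Plain-logit starting values for the deterministic parts; sigma starts
    at 0.1, all shifters at zero."""
    cols = list(spec.fixed) + list(spec.random_names)
    X = table.design(cols) if cols else np.zeros((table.n, 0))
    if spec.include_constant:
        X = sm.add_constant(X, prepend=True, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(table.outcome(), X).fit(disp=False, maxiter=200)
        coef = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(coef)):
            raise ValueError("non-finite plain-logit start")
    except PerfectSeparationError as exc:
        raise EstimationError(f"perfect separation in starting fit: {exc}") from exc
    except Exception:  # any other starting-fit hiccup: start from zeros
        coef = np.zeros(X.shape[1])
    i = int(spec.include_constant)
    pv = ParameterVector.template(spec)
    if spec.include_constant:
        pv.constant = float(coef[0])
    for j, c in enumerate(spec.fixed):
        pv.fixed[c] = float(coef[i + j])
    for j, name in enumerate(spec.random_names):
        pv.random[name].beta = float(coef[i + len(spec.fixed) + j])
        pv.random[name].sigma = 0.1
    return pv


def _numeric_hessian(grad, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    for j in range(k):
        h = step * max(1.0, abs(x[j]))
        e = np.zeros(k)
        e[j] = h
        H[:, j] = (grad(x + e) - grad(x - e)) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit_model(spec: ModelSpec, table: CrashTable, draws: DrawSet | None = None) -> FitResult:
    """Maximize the simulated log-likelihood by BFGS.

    Standard errors are taken from the inverse negative numerical Hessian at
    the optimum; the McFadden pseudo-R^2 and its parameter-count-adjusted
    variant are populated from the constants-only log-likelihood.
    """
    y = table.outcome()
    if y.min() == y.max():
        raise EstimationError("outcome has a single class; cannot estimate")
    cols = list(spec.fixed) + list(spec.random_names)
    if cols:
        sd = table.design(cols).std(axis=0)
        dead = [c for c, s in zip(cols, sd) if s == 0.0]
        if dead:
            raise EstimationError(f"zero-variance covariate(s) in spec: {dead}")
    if spec.random and draws is None:
        draws = normal_draw_matrix(spec, table.n)

    start = _start_values(spec, table)
    lik = _Likelihood(start, table, draws)
    x0 = start.flatten()

    # heterogeneity-in-variance coefficients are bounded: the sigma -> 0,
    # omega -> inf ridge is a flat direction the optimizer must not chase
    bounds = []
    i = int(spec.include_constant) + len(spec.fixed)
    bounds.extend([(None, None)] * i)
    for r in spec.random:
        bounds.extend([(None, None)] * (1 + len(r.z) + 1))
        bounds.extend([(-OMEGA_BOUND, OMEGA_BOUND)] * len(r.w))

    def neg(x):
        f, g = lik.value_and_grad(x)
        return -f, -g

    def accepted(res):
        # absolute gradient target, or relative to the log-likelihood scale:
        # a sigma ~ 0 ridge leaves the variance shifter unidentified and the
        # gradient there never reaches the absolute target although the
        # log-likelihood is flat to machine-level precision
        gmax = float(np.max(np.abs(lik.grad(res.x))))
        return gmax, gmax < GRAD_ACCEPT or gmax < 1e-4 * (1.0 + abs(res.fun))

    res = minimize(
        neg, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"gtol": GRAD_TOL, "ftol": 1e-12, "maxiter": MAX_ITER},
    )
    gmax, ok = accepted(res)
    if not ok:  # restart once with fresh curvature memory
        res = minimize(
            neg, res.x, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"gtol": GRAD_TOL, "ftol": 1e-14, "maxiter": MAX_ITER},
        )
        gmax, ok = accepted(res)
    if not ok:
        raise EstimationError(
            f"no convergence in {res.nit} iterations: {res.message} (|grad|_max={gmax:.3g})"
        )
    converged = True

    xhat = np.asarray(res.x, dtype=float)
    H = _numeric_hessian(lik.grad, xhat)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(-H)
    var = np.diag(cov).copy()
    var[var < 0] = np.nan
    se = np.sqrt(var)

    params = start.unflatten(xhat)
    # sigma is sign-invariant under normal mixing; report magnitudes
    for rc in params.random.values():
        rc.sigma = abs(rc.sigma)
    est = params.flatten()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se

    ll_beta = float(lik.loglik(xhat))
    ll_zero = float(constants_only_loglik(table))
    k = len(xhat)
    rho2 = 1.0 - ll_beta / ll_zero
    adj = 1.0 - (ll_beta - k) / ll_zero
    return FitResult(
        spec=spec,
        params=params,
        estimates=est,
        se=se,
        tstat=t,
        ll_beta=ll_beta,
        ll_zero=ll_zero,
        k=k,
        n=table.n,
        converged=converged,
        n_iter=int(res.nit),
        mcfadden_rho2=rho2,
        adjusted_rho2=adj,
    )
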