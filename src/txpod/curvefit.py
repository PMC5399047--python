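"""Dose-response model engine shared by the gene-level and apical workflows.

Continuous models (Gaussian likelihood, constant variance) and dichotomous
models (binomial likelihood) are fit by maximum likelihood.  For the Gaussian
constant-variance case the ML mean-parameter estimates coincide with least
squares, so linear/polynomial families are solved exactly and the nonlinear
families (power, Hill, exponential) use bounded nonlinear least squares with
moment-based starting values plus jittered restarts.

The benchmark dose (BMD) for continuous data is the smallest positive dose at
which the mean response departs from the control mean by ``bmr`` residual
standard deviations; for dichotomous data it is the dose producing ``bmr``
extra risk over background.  The BMDL is a one-sided 95% profile-likelihood
lower bound (deviance cutoff chi2_1(0.90)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

CONTINUOUS_FAMILIES = ("linear", "poly2", "poly3", "power", "hill", "exp4", "exp5")
DICHOTOMOUS_FAMILIES = (
    "gamma",
    "dhill",
    "logistic",
    "loglogistic",
    "probit",
    "logprobit",
    "weibull",
    "multistage",
)

PARAM_NAMES = {
    "linear": ("b0", "b1"),
    "poly2": ("b0", "b1", "b2"),
    "poly3": ("b0", "b1", "b2", "b3"),
    "power": ("g", "beta", "delta"),
    "hill": ("g", "v", "k", "n"),
    "exp4": ("a", "b", "c"),
    "exp5": ("a", "b", "c", "d"),
    "gamma": ("g", "a", "b"),
    "dhill": ("g", "v", "a", "b"),
    "logistic": ("a", "b"),
    "loglogistic": ("g", "a", "b"),
    "probit": ("a", "b"),
    "logprobit": ("g", "a", "b"),
    "weibull": ("g", "a", "b"),
    "multistage": ("g", "b1", "b2"),
}

#: one-sided 95% profile cutoff: chi-square(1) quantile at 0.90
PROFILE_CUTOFF_095 = float(stats.chi2.ppf(0.90, 1))

_TINY = 1e-12


@dataclass
class ModelSpec:
    """A model family plus a named parameter vector."""

    family: str
    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        names = PARAM_NAMES.get(self.family)
        if names is None:
            raise ValueError(f"unknown model family: {self.family!r}")
        if len(self.params) != len(names):
            raise ValueError(
                f"{self.family} expects {len(names)} parameters, got {len(self.params)}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.family]

    def __getitem__(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.params)))


def mean_function(spec: ModelSpec):
    """Return mu(d) for a continuous spec, vectorized over doses."""
    f, p = spec.family, spec.params
    if f == "linear":
        return lambda d: p[0] + p[1] * np.asarray(d, float)
    if f == "poly2":
        return lambda d: p[0] + p[1] * np.asarray(d, float) + p[2] * np.asarray(d, float) ** 2
    if f == "poly3":
        return lambda d: (
            p[0]
            + p[1] * np.asarray(d, float)
            + p[2] * np.asarray(d, float) ** 2
            + p[3] * np.asarray(d, float) ** 3
        )
    if f == "power":
        return lambda d: p[0] + p[1] * np.power(np.asarray(d, float), p[2])
    if f == "hill":

        def _hill(d):
            d = np.asarray(d, float)
            dn = np.power(d, p[3])
            return p[0] + p[1] * dn / (p[2] ** p[3] + dn)

        return _hill
    if f == "exp4":
        return lambda d: p[0] * (p[2] - (p[2] - 1.0) * np.exp(-p[1] * np.asarray(d, float)))
    if f == "exp5":
        return lambda d: p[0] * (
            p[2] - (p[2] - 1.0) * np.exp(-np.power(p[1] * np.asarray(d, float), p[3]))
        )
    raise ValueError(f"not a continuous family: {f!r}")


def prob_function(spec: ModelSpec):
    """Return P(response | dose) for a dichotomous spec."""
    f, p = spec.family, spec.params

    def _logd(d):
        d = np.asarray(d, float)
        with np.errstate(divide="ignore"):
            return np.where(d > 0, np.log(np.maximum(d, _TINY)), -np.inf)

    if f == "logistic":
        return lambda d: 1.0 / (1.0 + np.exp(-(p[0] + p[1] * np.asarray(d, float))))
    if f == "probit":
        return lambda d: stats.norm.cdf(p[0] + p[1] * np.asarray(d, float))
    if f == "loglogistic":

        def _ll(d):
            z = p[1] + p[2] * _logd(d)
            out = p[0] + (1.0 - p[0]) / (1.0 + np.exp(-z))
            return np.where(np.asarray(d, float) > 0, out, p[0])

        return _ll
    if f == "logprobit":

        def _lp(d):
            z = p[1] + p[2] * _logd(d)
            out = p[0] + (1.0 - p[0]) * stats.norm.cdf(z)
            return np.where(np.asarray(d, float) > 0, out, p[0])

        return _lp
    if f == "weibull":
        return lambda d: p[0] + (1.0 - p[0]) * (
            1.0 - np.exp(-p[2] * np.power(np.asarray(d, float), p[1]))
        )
    if f == "gamma":
        return lambda d: p[0] + (1.0 - p[0]) * stats.gamma.cdf(
            p[2] * np.asarray(d, float), p[1]
        )
    if f == "multistage":
        return lambda d: p[0] + (1.0 - p[0]) * (
            1.0 - np.exp(-p[1] * np.asarray(d, float) - p[2] * np.asarray(d, float) ** 2)
        )
    if f == "dhill":

        def _dh(d):
            z = p[2] + p[3] * _logd(d)
            out = p[0] + (p[1] - p[1] * p[0]) / (1.0 + np.exp(-z))
            return np.where(np.asarray(d, float) > 0, out, p[0])

        return _dh
    raise ValueError(f"not a dichotomous family: {f!r}")


@dataclass
class FitResult:
    """One fitted model with its likelihood bookkeeping.

    ``n_params`` counts estimated parameters (continuous fits include the
    residual SD).  ``aic`` satisfies ``2 * n_params - 2 * loglik`` exactly.
    """

    spec: ModelSpec
    loglik: float
    aic: float
    n_params: int
    converged: bool
    n_iter: int = 0
    sigma: float | None = None
    rss: float | None = None
    # data retained for GOF / profiling
    doses: np.ndarray = field(default_factory=lambda: np.array([]))
    responses: np.ndarray | None = None  # flat, aligned with doses (continuous)
    affected: np.ndarray | None = None  # per group (dichotomous)
    group_n: np.ndarray | None = None

    @property
    def family(self) -> str:
        return self.spec.family

    @property
    def is_dichotomous(self) -> bool:
        return self.spec.family in DICHOTOMOUS_FAMILIES

    def predict(self, d):
        fn = prob_function(self.spec) if self.is_dichotomous else mean_function(self.spec)
        return fn(d)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": self.spec.as_dict(),
            "loglik": self.loglik,
            "aic": self.aic,
            "sigma": self.sigma,
            "converged": self.converged,
        }


def _flatten(doses, responses):
    doses = np.asarray(doses, dtype=float)
    if np.ndim(responses) == 2 or (
        isinstance(responses, (list, tuple)) and np.ndim(responses[0]) >= 1
    ):
        x = np.concatenate([np.full(len(np.atleast_1d(r)), d) for d, r in zip(doses, responses)])
        y = np.concatenate([np.atleast_1d(np.asarray(r, float)) for r in responses])
    else:
        y = np.asarray(responses, dtype=float)
        if len(y) == len(doses):
            x = doses
        elif len(y) % len(doses) == 0:
            # flat replicate vector in group order: expand the group doses
            x = np.repeat(doses, len(y) // len(doses))
        else:
            raise ValueError(
                f"{len(y)} responses cannot align with {len(doses)} doses"
            )
    if len(np.unique(x)) < 2:
        raise ValueError("degenerate design: need at least two distinct dose groups")
    return x, y


def _gauss_loglik(rss: float, n: int) -> float:
    s2 = max(rss / n, _TINY)
    return -0.5 * n * (math.log(2 * math.pi * s2) + 1.0)


def _mean_params_count(family: str) -> int:
    return len(PARAM_NAMES[family])


def _continuous_bounds(family: str, x, y):
    lo, hi = {}, {}
    maxd = float(np.max(x))
    span = float(np.ptp(y)) + 1e-6
    big = 50 * span + 10 * abs(float(np.mean(y))) + 10.0
    if family == "power":
        return [(-big, big), (-big, big), (1.0, 18.0)]
    if family == "hill":
        return [(-big, big), (-big, big), (maxd * 1e-6, maxd * 100.0), (1.0, 18.0)]
    if family == "exp4":
        return [(1e-8, big), (1e-8 / maxd, 100.0 / maxd), (1e-6, 100.0)]
    if family == "exp5":
        return [(1e-8, big), (1e-8 / maxd, 100.0 / maxd), (1e-6, 100.0), (1.0, 18.0)]
    raise ValueError(family)


def _continuous_starts(family: str, x, y, rng):
    """Moment-based start plus jittered restarts for the nonlinear families."""
    groups = np.unique(x)
    gmeans = np.array([y[x == g].mean() for g in groups])
    g0 = gmeans[0]
    top = gmeans[-1]
    maxd = groups[-1]
    span = top - g0
    if abs(span) < 1e-9:
        span = math.copysign(1e-3, span if span != 0 else 1.0)
    starts = []
    if family == "power":
        base = [g0, span / maxd, 1.0]
    elif family == "hill":
        # k near the dose where half the span is reached
        half = g0 + span / 2.0
        idx = int(np.argmin(np.abs(gmeans - half)))
        k0 = max(groups[idx], maxd * 0.05)
        base = [g0, span, k0, 1.5]
    elif family == "exp4":
        a0 = max(abs(g0), 1e-3)
        c0 = max(top / a0, 1e-3) if a0 > 0 else 1.5
        base = [a0, 1.0 / maxd, c0]
    elif family == "exp5":
        a0 = max(abs(g0), 1e-3)
        c0 = max(top / a0, 1e-3) if a0 > 0 else 1.5
        base = [a0, 1.0 / maxd, c0, 1.0]
    else:
        raise ValueError(family)
    starts.append(np.array(base, dtype=float))
    for _ in range(4):
        jitter = np.exp(rng.normal(0.0, 0.5, size=len(base)))
        cand = np.array(base, dtype=float)
        cand *= jitter
        # keep signs of signed components from the base start
        for i, b in enumerate(base):
            if b < 0:
                cand[i] = b * jitter[i]
        starts.append(cand)
    return starts


def fit(
    doses,
    responses,
    family: str,
    *,
    restrict_power: bool = True,
    max_iter: int = 250,
    seed: int = 0,
) -> FitResult:
    """Fit a continuous dose-response model by maximum likelihood.

    ``responses`` may be a flat vector aligned with per-observation doses or a
    per-group list/array of replicates aligned with group doses.
    """
    if family not in CONTINUOUS_FAMILIES:
        raise ValueError(f"unknown continuous family: {family!r}")
    x, y = _flatten(doses, responses)
    n = len(y)
    k_mean = _mean_params_count(family)
    if len(np.unique(x)) < k_mean:
        raise ValueError("fewer dose groups than model parameters")

    if family in ("linear", "poly2", "poly3"):
        deg = {"linear": 1, "poly2": 2, "poly3": 3}[family]
        X = np.vander(x, deg + 1, increasing=True)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        spec = ModelSpec(family, beta)
        converged, n_iter = True, 1
    else:
        rng = np.random.default_rng(seed)
        bounds = _continuous_bounds(family, x, y)
        if not restrict_power:
            if family == "power":
                bounds[2] = (1e-2, 18.0)
            elif family == "hill":
                bounds[3] = (1e-2, 18.0)
            elif family == "exp5":
                bounds[3] = (1e-2, 18.0)
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])

        def resid_fn(p):
            return mean_function(ModelSpec(family, p))(x) - y

        best = None
        n_iter = 0
        for s in _continuous_starts(family, x, y, rng):
            s = np.clip(s, lo + 1e-12, hi - 1e-12)
            try:
                sol = optimize.least_squares(
                    resid_fn, s, bounds=(lo, hi), max_nfev=max_iter, method="trf"
                )
            except Exception:
                continue
            n_iter += sol.nfev
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            spec = ModelSpec(family, np.clip(np.zeros(k_mean), lo, hi))
            return FitResult(
                spec=spec,
                loglik=-np.inf,
                aic=np.inf,
                n_params=k_mean + 1,
                converged=False,
                sigma=None,
                rss=None,
                doses=x,
                responses=y,
            )
        spec = ModelSpec(family, best.x)
        rss = float(2 * best.cost)
        converged = bool(best.success)

    sigma = math.sqrt(max(rss / n, 0.0))
    ll = _gauss_loglik(rss, n)
    n_params = k_mean + 1  # residual SD is estimated
    return FitResult(
        spec=spec,
        loglik=ll,
        aic=2 * n_params - 2 * ll,
        n_params=n_params,
        converged=converged,
        n_iter=n_iter,
        sigma=sigma,
        rss=rss,
        doses=x,
        responses=y,
    )


def _binom_loglik(p, affected, n):
    p = np.clip(p, 1e-10, 1 - 1e-10)
    return float(np.sum(affected * np.log(p) + (n - affected) * np.log(1 - p)))


def _dichotomous_setup(family, doses, affected, n):
    doses = np.asarray(doses, float)
    affected = np.asarray(affected, float)
    n = np.asarray(n, float)
    obs = affected / n
    bg = max(obs[0], 1e-4)
    top = max(obs[-1], bg + 1e-3)
    maxd = doses[doses > 0].min(), doses.max()
    lo_pos, hi_d = maxd
    if family == "logistic":
        x0 = [math.log(bg / (1 - bg)), 1.0 / hi_d]
        bounds = [(-18, 18), (0.0, 1e4 / hi_d)]
    elif family == "probit":
        x0 = [stats.norm.ppf(bg), 1.0 / hi_d]
        bounds = [(-8, 8), (0.0, 1e4 / hi_d)]
    elif family in ("loglogistic", "logprobit"):
        x0 = [obs[0], -1.0, 1.0]
        bounds = [(0.0, 1 - 1e-6), (-40, 40), (1.0, 18.0)]
    elif family == "weibull":
        x0 = [obs[0], 1.0, 1.0 / hi_d]
        bounds = [(0.0, 1 - 1e-6), (1.0, 18.0), (1e-10, 1e4)]
    elif family == "gamma":
        x0 = [obs[0], 1.3, 1.0 / hi_d]
        bounds = [(0.0, 1 - 1e-6), (1.0, 18.0), (1e-10, 1e4)]
    elif family == "multistage":
        x0 = [obs[0], 0.5 / hi_d, 0.0]
        bounds = [(0.0, 1 - 1e-6), (0.0, 1e4), (0.0, 1e4)]
    elif family == "dhill":
        x0 = [obs[0], max(top, 0.5), 0.0, 1.0]
        bounds = [(0.0, 1 - 1e-6), (1e-6, 1.0), (-40, 40), (1.0, 18.0)]
    else:
        raise ValueError(f"unknown dichotomous family: {family!r}")
    return doses, affected, n, np.array(x0, float), bounds


def fit_dichotomous(
    doses, affected, n, family: str, *, max_iter: int = 250, seed: int = 0
) -> FitResult:
    """Fit a dichotomous (quantal) model to per-group incidence by binomial ML."""
    doses_, aff, ng, x0, bounds = _dichotomous_setup(family, doses, affected, n)
    if np.any(aff > ng) or np.any(aff < 0):
        raise ValueError("affected counts must satisfy 0 <= affected <= n")
    k = len(x0)
    if len(doses_) < k:
        raise ValueError("fewer dose groups than model parameters")
    rng = np.random.default_rng(seed)

    def nll(p):
        prob = prob_function(ModelSpec(family, p))(doses_)
        return -_binom_loglik(prob, aff, ng)

    best = None
    starts = [x0]
    for _ in range(4):
        cand = x0 * np.exp(rng.normal(0, 0.4, size=k))
        starts.append(cand)
    for s in starts:
        s = np.clip(s, [b[0] for b in bounds], [b[1] for b in bounds])
        try:
            sol = optimize.minimize(
                nll, s, method="L-BFGS-B", bounds=bounds, options={"maxiter": max_iter}
            )
        except Exception:
            continue
        if best is None or sol.fun < best.fun:
            best = sol
    if best is None or not np.isfinite(best.fun):
        return FitResult(
            spec=ModelSpec(family, x0),
            loglik=-np.inf,
            aic=np.inf,
            n_params=k,
            converged=False,
            doses=doses_,
            affected=aff,
            group_n=ng,
        )
    ll = -float(best.fun)
    return FitResult(
        spec=ModelSpec(family, best.x),
        loglik=ll,
        aic=2 * k - 2 * ll,
        n_params=k,
        converged=bool(best.success),
        n_iter=int(best.nit),
        doses=doses_,
        affected=aff,
        group_n=ng,
    )


def saturated_loglik(fit: FitResult) -> float:
    """Log-likelihood of the saturated (group-means) model on the fit's data."""
    if fit.is_dichotomous:
        phat = fit.affected / fit.group_n
        return _binom_loglik(phat, fit.affected, fit.group_n)
    x, y = fit.doses, fit.responses
    rss_sat = 0.0
    for g in np.unique(x):
        yy = y[x == g]
        rss_sat += float(np.sum((yy - yy.mean()) ** 2))
    return _gauss_loglik(rss_sat, len(y))


def goodness_of_fit(fit: FitResult) -> float:
    """Likelihood-ratio GOF p against the saturated group-means model.

    Returns NaN when the test has no residual degrees of freedom and the
    model is not itself saturated.
    """
    if fit.is_dichotomous:
        n_groups = len(fit.doses)
        k_mean = fit.n_params
    else:
        n_groups = len(np.unique(fit.doses))
        k_mean = fit.n_params - 1  # sigma does not shape group means
    df = n_groups - k_mean
    lr = 2.0 * (saturated_loglik(fit) - fit.loglik)
    lr = max(lr, 0.0)
    if df <= 0:
        return 1.0 if lr <= 1e-6 else float("nan")
    return float(stats.chi2.sf(lr, df))


def _bmd_continuous(spec: ModelSpec, sigma: float, bmr: float, max_dose: float):
    p = spec.params
    delta = bmr * sigma
    if delta <= 0:
        return None
    f = spec.family
    if f == "linear":
        if abs(p[1]) < _TINY:
            return None
        return delta / abs(p[1])
    if f == "power":
        if abs(p[1]) < _TINY:
            return None
        return (delta / abs(p[1])) ** (1.0 / p[2])
    if f == "hill":
        if abs(p[1]) < _TINY:
            return None
        a = delta / abs(p[1])
        if a >= 1.0:
            return None
        return p[2] * (a / (1.0 - a)) ** (1.0 / p[3])
    mu = mean_function(spec)
    mu0 = float(mu(0.0))

    def g(d):
        return abs(float(mu(d)) - mu0) - delta

    hi = 10.0 * max_dose
    grid = np.geomspace(max(max_dose * 1e-8, 1e-12), hi, 400)
    prev_d, prev_g = 0.0, -delta
    for d in grid:
        gd = g(d)
        if gd >= 0:
            if prev_g >= 0:
                return float(prev_d) if prev_d > 0 else float(d)
            return float(optimize.brentq(g, max(prev_d, 1e-15), d))
        prev_d, prev_g = d, gd
    return None


def _bmd_dichotomous(spec: ModelSpec, bmr: float, max_dose: float):
    pf = prob_function(spec)
    p0 = float(pf(0.0))

    def extra(d):
        return (float(pf(d)) - p0) / max(1.0 - p0, _TINY) - bmr

    hi = 10.0 * max_dose
    grid = np.geomspace(max(max_dose * 1e-8, 1e-12), hi, 400)
    prev_d = 1e-15
    for d in grid:
        if extra(d) >= 0:
            return float(optimize.brentq(extra, prev_d, d))
        prev_d = d
    return None


def bmd_from_fit(fit: FitResult, bmr: float, *, risk_type: str | None = None):
    """Invert the fitted curve to the benchmark dose; None if no crossing.

    ``risk_type`` defaults to 'sd' (continuous) or 'extra' (dichotomous).
    """
    max_dose = float(np.max(fit.doses))
    if fit.is_dichotomous:
        return _bmd_dichotomous(fit.spec, bmr, max_dose)
    if fit.sigma is None:
        return None
    return _bmd_continuous(fit.spec, fit.sigma, bmr, max_dose)


def _profile_deviance_continuous(fit: FitResult, b: float, bmr: float) -> float:
    x, y = fit.doses, fit.responses
    n = len(y)
    family = fit.family
    k_mean = _mean_params_count(family)
    max_dose = float(np.max(x))

    if family in ("linear", "poly2", "poly3"):
        bounds = [(None, None)] * k_mean
    else:
        bounds = [tuple(bb) for bb in _continuous_bounds(family, x, y)]
    bounds = list(bounds) + [(math.log(max(fit.sigma, 1e-8)) - 12, math.log(max(fit.sigma, 1e-8)) + 6)]

    def unpack(z):
        return ModelSpec(family, z[:k_mean]), math.exp(z[k_mean])

    def nll(z):
        spec, sig = unpack(z)
        r = mean_function(spec)(x) - y
        return n * math.log(sig) + float(r @ r) / (2 * sig * sig)

    def cons(z):
        spec, sig = unpack(z)
        bmd = _bmd_continuous(spec, sig, bmr, max_dose)
        if bmd is None:
            bmd = 100.0 * max_dose
        return math.log(bmd) - math.log(b)

    z0 = np.concatenate([fit.spec.params, [math.log(max(fit.sigma, 1e-8))]])
    sol = optimize.minimize(
        nll,
        z0,
        method="SLSQP",
        bounds=bounds,
        constraints=[{"type": "eq", "fun": cons}],
        options={"maxiter": 300, "ftol": 1e-10},
    )
    if not np.isfinite(sol.fun):
        return math.inf
    const = -0.5 * n * math.log(2 * math.pi)
    ll_c = -(float(sol.fun)) + const
    return 2.0 * (fit.loglik - ll_c)


def _profile_deviance_dichotomous(fit: FitResult, b: float, bmr: float) -> float:
    doses_, aff, ng = fit.doses, fit.affected, fit.group_n
    family = fit.family
    _, _, _, x0, bounds = _dichotomous_setup(family, doses_, aff, ng)
    max_dose = float(np.max(doses_))

    def nll(z):
        prob = prob_function(ModelSpec(family, z))(doses_)
        return -_binom_loglik(prob, aff, ng)

    def cons(z):
        bmd = _bmd_dichotomous(ModelSpec(family, z), bmr, max_dose)
        if bmd is None:
            bmd = 100.0 * max_dose
        return math.log(bmd) - math.log(b)

    sol = optimize.minimize(
        nll,
        fit.spec.params,
        method="SLSQP",
        bounds=bounds,
        constraints=[{"type": "eq", "fun": cons}],
        options={"maxiter": 300, "ftol": 1e-10},
    )
    if not np.isfinite(sol.fun):
        return math.inf
    return 2.0 * (fit.loglik + float(sol.fun))


def bmdl_profile(fit: FitResult, bmr: float, *, level: float = 0.95):
    """One-sided profile-likelihood lower confidence bound on the BMD.

    Returns None when the BMD itself is undefined or the profile cannot be
    bracketed (reported as not computable, never a number).
    """
    bmd = bmd_from_fit(fit, bmr)
    if bmd is None or not np.isfinite(bmd) or bmd <= 0:
        return None
    cutoff = float(stats.chi2.ppf(2 * level - 1, 1))

    dev_fn = (
        _profile_deviance_dichotomous if fit.is_dichotomous else _profile_deviance_continuous
    )

    def g(b):
        return dev_fn(fit, b, bmr) - cutoff

    b_hi, g_hi = bmd, None
    b_lo = bmd
    for _ in range(60):
        b_lo *= 0.75
        g_lo = g(b_lo)
        if not np.isfinite(g_lo):
            return None
        if g_lo > 0:
            break
        b_hi, g_hi = b_lo, g_lo
    else:
        return None
    if g_hi is None:
        g_hi = g(b_hi)
        if g_hi is None or not np.isfinite(g_hi):
            return None
    if g_hi > 0:
        # deviance already above the cutoff arbitrarily near the BMD
        return float(min(b_hi, bmd))
    try:
        bmdl = float(optimize.brentq(g, b_lo, b_hi, xtol=bmd * 1e-4, rtol=1e-4))
    except ValueError:
        return None
    return min(bmdl, bmd)


def lr_test(reduced: FitResult, full: FitResult) -> tuple[float, float]:
    """Likelihood-ratio test of nested fits; returns (statistic, p)."""
    stat = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    df = full.n_params - reduced.n_params
    if df <= 0:
        raise ValueError("full model must have more parameters than the reduced one")
    return stat, float(stats.chi2.sf(stat, df))


def nested_lr_select(
    linear_fit: FitResult, poly2_fit: FitResult, poly3_fit: FitResult, alpha: float = 0.05
) -> FitResult:
    """Step-up nested chi-square selection among linear/quadratic/cubic."""
    chosen = linear_fit
    _, p = lr_test(chosen, poly2_fit)
    if p < alpha:
        chosen = poly2_fit
    _, p = lr_test(chosen, poly3_fit)
    if p < alpha:
        chosen = poly3_fit
    return chosen
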