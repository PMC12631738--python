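"""Parametric survival families, censored maximum likelihood, and model selection.

Six families are supported, parameterized as follows (all times in months):

==============  ======================  =================================================
family          params                  survival function S(t)
==============  ======================  =================================================
exponential     (rate,)                 exp(-rate * t)
weibull         (scale, shape)          exp(-(t/scale)**shape)
gamma           (shape, scale)          1 - P(shape, t/scale), P = regularized lower
                                        incomplete gamma function
gompertz        (shape, rate)           exp(-(rate/shape) * (exp(shape*t) - 1));
                                        shape may be any real (shape -> 0 recovers the
                                        exponential; shape < 0 gives a defective
                                        distribution with a surviving fraction)
loglogistic     (scale, shape)          1 / (1 + (t/scale)**shape)
lognormal       (mu, sigma)             1 - Phi((ln t - mu)/sigma)
==============  ======================  =================================================

Published parameterizations of these families differ; conversion helpers for the
common rate/scale conventions are provided at the bottom of the module.

Fitting maximizes the right-censored log-likelihood

    ll = sum_events ln f(t_i) + sum_censored ln S(t_i)

by multi-start box-constrained quasi-Newton optimization on log-transformed
positive parameters (the Gompertz shape, which may be negative, is left
untransformed).  Model selection ranks fits by AIC (default) or BIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = [
    "FAMILIES",
    "PARAM_NAMES",
    "ParametricFit",
    "FitRanking",
    "InvalidParameterError",
    "NoEventsError",
    "FitFailureError",
    "UndefinedMedianError",
    "survival",
    "log_survival",
    "density",
    "log_density",
    "sample",
    "log_likelihood",
    "fit_mle",
    "fit_all",
    "rank_fits",
    "median_survival",
]

#: canonical family order; also the final tie-break order in rankings
FAMILIES: tuple[str, ...] = (
    "exponential",
    "gamma",
    "gompertz",
    "weibull",
    "loglogistic",
    "lognormal",
)

PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("scale", "shape"),
    "gamma": ("shape", "scale"),
    "gompertz": ("shape", "rate"),
    "loglogistic": ("scale", "shape"),
    "lognormal": ("mu", "sigma"),
}

#: floor applied to event times before evaluating log-densities; digitized grids
#: can emit exact zeros, where several densities are unbounded
EVENT_TIME_FLOOR = 1e-6


class InvalidParameterError(ValueError):
    """Parameters violate the positivity constraints of the family."""


class NoEventsError(ValueError):
    """Fitting requested on data with no observed events."""


class FitFailureError(RuntimeError):
    """The optimizer failed to converge from every starting point."""


class UndefinedMedianError(ValueError):
    """The survival function never falls to 0.5 (defective distribution)."""


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise InvalidParameterError(f"unknown survival family: {family!r}")


def validate_params(family: str, params) -> np.ndarray:
    _check_family(family)
    p = np.asarray(params, dtype=float)
    if p.shape != (len(PARAM_NAMES[family]),):
        raise InvalidParameterError(
            f"{family} expects {len(PARAM_NAMES[family])} parameters "
            f"{PARAM_NAMES[family]}, got {p.tolist()}"
        )
    if not np.all(np.isfinite(p)):
        raise InvalidParameterError(f"non-finite parameters for {family}: {p.tolist()}")
    if family == "gompertz":
        if p[1] <= 0:
            raise InvalidParameterError(f"gompertz rate must be > 0, got {p[1]}")
    elif family == "lognormal":
        if p[1] <= 0:
            raise InvalidParameterError(f"lognormal sigma must be > 0, got {p[1]}")
    else:
        if np.any(p <= 0):
            raise InvalidParameterError(f"{family} parameters must be > 0, got {p.tolist()}")
    return p


def _phi(x: np.ndarray) -> np.ndarray:
    """expm1(x)/x, continuous at 0 (value 1)."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-8
    safe = np.where(small, 1.0, x)
    with np.errstate(over="ignore"):  # expm1 overflow -> inf -> S = 0, correct
        return np.where(small, 1.0 + x / 2.0, np.expm1(safe) / safe)


def log_survival(family: str, params, t) -> np.ndarray:
    """ln S(t); `t` may be scalar or array, must be >= 0."""
    p = validate_params(family, params)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival times must be non-negative")
    if family == "exponential":
        return -p[0] * t
    if family == "weibull":
        scale, shape = p
        return -((t / scale) ** shape)
    if family == "gamma":
        shape, scale = p
        with np.errstate(divide="ignore"):
            return np.log(special.gammaincc(shape, t / scale))
    if family == "gompertz":
        a, b = p
        # -(b/a)(e^{at}-1) written as -b*t*phi(a*t), stable through a = 0
        return -b * t * _phi(a * t)
    if family == "loglogistic":
        scale, shape = p
        return -np.log1p((t / scale) ** shape)
    # lognormal
    mu, sigma = p
    with np.errstate(divide="ignore"):
        z = (np.log(np.maximum(t, 1e-300)) - mu) / sigma
    return np.where(t <= 0, 0.0, special.log_ndtr(-z))


def survival(family: str, params, t) -> np.ndarray:
    """S(t) for the given family; S(0) = 1 and S is non-increasing."""
    return np.exp(log_survival(family, params, t))


def log_density(family: str, params, t) -> np.ndarray:
    """ln f(t); event times below EVENT_TIME_FLOOR are floored before evaluation."""
    p = validate_params(family, params)
    t = np.maximum(np.asarray(t, dtype=float), EVENT_TIME_FLOOR)
    if family == "exponential":
        return np.log(p[0]) - p[0] * t
    if family == "weibull":
        scale, shape = p
        z = t / scale
        return np.log(shape) - np.log(scale) + (shape - 1.0) * np.log(z) - z**shape
    if family == "gamma":
        shape, scale = p
        return (
            (shape - 1.0) * np.log(t)
            - t / scale
            - shape * np.log(scale)
            - special.gammaln(shape)
        )
    if family == "gompertz":
        a, b = p
        return np.log(b) + a * t - b * t * _phi(a * t)
    if family == "loglogistic":
        scale, shape = p
        z = t / scale
        return (
            np.log(shape)
            - np.log(scale)
            + (shape - 1.0) * np.log(z)
            - 2.0 * np.log1p(z**shape)
        )
    mu, sigma = p
    z = (np.log(t) - mu) / sigma
    return -np.log(t) - np.log(sigma) - 0.5 * math.log(2 * math.pi) - 0.5 * z**2


def density(family: str, params, t) -> np.ndarray:
    return np.exp(log_density(family, params, t))


def sample(family: str, params, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw event times by inverse-survival sampling.

    A defective Gompertz (shape < 0) returns ``inf`` for the never-failing
    fraction; callers are expected to censor such draws administratively.
    """
    p = validate_params(family, params)
    u = 1.0 - rng.random(size)  # uniform on (0, 1]
    if family == "exponential":
        return -np.log(u) / p[0]
    if family == "weibull":
        scale, shape = p
        return scale * (-np.log(u)) ** (1.0 / shape)
    if family == "gamma":
        shape, scale = p
        return scale * special.gammainccinv(shape, u)
    if family == "gompertz":
        a, b = p
        if abs(a) < 1e-12:
            return -np.log(u) / b
        arg = 1.0 - (a / b) * np.log(u)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.log(arg) / a
        return np.where(arg > 0, t, np.inf)
    if family == "loglogistic":
        scale, shape = p
        return scale * ((1.0 - u) / u) ** (1.0 / shape)
    mu, sigma = p
    return np.exp(mu + sigma * special.ndtri(1.0 - np.clip(u, 1e-16, 1 - 1e-16)))


def log_likelihood(family: str, params, times, events) -> float:
    """Right-censored log-likelihood: ln f at events, ln S at censorings."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("empty dataset")
    ll = np.where(
        events > 0.5,
        log_density(family, params, times),
        log_survival(family, params, times),
    )
    return float(np.sum(ll))


@dataclass(frozen=True)
class ParametricFit:
    """A fitted survival family with its information criteria."""

    family: str
    params: tuple[float, ...]
    log_lik: float
    n: int
    k: int = field(init=False)
    aic: float = field(init=False)
    bic: float = field(init=False)

    def __post_init__(self):
        validate_params(self.family, self.params)
        object.__setattr__(self, "k", len(PARAM_NAMES[self.family]))
        object.__setattr__(self, "aic", 2.0 * self.k - 2.0 * self.log_lik)
        object.__setattr__(self, "bic", self.k * math.log(self.n) - 2.0 * self.log_lik)

    def survival(self, t) -> np.ndarray:
        return survival(self.family, self.params, t)

    def median(self) -> float:
        return median_survival(self)


def _starting_points(family: str, times, events) -> list[np.ndarray]:
    """Five moment/quantile-based starting points per family."""
    te = np.maximum(times[events > 0.5], EVENT_TIME_FLOOR)
    lt = np.log(te)
    m, s = float(np.mean(lt)), float(np.std(lt))
    s = max(s, 0.1)
    tbar = float(np.mean(te))
    tvar = max(float(np.var(te)), (0.25 * tbar) ** 2)
    lam0 = float(np.sum(events)) / float(np.sum(times))
    if family == "weibull":
        shape0 = 1.2826 / s  # sd of ln T for Weibull is pi/(sqrt(6)*shape)
        base = [np.exp(m), shape0]
        return [
            np.array(base),
            np.array([base[0], shape0 * 0.5]),
            np.array([base[0], shape0 * 2.0]),
            np.array([base[0] * 0.6, shape0]),
            np.array([base[0] * 1.6, shape0]),
        ]
    if family == "gamma":
        shape0 = tbar**2 / tvar
        scale0 = tvar / tbar
        return [
            np.array([shape0, scale0]),
            np.array([shape0 * 0.5, scale0 * 2.0]),
            np.array([shape0 * 2.0, scale0 * 0.5]),
            np.array([1.0, 1.0 / lam0]),
            np.array([shape0, scale0 * 1.5]),
        ]
    if family == "gompertz":
        return [
            np.array([0.01, lam0]),
            np.array([0.05, lam0]),
            np.array([0.15, lam0 * 0.5]),
            np.array([-0.02, lam0]),
            np.array([1e-4, lam0 * 1.5]),
        ]
    if family == "loglogistic":
        shape0 = 1.8138 / s  # sd of ln T for log-logistic is pi/(sqrt(3)*shape)
        alpha0 = float(np.exp(np.median(lt)))
        return [
            np.array([alpha0, shape0]),
            np.array([alpha0, shape0 * 0.5]),
            np.array([alpha0, shape0 * 2.0]),
            np.array([alpha0 * 0.6, shape0]),
            np.array([alpha0 * 1.6, shape0]),
        ]
    # lognormal
    return [
        np.array([m, s]),
        np.array([m, s * 0.5]),
        np.array([m, s * 2.0]),
        np.array([m - s, s]),
        np.array([m + s, s]),
    ]


def _to_x(family: str, params: np.ndarray) -> np.ndarray:
    if family == "gompertz":
        return np.array([params[0], np.log(params[1])])
    if family == "lognormal":
        return np.array([params[0], np.log(params[1])])
    return np.log(params)


def _from_x(family: str, x: np.ndarray) -> np.ndarray:
    if family == "gompertz":
        return np.array([x[0], np.exp(x[1])])
    if family == "lognormal":
        return np.array([x[0], np.exp(x[1])])
    return np.exp(x)


def fit_mle(family: str, times, events) -> ParametricFit:
    """Maximum-likelihood fit of one family to right-censored data.

    Raises NoEventsError if no events are observed, and FitFailureError if no
    optimizer start converges to a finite optimum.
    """
    _check_family(family)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("empty dataset")
    n = int(times.size)
    d = float(np.sum(events))
    if d < 1:
        raise NoEventsError("cannot fit a survival model to all-censored data")

    if family == "exponential":
        lam = d / float(np.sum(times))  # closed-form MLE: events / total exposure
        ll = log_likelihood(family, (lam,), times, events)
        return ParametricFit("exponential", (lam,), ll, n)

    def neg_ll(x: np.ndarray) -> float:
        params = _from_x(family, x)
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                val = -log_likelihood(family, params, times, events)
        except (InvalidParameterError, FloatingPointError):
            return np.inf
        return val if np.isfinite(val) else np.inf

    best: tuple[float, np.ndarray] | None = None
    diagnostics = []
    for start in _starting_points(family, times, events):
        x0 = _to_x(family, start)
        res = optimize.minimize(
            neg_ll,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000},
        )
        # polish with a gradient-based step from the simplex optimum
        res2 = optimize.minimize(neg_ll, res.x, method="L-BFGS-B", options={"ftol": 1e-12})
        cand = res2 if res2.fun <= res.fun else res
        diagnostics.append((start.tolist(), cand.fun))
        if np.isfinite(cand.fun) and (best is None or cand.fun < best[0]):
            best = (float(cand.fun), cand.x.copy())
    if best is None:
        raise FitFailureError(
            f"{family}: no start converged; tried {diagnostics}"
        )
    params = tuple(float(v) for v in _from_x(family, best[1]))
    return ParametricFit(family, params, -best[0], n)


def fit_all(times, events, families=FAMILIES) -> dict[str, ParametricFit]:
    """Fit every requested family; families whose optimization fails are dropped.

    Raises FitFailureError only if *no* family could be fitted.
    """
    fits: dict[str, ParametricFit] = {}
    errors = {}
    for fam in families:
        try:
            fits[fam] = fit_mle(fam, times, events)
        except NoEventsError:
            raise
        except FitFailureError as exc:  # pragma: no cover - rare
            errors[fam] = str(exc)
    if not fits:
        raise FitFailureError(f"every family failed: {errors}")
    return fits


@dataclass(frozen=True)
class FitRanking:
    """Fits ordered ascending by an information criterion."""

    criterion: str
    entries: tuple[tuple[str, float, float], ...]  # (family, aic, bic)
    selected: str


def rank_fits(fits, criterion: str = "aic") -> FitRanking:
    """Rank fits ascending by AIC or BIC; ties broken by fewer parameters, then
    by the canonical family order."""
    criterion = criterion.lower()
    if criterion not in ("aic", "bic"):
        raise ValueError(f"criterion must be 'aic' or 'bic', got {criterion!r}")
    fits = list(fits.values()) if isinstance(fits, dict) else list(fits)
    if not fits:
        raise ValueError("no fits to rank")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits come from datasets of different sizes: {sorted(ns)}")
    key = (lambda f: (f.aic, f.k, FAMILIES.index(f.family))) if criterion == "aic" else (
        lambda f: (f.bic, f.k, FAMILIES.index(f.family))
    )
    ordered = sorted(fits, key=key)
    entries = tuple((f.family, f.aic, f.bic) for f in ordered)
    return FitRanking(criterion, entries, ordered[0].family)


def median_survival(fit) -> float:
    """The time t with S(t) = 0.5, in months.

    Closed forms are used where available; the gamma and Gompertz medians
    invert S numerically/analytically.  Raises UndefinedMedianError when the
    survival function is bounded above 0.5 (defective Gompertz).
    """
    if isinstance(fit, ParametricFit):
        family, params = fit.family, fit.params
    else:
        family, params = fit
    p = validate_params(family, params)
    ln2 = math.log(2.0)
    if family == "exponential":
        return ln2 / p[0]
    if family == "weibull":
        return p[0] * ln2 ** (1.0 / p[1])
    if family == "gamma":
        return float(p[1] * special.gammainccinv(p[0], 0.5))
    if family == "gompertz":
        a, b = p
        if abs(a) < 1e-12:
            return ln2 / b
        arg = 1.0 + (a / b) * ln2
        if arg <= 0:  # surviving fraction exceeds one half
            raise UndefinedMedianError(
                f"gompertz(shape={a}, rate={b}) never reaches S = 0.5"
            )
        return math.log(arg) / a
    if family == "loglogistic":
        return p[0]
    return math.exp(p[0])


# -- parameterization conversion helpers ------------------------------------
#
# Published software conventions differ; these map the common alternatives
# onto the parameter vectors used here.


def weibull_from_rate(rate: float, shape: float) -> tuple[float, float]:
    """Convert the (rate, shape) convention S = exp(-rate * t**shape)."""
    return (rate ** (-1.0 / shape), shape)


def gamma_from_rate(shape: float, rate: float) -> tuple[float, float]:
    """Convert the (shape, rate) convention with rate = 1/scale."""
    return (shape, 1.0 / rate)


def loglogistic_from_rate(shape: float, rate: float) -> tuple[float, float]:
    """Convert the (shape, rate) convention S = 1/(1 + (rate*t)**shape)."""
    return (1.0 / rate, shape)
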