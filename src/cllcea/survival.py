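"""Parametric survival curves, per-cycle transition probabilities and MLE fitting.

Six standard parametric families are supported, each defined by its survival
function S(t) on a monthly time axis:

=============  ====================  ==============================================
family         parameters            S(t)
=============  ====================  ==============================================
exponential    rate                  exp(-rate*t)
weibull        shape, rate           exp(-(rate*t)**shape)
gompertz       shape, rate           exp(-(rate/shape)*(exp(shape*t)-1))
gamma          shape, rate           1 - GammaCDF(t; shape, rate)
lognormal      meanlog, sdlog        1 - Phi((ln t - meanlog)/sdlog)
loglogistic    shape, scale          1/(1 + (t/scale)**shape)
=============  ====================  ==============================================

The Gompertz family uses the proportional-hazards form h(t) = rate*exp(shape*t);
shape may be any real (shape -> 0 recovers the exponential), all other shape /
rate / scale / sdlog parameters must be strictly positive.  Fitting maximises
the right-censored log-likelihood sum(log f(t_i)) over events plus
sum(log S(t_j)) over censored subjects, via bounded quasi-Newton on
log-transformed positive parameters with a small multi-start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FAMILIES",
    "SurvivalDistribution",
    "FitResult",
    "ParameterError",
    "FitError",
    "survival_at",
    "transition_prob",
    "fit_mle",
    "fit_all",
    "select_best",
]

FAMILIES = ("exponential", "weibull", "gompertz", "gamma", "lognormal", "loglogistic")

_PARAM_NAMES = {
    "exponential": ("rate",),
    "weibull": ("shape", "rate"),
    "gompertz": ("shape", "rate"),
    "gamma": ("shape", "rate"),
    "lognormal": ("meanlog", "sdlog"),
    "loglogistic": ("shape", "scale"),
}

# parameters that must be strictly positive (all others are unconstrained reals)
_POSITIVE = {
    "exponential": ("rate",),
    "weibull": ("shape", "rate"),
    "gompertz": ("rate",),
    "gamma": ("shape", "rate"),
    "lognormal": ("sdlog",),
    "loglogistic": ("shape", "scale"),
}


class ParameterError(ValueError):
    """Invalid family name or parameter value."""


def _rebuild_distribution(family, params):  # pickle support
    return SurvivalDistribution(family, **params)


class FitError(RuntimeError):
    """Maximum-likelihood fit failed (non-identifiable data or non-convergence)."""


class SurvivalDistribution:
    """A parametric survival distribution on a monthly time axis.

    Parameters are passed by name, e.g.::

        SurvivalDistribution("gompertz", shape=0.02325928, rate=0.00943535)

    Instances are immutable, hashable and comparable by value.
    """

    __slots__ = ("family", "_values")

    def __init__(self, family: str, **params: float):
        if family not in FAMILIES:
            raise ParameterError(f"unknown survival family {family!r}")
        names = _PARAM_NAMES[family]
        if set(params) != set(names):
            raise ParameterError(
                f"{family} requires parameters {names}, got {tuple(params)}"
            )
        for name in _POSITIVE[family]:
            if not params[name] > 0:
                raise ParameterError(f"{family} parameter {name!r} must be > 0")
        for name, value in params.items():
            if not math.isfinite(value):
                raise ParameterError(f"{family} parameter {name!r} must be finite")
        object.__setattr__(self, "family", family)
        object.__setattr__(self, "_values", tuple(float(params[n]) for n in names))

    def __setattr__(self, name, value):  # immutability
        raise AttributeError("SurvivalDistribution is immutable")

    def __copy__(self):
        return self

    def __deepcopy__(self, memo):
        return self

    def __reduce__(self):
        return (_rebuild_distribution, (self.family, self.params))

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(_PARAM_NAMES[self.family], self._values))

    @property
    def n_params(self) -> int:
        return len(self._values)

    def __eq__(self, other):
        return (
            isinstance(other, SurvivalDistribution)
            and self.family == other.family
            and self._values == other._values
        )

    def __hash__(self):
        return hash((self.family, self._values))

    def __repr__(self):
        inner = ", ".join(f"{k}={v:g}" for k, v in self.params.items())
        return f"SurvivalDistribution({self.family!r}, {inner})"

    # -- survival machinery -------------------------------------------------

    def survival(self, t):
        """S(t) for scalar or array t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ParameterError("time must be non-negative")
        p = self._values
        fam = self.family
        if fam == "exponential":
            s = np.exp(-p[0] * t)
        elif fam == "weibull":
            s = np.exp(-np.power(p[1] * t, p[0]))
        elif fam == "gompertz":
            shape, rate = p
            if abs(shape) < 1e-12:
                s = np.exp(-rate * t)
            else:
                s = np.exp(-(rate / shape) * np.expm1(shape * t))
        elif fam == "gamma":
            s = stats.gamma.sf(t, a=p[0], scale=1.0 / p[1])
        elif fam == "lognormal":
            s = stats.lognorm.sf(t, s=p[1], scale=math.exp(p[0]))
        else:  # loglogistic
            with np.errstate(divide="ignore"):
                s = 1.0 / (1.0 + np.power(t / p[1], p[0]))
        return s if s.ndim else float(s)

    def log_pdf(self, t):
        """log f(t); vectorised."""
        t = np.asarray(t, dtype=float)
        p = self._values
        fam = self.family
        if fam == "exponential":
            return math.log(p[0]) - p[0] * t
        if fam == "weibull":
            return stats.weibull_min.logpdf(t, c=p[0], scale=1.0 / p[1])
        if fam == "gompertz":
            shape, rate = p
            if abs(shape) < 1e-12:
                return math.log(rate) - rate * t
            return np.log(rate) + shape * t - (rate / shape) * np.expm1(shape * t)
        if fam == "gamma":
            return stats.gamma.logpdf(t, a=p[0], scale=1.0 / p[1])
        if fam == "lognormal":
            return stats.lognorm.logpdf(t, s=p[1], scale=math.exp(p[0]))
        return stats.fisk.logpdf(t, c=p[0], scale=p[1])

    def log_sf(self, t):
        t = np.asarray(t, dtype=float)
        p = self._values
        fam = self.family
        if fam == "exponential":
            return -p[0] * t
        if fam == "weibull":
            return -np.power(p[1] * t, p[0])
        if fam == "gompertz":
            shape, rate = p
            if abs(shape) < 1e-12:
                return -rate * t
            return -(rate / shape) * np.expm1(shape * t)
        if fam == "gamma":
            return stats.gamma.logsf(t, a=p[0], scale=1.0 / p[1])
        if fam == "lognormal":
            return stats.lognorm.logsf(t, s=p[1], scale=math.exp(p[0]))
        return stats.fisk.logsf(t, c=p[0], scale=p[1])

    def transition_prob(self, t: float, delta: float) -> float:
        """Per-cycle probability 1 - S(t+delta)/S(t) of leaving by t+delta."""
        if t < 0 or delta <= 0:
            raise ParameterError("require t >= 0 and delta > 0")
        s0 = self.survival(t)
        if s0 <= 0.0:
            raise ParameterError(f"degenerate support: S({t}) = 0")
        return float(1.0 - self.survival(t + delta) / s0)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Sample event times by inverse-CDF (closed form) or scipy sampling."""
        p = self._values
        fam = self.family
        u = rng.uniform(size=n)
        if fam == "exponential":
            return -np.log(u) / p[0]
        if fam == "weibull":
            return np.power(-np.log(u), 1.0 / p[0]) / p[1]
        if fam == "gompertz":
            shape, rate = p
            if abs(shape) < 1e-12:
                return -np.log(u) / rate
            # S(t)=u has a solution only while u > exp(rate/shape) for shape<0
            arg = 1.0 - (shape / rate) * np.log(u)
            return np.log(arg) / shape
        if fam == "gamma":
            return stats.gamma.ppf(1 - u, a=p[0], scale=1.0 / p[1])
        if fam == "lognormal":
            return stats.lognorm.ppf(1 - u, s=p[1], scale=math.exp(p[0]))
        return p[1] * np.power(1.0 / u - 1.0, 1.0 / p[0])


def survival_at(dist: SurvivalDistribution, t) -> float:
    """Closed-form S(t) of `dist` at time t (months)."""
    return dist.survival(t)


def transition_prob(dist: SurvivalDistribution, t: float, delta: float) -> float:
    """Probability of the event occurring in (t, t+delta] conditional on reaching t."""
    return dist.transition_prob(t, delta)


@dataclass(frozen=True)
class FitResult:
    """A fitted parametric model with its information criteria."""

    distribution: SurvivalDistribution
    loglik: float
    aic: float
    bic: float
    n: int

    @property
    def family(self) -> str:
        return self.distribution.family


def _as_arrays(ipd) -> tuple[np.ndarray, np.ndarray]:
    """Accept (times, events) arrays or an iterable of IPDRecord-like objects."""
    if isinstance(ipd, tuple) and len(ipd) == 2:
        times, events = ipd
    else:
        rows = list(ipd)
        times = [r.time for r in rows]
        events = [r.event for r in rows]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape:
        raise ValueError("times and event flags must have equal length")
    if np.any(times <= 0):
        raise ValueError("event/censoring times must be strictly positive")
    return times, events


def _start_params(family: str, times: np.ndarray, events: np.ndarray) -> np.ndarray:
    m = float(np.mean(times))
    v = float(np.var(times)) or m**2
    d = max(int(events.sum()), 1)
    crude_rate = d / float(times.sum())
    if family == "exponential":
        return np.array([crude_rate])
    if family == "weibull":
        return np.array([1.0, crude_rate])
    if family == "gompertz":
        return np.array([0.005, crude_rate])
    if family == "gamma":
        return np.array([max(m * m / v, 0.1), max(m / v, 1e-6)])
    if family == "lognormal":
        lt = np.log(times)
        return np.array([float(np.mean(lt)), max(float(np.std(lt)), 0.1)])
    return np.array([1.5, float(np.median(times))])  # loglogistic


def fit_mle(ipd, family: str) -> FitResult:
    """Fit one parametric family to right-censored data by maximum likelihood.

    `ipd` is either an iterable of records with ``.time``/``.event`` attributes
    or a ``(times, events)`` pair of arrays.  Raises :class:`FitError` when the
    data carry fewer than two events or the optimiser fails to converge.
    """
    if family not in FAMILIES:
        raise ParameterError(f"unknown survival family {family!r}")
    times, events = _as_arrays(ipd)
    if events.sum() < 2:
        raise FitError("non-identifiable: need at least 2 events to fit")

    names = _PARAM_NAMES[family]
    positive = _POSITIVE[family]
    t_ev, t_cen = times[events], times[~events]

    def pack(raw: np.ndarray) -> dict[str, float]:
        return {
            name: (math.exp(raw[i]) if name in positive else raw[i])
            for i, name in enumerate(names)
        }

    def negloglik(raw: np.ndarray) -> float:
        try:
            dist = SurvivalDistribution(family, **pack(raw))
        except (ParameterError, OverflowError):
            return 1e12
        with np.errstate(all="ignore"):
            ll = float(np.sum(dist.log_pdf(t_ev)))
            if t_cen.size:
                ll += float(np.sum(dist.log_sf(t_cen)))
        return 1e12 if not math.isfinite(ll) else -ll

    x0 = _start_params(family, times, events)
    raw0 = np.array(
        [math.log(x) if n in positive else x for x, n in zip(x0, names)]
    )
    best = None
    for scale in (1.0, 0.5, 2.0):  # multi-start on the log scale
        start = raw0 + math.log(scale)
        res = optimize.minimize(negloglik, start, method="L-BFGS-B")
        if res.fun < 1e11 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError(f"MLE did not converge for family {family!r}")

    dist = SurvivalDistribution(family, **pack(best.x))
    loglik = -float(best.fun)
    k, n = len(names), len(times)
    return FitResult(
        distribution=dist,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * k,
        bic=-2.0 * loglik + k * math.log(n),
        n=n,
    )


def fit_all(ipd, families: Sequence[str] = FAMILIES) -> list[FitResult]:
    """Fit every requested family, skipping any that fail to converge."""
    out = []
    for fam in families:
        try:
            out.append(fit_mle(ipd, fam))
        except FitError:
            continue
    if not out:
        raise FitError("no family could be fitted")
    return out


def curve_frame(dist: SurvivalDistribution, times) -> "pandas.DataFrame":  # noqa: F821
    """Survival curve as a (t, S) table, ready for CSV export."""
    import pandas as pd

    t = np.asarray(times, dtype=float)
    return pd.DataFrame({"t": t, "S": np.asarray(dist.survival(t), dtype=float)})


def select_best(fits: Iterable[FitResult], criterion: str = "aic") -> FitResult:
    """Pick the fit minimising AIC or BIC.

    Ties are broken by fewer free parameters, then by family-name order.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("select_best requires a non-empty list of fits")
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    return min(
        fits,
        key=lambda f: (getattr(f, criterion), f.distribution.n_params, f.family),
    )
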