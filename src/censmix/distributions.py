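"""Probability distributions for concentration data.

Five positive-support families are provided: zero-truncated normal,
lognormal, gamma, Weibull and generalized gamma (Stacy).  Concentrations
are strictly positive, so the normal family is always left-truncated at
zero; the other four have positive support natively.

The generalized gamma density with parameters ``(a, d, p)`` is

    f(x; a, d, p) = (p / a**d) * x**(d-1) * exp(-(x/a)**p) / Gamma(d/p)

It nests the gamma distribution (p = 1, shape d, scale a) and the
Weibull distribution (d = p, shape p, scale a), which makes it a useful
envelope family for model comparison.

Log-density is the primitive everywhere; ``pdf`` is ``exp(logpdf)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats
from scipy import special
from scipy.special import gammaln

__all__ = [
    "FAMILIES",
    "DistributionSpec",
    "Interval",
    "logpdf",
    "pdf",
    "cdf",
    "truncated_logpdf",
    "truncated_pdf",
    "rvs",
]

FAMILIES = ("normal", "lognormal", "gamma", "weibull", "gengamma")

_N_PARAMS = {"normal": 2, "lognormal": 2, "gamma": 2, "weibull": 2, "gengamma": 3}

#: names of the parameters, in the order they appear in ``params``
PARAM_NAMES = {
    "normal": ("mu", "sigma"),
    "lognormal": ("mu", "sigma"),
    "gamma": ("shape", "scale"),
    "weibull": ("shape", "scale"),
    "gengamma": ("a", "d", "p"),
}

#: which parameters are constrained to be strictly positive (the rest are
#: unconstrained reals: the location parameters of normal / lognormal)
POSITIVE_MASK = {
    "normal": (False, True),
    "lognormal": (False, True),
    "gamma": (True, True),
    "weibull": (True, True),
    "gengamma": (True, True, True),
}


@dataclass(frozen=True)
class DistributionSpec:
    """A distribution family together with its parameter vector.

    Parameters follow the conventions above: normal/lognormal ``(mu,
    sigma)``, gamma ``(shape k, scale theta)``, weibull ``(shape,
    scale)``, gengamma ``(a, d, p)``.
    """

    family: str
    params: Tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        params = tuple(float(p) for p in self.params)
        object.__setattr__(self, "params", params)
        if len(params) != _N_PARAMS[self.family]:
            raise ValueError(
                f"{self.family} takes {_N_PARAMS[self.family]} parameters, got {len(params)}"
            )
        if not all(math.isfinite(p) for p in params):
            raise ValueError(f"non-finite parameter in {params}")
        for value, positive in zip(params, POSITIVE_MASK[self.family]):
            if positive and value <= 0:
                raise ValueError(
                    f"{self.family} parameters {params}: scale/shape parameters must be > 0"
                )
        if self.family in ("normal", "lognormal") and params[1] < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.family]

    def frozen(self):
        """The underlying (untruncated) scipy frozen distribution."""
        f, p = self.family, self.params
        if f == "normal":
            return stats.norm(loc=p[0], scale=p[1])
        if f == "lognormal":
            return stats.lognorm(s=p[1], scale=math.exp(p[0]))
        if f == "gamma":
            return stats.gamma(a=p[0], scale=p[1])
        if f == "weibull":
            return stats.weibull_min(c=p[0], scale=p[1])
        # gengamma(a, d, p) maps to scipy's gengamma(a=d/p, c=p, scale=a)
        a, d, pw = p
        return stats.gengamma(a=d / pw, c=pw, scale=a)

    def mean(self) -> float:
        """Mean of the zero-truncated distribution (plain mean for the
        positive-support families)."""
        f, p = self.family, self.params
        if f == "normal":
            mu, sigma = p
            alpha = -mu / sigma
            # E[X | X > 0] for a normal(mu, sigma)
            return mu + sigma * stats.norm.pdf(alpha) / stats.norm.sf(alpha)
        if f == "lognormal":
            return math.exp(p[0] + p[1] ** 2 / 2.0)
        if f == "gamma":
            return p[0] * p[1]
        if f == "weibull":
            return p[1] * math.gamma(1.0 + 1.0 / p[0])
        a, d, pw = p
        return a * math.exp(gammaln((d + 1.0) / pw) - gammaln(d / pw))


@dataclass(frozen=True)
class Interval:
    """A quantification window (LDL, UDL).

    ``lower = 0`` means no lower detection limit; ``upper = inf`` means
    no upper detection limit.
    """

    lower: float = 0.0
    upper: float = math.inf

    def __post_init__(self) -> None:
        lower = float(self.lower)
        upper = float(self.upper)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if not (0.0 <= lower < upper):
            raise ValueError(f"invalid window: need 0 <= lower < upper, got ({lower}, {upper})")

    @property
    def is_unbounded(self) -> bool:
        return self.lower == 0.0 and math.isinf(self.upper)


FULL_WINDOW = Interval(0.0, math.inf)


def _zero_trunc_logmass(spec: DistributionSpec) -> float:
    """log P(X > 0) under the untruncated family (0 except for normal)."""
    if spec.family == "normal":
        mu, sigma = spec.params
        return float(special.log_ndtr(mu / sigma))
    return 0.0


_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _base_logpdf(spec: DistributionSpec, arr: np.ndarray) -> np.ndarray:
    """Untruncated log-density, written out with scipy.special primitives:
    the likelihood loop calls this thousands of times, and the generic
    scipy.stats argument machinery would dominate the cost."""
    f, p = spec.family, spec.params
    if f == "normal":
        mu, sigma = p
        z = (arr - mu) / sigma
        return -0.5 * z * z - math.log(sigma) - _LOG_SQRT_2PI
    if f == "lognormal":
        mu, sigma = p
        logx = np.log(arr)
        z = (logx - mu) / sigma
        return -0.5 * z * z - logx - math.log(sigma) - _LOG_SQRT_2PI
    if f == "gamma":
        k, theta = p
        return (k - 1.0) * np.log(arr) - arr / theta - gammaln(k) - k * math.log(theta)
    with np.errstate(over="ignore"):  # z**c overflow -> -inf log-density, which is correct
        if f == "weibull":
            c, s = p
            z = arr / s
            return math.log(c / s) + (c - 1.0) * np.log(z) - z**c
        a, d, pw = p
        z = arr / a
        return math.log(pw) - d * math.log(a) + (d - 1.0) * np.log(arr) - z**pw - gammaln(d / pw)


def _base_cdf(spec: DistributionSpec, arr: np.ndarray) -> np.ndarray:
    f, p = spec.family, spec.params
    if f == "normal":
        return special.ndtr((arr - p[0]) / p[1])
    if f == "lognormal":
        with np.errstate(divide="ignore"):
            return special.ndtr((np.log(arr) - p[0]) / p[1])
    if f == "gamma":
        return special.gammainc(p[0], arr / p[1])
    if f == "weibull":
        return -np.expm1(-((arr / p[1]) ** p[0]))
    a, d, pw = p
    return special.gammainc(d / pw, (arr / a) ** pw)


def logpdf(spec: DistributionSpec, x) -> np.ndarray | float:
    """Log-density at x > 0 (normal family zero-truncated)."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("density is defined for x > 0 only")
    out = _base_logpdf(spec, arr) - _zero_trunc_logmass(spec)
    return out if arr.shape else float(out)


def pdf(spec: DistributionSpec, x) -> np.ndarray | float:
    return np.exp(logpdf(spec, x))


def cdf(spec: DistributionSpec, x) -> np.ndarray | float:
    """P(X <= x) of the zero-truncated distribution, i.e. the integral of
    :func:`pdf` over (0, x]."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("cdf is defined for x >= 0 only")
    if spec.family == "normal":
        mu, sigma = spec.params
        b0 = special.ndtr(-mu / sigma)
        out = (_base_cdf(spec, arr) - b0) / (1.0 - b0)
    else:
        out = _base_cdf(spec, arr)
    out = np.clip(out, 0.0, 1.0)
    return out if arr.shape else float(out)


def window_logmass(spec: DistributionSpec, window: Interval) -> float:
    """log P(lower < X < upper) under the zero-truncated distribution."""
    hi = 1.0 if math.isinf(window.upper) else cdf(spec, window.upper)
    lo = cdf(spec, window.lower) if window.lower > 0 else 0.0
    mass = hi - lo
    if mass <= 0.0:
        return -math.inf
    return math.log(mass)


def truncated_logpdf(spec: DistributionSpec, x, window: Interval) -> np.ndarray | float:
    """Log-density conditional on lower < X < upper."""
    arr = np.asarray(x, dtype=float)
    # the closed boundary is tolerated: a value reported exactly at a
    # detection limit is treated as quantified
    if np.any(arr < window.lower) or np.any(arr > window.upper):
        raise ValueError(f"x outside window ({window.lower}, {window.upper})")
    logmass = window_logmass(spec, window)
    if logmass == -math.inf:
        raise ValueError(f"window ({window.lower}, {window.upper}) has zero probability mass")
    out = logpdf(spec, arr) - logmass
    return out if arr.shape else float(out)


def truncated_pdf(spec: DistributionSpec, x, window: Interval) -> np.ndarray | float:
    return np.exp(truncated_logpdf(spec, x, window))


def rvs(
    spec: DistributionSpec,
    n: int,
    window: Interval = FULL_WINDOW,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draws from the window-truncated distribution via inverse CDF.

    Uniforms are rescaled to [F(lower), F(upper)] of the underlying
    distribution, then mapped through its quantile function; this is
    exact for any window with positive mass.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    dist = spec.frozen()
    lo = max(window.lower, 0.0)
    p_lo = dist.cdf(lo) if lo > 0 or spec.family == "normal" else 0.0
    if spec.family == "normal":
        p_lo = max(p_lo, dist.cdf(0.0))
    p_hi = 1.0 if math.isinf(window.upper) else dist.cdf(window.upper)
    if p_hi <= p_lo:
        raise ValueError(f"window ({window.lower}, {window.upper}) has zero probability mass")
    u = rng.uniform(p_lo, p_hi, size=int(n))
    return np.asarray(dist.ppf(u), dtype=float)
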