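"""Maximum-likelihood fitting of censored/truncated mixture models.

Optimization runs on an unconstrained scale: positive parameters are
log-transformed, the location of the normal / lognormal families stays
raw, and the J-1 free mixture weights are stick-breaking fractions on a
logit scale.  A box-constrained quasi-Newton optimizer (L-BFGS-B) then
maximizes the conditional log-likelihood.  Mixture likelihoods are
multimodal, so several jittered restarts around a deterministic
quantile-sliced moment initialization are used and the best optimum
kept; components are finally sorted by mean so the reported labelling is
unique.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special

from .distributions import (
    FAMILIES,
    PARAM_NAMES,
    POSITIVE_MASK,
    DistributionSpec,
)
from .likelihood import CUT_TRUNCATED, MixtureModel, ObservationSet, loglik

__all__ = ["FitResult", "ParamTransform", "initialize", "fit_mle", "fit_all"]

log = logging.getLogger(__name__)

_LOG_BOUND = 20.0  # box bounds exp(+-20) for positive parameters
_LOGIT_BOUND = 20.0


def _sigmoid(y: np.ndarray | float):
    return special.expit(y)


def _logit(v: float) -> float:
    return float(special.logit(v))


class ParamTransform:
    """Maps between a free real vector and a :class:`MixtureModel`.

    Layout: for each component, its parameters (log scale where the
    parameter is positive); then J-1 stick-breaking logits.  The same
    transform backs both the optimizer and the MCMC sampler.
    """

    def __init__(self, family: str, J: int):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        if not (1 <= J <= 9):
            raise ValueError("J must be between 1 and 9")
        self.family = family
        self.J = J
        self.positive = POSITIVE_MASK[family]
        self.dim_component = len(self.positive)
        self.n_free = J * self.dim_component + (J - 1)
        names = []
        for j in range(J):
            for pname in PARAM_NAMES[family]:
                names.append(f"{family}{j + 1}.{pname}")
        for j in range(J - 1):
            names.append(f"stick{j + 1}")
        #: free-parameter names (transformed-scale layout)
        self.free_names = names

    # -- free vector <-> model -------------------------------------------
    def to_free(self, model: MixtureModel) -> np.ndarray:
        if model.family != self.family or model.J != self.J:
            raise ValueError("model does not match transform layout")
        y = []
        for comp in model.components:
            for value, pos in zip(comp.params, self.positive):
                y.append(math.log(value) if pos else value)
        rest = 1.0
        for q in model.weights[:-1]:
            v = q / rest
            y.append(_logit(min(max(v, 1e-12), 1.0 - 1e-12)))
            rest -= q
        return np.asarray(y, dtype=float)

    def to_model(self, y: np.ndarray) -> MixtureModel:
        y = np.asarray(y, dtype=float)
        comps = []
        k = 0
        for _ in range(self.J):
            params = []
            for pos in self.positive:
                params.append(math.exp(y[k]) if pos else y[k])
                k += 1
            comps.append(DistributionSpec(self.family, tuple(params)))
        weights = []
        rest = 1.0
        for _ in range(self.J - 1):
            v = float(_sigmoid(y[k]))
            k += 1
            weights.append(rest * v)
            rest *= 1.0 - v
        weights.append(rest)
        return MixtureModel(tuple(comps), tuple(weights))

    def natural(self, y: np.ndarray) -> np.ndarray:
        """Natural-scale value of every free parameter (positive params
        exponentiated, stick logits mapped to (0,1) fractions)."""
        y = np.asarray(y, dtype=float)
        out = np.empty_like(y)
        k = 0
        for _ in range(self.J):
            for pos in self.positive:
                out[k] = math.exp(y[k]) if pos else y[k]
                k += 1
        for _ in range(self.J - 1):
            out[k] = float(_sigmoid(y[k]))
            k += 1
        return out

    def log_jacobian(self, y: np.ndarray) -> float:
        """log |d natural / d free| — needed when sampling on the free
        scale under a prior stated on the natural scale."""
        y = np.asarray(y, dtype=float)
        total = 0.0
        k = 0
        for _ in range(self.J):
            for pos in self.positive:
                if pos:
                    total += y[k]
                k += 1
        for _ in range(self.J - 1):
            v = float(_sigmoid(y[k]))
            total += math.log(max(v * (1.0 - v), 1e-300))
            k += 1
        return total

    def bounds(self) -> list[tuple[float | None, float | None]]:
        out: list[tuple[float | None, float | None]] = []
        for _ in range(self.J):
            for pos in self.positive:
                out.append((-_LOG_BOUND, _LOG_BOUND) if pos else (None, None))
        out.extend([(-_LOGIT_BOUND, _LOGIT_BOUND)] * (self.J - 1))
        return out


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit with its information criteria."""

    model: MixtureModel | None
    loglik: float
    n_params: int
    n_obs: int
    aic: float
    aicc: float
    bic: float
    converged: bool
    family: str
    J: int
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.model is not None


def _criteria(ll: float, p: int, n: int) -> tuple[float, float, float]:
    aic = -2.0 * ll + 2.0 * p
    aicc = aic + 2.0 * p * (p + 1) / (n - p - 1) if n > p + 1 else math.inf
    bic = -2.0 * ll + p * math.log(n)
    return aic, aicc, bic


def _moment_spec(family: str, values: np.ndarray, fallback_sd: float) -> DistributionSpec:
    m = float(np.mean(values))
    s = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    if s <= 0.0 or not math.isfinite(s):
        s = max(fallback_sd, 1e-3 * max(m, 1.0))
    if family == "normal":
        return DistributionSpec("normal", (m, s))
    if family == "lognormal":
        logs = np.log(values)
        mu = float(np.mean(logs))
        sd = float(np.std(logs, ddof=1)) if values.size > 1 else 0.0
        if sd <= 0.0 or not math.isfinite(sd):
            sd = 0.25
        return DistributionSpec("lognormal", (mu, sd))
    v = s * s
    if family == "gamma":
        k = max(m * m / v, 1e-3)
        return DistributionSpec("gamma", (k, max(m / k, 1e-6)))
    if family == "weibull":
        cv2 = v / (m * m)

        def g(c: float) -> float:
            return math.exp(special.gammaln(1 + 2 / c) - 2 * special.gammaln(1 + 1 / c)) - 1 - cv2

        try:
            c = optimize.brentq(g, 0.08, 80.0)
        except ValueError:
            c = 1.0
        scale = m / math.exp(special.gammaln(1 + 1 / c))
        return DistributionSpec("weibull", (c, scale))
    # gengamma seeded at its gamma special case (p = 1)
    k = max(m * m / v, 1e-3)
    return DistributionSpec("gengamma", (max(m / k, 1e-6), k, 1.0))


def initialize(obs: ObservationSet, family: str, J: int = 1) -> MixtureModel:
    """Deterministic starting model from quantile-sliced moment estimates.

    The quantified values are sorted and cut into J equal quantile bands;
    each band yields a method-of-moments component, weighted 1/J.
    """
    vals = np.sort(obs.quantified)
    if vals.size < 2 * J:
        raise ValueError(f"need at least {2 * J} quantified values to initialize J={J}")
    pooled_sd = float(np.std(vals, ddof=1))
    comps = []
    edges = [int(round(j * vals.size / J)) for j in range(J + 1)]
    for j in range(J):
        band = vals[edges[j]:edges[j + 1]]
        comps.append(_moment_spec(family, band, fallback_sd=pooled_sd / (2 * J)))
    return MixtureModel(tuple(comps), tuple([1.0 / J] * J))


def _check_fittable(obs: ObservationSet) -> None:
    for s in obs.strata():
        if s.cut == CUT_TRUNCATED and math.isfinite(s.window.upper):
            raise ValueError(
                "right-truncated data cannot be fitted: with the upper tail removed "
                "and no record of how many values were lost, the mass above the UDL "
                "is not identifiable"
            )


def fit_mle(
    obs: ObservationSet,
    family: str,
    J: int = 1,
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
    start: MixtureModel | None = None,
) -> FitResult:
    """Fit a J-component mixture by box-constrained quasi-Newton MLE."""
    _check_fittable(obs)
    transform = ParamTransform(family, J)
    init = start if start is not None else initialize(obs, family, J)
    y0 = transform.to_free(init)
    bounds = transform.bounds()

    def objective(y: np.ndarray) -> float:
        try:
            ll = loglik(obs, transform.to_model(y))
        except (ValueError, OverflowError, FloatingPointError):
            return 1e10
        if not math.isfinite(ll):
            return 1e10
        return -ll

    rng = np.random.default_rng(seed)
    starts = [y0] + [y0 + rng.normal(0.0, 0.3, size=y0.size) for _ in range(max(0, n_starts - 1))]
    best = None
    with np.errstate(all="ignore"):
        for y_start in starts:
            res = optimize.minimize(
                objective, y_start, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 500, "ftol": tol},
            )
            if best is None or res.fun < best.fun:
                best = res
        # polish from the best optimum; also verifies local stationarity
        res = optimize.minimize(
            objective, best.x, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": tol},
        )
        if res.fun <= best.fun:
            best = res

    model = transform.to_model(best.x).sorted_by_mean()
    ll = float(-best.fun)
    p = model.n_free_params
    n = obs.effective_n()
    aic, aicc, bic = _criteria(ll, p, n)
    return FitResult(
        model=model, loglik=ll, n_params=p, n_obs=n,
        aic=aic, aicc=aicc, bic=bic,
        converged=bool(best.success) and ll > -1e9,
        family=family, J=J, message=str(best.message),
    )


def fit_all(
    obs: ObservationSet,
    families: Sequence[str] = FAMILIES,
    J_list: Sequence[int] = (1, 2),
    **kwargs,
) -> list[FitResult]:
    """One :class:`FitResult` per (family, J) pair, in stable order.

    Individual failures are recorded in the result (``model=None``)
    rather than raised, so a sweep over families survives a pathological
    combination.
    """
    if not families or not J_list:
        raise ValueError("families and J_list must be non-empty")
    out = []
    for family in families:
        for J in J_list:
            try:
                out.append(fit_mle(obs, family, J, **kwargs))
            except Exception as exc:  # noqa: BLE001 - sweep must survive
                log.warning("fit failed for %s J=%d: %s", family, J, exc)
                out.append(
                    FitResult(
                        model=None, loglik=-math.inf, n_params=0,
                        n_obs=obs.effective_n(), aic=math.inf, aicc=math.inf,
                        bic=math.inf, converged=False, family=family, J=J,
                        message=str(exc),
                    )
                )
    return out
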