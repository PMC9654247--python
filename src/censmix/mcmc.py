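"""Adaptive Metropolis-Hastings sampling of mixture-model posteriors.

The sampler is a one-parameter-at-a-time Gaussian random walk on the
transformed scale (log for positive parameters, logit for the
stick-breaking weight fractions), started at the maximum-likelihood
estimate.  Priors are uniform on the natural scale — by default
[MLE/1000, MLE*1000] for positive parameters, a similarly wide symmetric
box for real-valued locations, and (0, 1) for each stick fraction — so
the transformed-scale target includes the change-of-variables Jacobian.

During burn-in each per-parameter proposal sd is tuned by Robbins-Monro
updates toward the 0.234 acceptance rate that is near-optimal for random
walk Metropolis; the scales are frozen afterwards so the retained chain
is Markovian.  Because the chain starts at the MLE, a short burn-in
(default 100 sweeps) suffices; proposal scales are pre-seeded from the
curvature of the log-posterior at the start so that 100 sweeps of tuning
is genuinely enough.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .likelihood import MixtureModel, ObservationSet, loglik
from .mle import FitResult, ParamTransform

__all__ = ["MCMCTrace", "run_mcmc", "summarize", "default_priors", "adaptive_metropolis"]

log = logging.getLogger(__name__)

TARGET_ACCEPTANCE = 0.234


@dataclass
class MCMCTrace:
    """Posterior draws from :func:`run_mcmc`.

    ``draws`` holds one row per sweep (burn-in included, flagged via
    ``burn_in``) on the natural scale: every component parameter followed
    by all J mixture weights.  ``free_draws`` keeps the transformed-scale
    states used internally, so models can be rebuilt exactly.
    """

    draws: np.ndarray
    logliks: np.ndarray
    param_names: list[str]
    burn_in: int
    acceptance_rate: float
    proposal_sds: np.ndarray
    priors: np.ndarray  # (n_free, 2) natural-scale uniform bounds
    seed: int | None
    family: str
    J: int
    free_draws: np.ndarray = field(repr=False, default=None)

    @property
    def n_iter(self) -> int:
        return self.draws.shape[0] - 1  # first row is the start point

    def posterior(self) -> np.ndarray:
        """Post-burn-in natural-scale draws."""
        return self.draws[self.burn_in + 1:]

    def posterior_free(self) -> np.ndarray:
        return self.free_draws[self.burn_in + 1:]

    def model_at(self, i: int, *, post_burn_in: bool = True) -> MixtureModel:
        """Rebuild the mixture model at row ``i`` of the (post-burn-in)
        trace."""
        transform = ParamTransform(self.family, self.J)
        rows = self.posterior_free() if post_burn_in else self.free_draws
        return transform.to_model(rows[i])

    def to_frame(self, include_burn_in: bool = False) -> pd.DataFrame:
        frame = pd.DataFrame(self.draws, columns=self.param_names)
        frame["loglik"] = self.logliks
        if not include_burn_in:
            frame = frame.iloc[self.burn_in + 1:].reset_index(drop=True)
        return frame


def _natural_names(family: str, J: int) -> list[str]:
    transform = ParamTransform(family, J)
    names = [n for n in transform.free_names if not n.startswith("stick")]
    if J > 1:
        names += [f"q{j + 1}" for j in range(J)]
    return names


def _to_natural_row(transform: ParamTransform, y: np.ndarray) -> np.ndarray:
    model = transform.to_model(y)
    row = [p for comp in model.components for p in comp.params]
    if transform.J > 1:
        row += list(model.weights)
    return np.asarray(row, dtype=float)


def default_priors(transform: ParamTransform, y0: np.ndarray) -> np.ndarray:
    """Wide uniform prior bounds on the natural scale of each free
    parameter: [m/1000, 1000 m] around a positive start m, a symmetric
    box of half-width 1000*max(|m|, 1) for real locations, (0, 1) for
    stick fractions."""
    natural = transform.natural(y0)
    bounds = np.empty((transform.n_free, 2))
    k = 0
    for _ in range(transform.J):
        for pos in transform.positive:
            m = natural[k]
            if pos:
                bounds[k] = (m / 1000.0, m * 1000.0)
            else:
                half = 1000.0 * max(abs(m), 1.0)
                bounds[k] = (m - half, m + half)
            k += 1
    for _ in range(transform.J - 1):
        bounds[k] = (0.0, 1.0)
        k += 1
    return bounds


def adaptive_metropolis(
    log_target,
    y0: np.ndarray,
    n_iter: int,
    burn_in: int,
    rng: np.random.Generator,
    init_sds: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Component-wise adaptive random-walk Metropolis on R^d.

    Each sweep proposes every coordinate in turn from a Gaussian centred
    at the current value.  During the first ``burn_in`` sweeps the
    per-coordinate proposal sd follows Robbins-Monro updates toward the
    0.234 target acceptance rate and is frozen afterwards.

    Returns ``(states, log_targets, acceptance_rate, proposal_sds)``
    where ``states`` has ``n_iter + 1`` rows (the start point first) and
    the acceptance rate counts post-burn-in proposals only.
    """
    y = np.asarray(y0, dtype=float).copy()
    d = y.size
    log_sds = np.log(np.full(d, 0.1) if init_sds is None else np.asarray(init_sds, dtype=float))
    lp = log_target(y)
    if not math.isfinite(lp):
        raise ValueError("start point has zero target density")
    states = np.empty((n_iter + 1, d))
    lps = np.empty(n_iter + 1)
    states[0], lps[0] = y, lp
    accepted_post = proposed_post = 0
    consecutive_rejects = 0
    warned = False
    for t in range(1, n_iter + 1):
        adapting = t <= burn_in
        for i in range(d):
            prop = y.copy()
            prop[i] += rng.normal(0.0, math.exp(log_sds[i]))
            lp_prop = log_target(prop)
            accept = math.log(rng.uniform()) < lp_prop - lp
            if accept:
                y, lp = prop, lp_prop
                consecutive_rejects = 0
            else:
                consecutive_rejects += 1
                if consecutive_rejects >= 1000 and not warned:
                    log.warning("MCMC: 1000 consecutive rejected proposals; chain may be stuck")
                    warned = True
            if adapting:
                # Robbins-Monro step toward the 0.234 target rate
                gamma = 1.0 / math.sqrt(t)
                log_sds[i] += gamma * ((1.0 if accept else 0.0) - TARGET_ACCEPTANCE)
            else:
                proposed_post += 1
                accepted_post += int(accept)
        states[t] = y
        lps[t] = lp
    rate = accepted_post / proposed_post if proposed_post else 0.0
    return states, lps, rate, np.exp(log_sds)


def _curvature_sds(log_post, y0: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Proposal scales 2.4 / sqrt(-d2 logpost / dy2), per parameter."""
    f0 = log_post(y0)
    sds = np.full(y0.size, 0.1)
    for i in range(y0.size):
        step = np.zeros_like(y0)
        step[i] = h
        d2 = (log_post(y0 + step) - 2.0 * f0 + log_post(y0 - step)) / (h * h)
        if math.isfinite(d2) and d2 < -1e-12:
            sds[i] = 2.4 / math.sqrt(-d2)
    return np.clip(sds, 1e-4, 5.0)


def run_mcmc(
    obs: ObservationSet,
    start: FitResult | MixtureModel,
    n_iter: int = 5000,
    burn_in: int = 100,
    seed: int | None = None,
    priors: np.ndarray | None = None,
) -> MCMCTrace:
    """Sample the posterior of a mixture model by adaptive MH.

    Parameters
    ----------
    obs
        The data whose conditional likelihood defines the posterior.
    start
        MLE fit (or a model) used as starting point; starting at the
        mode is what justifies the short default burn-in.
    n_iter, burn_in
        Post-start sweeps in total and how many of them are burn-in
        (used for proposal adaptation and excluded from summaries).
    priors
        Optional (n_free, 2) natural-scale uniform bounds overriding
        :func:`default_priors`.
    """
    model = start.model if isinstance(start, FitResult) else start
    if model is None:
        raise ValueError("start fit has no model")
    if burn_in < 0 or n_iter < burn_in:
        raise ValueError("need 0 <= burn_in <= n_iter")
    transform = ParamTransform(model.family, model.J)
    y = transform.to_free(model)
    if priors is None:
        priors = default_priors(transform, y)
    priors = np.asarray(priors, dtype=float)
    if priors.shape != (transform.n_free, 2):
        raise ValueError(f"priors must have shape ({transform.n_free}, 2)")
    natural0 = transform.natural(y)
    if np.any(natural0 <= priors[:, 0]) or np.any(natural0 >= priors[:, 1]):
        raise ValueError("start point lies outside the prior bounds")

    def log_post(yv: np.ndarray) -> float:
        nat = transform.natural(yv)
        if np.any(nat <= priors[:, 0]) or np.any(nat >= priors[:, 1]):
            return -math.inf
        try:
            ll = loglik(obs, transform.to_model(yv))
        except (ValueError, OverflowError, FloatingPointError):
            return -math.inf
        if not math.isfinite(ll):
            return -math.inf
        return ll + transform.log_jacobian(yv)

    rng = np.random.default_rng(seed)
    init_sds = _curvature_sds(log_post, y)
    free_rows, lps, rate, final_sds = adaptive_metropolis(
        log_post, y, n_iter, burn_in, rng, init_sds=init_sds
    )
    nat_rows = np.empty((n_iter + 1, len(_natural_names(model.family, model.J))))
    lls = np.empty(n_iter + 1)
    for t in range(n_iter + 1):
        nat_rows[t] = _to_natural_row(transform, free_rows[t])
        lls[t] = lps[t] - transform.log_jacobian(free_rows[t])

    return MCMCTrace(
        draws=nat_rows,
        logliks=lls,
        param_names=_natural_names(model.family, model.J),
        burn_in=burn_in,
        acceptance_rate=rate,
        proposal_sds=final_sds,
        priors=priors,
        seed=seed,
        family=model.family,
        J=model.J,
        free_draws=free_rows,
    )


def summarize(
    trace: MCMCTrace, quantiles: Sequence[float] = (0.025, 0.5, 0.975)
) -> pd.DataFrame:
    """Per-parameter mean, sd and empirical quantiles, burn-in excluded."""
    rows = trace.posterior()
    if rows.shape[0] < 10:
        raise ValueError("need at least 10 post-burn-in draws to summarize")
    out = pd.DataFrame(index=trace.param_names)
    out["mean"] = rows.mean(axis=0)
    out["sd"] = rows.std(axis=0, ddof=1)
    for q in quantiles:
        out[f"q{q:g}"] = np.quantile(rows, q, axis=0)
    return out
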