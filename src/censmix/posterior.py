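"""Posterior-predictive goodness-of-fit, imputation and density bands.

Goodness-of-fit is the classical posterior-predictive p-value: for
parameter draws theta_i along the chain, a replicate dataset with the
same size, strata and cut regime as the observed one is simulated and
its likelihood compared with the observed likelihood under the same
theta_i.  The reported value is the fraction of replicates *less likely*
than the observed data (ties split 50/50); values near 0 or 1 flag a
model that cannot have generated the data.

Imputation replaces each unquantifiable (UnQ) cell by a draw from the
fitted mixture *conditional on the censoring event* — truncated to
(0, LDL) for a below-LDL cell, to (UDL, inf) for an above-UDL cell —
with mixture parameters resampled from the chain, so the completed
datasets propagate posterior uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from . import distributions as dist
from .distributions import Interval
from .likelihood import (
    CUT_CENSORED,
    UNQ_HIGH,
    UNQ_LOW,
    MixtureModel,
    ObservationSet,
    loglik,
    mixture_density,
)
from .mcmc import MCMCTrace

__all__ = ["GofResult", "ImputationDraws", "gof", "impute", "predictive_band", "mixture_rvs"]


@dataclass(frozen=True)
class GofResult:
    """Posterior-predictive goodness-of-fit."""

    p_value: float
    observed_logliks: np.ndarray
    replicate_logliks: np.ndarray

    @property
    def n_replicates(self) -> int:
        return self.replicate_logliks.size


@dataclass(frozen=True)
class ImputationDraws:
    """Completed datasets with UnQ cells filled in."""

    completed_datasets: np.ndarray  # (n_draws, n) matrix
    unq_mask: np.ndarray
    source_iterations: np.ndarray
    mode: str


def mixture_rvs(
    model: MixtureModel,
    n: int,
    window: Interval = dist.FULL_WINDOW,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draws from the window-truncated mixture.

    A component is picked with probability proportional to
    q_j * P_j(window), then an inverse-CDF draw is made inside the
    window — exactly the conditional mixture, not a crude
    accept/reject."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if n == 0:
        return np.empty(0)
    mass = np.array(
        [q * math.exp(dist.window_logmass(c, window)) for q, c in zip(model.weights, model.components)]
    )
    total = mass.sum()
    if total <= 0.0:
        raise ValueError("window has zero probability mass under the mixture")
    picks = rng.choice(model.J, size=n, p=mass / total)
    out = np.empty(n)
    for j in range(model.J):
        sel = picks == j
        if sel.any():
            out[sel] = dist.rvs(model.components[j], int(sel.sum()), window, rng)
    return out


def _select_iterations(trace: MCMCTrace, n: int, rng: np.random.Generator) -> np.ndarray:
    rows = trace.posterior_free().shape[0]
    if rows == 0:
        raise ValueError("trace has no post-burn-in draws")
    if n <= rows:
        # evenly thinned pass over the chain
        return np.linspace(0, rows - 1, n).round().astype(int)
    return rng.integers(0, rows, size=n)


def _simulate_replicate(
    obs: ObservationSet, model: MixtureModel, rng: np.random.Generator
) -> ObservationSet:
    """A dataset with the observed size, strata and cut regimes drawn
    from ``model``."""
    values, ldl, udl, cut = [], [], [], []
    for s in obs.strata():
        if s.cut == CUT_CENSORED:
            raw = mixture_rvs(model, s.n, dist.FULL_WINDOW, rng)
            sim = np.where(
                raw < s.window.lower, UNQ_LOW, np.where(raw > s.window.upper, UNQ_HIGH, raw)
            )
        else:
            sim = mixture_rvs(model, s.n_quantified, s.window, rng)
        values.append(sim)
        ldl.append(np.full(sim.size, s.window.lower))
        udl.append(np.full(sim.size, s.window.upper))
        cut.extend([s.cut] * sim.size)
    return ObservationSet(
        np.concatenate(values), np.concatenate(ldl), np.concatenate(udl), cut
    )


def gof(
    trace: MCMCTrace,
    obs: ObservationSet,
    n_rep: int = 5000,
    seed: int | None = None,
) -> GofResult:
    """Posterior-predictive p-value of the fitted model for ``obs``."""
    rng = np.random.default_rng(seed)
    idx = _select_iterations(trace, n_rep, rng)
    obs_ll = np.empty(idx.size)
    rep_ll = np.empty(idx.size)
    for k, i in enumerate(idx):
        model = trace.model_at(int(i))
        obs_ll[k] = loglik(obs, model)
        rep_ll[k] = loglik(_simulate_replicate(obs, model, rng), model)
    p = float(np.mean((rep_ll < obs_ll) + 0.5 * (rep_ll == obs_ll)))
    return GofResult(p_value=p, observed_logliks=obs_ll, replicate_logliks=rep_ll)


def _unq_window(value: float, ldl: float, udl: float) -> Interval:
    if value == UNQ_LOW:
        return Interval(0.0, ldl)
    return Interval(udl, math.inf)


def _conditional_mean(model: MixtureModel, window: Interval) -> float:
    """E[X | X in window] under the mixture, by adaptive quadrature.

    Components are weighted by q_j * P_j(window) — the exact conditional
    of the mixture given the censoring event, matching what
    :func:`mixture_rvs` samples from.
    """
    upper = window.upper
    if math.isinf(upper):
        # integrate to a far quantile of the slowest-decaying component
        upper = max(c.frozen().ppf(1.0 - 1e-10) for c in model.components)
        upper = max(upper, window.lower * 10.0, 1.0)
    num = den = 0.0
    for q, comp in zip(model.weights, model.components):
        mass = math.exp(dist.window_logmass(comp, window))
        if mass <= 0.0:
            continue
        part, _ = integrate.quad(
            lambda x: x * dist.truncated_pdf(comp, x, window),
            window.lower, upper, limit=200,
        )
        num += q * mass * part
        den += q * mass
    if den <= 0.0:
        raise ValueError("window has zero probability mass under the mixture")
    return float(num / den)


def impute(
    trace: MCMCTrace,
    obs: ObservationSet,
    n_draws: int = 1000,
    mode: str = "random",
    seed: int | None = None,
) -> ImputationDraws:
    """Fill UnQ cells from the posterior predictive distribution.

    ``mode="random"``: each draw resamples chain parameters and then
    each UnQ cell from the mixture truncated to its censoring side.
    ``mode="point"``: a single completed dataset in which every UnQ cell
    holds its posterior-mean conditional expectation.
    """
    if mode not in ("random", "point"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    mask = obs.unq_mask
    unq_idx = np.flatnonzero(mask)

    rng = np.random.default_rng(seed)
    if mode == "point":
        n_iter = min(500, trace.posterior_free().shape[0])
        idx = _select_iterations(trace, n_iter, rng)
        completed = obs.values.copy()[None, :]
        cache: dict[tuple, float] = {}
        for i in unq_idx:
            window = _unq_window(obs.values[i], obs.ldl[i], obs.udl[i])
            key = (window.lower, window.upper)
            if key not in cache:
                means = [_conditional_mean(trace.model_at(int(j)), window) for j in idx]
                cache[key] = float(np.mean(means))
            completed[0, i] = cache[key]
        return ImputationDraws(completed, mask, idx, mode)

    idx = rng.integers(0, trace.posterior_free().shape[0], size=n_draws)
    completed = np.tile(obs.values, (n_draws, 1))
    for d, it in enumerate(idx):
        model = trace.model_at(int(it))
        for i in unq_idx:
            window = _unq_window(obs.values[i], obs.ldl[i], obs.udl[i])
            completed[d, i] = mixture_rvs(model, 1, window, rng)[0]
    return ImputationDraws(completed, mask, idx, mode)


def predictive_band(
    trace: MCMCTrace,
    grid: np.ndarray,
    quantiles=(0.025, 0.975),
    n_iter: int | None = None,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Pointwise posterior mean and quantiles of the mixture density.

    Evaluates the unconditioned (full positive support) mixture density
    on ``grid`` for draws along the chain; suitable for overlaying on a
    histogram together with a credible envelope.
    """
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    rows = trace.posterior_free().shape[0]
    idx = _select_iterations(trace, n_iter or rows, rng)
    dens = np.empty((idx.size, grid.size))
    for k, i in enumerate(idx):
        dens[k] = mixture_density(trace.model_at(int(i)), grid, dist.FULL_WINDOW)
    out = {"grid": grid, "mean": dens.mean(axis=0)}
    for q in quantiles:
        out[f"q{q:g}"] = np.quantile(dens, q, axis=0)
    return out
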