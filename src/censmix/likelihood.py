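"""Conditional likelihood for censored / truncated concentration data.

An observation is either a quantified value or an *unquantifiable* (UnQ)
marker: ``-inf`` for a value known only to lie below its lower detection
limit (LDL), ``+inf`` for one above its upper detection limit (UDL).
Each row carries its own detection window and *cut* regime:

``censored``
    UnQ rows are present as markers; the likelihood of quantified values
    is conditional on the quantification window, and the split of counts
    (below LDL / quantified / above UDL) contributes a multinomial term.

``truncated``
    Out-of-window observations are absent entirely; only the
    window-conditional density of the quantified values enters.

Rows sharing the same (LDL, UDL, cut) form a *stratum*; each censored
stratum gets its own multinomial term, which is what makes datasets with
varying detection limits well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.special import gammaln

from .distributions import (
    DistributionSpec,
    Interval,
    cdf,
    truncated_logpdf,
    window_logmass,
)

__all__ = [
    "UNQ_LOW",
    "UNQ_HIGH",
    "CUT_CENSORED",
    "CUT_TRUNCATED",
    "Stratum",
    "ObservationSet",
    "MixtureModel",
    "mixture_logdensity",
    "mixture_density",
    "mixture_cdf",
    "censoring_probs",
    "multinomial_logmass",
    "loglik",
]

UNQ_LOW = -math.inf
UNQ_HIGH = math.inf

CUT_CENSORED = "censored"
CUT_TRUNCATED = "truncated"
_CUTS = (CUT_CENSORED, CUT_TRUNCATED)


@dataclass(frozen=True)
class Stratum:
    """All rows sharing one (window, cut) combination."""

    window: Interval
    cut: str
    quantified: np.ndarray  # strictly the finite values
    n_ldl: int  # count of below-LDL markers (censored only)
    n_udl: int  # count of above-UDL markers (censored only)

    @property
    def n(self) -> int:
        return self.quantified.size + self.n_ldl + self.n_udl

    @property
    def n_quantified(self) -> int:
        return self.quantified.size


class ObservationSet:
    """Concentration observations with per-row detection limits.

    Parameters
    ----------
    values
        Observed values; ``-inf`` / ``+inf`` encode UnQ entries below /
        above the row's detection limits.
    ldl, udl
        Per-row limits, or scalars for a homogeneous dataset.  ``ldl=0``
        and ``udl=inf`` mean "no limit".
    cut
        ``"censored"`` or ``"truncated"``, per row or scalar.
    """

    def __init__(self, values, ldl=0.0, udl=math.inf, cut=CUT_CENSORED):
        values = np.asarray(values, dtype=float).ravel()
        if values.size == 0:
            raise ValueError("empty observation set")
        n = values.size
        ldl = np.broadcast_to(np.asarray(ldl, dtype=float), (n,)).copy()
        udl = np.broadcast_to(np.asarray(udl, dtype=float), (n,)).copy()
        cut_in = np.broadcast_to(np.asarray(cut, dtype=object), (n,))
        cut_arr = np.array([str(c).strip().lower() for c in cut_in], dtype=object)

        def _fail(mask: np.ndarray, message: str) -> None:
            row = int(np.flatnonzero(mask)[0]) + 1  # 1-based row numbers
            raise ValueError(f"row {row}: {message}")

        bad = ~np.isin(cut_arr.astype(str), _CUTS)
        if bad.any():
            _fail(bad, f"unknown cut method {cut_in[bad][0]!r}")
        bad = ~((ldl >= 0.0) & (ldl < udl))
        if bad.any():
            _fail(bad, f"invalid limits LDL={ldl[bad][0]}, UDL={udl[bad][0]}")
        low = values == UNQ_LOW
        high = values == UNQ_HIGH
        finite = ~(low | high)
        truncated = cut_arr.astype(str) == CUT_TRUNCATED
        bad = low & (ldl <= 0.0)
        if bad.any():
            _fail(bad, "below-LDL marker but no LDL given")
        bad = high & np.isinf(udl)
        if bad.any():
            _fail(bad, "above-UDL marker but no UDL given")
        bad = (low | high) & truncated
        if bad.any():
            _fail(
                bad,
                "truncated rows cannot carry UnQ markers "
                "(truncation removes out-of-window rows entirely)",
            )
        bad = finite & (~np.isfinite(values) | (values <= 0.0))
        if bad.any():
            _fail(bad, f"observations must be positive, got {values[bad][0]}")
        # a value exactly at a limit counts as quantified
        bad = finite & ((values < ldl) | (values > udl))
        if bad.any():
            _fail(
                bad,
                f"quantified value {values[bad][0]} outside its window "
                f"({ldl[bad][0]}, {udl[bad][0]})",
            )

        self.values = values
        self.ldl = ldl
        self.udl = udl
        self.cut = cut_arr

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_quantified(self) -> int:
        return int(np.sum(np.isfinite(self.values)))

    @property
    def n_unq(self) -> int:
        return len(self) - self.n_quantified

    @property
    def quantified(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]

    @property
    def unq_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def strata(self) -> list[Stratum]:
        # observation sets are immutable after validation, so the stratum
        # decomposition is computed once and cached (loglik is hot)
        cached = getattr(self, "_strata", None)
        if cached is not None:
            return cached
        out = []
        keys = list(zip(self.ldl, self.udl, self.cut))
        seen: dict[tuple, int] = {}
        for key in keys:
            if key not in seen:
                seen[key] = len(seen)
        for key in sorted(seen, key=seen.get):
            lo, hi, cut = key
            mask = (self.ldl == lo) & (self.udl == hi) & (self.cut == cut)
            vals = self.values[mask]
            out.append(
                Stratum(
                    window=Interval(lo, hi),
                    cut=cut,
                    quantified=vals[np.isfinite(vals)],
                    n_ldl=int(np.sum(vals == UNQ_LOW)),
                    n_udl=int(np.sum(vals == UNQ_HIGH)),
                )
            )
        self._strata = out
        return out

    def effective_n(self) -> int:
        """Sample size carried by the likelihood: all rows for censored
        strata (UnQ markers are information), quantified rows only for
        truncated strata."""
        return sum(s.n if s.cut == CUT_CENSORED else s.n_quantified for s in self.strata())


@dataclass(frozen=True)
class MixtureModel:
    """A weighted mixture of J components from a single family."""

    components: Tuple[DistributionSpec, ...]
    weights: Tuple[float, ...]

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        w = tuple(float(x) for x in self.weights)
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "weights", w)
        if not comps:
            raise ValueError("mixture needs at least one component")
        if len(comps) != len(w):
            raise ValueError("component and weight counts differ")
        if len({c.family for c in comps}) != 1:
            raise ValueError("all mixture components must share one family")
        if len(comps) > 9:
            raise ValueError("at most 9 mixture components are supported")
        if any(x <= 0.0 or x > 1.0 for x in w):
            raise ValueError(f"weights must lie in (0, 1], got {w}")
        if abs(sum(w) - 1.0) > 1e-8:
            raise ValueError(f"weights must sum to 1, got {sum(w)}")

    @property
    def J(self) -> int:
        return len(self.components)

    @property
    def family(self) -> str:
        return self.components[0].family

    @property
    def n_free_params(self) -> int:
        """J * dim(family) component parameters plus J - 1 free weights."""
        return sum(c.n_params for c in self.components) + (self.J - 1)

    def mean(self) -> float:
        return float(sum(q * c.mean() for q, c in zip(self.weights, self.components)))

    def sorted_by_mean(self) -> "MixtureModel":
        order = np.argsort([c.mean() for c in self.components], kind="stable")
        return MixtureModel(
            components=tuple(self.components[i] for i in order),
            weights=tuple(self.weights[i] for i in order),
        )


def mixture_logdensity(model: MixtureModel, x, window: Interval) -> np.ndarray | float:
    """log sum_j q_j f(x | window; theta_j)."""
    arr = np.asarray(x, dtype=float)
    if model.J == 1:
        out = np.atleast_1d(truncated_logpdf(model.components[0], arr, window))
    else:
        parts = np.stack(
            [
                math.log(q) + np.atleast_1d(truncated_logpdf(c, arr, window))
                for q, c in zip(model.weights, model.components)
            ]
        )
        # lean log-sum-exp over the component axis
        m = np.max(parts, axis=0)
        safe = np.where(np.isfinite(m), m, 0.0)
        out = safe + np.log(np.sum(np.exp(parts - safe), axis=0))
        out = np.where(np.isfinite(m), out, m)
    return out if arr.shape else float(out[0])


def mixture_density(model: MixtureModel, x, window: Interval) -> np.ndarray | float:
    return np.exp(mixture_logdensity(model, x, window))


def mixture_cdf(model: MixtureModel, x) -> np.ndarray | float:
    """CDF of the (unconditioned, zero-truncated) mixture."""
    arr = np.asarray(x, dtype=float)
    out = sum(q * np.asarray(cdf(c, arr)) for q, c in zip(model.weights, model.components))
    return out if arr.shape else float(out)


def censoring_probs(model: MixtureModel, window: Interval) -> tuple[float, float, float]:
    """(pLDL, pLU, pUDL): probability mass below, inside and above the window."""
    p_ldl = float(mixture_cdf(model, window.lower)) if window.lower > 0.0 else 0.0
    p_udl = 0.0 if math.isinf(window.upper) else 1.0 - float(mixture_cdf(model, window.upper))
    p_ldl = min(max(p_ldl, 0.0), 1.0)
    p_udl = min(max(p_udl, 0.0), 1.0 - p_ldl)
    return p_ldl, 1.0 - p_ldl - p_udl, p_udl


def multinomial_logmass(
    counts: Sequence[int], probs: Sequence[float]
) -> float:
    """Log-probability of (nLDL, nLU, nUDL) counts under (pLDL, pLU, pUDL).

    Reduces to a binomial when a count is zero; a positive count paired
    with zero probability yields ``-inf`` (an impossible model, signalled
    rather than raised so optimizers can back off).
    """
    counts = [int(c) for c in counts]
    probs = [float(p) for p in probs]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if any(p < -1e-12 for p in probs) or abs(sum(probs) - 1.0) > 1e-8:
        raise ValueError(f"probs must form a simplex point, got {probs}")
    n = sum(counts)
    out = gammaln(n + 1) - sum(gammaln(c + 1) for c in counts)
    for c, p in zip(counts, probs):
        if c == 0:
            continue
        if p <= 0.0:
            return -math.inf
        out += c * math.log(p)
    return float(out)


def _stratum_loglik(stratum: Stratum, model: MixtureModel) -> float:
    ll = 0.0
    if stratum.n_quantified:
        dens = mixture_logdensity(model, stratum.quantified, stratum.window)
        total = float(np.sum(dens))
        if not math.isfinite(total):
            return -math.inf
        ll += total
    if stratum.cut == CUT_CENSORED:
        probs = censoring_probs(model, stratum.window)
        counts = (stratum.n_ldl, stratum.n_quantified, stratum.n_udl)
        ll += multinomial_logmass(counts, probs)
    return ll


def loglik(obs: ObservationSet, model: MixtureModel) -> float:
    """Conditional log-likelihood of the observations under the model.

    Per stratum: the sum of window-conditional mixture log-densities of
    the quantified values, plus — for censored strata — the multinomial
    log-mass of the (below, inside, above) counts.  Returns ``-inf`` for
    parameter values that make the data impossible.
    """
    total = 0.0
    for stratum in obs.strata():
        ll = _stratum_loglik(stratum, model)
        if ll == -math.inf:
            return -math.inf
        total += ll
    return total
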