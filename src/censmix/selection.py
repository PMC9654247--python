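"""Information-criterion comparison and the BIC-weight homogeneity test.

Akaike weights turn a set of criterion values into relative
probabilities that each model is the best of those compared:

    w_j = exp(-Delta_j / 2) / sum_i exp(-Delta_i / 2),
    Delta_j = IC_j - min_i IC_i

The same weighting applied to BIC values of a "one common model" fit
versus the sum of per-group fits gives the *w-value*: the probability
that several datasets are adequately modeled together rather than
separately.  A small w-value (default threshold 0.001) indicates the
groups differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .mle import FitResult

__all__ = [
    "ModelComparison",
    "akaike_weights",
    "compare",
    "homogeneity_w_value",
    "select_best",
    "HOMOGENEITY_THRESHOLD",
]

#: w-values below this are reported as "the groups differ"
HOMOGENEITY_THRESHOLD = 1e-3


def akaike_weights(values: Sequence[float]) -> np.ndarray:
    """Normalized exp(-Delta/2) weights of a list of criterion values.

    Infinite values (failed fits) receive weight 0.  Computed with the
    min-shift so very large criteria do not underflow the whole set.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one criterion value")
    finite = np.isfinite(arr)
    if not finite.any():
        raise ValueError("need at least one finite criterion value")
    delta = arr - arr[finite].min()
    raw = np.where(finite, np.exp(-0.5 * np.where(finite, delta, 0.0)), 0.0)
    return raw / raw.sum()


@dataclass(frozen=True)
class ModelComparison:
    """A ranked table of models under one criterion."""

    labels: tuple[str, ...]
    values: tuple[float, ...]
    criterion: str
    gof: tuple[float, ...] | None = None

    @property
    def delta(self) -> np.ndarray:
        arr = np.asarray(self.values, dtype=float)
        return arr - arr[np.isfinite(arr)].min()

    @property
    def weights(self) -> np.ndarray:
        return akaike_weights(self.values)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "label": self.labels,
                self.criterion: self.values,
                "delta": self.delta,
                "weight": self.weights,
            }
        )
        if self.gof is not None:
            frame["GoF"] = self.gof
        return frame

    def to_text(self) -> str:
        return self.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4f}")


def compare(
    fits: Sequence[FitResult],
    criterion: str = "AIC",
    gof: Sequence[float] | None = None,
) -> ModelComparison:
    """Build a :class:`ModelComparison` from fitted models."""
    crit = criterion.upper()
    if crit not in ("AIC", "AICC", "BIC"):
        raise ValueError(f"unknown criterion {criterion!r}")
    attr = {"AIC": "aic", "AICC": "aicc", "BIC": "bic"}[crit]
    labels = tuple(f"{f.family}-{f.J}" for f in fits)
    values = tuple(getattr(f, attr) for f in fits)
    return ModelComparison(
        labels=labels,
        values=values,
        criterion=crit,
        gof=tuple(gof) if gof is not None else None,
    )


def homogeneity_w_value(
    fit_combined: FitResult, fits_separate: Sequence[FitResult]
) -> float:
    """BIC weight of "one model for all groups" against per-group models.

    The separate alternative's BIC is the sum of the parts' BICs (each
    part penalized with its own sample size).  Returns the probability
    that the pooled model suffices; values below
    :data:`HOMOGENEITY_THRESHOLD` indicate the groups differ.
    """
    if len(fits_separate) < 2:
        raise ValueError("need at least two separate group fits")
    for f in fits_separate:
        if f.family != fit_combined.family or f.J != fit_combined.J:
            raise ValueError("separate fits must match the combined fit's family and J")
    if sum(f.n_obs for f in fits_separate) != fit_combined.n_obs:
        raise ValueError("separate fits must partition the combined data")
    bic_separate = float(sum(f.bic for f in fits_separate))
    w = akaike_weights([fit_combined.bic, bic_separate])
    return float(w[0])


def w_value_from_bics(bic_combined: float, bic_separate_total: float) -> float:
    """Homogeneity w-value straight from the two BIC numbers."""
    return float(akaike_weights([bic_combined, bic_separate_total])[0])


def select_best(comparison: ModelComparison) -> str:
    """Label of the best-supported model.

    The maximal Akaike weight wins; when contenders sit within Delta < 2
    of the best, ties are broken by higher goodness-of-fit if available,
    otherwise the earlier (fewer-parameter, given sorted input) entry is
    kept.
    """
    if not comparison.labels:
        raise ValueError("empty comparison")
    weights = comparison.weights
    delta = comparison.delta
    best = int(np.argmax(weights))
    near = np.flatnonzero(delta < 2.0)
    if comparison.gof is not None and near.size > 1:
        gof = np.asarray(comparison.gof, dtype=float)
        best = int(near[np.argmax(gof[near])])
    return comparison.labels[best]
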