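"""Synthetic censored/truncated datasets for testing and validation.

The reference scenario is a two-component gamma mixture: 100 values from
gamma(shape=10, scale=20) — mean 200 — and 100 values from
gamma(shape=5, scale=10) — mean 50.  Pooled, the 200 values have mean
125 and standard deviation sqrt(7875) ~ 88.7, with the lower component
partly hidden below a detection limit of 20 (or entirely below one of
100).  Datasets derived from it exercise every regime the likelihood
supports: left censoring, left truncation, simultaneous left and right
censoring, and two-group homogeneity comparisons.

Note on reproducibility: draws are made with NumPy's PCG64 generator.  A
given seed therefore yields a fixed dataset, but not the same values an
R session would produce from its own seed — targets on these datasets
are distributional (means, orderings), never value-exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import distributions as dist
from .distributions import DistributionSpec, Interval
from .likelihood import CUT_CENSORED, CUT_TRUNCATED, UNQ_HIGH, UNQ_LOW, ObservationSet

__all__ = [
    "ScenarioConfig",
    "generate_raw",
    "censor",
    "truncate",
    "FictiveBundle",
    "fictive_reference_datasets",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """A mixture-sampling scenario: per-component (family, params, n)."""

    components: tuple[tuple[str, tuple[float, ...], int], ...]
    window: Interval = dist.FULL_WINDOW
    cut: str = CUT_CENSORED
    seed: int = 0

    def __post_init__(self) -> None:
        for family, params, n in self.components:
            DistributionSpec(family, params)  # validates
            if n < 0:
                raise ValueError("component sample size must be >= 0")


#: the canonical two-gamma scenario (shape 10 / scale 20 and shape 5 / scale 10)
TWO_GAMMA_COMPONENTS = (
    ("gamma", (10.0, 20.0), 100),
    ("gamma", (5.0, 10.0), 100),
)


def generate_raw(config: ScenarioConfig) -> np.ndarray:
    """Concatenated i.i.d. draws per component; no limits applied."""
    rng = np.random.default_rng(config.seed)
    parts = [
        dist.rvs(DistributionSpec(family, params), n, dist.FULL_WINDOW, rng)
        for family, params, n in config.components
    ]
    return np.concatenate(parts) if parts else np.empty(0)


def censor(values: np.ndarray, window: Interval) -> ObservationSet:
    """Replace out-of-window values by UnQ markers; all rows retained."""
    values = np.asarray(values, dtype=float)
    marked = np.where(
        values < window.lower, UNQ_LOW, np.where(values > window.upper, UNQ_HIGH, values)
    )
    return ObservationSet(marked, ldl=window.lower, udl=window.upper, cut=CUT_CENSORED)


def truncate(values: np.ndarray, window: Interval) -> ObservationSet:
    """Drop out-of-window values entirely; counts of removed rows are not
    retained (that is what truncation means)."""
    values = np.asarray(values, dtype=float)
    keep = values[(values >= window.lower) & (values <= window.upper)]
    if keep.size == 0:
        raise ValueError("truncation removed every value")
    return ObservationSet(keep, ldl=window.lower, udl=window.upper, cut=CUT_TRUNCATED)


@dataclass(frozen=True)
class FictiveBundle:
    """The reference synthetic datasets, plus the raw values behind them
    (handy as held-out truth for what lies below a detection limit)."""

    raw_a: np.ndarray
    censored_a: ObservationSet  # LDL = 20, censored
    truncated_a: ObservationSet  # LDL = 20, truncated
    raw_b: np.ndarray
    censored_b: ObservationSet  # LDL = 20 and UDL = 300, censored
    raw_group1: np.ndarray
    group1: ObservationSet  # 90/10 mix, LDL = 30, censored
    raw_group2: np.ndarray
    group2: ObservationSet  # 10/90 mix, LDL = 30, censored
    raw_hidden: np.ndarray
    hidden_bimodal: ObservationSet  # LDL = 100, censored

    def as_dict(self) -> dict[str, ObservationSet]:
        return {
            "censored_a": self.censored_a,
            "truncated_a": self.truncated_a,
            "censored_b": self.censored_b,
            "group1": self.group1,
            "group2": self.group2,
            "hidden_bimodal": self.hidden_bimodal,
        }


def fictive_reference_datasets(seed: int = 1234) -> FictiveBundle:
    """Regenerate the reference synthetic datasets from one seed.

    * dataset A: the two-gamma sample, censored and truncated at LDL 20;
    * dataset B: an independent two-gamma sample censored at LDL 20 and
      UDL 300;
    * homogeneity groups: group 1 draws 90% from gamma(10, 20) and 10%
      from gamma(5, 10), group 2 the reverse, both censored at LDL 30;
    * hidden-bimodal: a two-gamma sample censored at LDL 100, where only
      the upper mode remains visible.
    """
    def cfg(components, sub_seed):
        return ScenarioConfig(components=components, seed=sub_seed)

    base = np.random.SeedSequence(seed).spawn(5)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in base]

    raw_a = generate_raw(cfg(TWO_GAMMA_COMPONENTS, seeds[0]))
    raw_b = generate_raw(cfg(TWO_GAMMA_COMPONENTS, seeds[1]))
    g1_components = (("gamma", (10.0, 20.0), 180), ("gamma", (5.0, 10.0), 20))
    g2_components = (("gamma", (10.0, 20.0), 20), ("gamma", (5.0, 10.0), 180))
    raw_g1 = generate_raw(cfg(g1_components, seeds[2]))
    raw_g2 = generate_raw(cfg(g2_components, seeds[3]))
    raw_hidden = generate_raw(cfg(TWO_GAMMA_COMPONENTS, seeds[4]))

    return FictiveBundle(
        raw_a=raw_a,
        censored_a=censor(raw_a, Interval(20.0, math.inf)),
        truncated_a=truncate(raw_a, Interval(20.0, math.inf)),
        raw_b=raw_b,
        censored_b=censor(raw_b, Interval(20.0, 300.0)),
        raw_group1=raw_g1,
        group1=censor(raw_g1, Interval(30.0, math.inf)),
        raw_group2=raw_g2,
        group2=censor(raw_g2, Interval(30.0, math.inf)),
        raw_hidden=raw_hidden,
        hidden_bimodal=censor(raw_hidden, Interval(100.0, math.inf)),
    )
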