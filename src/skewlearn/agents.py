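"""Individual foragers: learning propensity, patch memory, and the fitness proxy.

An individual carries a social-learning propensity alpha (probability that a
learning turn is social rather than individual), a sex, an age, a memory
mapping patch index -> last-observed expected payoff, and a rolling history
of its last delta per-round collected payoffs (0 for learning rounds).

The fitness proxy of a reproductively mature individual (age >= delta) is the
exponentially discounted sum of its recent payoffs,

    F_i(t) = sum_{j=0}^{delta-1} e^{-r j} * p_{i, t-j},

with discount rate r; a "single_round" variant uses only the current round's
payoff, F_i(t) = p_{i,t}.

This module provides the per-individual record API used for inspection and
small-scale reasoning; the round engine in :mod:`skewlearn.dynamics` applies
the same semantics vectorized over the whole population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "MaturityError",
    "FitnessParams",
    "Individual",
    "discount_weights",
    "fitness_proxy",
    "fitness_from_history",
    "update_memory",
    "best_remembered_patch",
]


class MaturityError(ValueError):
    """Fitness proxy requested for an individual below reproductive maturity."""


@dataclass(frozen=True)
class FitnessParams:
    """Fitness-proxy parameters: window delta, discount r, and variant."""

    window: int = 5
    discount: float = 0.2
    mode: str = "windowed"

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        if self.discount < 0:
            raise ValueError(f"discount must be >= 0, got {self.discount}")
        if self.mode not in ("windowed", "single_round"):
            raise ValueError(f"unknown fitness mode {self.mode!r}")


def discount_weights(params: FitnessParams) -> np.ndarray:
    """Weights e^{-r j}, j = 0..delta-1, most recent round first."""
    return np.exp(-params.discount * np.arange(params.window))


@dataclass(frozen=True)
class Individual:
    """Immutable record of one forager.

    ``memory`` maps patch index -> expected payoff q_{i,m} (the last observed
    pi_m / n_m for that patch). ``payoff_history`` holds the most recent
    collected payoffs, most recent first, truncated to the fitness window;
    learning rounds contribute 0.
    """

    ident: int
    alpha: float
    sex: str = "none"
    age: int = 0
    memory: Dict[int, float] = field(default_factory=dict)
    payoff_history: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if any(v < 0 for v in self.memory.values()):
            raise ValueError("memory values must be >= 0")
        if any(p < 0 for p in self.payoff_history):
            raise ValueError("payoff history entries must be >= 0")


def fitness_proxy(ind: Individual, params: FitnessParams) -> float:
    """Fitness proxy F_i of ``ind``.

    In windowed mode the individual must have lived at least ``params.window``
    rounds; immature individuals raise :class:`MaturityError` (callers are
    expected to filter the parent pool first rather than rank on a fabricated
    value).
    """
    if params.mode == "windowed" and ind.age < params.window:
        raise MaturityError(
            f"individual {ind.ident} has age {ind.age} < window {params.window}")
    hist = np.zeros(params.window)
    recent = np.asarray(ind.payoff_history[: params.window], dtype=float)
    hist[: recent.size] = recent
    if params.mode == "single_round":
        return float(hist[0])
    return float(hist @ discount_weights(params))


def fitness_from_history(history: np.ndarray, params: FitnessParams) -> np.ndarray:
    """Vectorized fitness proxy from an (N, delta) history matrix.

    Column 0 is the current round. No maturity check: the engine masks
    immature individuals out of the parent pool itself.
    """
    if params.mode == "single_round":
        return np.asarray(history[:, 0], dtype=float)
    return history @ discount_weights(params)


def update_memory(ind: Individual, patch: int, observed: float) -> Individual:
    """Store the observed expected payoff for ``patch``, overwriting any
    previous entry; other entries are untouched."""
    if observed < 0:
        raise ValueError(f"observed payoff must be >= 0, got {observed}")
    mem = dict(ind.memory)
    mem[patch] = float(observed)
    return replace(ind, memory=mem)


def best_remembered_patch(ind: Individual, rng: np.random.Generator) -> Optional[int]:
    """Patch with the highest remembered expected payoff.

    Ties are broken uniformly at random; returns ``None`` for an empty memory.
    """
    if not ind.memory:
        return None
    best = max(ind.memory.values())
    tied = [m for m, v in ind.memory.items() if v == best]
    if len(tied) == 1:
        return tied[0]
    return int(tied[rng.integers(len(tied))])
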