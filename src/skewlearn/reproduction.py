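"""Mortality and replacement: reproductive skew, inheritance, mutation.

Individuals die randomly (probability ``death_prob`` per round) or
deterministically on reaching ``max_age``. Every death is replaced in the
same round, keeping the population size constant. Replacement modes:

``fixed_proportion``
    Each dead individual is replaced by a copy of itself (same alpha and
    sex) with an empty memory and history — no selection, no mutation.
``asexual``
    Mature survivors (age >= delta) are ranked by the current fitness proxy;
    the top ceil(beta * n_mature) form the parent pool. Under the minimum-
    income criterion every pool member is equally likely to be drawn; under
    the relative-income criterion the draw probability is proportional to
    the fitness proxy. Offspring inherit the parent's alpha, flipped with
    probability mu.
``sexual``
    Pools are formed within each sex (top beta_f of mature females, top
    beta_m of mature males). Each replacement draws one mother and one
    father (with replacement), assigns the offspring's sex by a fair coin,
    and copies alpha from the same-sex parent (mothers to daughters,
    fathers to sons), flipped with probability mu.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .agents import FitnessParams, fitness_from_history
from .config import SimConfig
from .population import SEX_FEMALE, SEX_MALE, PopulationState

__all__ = [
    "SkewConfig",
    "apply_mortality",
    "eligible_parents",
    "reproduce_asexual",
    "reproduce_sexual",
    "replace_fixed",
    "replace_dead",
]


@dataclass(frozen=True)
class SkewConfig:
    """Reproduction parameters (a view of the relevant SimConfig fields)."""

    beta: float = 1.0
    beta_f: Optional[float] = None
    beta_m: Optional[float] = None
    criterion: str = "minimum_income"
    mode: str = "asexual"
    mutation_rate: float = 0.001
    death_prob: float = 0.01
    max_age: int = 100
    strict_sex_ratio: bool = False

    @classmethod
    def from_sim(cls, cfg: SimConfig) -> "SkewConfig":
        return cls(
            beta=cfg.beta,
            beta_f=cfg.beta_f,
            beta_m=cfg.beta_m,
            criterion=cfg.criterion,
            mode=cfg.mode,
            mutation_rate=cfg.resolved_mutation_rate(),
            death_prob=cfg.death_prob,
            max_age=cfg.max_age,
            strict_sex_ratio=cfg.strict_sex_ratio,
        )


def apply_mortality(pop: PopulationState, cfg, rng: np.random.Generator) -> np.ndarray:
    """Indices of individuals dying this round.

    Each individual dies independently with probability ``death_prob`` and
    deterministically once ``age >= max_age``. ``cfg`` may be a SimConfig or
    a SkewConfig.
    """
    dead = rng.random(pop.n) < cfg.death_prob
    dead |= pop.age >= cfg.max_age
    return np.flatnonzero(dead)


def eligible_parents(
    candidates: np.ndarray,
    fitness: np.ndarray,
    beta: float,
    criterion: str,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Parent pool and sampling weights from mature candidates.

    The pool is the top ``ceil(beta * len(candidates))`` candidates ranked by
    ``fitness`` (indexed by candidate), with ties at the cutoff broken
    uniformly at random. Weights are ``None`` (uniform) for the minimum-
    income criterion, or proportional to the fitness proxy for the
    relative-income criterion (uniform fallback when all pool fitnesses are
    zero).
    """
    k = math.ceil(beta * candidates.size)
    if k < candidates.size:
        # random permutation before a stable sort => uniform tie-breaking
        perm = rng.permutation(candidates.size)
        shuffled = candidates[perm]
        order = shuffled[np.argsort(-fitness[shuffled], kind="stable")]
        pool = order[:k]
    else:
        pool = candidates
    if criterion == "relative_income":
        w = fitness[pool].astype(float)
        total = w.sum()
        if total > 0:
            return pool, w / total
        return pool, None
    return pool, None


def _sample(pool: np.ndarray, weights: Optional[np.ndarray], size: int,
            rng: np.random.Generator) -> np.ndarray:
    if weights is None:
        return pool[rng.integers(0, pool.size, size=size)]
    return rng.choice(pool, size=size, replace=True, p=weights)


def _mutate(alpha: np.ndarray, mu: float, rng: np.random.Generator) -> np.ndarray:
    flips = rng.random(alpha.size) < mu
    out = alpha.copy()
    out[flips] = 1.0 - out[flips]
    return out


def _parent_pool_for(
    pop: PopulationState,
    alive_mask: np.ndarray,
    sex: Optional[int],
    beta: float,
    criterion: str,
    fitness: np.ndarray,
    delta: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Pool of eligible parents among mature survivors (optionally of one sex),
    falling back to all survivors (then everyone) if the pool would be empty."""
    mask = alive_mask.copy()
    if sex is not None:
        mask &= pop.sex == sex
    candidates = np.flatnonzero(mask & (pop.age >= delta))
    if candidates.size == 0:
        fallback = np.flatnonzero(mask)
        if fallback.size == 0:
            fallback = np.flatnonzero(alive_mask)
        warnings.warn(
            "no mature candidate parents available; drawing uniformly from "
            f"{fallback.size} living individuals", RuntimeWarning, stacklevel=2)
        return fallback, None
    return eligible_parents(candidates, fitness, beta, criterion, rng)


def replace_fixed(pop: PopulationState, dead_idx: np.ndarray) -> None:
    """Fixed-proportion replacement: each dead individual is replaced by a
    newborn copy of itself (same alpha and sex, empty memory and history)."""
    alpha = pop.alpha[dead_idx].copy()
    sex = pop.sex[dead_idx].copy()
    pop.reset_slots(dead_idx)
    pop.alpha[dead_idx] = alpha
    pop.sex[dead_idx] = sex


def reproduce_asexual(
    pop: PopulationState,
    dead_idx: np.ndarray,
    skew: SkewConfig,
    fitness: np.ndarray,
    delta: int,
    rng: np.random.Generator,
) -> None:
    """Replace the dead with offspring of parents drawn from the skewed pool."""
    alive = np.ones(pop.n, dtype=bool)
    alive[dead_idx] = False
    pool, w = _parent_pool_for(pop, alive, None, skew.beta, skew.criterion,
                               fitness, delta, rng)
    parents = _sample(pool, w, dead_idx.size, rng)
    alpha = _mutate(pop.alpha[parents], skew.mutation_rate, rng)
    pop.reset_slots(dead_idx)
    pop.alpha[dead_idx] = alpha


def reproduce_sexual(
    pop: PopulationState,
    dead_idx: np.ndarray,
    skew: SkewConfig,
    fitness: np.ndarray,
    delta: int,
    rng: np.random.Generator,
) -> None:
    """Sexual replacement with sex-linked inheritance.

    For each dead individual one mother and one father are drawn (with
    replacement) from the within-sex top-beta pools; the offspring's sex is a
    fair coin (or copies the dead individual's sex under strict_sex_ratio)
    and its alpha comes from the same-sex parent, flipped with probability mu.
    """
    alive = np.ones(pop.n, dtype=bool)
    alive[dead_idx] = False
    beta_f = skew.beta_f if skew.beta_f is not None else skew.beta
    beta_m = skew.beta_m if skew.beta_m is not None else skew.beta
    pool_f, w_f = _parent_pool_for(pop, alive, SEX_FEMALE, beta_f, skew.criterion,
                                   fitness, delta, rng)
    pool_m, w_m = _parent_pool_for(pop, alive, SEX_MALE, beta_m, skew.criterion,
                                   fitness, delta, rng)
    k = dead_idx.size
    mothers = _sample(pool_f, w_f, k, rng)
    fathers = _sample(pool_m, w_m, k, rng)
    if skew.strict_sex_ratio:
        child_sex = pop.sex[dead_idx].copy()
    else:
        child_sex = rng.integers(0, 2, size=k).astype(np.int8)
    alpha = np.where(child_sex == SEX_FEMALE, pop.alpha[mothers], pop.alpha[fathers])
    alpha = _mutate(alpha, skew.mutation_rate, rng)
    pop.reset_slots(dead_idx)
    pop.alpha[dead_idx] = alpha
    pop.sex[dead_idx] = child_sex


def replace_dead(
    pop: PopulationState,
    dead_idx: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> None:
    """Dispatch replacement of ``dead_idx`` according to ``cfg.mode``."""
    if dead_idx.size == 0:
        return
    if cfg.mode == "fixed_proportion":
        replace_fixed(pop, dead_idx)
        return
    skew = SkewConfig.from_sim(cfg)
    params = FitnessParams(window=cfg.delta, discount=cfg.discount_r,
                           mode=cfg.fitness_mode)
    fitness = fitness_from_history(pop.history, params)
    if cfg.mode == "asexual":
        reproduce_asexual(pop, dead_idx, skew, fitness, cfg.delta, rng)
    else:
        reproduce_sexual(pop, dead_idx, skew, fitness, cfg.delta, rng)
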