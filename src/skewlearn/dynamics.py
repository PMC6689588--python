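"""One simulation round: actions, patch choice, scramble competition, learning.

Event order within a round (fixed):

1. every individual draws learner (prob ``learn_prob``) or exploiter;
   an exploiter with an empty memory becomes an individual learner;
2. all exploiters simultaneously commit to their best remembered patch;
3. occupancy n_m is computed once and each exploiter of patch m collects
   pi_m / n_m (scramble competition); exploiters update their memory of the
   patch to the realized per-capita payoff;
4. learners observe: individual learners sample a uniformly random patch,
   social learners sample a uniformly random previous-round exploiter and
   observe that individual's previous patch; either way the stored value is
   the current expected payoff p_hat = pi_m / n_m (pi_m when n_m = 0),
   using this round's payoffs and occupancy;
5. payoff histories shift (learners contribute 0) and ages advance;
6. environmental turnover redraws patch payoffs;
7. mortality and reproduction (see :mod:`skewlearn.reproduction`) keep the
   population size constant.

Social learners with no demonstrators (round 1, or an all-learner round)
fall back to individual learning. The demonstrator pool is all previous-
round exploitation records regardless of success or survival; sampling is
unbiased (no payoff-biased copying) and self-sampling is allowed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .config import SimConfig
from .environment import Environment, apply_turnover
from .population import PopulationState
from ._kernels import update_memory_kernel
from . import reproduction

__all__ = [
    "RoundRecord",
    "draw_actions",
    "resolve_exploitation",
    "individual_learn",
    "social_learn",
    "observe",
    "step_round",
]


@dataclass
class RoundRecord:
    """Per-round summary emitted by :func:`step_round`.

    Strategy-wise statistics cover *exploiting* individuals only and use the
    actors' alpha values before any replacement this round; ``alpha_freq``
    fields describe the population after replacement (end of round).
    """

    n_learners: int
    n_exploit_social: int
    n_exploit_individual: int
    mean_social: float
    mean_individual: float
    var_social: float
    var_individual: float
    total_collected: float
    n_deaths: int
    alpha_freq: float
    alpha_freq_female: float
    alpha_freq_male: float
    fixated: bool
    # per-individual arrays for this round (views for the caller to copy if kept)
    collected: np.ndarray | None = None
    exploited: np.ndarray | None = None  # bool mask: exploited this round
    actor_alpha: np.ndarray | None = None  # alpha of each slot when it acted
    actor_sex: np.ndarray | None = None


def draw_actions(
    pop: PopulationState, learn_prob: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Partition the population into learners and exploiters.

    Returns ``(learner_mask, social_mask)``. Each individual independently
    learns with probability ``learn_prob``; exploiters with empty memories
    are reassigned to learners (they have nothing to exploit). The social/
    individual channel is drawn for everyone (prob alpha_i) to keep the
    random-stream layout independent of who learns; it is consulted only for
    learners.
    """
    learner = rng.random(pop.n) < learn_prob
    social = rng.random(pop.n) < pop.alpha
    learner |= pop.mem_count == 0
    return learner, social


def resolve_exploitation(
    pop: PopulationState, env: Environment, exploiter_idx: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Commit exploiters to their best remembered patches and share payoffs.

    All exploiters commit simultaneously; occupancy is computed once. Returns
    ``(chosen_patches, occupancy, per_capita_payoff)`` where occupancy has
    shape (M,) and the payoff array aligns with ``exploiter_idx``.
    """
    chosen = pop.best_patch[exploiter_idx]
    occupancy = np.bincount(chosen, minlength=env.n_patches)
    share = env.payoffs[chosen] / occupancy[chosen]
    return chosen, occupancy, share


def individual_learn(
    pop: PopulationState, env: Environment, idx: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Each learner in ``idx`` samples a uniformly random patch index."""
    return rng.integers(0, env.n_patches, size=idx.size)


def social_learn(
    pop: PopulationState,
    idx: np.ndarray,
    prev_patches: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Each learner in ``idx`` copies the patch of a random previous-round
    exploitation record (callers must ensure ``prev_patches`` is nonempty)."""
    demo = rng.integers(0, prev_patches.size, size=idx.size)
    return prev_patches[demo]


def observe(
    pop: PopulationState,
    env: Environment,
    occupancy: np.ndarray,
    idx: np.ndarray,
    patches: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Store the expected payoff p_hat of ``patches`` in the learners' memories.

    p_hat = pi_m / n_m with this round's payoff and occupancy; pi_m when the
    patch is unoccupied.
    """
    n_occ = occupancy[patches]
    phat = env.payoffs[patches] / np.maximum(n_occ, 1)
    _update_memory_batch(pop, idx, patches, phat, rng)


def _update_memory_batch(
    pop: PopulationState,
    agents: np.ndarray,
    patches: np.ndarray,
    values: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Write one observation per agent and maintain the best-patch cache.

    Each agent appears at most once per round. A repeat observation of a
    known patch overwrites that patch's slot; a new patch is appended. If
    the new value exceeds the cached best, the cache moves to the new entry
    (an equal-valued observation of a *different* patch is a tie, broken by
    a fair coin); if the agent's current best entry itself was revised
    downward, its memory row is rescanned. With continuous gamma payoffs
    exact cross-patch ties have probability zero, so the rescan uses a
    plain argmax.
    """
    if agents.size == 0:
        return
    coins = rng.random(agents.size)  # consulted only on exact-value ties
    update_memory_kernel(
        pop.mem_keys, pop.mem_vals, pop.mem_count,
        pop.best_patch, pop.best_val,
        np.ascontiguousarray(agents), np.ascontiguousarray(patches),
        np.ascontiguousarray(values, dtype=np.float64), coins,
    )


def _strategy_stats(collected: np.ndarray, mask: np.ndarray) -> Tuple[int, float, float]:
    """(count, mean, unbiased variance) of collected payoffs under ``mask``."""
    k = int(mask.sum())
    if k == 0:
        return 0, float("nan"), float("nan")
    vals = collected[mask]
    mean = float(vals.mean())
    var = float(vals.var(ddof=1)) if k > 1 else float("nan")
    return k, mean, var


def step_round(
    pop: PopulationState,
    env: Environment,
    prev_patches: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> Tuple[RoundRecord, np.ndarray]:
    """Execute one full round in place; returns ``(record, prev_patches)``.

    ``prev_patches`` is the array of patch indices exploited this round, to
    be passed back in as the demonstrator pool of the next round.
    """
    n = pop.n

    # (1) action draw
    learner_mask, social_mask = draw_actions(pop, cfg.learn_prob, rng)
    exploiter_idx = np.flatnonzero(~learner_mask)
    learner_idx = np.flatnonzero(learner_mask)

    # (2)-(3) simultaneous commitment, occupancy, scramble shares
    if exploiter_idx.size:
        chosen, occupancy, share = resolve_exploitation(pop, env, exploiter_idx)
    else:
        chosen = np.empty(0, dtype=np.int64)
        occupancy = np.zeros(env.n_patches, dtype=np.int64)
        share = np.empty(0)
    collected = np.zeros(n)
    collected[exploiter_idx] = share
    _update_memory_batch(pop, exploiter_idx, chosen, share, rng)

    # (4) learning
    if learner_idx.size:
        soc = social_mask[learner_idx]
        if not cfg.social_enabled or prev_patches.size == 0:
            soc = np.zeros(learner_idx.size, dtype=bool)
        soc_idx = learner_idx[soc]
        ind_idx = learner_idx[~soc]
        if ind_idx.size:
            patches_i = individual_learn(pop, env, ind_idx, rng)
            observe(pop, env, occupancy, ind_idx, patches_i, rng)
        if soc_idx.size:
            patches_s = social_learn(pop, soc_idx, prev_patches, rng)
            observe(pop, env, occupancy, soc_idx, patches_s, rng)

    # snapshot actor attributes before replacement
    actor_alpha = pop.alpha.copy()
    actor_sex = pop.sex.copy()
    exploited = ~learner_mask

    n_soc, mean_soc, var_soc = _strategy_stats(collected, exploited & (actor_alpha == 1.0))
    n_ind, mean_ind, var_ind = _strategy_stats(collected, exploited & (actor_alpha == 0.0))

    # (5) histories and ages
    pop.history[:, 1:] = pop.history[:, :-1]
    pop.history[:, 0] = collected
    pop.age += 1

    # (6) turnover
    apply_turnover(env, rng)

    # (7) mortality and reproduction
    dead_idx = reproduction.apply_mortality(pop, cfg, rng)
    reproduction.replace_dead(pop, dead_idx, cfg, rng)

    freq = pop.alpha_frequency()
    if cfg.mode == "sexual":
        freq_f, freq_m = pop.alpha_frequency_by_sex()
    else:
        freq_f = freq_m = float("nan")
    fixated = bool(pop.alpha.min() == pop.alpha.max())

    record = RoundRecord(
        n_learners=int(learner_idx.size),
        n_exploit_social=n_soc,
        n_exploit_individual=n_ind,
        mean_social=mean_soc,
        mean_individual=mean_ind,
        var_social=var_soc,
        var_individual=var_ind,
        total_collected=float(collected.sum()),
        n_deaths=int(dead_idx.size),
        alpha_freq=freq,
        alpha_freq_female=freq_f,
        alpha_freq_male=freq_m,
        fixated=fixated,
        collected=collected,
        exploited=exploited,
        actor_alpha=actor_alpha,
        actor_sex=actor_sex,
    )
    return record, chosen
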