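"""Replicate runs and parameter sweeps.

A single run executes rounds until all individuals share the same alpha
(evolutionary modes only) or ``max_rounds`` is reached. Replicates use
independent child streams spawned from a base seed, so a replicate set is
reproducible and extensible regardless of execution order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .config import ConfigurationError, SimConfig
from .dynamics import step_round
from .environment import create_environment
from .population import init_population

__all__ = ["RunResult", "run_single", "run_replicates", "sweep", "PAPER_BETA_GRID",
           "PAPER_TAU_GRID", "PAPER_VARIANCE_GRID"]

# default sweep axes: the full beta / turnover / payoff-variance grids
PAPER_BETA_GRID: tuple = (0.01, 0.02, 0.04, 0.08, 0.1, 0.2, 0.3, 0.4, 0.5,
                          0.6, 0.7, 0.8, 0.9, 1.0)
PAPER_TAU_GRID: tuple = tuple(10.0 ** e for e in
                              (0.0, -0.5, -1.0, -1.5, -2.0, -2.5, -3.0))
PAPER_VARIANCE_GRID: tuple = (1.0, 100.0)

_PER_ROUND_FIELDS = (
    "alpha_freq", "alpha_freq_female", "alpha_freq_male",
    "mean_social", "mean_individual", "var_social", "var_individual",
    "n_exploit_social", "n_exploit_individual",
    "n_learners", "total_collected", "n_deaths",
)


@dataclass
class RunResult:
    """Per-round and end-of-run summaries of one simulation run.

    Per-round arrays (length ``n_rounds``) hold the population's alpha
    frequency (overall and by sex, end of round) and, for exploiting
    individuals of each pure strategy, the within-round mean and unbiased
    variance of collected payoffs. ``final_*`` arrays snapshot every
    individual's last round (collected payoff, whether it exploited, its
    alpha and sex when acting).
    """

    config: SimConfig
    seed: int
    n_rounds: int
    termination_cause: str  # "fixation" | "max_rounds"
    per_round: pd.DataFrame
    final_collected: np.ndarray
    final_exploited: np.ndarray
    final_alpha: np.ndarray
    final_sex: np.ndarray

    @property
    def final_alpha_freq(self) -> float:
        return float(self.per_round["alpha_freq"].iloc[-1])

    def final_social_fraction(self, window: int = 1) -> float:
        """Mean alpha frequency over the trailing ``window`` rounds."""
        if window < 1:
            raise ValueError(f"window must be >= 1, got {window}")
        return float(self.per_round["alpha_freq"].tail(window).mean())

    def summary_row(self) -> dict:
        """Flat end-of-run summary (one sweep/CSV row)."""
        last = self.per_round.iloc[-1]
        return {
            "seed": self.seed,
            "n_rounds": self.n_rounds,
            "termination_cause": self.termination_cause,
            "final_alpha_freq": float(last["alpha_freq"]),
            "final_alpha_freq_female": float(last["alpha_freq_female"]),
            "final_alpha_freq_male": float(last["alpha_freq_male"]),
            "final_mean_social": float(last["mean_social"]),
            "final_mean_individual": float(last["mean_individual"]),
            "final_var_social": float(last["var_social"]),
            "final_var_individual": float(last["var_individual"]),
            "final_n_exploit_social": int(last["n_exploit_social"]),
            "final_n_exploit_individual": int(last["n_exploit_individual"]),
        }


def run_single(config: SimConfig, seed: int) -> RunResult:
    """Run one fully seeded simulation.

    The run is bit-reproducible given ``(config, seed)``. Fixation (all
    individuals sharing the same alpha) terminates evolutionary runs;
    fixed-proportion runs always execute ``max_rounds`` rounds.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    env = create_environment(config.n_patches, config.mean_payoff,
                             config.payoff_variance, rng, turnover=config.turnover)
    pop = init_population(config, rng)
    prev_patches = np.empty(0, dtype=np.int64)

    check_fixation = config.mode != "fixed_proportion"
    buf = {name: np.empty(config.max_rounds) for name in _PER_ROUND_FIELDS}
    cause = "max_rounds"
    t = 0
    record = None
    for t in range(config.max_rounds):
        record, prev_patches = step_round(pop, env, prev_patches, config, rng)
        buf["alpha_freq"][t] = record.alpha_freq
        buf["alpha_freq_female"][t] = record.alpha_freq_female
        buf["alpha_freq_male"][t] = record.alpha_freq_male
        buf["mean_social"][t] = record.mean_social
        buf["mean_individual"][t] = record.mean_individual
        buf["var_social"][t] = record.var_social
        buf["var_individual"][t] = record.var_individual
        buf["n_exploit_social"][t] = record.n_exploit_social
        buf["n_exploit_individual"][t] = record.n_exploit_individual
        buf["n_learners"][t] = record.n_learners
        buf["total_collected"][t] = record.total_collected
        buf["n_deaths"][t] = record.n_deaths
        if check_fixation and record.fixated:
            cause = "fixation"
            break
    n_rounds = t + 1
    per_round = pd.DataFrame({name: buf[name][:n_rounds] for name in _PER_ROUND_FIELDS})
    per_round.insert(0, "round", np.arange(1, n_rounds + 1))
    return RunResult(
        config=config,
        seed=seed,
        n_rounds=n_rounds,
        termination_cause=cause,
        per_round=per_round,
        final_collected=record.collected.copy(),
        final_exploited=record.exploited.copy(),
        final_alpha=record.actor_alpha.copy(),
        final_sex=record.actor_sex.copy(),
    )


def replicate_seeds(base_seed: int, n_replicates: int) -> List[int]:
    """Independent per-replicate seeds derived from ``base_seed``.

    Uses a spawned SeedSequence per replicate, so extending the replicate
    count never reshuffles existing seeds.
    """
    children = np.random.SeedSequence(base_seed).spawn(n_replicates)
    return [int(c.generate_state(1)[0]) for c in children]


def run_replicates(
    config: SimConfig,
    n_replicates: Optional[int] = None,
    base_seed: Optional[int] = None,
    n_jobs: int = 1,
) -> List[RunResult]:
    """Independent seeded replicates of ``config``.

    Results are returned in replicate order and are identical regardless of
    ``n_jobs`` (seeds are derived up front, not from scheduling).
    """
    if n_replicates is None:
        n_replicates = config.replicates
    if n_replicates < 1:
        raise ConfigurationError(f"n_replicates must be >= 1, got {n_replicates}")
    if base_seed is None:
        base_seed = config.base_seed if config.base_seed is not None else 0
    seeds = replicate_seeds(base_seed, n_replicates)
    if n_jobs == 1:
        return [run_single(config, s) for s in seeds]
    return Parallel(n_jobs=n_jobs)(delayed(run_single)(config, s) for s in seeds)


def sweep(
    template: SimConfig,
    grid: Mapping[str, Sequence],
    n_replicates: Optional[int] = None,
    base_seed: Optional[int] = None,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Run replicates over the cartesian product of ``grid`` values.

    ``grid`` maps SimConfig field names (e.g. ``beta``, ``turnover``,
    ``payoff_variance``, ``beta_f``, ``beta_m``) to value sequences. Returns
    a long-format table with one row per (cell, replicate): the grid values,
    the replicate seed, and the end-of-run summary. Cell i uses base seed
    ``base_seed + i``, so a one-cell sweep reproduces ``run_replicates``
    exactly and adding replicates never reshuffles existing ones.
    """
    if not grid:
        raise ConfigurationError("sweep grid must not be empty")
    keys = list(grid)
    cells = list(itertools.product(*(grid[k] for k in keys)))
    if base_seed is None:
        base_seed = template.base_seed if template.base_seed is not None else 0
    rows = []
    for i, cell_values in enumerate(cells):
        cfg = template.replace(**dict(zip(keys, cell_values)))
        results = run_replicates(cfg, n_replicates=n_replicates,
                                 base_seed=base_seed + i, n_jobs=n_jobs)
        for rep, res in enumerate(results):
            row = dict(zip(keys, cell_values))
            row["replicate"] = rep
            row.update(res.summary_row())
            rows.append(row)
    return pd.DataFrame(rows)
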