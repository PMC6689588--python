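"""Population state as a struct of arrays, sized for fast per-round updates.

Memory is stored compactly: an individual observes at most one patch per
round and lives at most ``max_age`` rounds, so each memory holds at most
``max_age`` entries. ``mem_keys``/``mem_vals`` are (N, max_age + 1) slabs
(key -1 / value -inf marking unused slots), and the best-remembered patch of
every individual is cached (``best_patch`` / ``best_val``) and maintained
incrementally as observations arrive; a row rescan is only needed when an
individual's current best entry is revised downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agents import Individual
from .config import SimConfig

__all__ = ["PopulationState", "init_population", "SEX_NONE", "SEX_FEMALE", "SEX_MALE"]

SEX_NONE = -1
SEX_FEMALE = 0
SEX_MALE = 1

_SEX_NAMES = {SEX_NONE: "none", SEX_FEMALE: "female", SEX_MALE: "male"}


@dataclass
class PopulationState:
    """All individuals of a running simulation.

    Attributes
    ----------
    ident : (N,) int64
        Unique identifier of the occupant of each slot.
    alpha : (N,) float64
        Social-learning propensity of each individual.
    sex : (N,) int8
        ``SEX_NONE`` (asexual/fixed runs), ``SEX_FEMALE`` or ``SEX_MALE``.
    age : (N,) int64
        Rounds lived.
    mem_keys : (N, K) int64
        Patch indices known to each individual (-1 = unused slot).
    mem_vals : (N, K) float64
        Remembered expected payoff per known patch (-inf = unused slot).
    mem_count : (N,) int64
        Number of known patches (for the empty-memory check).
    best_patch : (N,) int64
        Cached best-remembered patch; ``-1`` when memory is empty.
    best_val : (N,) float64
        Cached best remembered value; ``-inf`` when memory is empty.
    history : (N, delta) float64
        Rolling payoff history, column 0 = most recent round; zero-filled.
    """

    ident: np.ndarray
    alpha: np.ndarray
    sex: np.ndarray
    age: np.ndarray
    mem_keys: np.ndarray
    mem_vals: np.ndarray
    mem_count: np.ndarray
    best_patch: np.ndarray
    best_val: np.ndarray
    history: np.ndarray
    next_ident: int = 0

    @property
    def n(self) -> int:
        return self.alpha.shape[0]

    def reset_slots(self, idx: np.ndarray) -> None:
        """Reinitialize slots ``idx`` as newborns: age 0, empty memory, empty
        history, fresh identifiers. alpha and sex are set by the caller."""
        if idx.size == 0:
            return
        self.age[idx] = 0
        self.mem_keys[idx, :] = -1
        self.mem_vals[idx, :] = -np.inf
        self.mem_count[idx] = 0
        self.best_patch[idx] = -1
        self.best_val[idx] = -np.inf
        self.history[idx, :] = 0.0
        self.ident[idx] = self.next_ident + np.arange(idx.size)
        self.next_ident += idx.size

    def alpha_frequency(self) -> float:
        """Population mean of alpha (the social-learning frequency for binary
        strategies)."""
        return float(self.alpha.mean())

    def alpha_frequency_by_sex(self) -> tuple[float, float]:
        """(female, male) mean alpha; nan for an absent sex."""
        out = []
        for s in (SEX_FEMALE, SEX_MALE):
            mask = self.sex == s
            out.append(float(self.alpha[mask].mean()) if mask.any() else float("nan"))
        return out[0], out[1]

    def memory_of(self, i: int) -> dict:
        """Memory of slot ``i`` as a patch -> expected-payoff mapping."""
        used = self.mem_keys[i] >= 0
        return {int(p): float(v) for p, v in
                zip(self.mem_keys[i, used], self.mem_vals[i, used])}

    def individual(self, i: int) -> Individual:
        """Snapshot of slot ``i`` as a per-record :class:`~skewlearn.agents.Individual`."""
        return Individual(
            ident=int(self.ident[i]),
            alpha=float(self.alpha[i]),
            sex=_SEX_NAMES[int(self.sex[i])],
            age=int(self.age[i]),
            memory=self.memory_of(i),
            payoff_history=tuple(float(v) for v in self.history[i]),
        )


def init_population(cfg: SimConfig, rng: np.random.Generator) -> PopulationState:
    """Build the starting population for ``cfg``.

    Initial individuals have empty memories and histories. Ages are drawn
    uniformly on {0, ..., max_age - 1} so that mature individuals exist from
    the first rounds. Strategy composition: fixed-proportion and asexual runs
    start with an exact split (round(N * initial_social_fraction) social
    learners, shuffled); sexual runs draw each individual's alpha as an
    independent fair Bernoulli(initial_social_fraction) and split the sexes
    exactly 50/50 (shuffled).
    """
    n = cfg.n_individuals
    # at most one observation per round lived, and a life is bounded by both
    # the maximum age and the run length
    k = min(cfg.max_age, cfg.max_rounds) + 1

    if cfg.mode == "sexual":
        alpha = (rng.random(n) < cfg.initial_social_fraction).astype(float)
        sex = np.full(n, SEX_MALE, dtype=np.int8)
        sex[: n // 2] = SEX_FEMALE
        rng.shuffle(sex)
    else:
        n_social = int(round(n * cfg.initial_social_fraction))
        alpha = np.zeros(n)
        alpha[:n_social] = 1.0
        rng.shuffle(alpha)
        sex = np.full(n, SEX_NONE, dtype=np.int8)

    pop = PopulationState(
        ident=np.arange(n, dtype=np.int64),
        alpha=alpha,
        sex=sex,
        age=rng.integers(0, cfg.max_age, size=n).astype(np.int64),
        mem_keys=np.full((n, k), -1, dtype=np.int64),
        mem_vals=np.full((n, k), -np.inf),
        mem_count=np.zeros(n, dtype=np.int64),
        best_patch=np.full(n, -1, dtype=np.int64),
        best_val=np.full(n, -np.inf),
        history=np.zeros((n, cfg.delta)),
        next_ident=n,
    )
    return pop
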