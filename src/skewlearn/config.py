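"""Simulation configuration: defaults, validation, YAML round-tripping.

All model parameters live on a single flat :class:`SimConfig`. Defaults are
the baseline parameterization of the model: N = 1000 foragers, M = 1000
patches, mean patch payoff 4, learning probability 0.2, fitness window
delta = 5 with discount r = 0.2, random death probability 0.01 per round,
maximum age 100 rounds, mutation rate 1/N, and runs capped at 5000 rounds.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

__all__ = [
    "ConfigurationError",
    "SimConfig",
    "load_config",
    "VALID_MODES",
    "VALID_CRITERIA",
    "VALID_FITNESS_MODES",
]

VALID_MODES = ("fixed_proportion", "asexual", "sexual")
VALID_CRITERIA = ("minimum_income", "relative_income")
VALID_FITNESS_MODES = ("windowed", "single_round")

SCHEMA_VERSION = 1


class ConfigurationError(ValueError):
    """Raised when a configuration value violates the model's constraints."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass
class SimConfig:
    """Complete parameter set for one simulation run (or replicate set).

    Parameters
    ----------
    n_individuals
        Population size N, constant throughout a run.
    n_patches
        Number of resource patches M.
    mean_payoff
        Mean of the gamma distribution generating patch payoffs (resource
        units per round).
    payoff_variance
        Variance of the payoff distribution: 1 is an "even" world, 100 an
        "uneven" world.
    turnover
        Per-patch, per-round probability tau that a patch payoff is redrawn.
    learn_prob
        Probability that an individual spends a round learning rather than
        exploiting.
    delta
        Fitness window: number of most recent rounds entering the fitness
        proxy; also the age of reproductive maturity.
    discount_r
        Temporal discount rate r in the fitness proxy weights e^{-r j}.
    fitness_mode
        "windowed" (discounted sum over the last delta rounds) or
        "single_round" (current round's payoff only).
    mode
        "fixed_proportion" (dead replaced by copies of themselves, no
        selection), "asexual", or "sexual".
    criterion
        "minimum_income" (everyone in the top-beta pool reproduces with
        equal probability) or "relative_income" (probability proportional
        to the fitness proxy within the pool).
    beta
        Proportion of mature individuals eligible to reproduce (asexual
        runs). Small beta = high reproductive skew.
    beta_f, beta_m
        Per-sex eligible proportions for sexual runs.
    mutation_rate
        Per-offspring probability of flipping alpha, or the string "1/N".
    death_prob
        Per-round random death probability.
    max_age
        Deterministic death age (rounds).
    max_rounds
        Hard cap on the number of rounds per run.
    replicates
        Default replicate count for :func:`skewlearn.experiments.run_replicates`.
    base_seed
        Default base seed for replicate streams.
    initial_social_fraction
        Starting frequency of social learners (alpha = 1). Exact split in
        fixed/asexual runs; independent fair per-individual draws in sexual
        runs.
    strict_sex_ratio
        If true, dead individuals are replaced by same-sex offspring
        (sex counts frozen); default false (offspring sex is a fair coin).
    social_enabled
        Internal switch: when false every learning turn is individual
        regardless of alpha, with an identical random-stream layout. Used
        for the no-social-channel equivalence check.
    """

    n_individuals: int = 1000
    n_patches: int = 1000
    mean_payoff: float = 4.0
    payoff_variance: float = 100.0
    turnover: float = 10 ** -1.5
    learn_prob: float = 0.2
    delta: int = 5
    discount_r: float = 0.2
    fitness_mode: str = "windowed"
    mode: str = "fixed_proportion"
    criterion: str = "minimum_income"
    beta: float = 1.0
    beta_f: Optional[float] = None
    beta_m: Optional[float] = None
    mutation_rate: Any = "1/N"
    death_prob: float = 0.01
    max_age: int = 100
    max_rounds: int = 5000
    replicates: int = 200
    base_seed: Optional[int] = None
    initial_social_fraction: float = 0.5
    strict_sex_ratio: bool = False
    social_enabled: bool = True
    schema_version: int = SCHEMA_VERSION
    provenance: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        _check(int(self.n_individuals) == self.n_individuals and self.n_individuals >= 1,
               f"n_individuals must be a positive integer, got {self.n_individuals}")
        _check(int(self.n_patches) == self.n_patches and self.n_patches >= 1,
               f"n_patches must be a positive integer, got {self.n_patches}")
        self.n_individuals = int(self.n_individuals)
        self.n_patches = int(self.n_patches)
        _check(self.mean_payoff > 0, f"mean_payoff must be > 0, got {self.mean_payoff}")
        _check(self.payoff_variance > 0,
               f"payoff_variance must be > 0, got {self.payoff_variance}")
        for name in ("turnover", "learn_prob", "death_prob"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must be a probability in [0, 1], got {v}")
        _check(self.delta >= 1, f"delta must be >= 1, got {self.delta}")
        _check(self.discount_r >= 0, f"discount_r must be >= 0, got {self.discount_r}")
        _check(self.fitness_mode in VALID_FITNESS_MODES,
               f"fitness_mode must be one of {VALID_FITNESS_MODES}, got {self.fitness_mode!r}")
        _check(self.mode in VALID_MODES,
               f"mode must be one of {VALID_MODES}, got {self.mode!r}")
        _check(self.criterion in VALID_CRITERIA,
               f"criterion must be one of {VALID_CRITERIA}, got {self.criterion!r}")
        _check(0.0 < self.beta <= 1.0, f"beta must be in (0, 1], got {self.beta}")
        for name in ("beta_f", "beta_m"):
            v = getattr(self, name)
            if v is not None:
                _check(0.0 < v <= 1.0, f"{name} must be in (0, 1], got {v}")
        if self.mode == "sexual" and (self.beta_f is None or self.beta_m is None):
            # fall back to the shared beta for both sexes
            if self.beta_f is None:
                self.beta_f = self.beta
            if self.beta_m is None:
                self.beta_m = self.beta
        mu = self.resolved_mutation_rate()
        _check(0.0 <= mu <= 1.0, f"mutation_rate must resolve to [0, 1], got {mu}")
        _check(self.max_age >= 1, f"max_age must be >= 1, got {self.max_age}")
        _check(self.max_rounds >= 1, f"max_rounds must be >= 1, got {self.max_rounds}")
        _check(self.replicates >= 1, f"replicates must be >= 1, got {self.replicates}")
        _check(0.0 <= self.initial_social_fraction <= 1.0,
               f"initial_social_fraction must be in [0, 1], got {self.initial_social_fraction}")

    def resolved_mutation_rate(self) -> float:
        """Numeric mutation rate; the string ``"1/N"`` resolves to 1/n_individuals."""
        mu = self.mutation_rate
        if isinstance(mu, str):
            s = mu.replace(" ", "")
            if s in ("1/N", "1/n"):
                return 1.0 / self.n_individuals
            raise ConfigurationError(
                f"mutation_rate string must be '1/N', got {mu!r}")
        mu = float(mu)
        if not math.isfinite(mu):
            raise ConfigurationError(f"mutation_rate must be finite, got {mu}")
        return mu

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("provenance", None)
        return d

    @classmethod
    def from_dict(cls, data: dict, provenance: Optional[dict] = None) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)} - {"provenance"}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown configuration keys: {sorted(unknown)}; valid keys are {sorted(known)}")
        return cls(**data, provenance=provenance or {})

    def replace(self, **changes: Any) -> "SimConfig":
        """Return a copy with ``changes`` applied (re-validated)."""
        d = self.to_dict()
        d.update(changes)
        prov = dict(self.provenance)
        prov.update({k: "flag" for k in changes})
        return SimConfig.from_dict(d, provenance=prov)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML file, applying overrides on top.

    An empty (or absent) file yields the full default configuration. Unknown
    keys are rejected with a :class:`ConfigurationError` naming the key.
    Provenance of each key (``default`` / ``file`` / ``flag``) is recorded on
    the returned config.
    """
    data: dict = {}
    provenance: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(
                f"configuration file {path!r} must contain a mapping, got {type(loaded).__name__}")
        data.update(loaded)
        provenance.update({k: "file" for k in loaded})
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
        provenance.update({k: "flag" for k, v in overrides.items() if v is not None})
    cfg = SimConfig.from_dict(data, provenance=provenance)
    for f in dataclasses.fields(SimConfig):
        if f.name not in cfg.provenance and f.name != "provenance":
            cfg.provenance[f.name] = "default"
    return cfg
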