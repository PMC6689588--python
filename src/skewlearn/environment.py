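"""Patchy resource environment: gamma payoffs, replenishment, turnover.

The world consists of M patches. Patch m holds a payoff pi_m, drawn i.i.d.
from a gamma distribution with a given mean and variance (moment matching:
shape = mean^2 / variance, scale = variance / mean). Payoffs replenish every
round — exploitation never depletes a patch — and each patch is independently
redrawn from the same stationary distribution with probability tau per round
(environmental turnover).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError

__all__ = ["Environment", "create_environment", "apply_turnover"]


@dataclass
class Environment:
    """The M patches, their current payoffs, and the turnover process.

    Attributes
    ----------
    payoffs
        Current payoff pi_m of each patch, shape (M,), all >= 0.
    mean_payoff, payoff_variance
        Moments of the stationary generating gamma distribution.
    turnover
        Per-patch per-round redraw probability tau in [0, 1].
    """

    payoffs: np.ndarray
    mean_payoff: float
    payoff_variance: float
    turnover: float

    @property
    def n_patches(self) -> int:
        return self.payoffs.shape[0]

    @property
    def gamma_shape(self) -> float:
        return self.mean_payoff ** 2 / self.payoff_variance

    @property
    def gamma_scale(self) -> float:
        return self.payoff_variance / self.mean_payoff

    def draw_payoffs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Fresh i.i.d. draws from the stationary payoff distribution."""
        return rng.gamma(self.gamma_shape, self.gamma_scale, size=size)


def create_environment(
    n_patches: int,
    mean_payoff: float,
    payoff_variance: float,
    rng: np.random.Generator,
    turnover: float = 0.0,
) -> Environment:
    """Create an environment with i.i.d. gamma payoffs.

    The generating distribution is parameterized by moment matching so that
    its mean equals ``mean_payoff`` and its variance ``payoff_variance``.
    """
    if n_patches < 1:
        raise ConfigurationError(f"n_patches must be >= 1, got {n_patches}")
    if mean_payoff <= 0:
        raise ConfigurationError(f"mean_payoff must be > 0, got {mean_payoff}")
    if payoff_variance <= 0:
        raise ConfigurationError(f"payoff_variance must be > 0, got {payoff_variance}")
    if not 0.0 <= turnover <= 1.0:
        raise ConfigurationError(f"turnover must be in [0, 1], got {turnover}")
    env = Environment(
        payoffs=np.empty(n_patches),
        mean_payoff=float(mean_payoff),
        payoff_variance=float(payoff_variance),
        turnover=float(turnover),
    )
    env.payoffs[:] = env.draw_payoffs(n_patches, rng)
    return env


def apply_turnover(env: Environment, rng: np.random.Generator) -> int:
    """Redraw each patch payoff with probability tau; returns the change count.

    A turnover event is a redraw from the stationary gamma distribution; it
    counts as a change even if the drawn value happens to equal the old one.
    Modifies ``env`` in place.
    """
    changed = rng.random(env.n_patches) < env.turnover
    k = int(changed.sum())
    if k:
        env.payoffs[changed] = env.draw_payoffs(k, rng)
    return k
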