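"""Named configurations for the standard experiments.

``fixed_5050`` cells reproduce the risk-sensitivity comparison (fixed 50/50
strategy composition, no selection); ``neutral_*`` presets are the beta = 1
no-selection limits of the evolutionary modes; ``full_asexual_grid`` is the
full published sweep (200 replicates per cell — a long-running preset, not
part of any test). ``desk`` variants reduce replicate counts for quick runs.
"""

from __future__ import annotations

from typing import Dict

from .config import SimConfig
from .experiments import PAPER_BETA_GRID, PAPER_TAU_GRID, PAPER_VARIANCE_GRID

__all__ = ["fixed_5050", "neutral_asexual", "neutral_sexual", "sexual_run",
           "full_asexual_grid", "sexual_grid", "get_preset", "PRESETS"]

SLOW_TURNOVER = 1e-2
FAST_TURNOVER = 1e-1
INTERMEDIATE_TURNOVER = 10 ** -1.5


def fixed_5050(payoff_variance: float, turnover: float, replicates: int = 200) -> SimConfig:
    """Fixed-proportion run: 500 social + 500 individual learners."""
    return SimConfig(
        mode="fixed_proportion",
        payoff_variance=payoff_variance,
        turnover=turnover,
        replicates=replicates,
    )


def neutral_asexual(replicates: int = 200) -> SimConfig:
    """Asexual evolution at beta = 1 (no selection, symmetric mutation)."""
    return SimConfig(
        mode="asexual",
        beta=1.0,
        payoff_variance=100.0,
        turnover=INTERMEDIATE_TURNOVER,
        replicates=replicates,
    )


def sexual_run(beta_f: float, beta_m: float, replicates: int = 200) -> SimConfig:
    """Sexual evolution in the uneven, intermediate-turnover environment."""
    return SimConfig(
        mode="sexual",
        beta_f=beta_f,
        beta_m=beta_m,
        payoff_variance=100.0,
        turnover=INTERMEDIATE_TURNOVER,
        replicates=replicates,
    )


def neutral_sexual(beta_m: float = 0.01, replicates: int = 200) -> SimConfig:
    """Sexual evolution with no selection on females (beta_f = 1)."""
    return sexual_run(beta_f=1.0, beta_m=beta_m, replicates=replicates)


def full_asexual_grid() -> Dict[str, tuple]:
    """The full published asexual sweep grid (14 beta x 7 tau x 2 variance)."""
    return {
        "beta": PAPER_BETA_GRID,
        "turnover": PAPER_TAU_GRID,
        "payoff_variance": PAPER_VARIANCE_GRID,
    }


def sexual_grid() -> Dict[str, tuple]:
    """Default (beta_f, beta_m) sweep grid: the asexual beta list on both axes."""
    return {"beta_f": PAPER_BETA_GRID, "beta_m": PAPER_BETA_GRID}


PRESETS = {
    "fixed-even-slow": lambda: fixed_5050(1.0, SLOW_TURNOVER),
    "fixed-even-fast": lambda: fixed_5050(1.0, FAST_TURNOVER),
    "fixed-uneven-slow": lambda: fixed_5050(100.0, SLOW_TURNOVER),
    "fixed-uneven-fast": lambda: fixed_5050(100.0, FAST_TURNOVER),
    "neutral-asexual": neutral_asexual,
    "neutral-sexual": neutral_sexual,
    "fixed-even-slow-desk": lambda: fixed_5050(1.0, SLOW_TURNOVER, replicates=30),
    "fixed-even-fast-desk": lambda: fixed_5050(1.0, FAST_TURNOVER, replicates=30),
    "fixed-uneven-slow-desk": lambda: fixed_5050(100.0, SLOW_TURNOVER, replicates=30),
    "fixed-uneven-fast-desk": lambda: fixed_5050(100.0, FAST_TURNOVER, replicates=30),
    "neutral-asexual-desk": lambda: neutral_asexual(replicates=30),
    "neutral-sexual-desk": lambda: neutral_sexual(replicates=30),
}


def get_preset(name: str) -> SimConfig:
    """Look up a named preset configuration."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
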