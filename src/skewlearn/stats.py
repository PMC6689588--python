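"""Summary statistics over replicate sets.

The central quantity is the variance ratio of foraging returns between the
two pure strategies (social, alpha = 1; individual, alpha = 0) among
exploiting individuals in a designated round (by default the last). A ratio
below 1 means social learners' returns are less variable — social learning
is the risk-averse strategy.

Two readings of "variance of collected resources" are implemented:

``within_round`` (default)
    Across-individual variance of collected payoffs within the designated
    round, averaged over replicates (ratio of the averages). This is the
    reading that reproduces the published ratios; its replicate-to-replicate
    dispersion is small because each replicate contributes a variance over
    hundreds of individuals.
``across_replicates``
    Variance across replicates of the within-replicate strategy mean. This
    estimator's sampling error is large at any practical replicate count (a
    ratio of two variances estimated from tens of replicate-level numbers),
    so it is exposed for comparison rather than used as the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .experiments import RunResult

__all__ = [
    "VarianceRatioResult",
    "strategy_means",
    "variance_ratio",
    "bootstrap_ci",
    "social_learning_proportion",
    "SocialLearningProportion",
    "yield_distribution",
    "YieldDistribution",
]


@dataclass
class VarianceRatioResult:
    """Variance ratio var(social) / var(individual) with bootstrap CIs."""

    ratio: float
    var_social: float
    var_individual: float
    sd_social: float
    sd_individual: float
    ci_low: float
    ci_high: float
    n_replicates: int
    reading: str
    per_replicate: pd.DataFrame


def strategy_means(results: Sequence[RunResult], round_index: int = -1) -> pd.DataFrame:
    """Per-replicate strategy-wise mean (and within-round variance) of payoffs
    collected by exploiting individuals in the designated round.

    ``round_index`` indexes each replicate's per-round table (negative values
    count from the end, so -1 is each run's final round).
    """
    rows = []
    for k, res in enumerate(results):
        r = res.per_round.iloc[round_index]
        rows.append({
            "replicate": k,
            "mean_social": float(r["mean_social"]),
            "mean_individual": float(r["mean_individual"]),
            "var_social": float(r["var_social"]),
            "var_individual": float(r["var_individual"]),
            "n_social": int(r["n_exploit_social"]),
            "n_individual": int(r["n_exploit_individual"]),
        })
    return pd.DataFrame(rows)


def bootstrap_ci(
    social: np.ndarray,
    individual: np.ndarray,
    statistic,
    n_boot: int = 10_000,
    level: float = 0.95,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float]:
    """Percentile bootstrap CI for a paired replicate-level statistic.

    Resamples replicates (keeping each replicate's social/individual pair
    together, since both strategies share the replicate's environment).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = social.size
    idx = rng.integers(0, n, size=(n_boot, n))
    vals = np.array([statistic(social[i], individual[i]) for i in idx])
    lo, hi = np.nanpercentile(vals, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


def variance_ratio(
    results: Sequence[RunResult],
    round_index: int = -1,
    reading: str = "within_round",
    n_boot: int = 10_000,
    ci_level: float = 0.95,
    rng: Optional[np.random.Generator] = None,
) -> VarianceRatioResult:
    """Variance ratio var(social) / var(individual) of collected resources.

    Replicates in which a strategy has no exploiting individuals in the
    designated round are excluded with a warning. Requires at least two
    usable replicates.
    """
    if reading not in ("across_replicates", "within_round"):
        raise ValueError(f"unknown reading {reading!r}")
    df = strategy_means(results, round_index)
    ok = np.isfinite(df["mean_social"]) & np.isfinite(df["mean_individual"])
    if reading == "within_round":
        ok &= np.isfinite(df["var_social"]) & np.isfinite(df["var_individual"])
    if (~ok).any():
        warnings.warn(
            f"excluding {int((~ok).sum())} replicate(s) with a strategy absent "
            "in the designated round", RuntimeWarning, stacklevel=2)
    df = df[ok].reset_index(drop=True)
    if len(df) < 2:
        raise ValueError("variance_ratio needs >= 2 usable replicates")

    if reading == "across_replicates":
        soc = df["mean_social"].to_numpy()
        ind = df["mean_individual"].to_numpy()
        stat = lambda s, i: np.var(s, ddof=1) / np.var(i, ddof=1)
    else:
        soc = df["var_social"].to_numpy()
        ind = df["var_individual"].to_numpy()
        stat = lambda s, i: np.mean(s) / np.mean(i)

    var_s = float(np.var(df["mean_social"], ddof=1))
    var_i = float(np.var(df["mean_individual"], ddof=1))
    if reading == "within_round":
        num, den = float(np.mean(soc)), float(np.mean(ind))
    else:
        num, den = var_s, var_i
    with np.errstate(divide="ignore", invalid="ignore"):
        lo, hi = bootstrap_ci(soc, ind, stat, n_boot=n_boot, level=ci_level, rng=rng)
    return VarianceRatioResult(
        ratio=num / den,
        var_social=var_s,
        var_individual=var_i,
        sd_social=var_s ** 0.5,
        sd_individual=var_i ** 0.5,
        ci_low=lo,
        ci_high=hi,
        n_replicates=len(df),
        reading=reading,
        per_replicate=df,
    )


@dataclass
class SocialLearningProportion:
    """Trailing-window mean social-learning frequency, overall and by sex."""

    overall: float
    female: float
    male: float
    window: int


def social_learning_proportion(result: RunResult, window: int = 1) -> SocialLearningProportion:
    """Mean alpha frequency over the trailing ``window`` rounds of a run.

    At fixation the frequency is constant, so any window returns the fixed
    value (0 or 1).
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    tail = result.per_round.tail(window)
    return SocialLearningProportion(
        overall=float(tail["alpha_freq"].mean()),
        female=float(tail["alpha_freq_female"].mean()),
        male=float(tail["alpha_freq_male"].mean()),
        window=window,
    )


@dataclass
class YieldDistribution:
    """Pooled final-round collected payoffs by strategy, with histograms."""

    social: np.ndarray
    individual: np.ndarray
    mean_social: float
    mean_individual: float
    bin_edges: np.ndarray
    hist_social: np.ndarray
    hist_individual: np.ndarray
    env_density: np.ndarray  # stationary payoff pdf evaluated at bin centers
    empty: bool


def yield_distribution(
    results: Sequence[RunResult],
    max_value: float = 25.0,
    n_bins: int = 100,
) -> YieldDistribution:
    """Distribution of per-individual collected payoffs by strategy.

    Pools every replicate's final-round exploiting individuals; values are
    truncated at ``max_value`` for the histograms (means use all values).
    The environment's stationary gamma payoff density is evaluated at the
    bin centers for overlay. If no individual exploited, the result is
    flagged ``empty``.
    """
    soc, ind = [], []
    for res in results:
        e = res.final_exploited
        soc.append(res.final_collected[e & (res.final_alpha == 1.0)])
        ind.append(res.final_collected[e & (res.final_alpha == 0.0)])
    soc = np.concatenate(soc) if soc else np.empty(0)
    ind = np.concatenate(ind) if ind else np.empty(0)
    empty = soc.size == 0 and ind.size == 0
    edges = np.linspace(0.0, max_value, n_bins + 1)
    hist_s = np.histogram(soc[soc <= max_value], bins=edges, density=True)[0] \
        if soc.size else np.zeros(n_bins)
    hist_i = np.histogram(ind[ind <= max_value], bins=edges, density=True)[0] \
        if ind.size else np.zeros(n_bins)
    cfg = results[0].config
    shape = cfg.mean_payoff ** 2 / cfg.payoff_variance
    scale = cfg.payoff_variance / cfg.mean_payoff
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = sps.gamma.pdf(centers, a=shape, scale=scale)
    return YieldDistribution(
        social=soc,
        individual=ind,
        mean_social=float(soc.mean()) if soc.size else float("nan"),
        mean_individual=float(ind.mean()) if ind.size else float("nan"),
        bin_edges=edges,
        hist_social=hist_s,
        hist_individual=hist_i,
        env_density=density,
        empty=empty,
    )
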