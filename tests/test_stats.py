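"""Summary statistics: variance ratios, evolved proportions, yield identity."""

import numpy as np
import pandas as pd
import pytest
from conftest import small_cfg

from skewlearn import run_replicates, social_learning_proportion, variance_ratio
from skewlearn.experiments import RunResult
from skewlearn.stats import strategy_means, yield_distribution


def _fake_result(mean_soc, mean_ind, var_soc=1.0, var_ind=1.0, freq=0.5,
                 freq_f=np.nan, freq_m=np.nan, n_rounds=3):
    per_round = pd.DataFrame({
        "round": np.arange(1, n_rounds + 1),
        "alpha_freq": np.full(n_rounds, freq),
        "alpha_freq_female": np.full(n_rounds, freq_f),
        "alpha_freq_male": np.full(n_rounds, freq_m),
        "mean_social": np.full(n_rounds, mean_soc),
        "mean_individual": np.full(n_rounds, mean_ind),
        "var_social": np.full(n_rounds, var_soc),
        "var_individual": np.full(n_rounds, var_ind),
        "n_exploit_social": np.full(n_rounds, 10),
        "n_exploit_individual": np.full(n_rounds, 10),
        "n_learners": np.full(n_rounds, 5),
        "total_collected": np.full(n_rounds, 40.0),
        "n_deaths": np.zeros(n_rounds),
    })
    return RunResult(
        config=small_cfg(), seed=0, n_rounds=n_rounds,
        termination_cause="max_rounds", per_round=per_round,
        final_collected=np.zeros(4), final_exploited=np.zeros(4, dtype=bool),
        final_alpha=np.zeros(4), final_sex=np.full(4, -1),
    )


def test_identical_strategy_statistics_give_unit_ratio():
    # both strategies identical in every replicate => ratio 1 in both readings
    means = [1.0, 2.0, 3.0, 4.0]
    results = [_fake_result(m, m, var_soc=m, var_ind=m) for m in means]
    for reading in ("within_round", "across_replicates"):
        out = variance_ratio(results, reading=reading, n_boot=200)
        assert out.ratio == pytest.approx(1.0)
    assert out.var_social == pytest.approx(out.var_individual)
    assert out.n_replicates == 4


def test_variance_ratio_across_replicates_matches_hand_computation():
    soc = [2.0, 2.5, 3.0, 2.2]
    ind = [1.0, 4.0, 2.0, 6.0]
    results = [_fake_result(s, i) for s, i in zip(soc, ind)]
    out = variance_ratio(results, reading="across_replicates", n_boot=500)
    expected = np.var(soc, ddof=1) / np.var(ind, ddof=1)
    assert out.ratio == pytest.approx(expected)
    assert out.ci_low <= out.ratio <= out.ci_high


def test_within_round_reading_averages_individual_level_variances():
    results = [_fake_result(2.0, 2.0, var_soc=v, var_ind=2 * v)
               for v in (1.0, 2.0, 3.0)]
    out = variance_ratio(results, reading="within_round", n_boot=200)
    assert out.ratio == pytest.approx(0.5)


def test_replicates_missing_a_strategy_are_excluded_with_warning():
    results = [_fake_result(2.0, 1.0), _fake_result(2.5, 1.5),
               _fake_result(3.0, 2.0), _fake_result(np.nan, 1.0)]
    with pytest.warns(RuntimeWarning, match="excluding 1 replicate"):
        out = variance_ratio(results, n_boot=100)
    assert out.n_replicates == 3


def test_social_learning_proportion_at_fixation_and_windowed():
    assert social_learning_proportion(_fake_result(1, 1, freq=1.0)).overall == 1.0
    assert social_learning_proportion(_fake_result(1, 1, freq=0.0)).overall == 0.0
    res = _fake_result(1, 1)
    res.per_round.loc[:, "alpha_freq"] = [0.2, 0.4, 0.6]
    assert social_learning_proportion(res, window=2).overall == pytest.approx(0.5)
    assert social_learning_proportion(res, window=3).overall == pytest.approx(0.4)


def test_yield_distribution_weighted_means_equal_overall_mean():
    """Strategy means weighted by exploiter counts recover the pooled mean."""
    cfg = small_cfg(mode="fixed_proportion", max_rounds=30)
    results = run_replicates(cfg, n_replicates=3, base_seed=2)
    dist = yield_distribution(results)
    assert not dist.empty
    n_s, n_i = dist.social.size, dist.individual.size
    pooled = np.concatenate([dist.social, dist.individual])
    weighted = (dist.mean_social * n_s + dist.mean_individual * n_i) / (n_s + n_i)
    assert weighted == pytest.approx(pooled.mean())
    # cross-check against the per-round records of the final round
    sm = strategy_means(results)
    total_records = sm["n_social"].sum() + sm["n_individual"].sum()
    assert n_s + n_i == total_records


def test_yield_distribution_histograms_truncate_at_maximum():
    cfg = small_cfg(mode="fixed_proportion", max_rounds=20, payoff_variance=100.0)
    results = run_replicates(cfg, n_replicates=2, base_seed=3)
    dist = yield_distribution(results, max_value=25.0)
    assert dist.bin_edges[0] == 0.0 and dist.bin_edges[-1] == 25.0
    assert dist.env_density.shape == dist.hist_social.shape
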