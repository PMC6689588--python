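"""Round execution: scramble sharing, learning channels, conservation."""

import numpy as np
import pytest
from conftest import small_cfg

from skewlearn import init_population, run_single, step_round
from skewlearn.dynamics import observe, social_learn
from skewlearn.environment import create_environment


def _fresh(cfg, seed=7):
    rng = np.random.default_rng(seed)
    env = create_environment(cfg.n_patches, cfg.mean_payoff, cfg.payoff_variance,
                             rng, turnover=cfg.turnover)
    pop = init_population(cfg, rng)
    return pop, env, rng


def test_equal_sharing_on_a_single_patch():
    """Two foragers on one patch each collect pi/2; the round total is pi."""
    cfg = small_cfg(n_individuals=2, n_patches=1, learn_prob=0.0, turnover=0.0,
                    death_prob=0.0, payoff_variance=1.0)
    pop, env, rng = _fresh(cfg)
    pi = float(env.payoffs[0])
    prev = np.empty(0, dtype=np.int64)
    # round 1: empty memories force individual learning of the only patch
    rec, prev = step_round(pop, env, prev, cfg, rng)
    assert rec.n_learners == 2 and rec.total_collected == 0.0
    # unoccupied patch is remembered at full value pi
    assert pop.memory_of(0) == {0: pytest.approx(pi)}
    # round 2: both exploit patch 0 and share equally
    rec, prev = step_round(pop, env, prev, cfg, rng)
    assert rec.collected[0] == pytest.approx(pi / 2)
    assert rec.collected[1] == pytest.approx(pi / 2)
    assert rec.total_collected == pytest.approx(pi)
    # realized per-capita payoff overwrites the remembered value
    assert pop.memory_of(0) == {0: pytest.approx(pi / 2)}


def test_payoff_conservation_and_occupancy_every_round():
    """Sum of collected payoffs equals the payoff of occupied patches exactly."""
    cfg = small_cfg(n_individuals=100, n_patches=30, turnover=0.1)
    pop, env, rng = _fresh(cfg)
    prev = np.empty(0, dtype=np.int64)
    for _ in range(100):
        payoffs_before = env.payoffs.copy()
        rec, chosen = step_round(pop, env, prev, cfg, rng)
        occupied = np.unique(chosen)
        assert rec.total_collected == pytest.approx(
            payoffs_before[occupied].sum(), abs=1e-9)
        assert chosen.size == cfg.n_individuals - rec.n_learners
        prev = chosen


def test_exploitation_never_depletes_patches():
    """Payoffs replenish each round; only turnover changes them."""
    cfg = small_cfg(n_individuals=50, n_patches=20, turnover=0.0)
    pop, env, rng = _fresh(cfg)
    before = env.payoffs.copy()
    prev = np.empty(0, dtype=np.int64)
    for _ in range(30):
        _, prev = step_round(pop, env, prev, cfg, rng)
    np.testing.assert_array_equal(env.payoffs, before)


def test_unoccupied_patch_observed_at_full_value():
    cfg = small_cfg(n_individuals=4, n_patches=6)
    pop, env, rng = _fresh(cfg)
    occupancy = np.zeros(cfg.n_patches, dtype=np.int64)
    occupancy[2] = 2
    idx = np.array([0, 1])
    patches = np.array([3, 2])
    observe(pop, env, occupancy, idx, patches, rng)
    assert pop.memory_of(0) == {3: pytest.approx(float(env.payoffs[3]))}
    assert pop.memory_of(1) == {2: pytest.approx(float(env.payoffs[2]) / 2)}


def test_social_learning_samples_only_previous_round_patches(rng):
    cfg = small_cfg(n_individuals=20, n_patches=50)
    pop, env, _ = _fresh(cfg)
    prev = np.array([5, 5, 17, 3], dtype=np.int64)
    patches = social_learn(pop, np.arange(10), prev, rng)
    assert set(patches) <= {5, 17, 3}


def test_all_individual_learners_equivalent_to_disabled_social_channel():
    """With alpha = 0 everywhere the trajectory is identical to a model with
    no social channel at all, under a shared seed."""
    cfg = small_cfg(initial_social_fraction=0.0, max_rounds=40)
    res_a = run_single(cfg, 99)
    res_b = run_single(cfg.replace(social_enabled=False), 99)
    assert res_a.per_round.equals(res_b.per_round)
    np.testing.assert_array_equal(res_a.final_collected, res_b.final_collected)


def test_survivor_ages_advance_by_one():
    cfg = small_cfg(n_individuals=30, death_prob=0.0, max_age=10 ** 6)
    pop, env, rng = _fresh(cfg)
    ages_before = pop.age.copy()
    step_round(pop, env, np.empty(0, dtype=np.int64), cfg, rng)
    np.testing.assert_array_equal(pop.age, ages_before + 1)


def test_newborns_never_inherit_memory():
    """Dying wipes memory: replacement newborns start with empty memories."""
    cfg = small_cfg(n_individuals=20, death_prob=1.0)
    pop, env, rng = _fresh(cfg)
    prev = np.empty(0, dtype=np.int64)
    _, prev = step_round(pop, env, prev, cfg, rng)  # everyone learns something
    _, prev = step_round(pop, env, prev, cfg, rng)  # then everyone dies
    assert (pop.mem_count == 0).all()
    assert (pop.age == 0).all()
    assert (pop.history == 0.0).all()
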