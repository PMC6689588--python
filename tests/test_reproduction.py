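"""Mortality, skewed parent pools, inheritance, and mutation."""

import numpy as np
import pytest
from conftest import small_cfg

from skewlearn import apply_mortality, eligible_parents, init_population, run_single
from skewlearn.population import SEX_FEMALE, SEX_MALE
from skewlearn.reproduction import (
    SkewConfig,
    reproduce_asexual,
    reproduce_sexual,
    replace_fixed,
)


def _pop(cfg, seed=3):
    return init_population(cfg, np.random.default_rng(seed))


def test_no_mortality_when_disabled_and_young():
    cfg = small_cfg(death_prob=0.0)
    pop = _pop(cfg)
    pop.age[:] = 50
    dead = apply_mortality(pop, cfg, np.random.default_rng(0))
    assert dead.size == 0


def test_maximum_age_is_deterministic_death():
    cfg = small_cfg(death_prob=0.0, max_age=100)
    pop = _pop(cfg)
    pop.age[:] = 10
    pop.age[[2, 5]] = 100
    dead = apply_mortality(pop, cfg, np.random.default_rng(0))
    np.testing.assert_array_equal(dead, [2, 5])


def test_random_death_rate_matches_probability(rng):
    cfg = small_cfg(n_individuals=1000, death_prob=0.01, max_age=10 ** 6)
    pop = _pop(cfg)
    deaths = sum(apply_mortality(pop, cfg, rng).size for _ in range(500))
    assert deaths == pytest.approx(500 * 1000 * 0.01, rel=0.15)


def test_top_beta_pool_size_uses_ceiling(rng):
    fitness = np.arange(1000, dtype=float)
    candidates = np.arange(1000)
    pool, w = eligible_parents(candidates, fitness, 0.01, "minimum_income", rng)
    assert pool.size == 10
    assert set(pool) == set(range(990, 1000))  # the top-ranked ten
    assert w is None  # minimum income: equally likely
    pool, _ = eligible_parents(np.arange(10), np.arange(10.0), 0.25,
                               "minimum_income", rng)
    assert pool.size == 3


def test_beta_one_includes_every_candidate(rng):
    candidates = np.arange(57)
    pool, w = eligible_parents(candidates, np.ones(57), 1.0, "minimum_income", rng)
    np.testing.assert_array_equal(np.sort(pool), candidates)
    assert w is None


def test_relative_income_weights_proportional_to_fitness(rng):
    fitness = np.array([3.0, 1.0])
    pool, w = eligible_parents(np.array([0, 1]), fitness, 1.0,
                               "relative_income", rng)
    weights = dict(zip(pool.tolist(), w.tolist()))
    assert weights[0] == pytest.approx(0.75)
    assert weights[1] == pytest.approx(0.25)


def test_cutoff_ties_broken_uniformly():
    # all-equal fitness, beta = 0.5: each candidate is in the pool about half
    # the time across independent draws
    hits = np.zeros(10)
    for seed in range(400):
        rng = np.random.default_rng(seed)
        pool, _ = eligible_parents(np.arange(10), np.ones(10), 0.5,
                                   "minimum_income", rng)
        hits[pool] += 1
    frac = hits / 400
    assert ((frac > 0.35) & (frac < 0.65)).all()


def test_asexual_offspring_inherit_parent_alpha():
    cfg = small_cfg(mode="asexual", mutation_rate=0.0)
    pop = _pop(cfg)
    pop.alpha[:] = 1.0
    pop.age[:] = 20
    skew = SkewConfig.from_sim(cfg)
    fitness = np.ones(pop.n)
    dead = np.array([0, 1, 2])
    reproduce_asexual(pop, dead, skew, fitness, cfg.delta, np.random.default_rng(1))
    assert (pop.alpha[dead] == 1.0).all()
    assert (pop.age[dead] == 0).all()


def test_mutation_flips_binary_alpha():
    cfg = small_cfg(mode="asexual", mutation_rate=1.0)
    pop = _pop(cfg)
    pop.alpha[:] = 1.0
    pop.age[:] = 20
    skew = SkewConfig.from_sim(cfg)
    dead = np.arange(10)
    reproduce_asexual(pop, dead, skew, np.ones(pop.n), cfg.delta,
                      np.random.default_rng(1))
    assert (pop.alpha[dead] == 0.0).all()  # every offspring mutated 1 -> 0


def test_mutation_rate_string_resolves_to_one_over_n():
    assert small_cfg(n_individuals=1000).resolved_mutation_rate() == pytest.approx(0.001)
    assert small_cfg(n_individuals=500).resolved_mutation_rate() == pytest.approx(0.002)


def test_sex_linked_inheritance_mother_to_daughter_father_to_son():
    cfg = small_cfg(mode="sexual", mutation_rate=0.0, n_individuals=40)
    pop = _pop(cfg)
    pop.alpha[pop.sex == SEX_FEMALE] = 1.0
    pop.alpha[pop.sex == SEX_MALE] = 0.0
    pop.age[:] = 20
    skew = SkewConfig.from_sim(cfg)
    dead = np.arange(12)
    reproduce_sexual(pop, dead, skew, np.ones(pop.n), cfg.delta,
                     np.random.default_rng(2))
    kids_f = dead[pop.sex[dead] == SEX_FEMALE]
    kids_m = dead[pop.sex[dead] == SEX_MALE]
    assert (pop.alpha[kids_f] == 1.0).all()  # daughters copy mothers
    assert (pop.alpha[kids_m] == 0.0).all()  # sons copy fathers


def test_strict_sex_ratio_preserves_sex_counts():
    cfg = small_cfg(mode="sexual", mutation_rate=0.0, strict_sex_ratio=True,
                    n_individuals=40)
    pop = _pop(cfg)
    pop.age[:] = 20
    before = (pop.sex == SEX_FEMALE).sum()
    dead = np.arange(15)
    dead_sexes = pop.sex[dead].copy()
    reproduce_sexual(pop, dead, SkewConfig.from_sim(cfg), np.ones(pop.n),
                     cfg.delta, np.random.default_rng(4))
    np.testing.assert_array_equal(pop.sex[dead], dead_sexes)
    assert (pop.sex == SEX_FEMALE).sum() == before


def test_fixed_replacement_copies_strategy_and_wipes_state():
    cfg = small_cfg(mode="fixed_proportion")
    pop = _pop(cfg)
    pop.history[:, :] = 5.0
    alpha_before = pop.alpha.copy()
    counts_before = (pop.alpha == 1.0).sum()
    dead = np.array([1, 4, 9])
    replace_fixed(pop, dead)
    np.testing.assert_array_equal(pop.alpha, alpha_before)  # copies of themselves
    assert (pop.alpha == 1.0).sum() == counts_before
    assert (pop.mem_count[dead] == 0).all()
    assert (pop.history[dead] == 0.0).all()


def test_monomorphic_population_stays_monomorphic_without_mutation():
    cfg = small_cfg(mode="asexual", mutation_rate=0.0,
                    initial_social_fraction=0.0, max_rounds=30)
    res = run_single(cfg, 11)
    # an absorbed state is permanent and terminates the run immediately
    assert res.termination_cause == "fixation"
    assert res.final_alpha_freq == 0.0


@pytest.mark.parametrize("mode", ["fixed_proportion", "asexual", "sexual"])
def test_population_size_constant_in_all_modes(mode):
    cfg = small_cfg(mode=mode, max_rounds=30, mutation_rate=0.1)
    res = run_single(cfg, 5)
    assert res.final_collected.shape == (cfg.n_individuals,)
    assert np.isfinite(res.per_round["alpha_freq"]).all()
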