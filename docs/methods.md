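# Model and methods

`skewlearn` simulates a population of `N` foragers exploiting `M` resource
patches to study how reproductive skew — the fraction of a population that
can reproduce at all — shapes the evolutionary balance between individual
and social learning.

## The world

Patch `m` holds a payoff `π_m`, drawn i.i.d. from a gamma distribution
parameterized by moment matching: shape `π̄²/σ²`, scale `σ²/π̄`, so that the
mean is `π̄` and the variance `σ²`. Two canonical worlds are used: *even*
(`σ² = 1`) and *uneven* (`σ² = 100`), both with `π̄ = 4`. Payoffs replenish
every round; exploitation never depletes a patch. Environmental turnover
redraws each patch's payoff independently with probability `τ` per round,
from the same stationary distribution (this preserves the stated world
moments; the redraw counts as a turnover event even if the new value
happens to equal the old one). Payoffs are continuous reals; there is no
spatial structure and no within-round depletion.

## A round

1. **Action draw.** Each individual learns with probability 0.2, otherwise
   it exploits. An exploiter with an empty memory is converted to an
   individual learner for the round: agents can only exploit patches they
   know about, and idling would leave newborns with no path to information.
2. **Exploitation.** All exploiters simultaneously commit to the patch in
   their memory with the highest remembered expected payoff (ties broken
   uniformly at random; with continuous payoffs cross-patch ties have
   probability zero). With `n_m` exploiters on patch `m`, each collects
   `π_m / n_m` — exploitative scramble competition — and overwrites its
   memory of that patch with the realized per-capita payoff. Occupancy is
   computed once per round; there is no sequential displacement.
3. **Learning.** A learning turn is social with probability `α_i`
   (the individual's heritable social-learning propensity), individual
   otherwise. An individual learner inspects a uniformly random patch; a
   social learner picks a uniformly random exploitation record from the
   previous round (unbiased copying — any demonstrator, regardless of
   success, sex, or survival; self-records included) and inspects that
   patch. Either way the stored value is the current expected payoff
   `p̂_m = π_m / n_m` using this round's payoff and occupancy (`π_m` if the
   patch is unoccupied), so stored information can go stale through both
   turnover and occupancy change. Social learners with no demonstrators
   (first round, or an all-learner round) fall back to individual learning.
4. **Bookkeeping.** Collected payoffs (0 for learners) enter a rolling
   history; ages advance; turnover is applied.
5. **Mortality and replacement.** Individuals die randomly with probability
   0.01 per round or deterministically at age 100, and are replaced in the
   same round, keeping `N` constant.

Memory persists until death, is never inherited, and is unbounded (in
practice it is capped by construction at one new entry per round lived,
which is what the engine's compact memory layout exploits).

## Fitness and reproduction

The fitness proxy of an individual that has lived at least `δ` rounds is
the discounted sum of its last `δ` collected payoffs,

    F_i(t) = Σ_{j=0}^{δ−1} e^{−r·j} · p_{i,t−j},

with window `δ = 5` and discount `r = 0.2` by default (a `single_round`
variant uses `F_i(t) = p_{i,t}`). Individuals younger than `δ` are excluded
from the parent pool rather than assigned a value, which keeps ranking
semantics clean.

Reproductive skew is the proportion `β ∈ (0, 1]` of mature survivors
eligible to reproduce: candidates are ranked by the current round's fitness
proxy and the top `⌈β·n_mature⌉` form the pool, ties at the cutoff broken
uniformly at random (the ceiling guarantees a nonempty pool for any β).
Under the *minimum-income* criterion every pool member is equally likely to
be drawn; under the *relative-income* criterion draw probability is
proportional to the fitness proxy within the pool.

Three replacement modes:

- **fixed_proportion** — the dead are replaced by newborn copies of
  themselves (same `α`, same sex, empty memory and history): no selection,
  used to compare the pure strategies at a frozen 50/50 composition.
- **asexual** — one parent per replacement from the skewed pool; offspring
  inherit `α`, flipped with mutation probability `μ = 1/N`.
- **sexual** — pools are formed within each sex with separate `β_f`, `β_m`;
  each replacement draws one mother and one father (with replacement),
  assigns the offspring's sex by a fair coin, and copies `α` from the
  same-sex parent (mother→daughter, father→son), then mutates. Because
  inheritance is sex-linked, each sex's strategy evolves independently
  except through ecological competition. Realized sex counts drift slightly
  around `N/2`; an optional `strict_sex_ratio` mode replaces each dead
  individual with a same-sex offspring for sensitivity analysis.

Runs terminate at fixation (all `α` equal; checked after replacement each
round, evolutionary modes only) or after `max_rounds = 5000` rounds.

## Initialization

Initial individuals have empty memories and histories. Ages are uniform on
{0, …, 99} so that mature individuals exist from the first rounds (with a
single cohort of age 0 the first generations would have an empty parent
pool). Fixed and asexual runs start with an exact 50/50 split of `α ∈
{0, 1}`; sexual runs draw each individual's `α` as an independent fair coin
and split the sexes exactly 50/50. Evolved `α` is binary; fixed-proportion
runs accept any `α ∈ [0, 1]` but continuous-`α` evolution is out of scope
(no mutation kernel is defined for it).

## Statistics

- **Variance ratio** (`skewlearn.stats.variance_ratio`): the risk
  comparison between strategies is the ratio var(social)/var(individual)
  of payoffs collected by exploiting individuals in the final round.
  The default reading (`within_round`) averages the within-round,
  across-individual variance over replicates and takes the ratio of the
  averages; this estimator is stable because every replicate contributes a
  variance over hundreds of individuals, and it is the reading that
  reproduces the published ratios (~1.04/0.94 even, ~0.34/0.36 uneven).
  An alternative reading (`across_replicates`) — the variance across
  replicates of the per-replicate strategy mean — is implemented behind a
  flag for comparison; as a ratio of two variances estimated from tens of
  replicate-level numbers its sampling error is larger than the effects of
  interest, so it is not the default. Bootstrap CIs resample replicates
  (10,000 resamples, percentile method), keeping each replicate's
  social/individual pair together.
- **Evolved social learning** is the `α` frequency at the end of a run
  (optionally averaged over a trailing window), overall and by sex.
- **Yield distributions** pool final-round per-individual collected
  payoffs by strategy, truncated at 25 for display, with the stationary
  gamma payoff density for overlay.

## Numerical and design choices

- One `numpy.random.Generator` (PCG64) per run drives every stochastic
  event; replicate seeds are spawned from a base seed via `SeedSequence`,
  so replicate sets are reproducible, order-independent, and extensible.
  The social/individual channel is drawn for every individual whether or
  not it learns, so switching the social channel off (or setting all
  `α = 0`) leaves the random-stream layout — and hence the trajectory —
  bit-identical.
- The engine is vectorized over agents. Each individual's best-remembered
  patch is cached and maintained incrementally; a full memory rescan
  happens only when the current best entry is revised downward. Exact-value
  ties on update are broken by a fair coin (they occur with probability
  zero under continuous payoffs but are handled for completeness).
- Payoff conservation holds exactly each round (Σ collected = Σ `π_m` over
  occupied patches, to 1e-9), and is tested.
- Degenerate inputs: an empty mature parent pool (possible only in
  pathological configurations, since initial ages are staggered) falls back
  to drawing parents uniformly from the living, with a runtime warning.

## Problem sizes and what the tests show

Headline checks run at the published scale — `N = M = 1000`, 5000 rounds —
with 30–40 replicates per condition for the variance ratios, 30–32 for the
neutral limits (`β = 1`, where symmetric mutation and drift keep the mean
evolved social-learning frequency at 50%), and 20 replicates per cell for
the qualitative skew/sex/world comparisons. Full 200-replicate, full-grid
surface reproduction is available as a long-running preset
(`skewlearn.presets.full_asexual_grid`) but is not part of the test suite.

The generator *is* the study system: these are simulations of the model
itself, not fits to animal data, so passing tests demonstrate internal
reproduction of the model's reported behaviour, not claims about any
empirical population.

## Known limitations

- No payoff-biased or conformist copying; no memory decay; no within-round
  patch switching; no spatial structure.
- Continuous-`α` evolution and absolute-income reproduction thresholds are
  not implemented.
- The across-replicate variance-ratio reading is statistically fragile at
  desk-scale replicate counts; use the default within-round reading for
  quantitative comparisons.
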