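# Model and methods

`trimorph` simulates a two-sex, two-age-class population in which adult
males compete for mates through a three-strategy rock-paper-scissors (RPS)
game — monogamous (M), polygynous (P) and sneaker (S) — encoded at a single
diploid autosomal locus with alleles `m`, `p`, `s`, and provides the
time-series machinery used to detect and attribute cyclical structure in
the resulting strategy-frequency dynamics.

## Life cycle

Each time step applies four phases in a fixed order:

1. **Recruitment.** Every juvenile becomes an adult with probability
   `p_rec(N) = exp(-k N)`, where `N` is the total population (all age
   classes) before recruitment — scramble competition in its canonical
   (Ricker) form.  A Beverton–Holt alternative `1/(1 + k N)` is available
   via `LifeCycleParams(recruitment_form="beverton_holt")`.  Non-recruited
   juveniles survive with probability `s_j` and may try again next step.
   Newly adult males are assigned their lifelong strategy (below).
2. **Mating.** Neighbourhoods, harems, contests (below); defines each
   mated female's single mate.
3. **Reproduction.** Each mated female produces `Poisson(F)` offspring;
   offspring sex is female with probability `sigma` and the genotype draws
   one allele uniformly from each parent.  Offspring join the juvenile
   pool *after* recruitment has run, so nobody is recruited in the step of
   its birth.
4. **Adult death.** Each adult survives with probability `s_a`.

Default parameters follow the standard nomenclature: `sigma = 0.5`;
`s_j, s_a ∈ {0.2, 0.5}` (short- to long-lived life cycles paired with
fecundities `F ∈ {14, 9.2, 6.5, 4.4}`); competition coefficients
`k ∈ {0.004, 0.002, 0.001}` paired with carrying capacities
`K ∈ {500, 1000, 2000}`.  `LifeCycleParams.short_lived(K)` uses
(`s = 0.2`, `F = 14`) and `LifeCycleParams.long_lived(K)` (`s = 0.5`,
`F = 4.4`) — the two ends of the gradient.

Two consequences of this structure are worth stating because they shape
everything downstream.  First, the age structure is strongly
juvenile-biased: at the short-lived equilibrium only ~2–3% of individuals
are adults after mortality (about 35 adult males take part in each mating
phase at `K = 500`), so demographic stochasticity at the adult bottleneck
is the dominant noise source.  Second, the low-density growth rate of the
life cycle is large (≈ 2.5–7 per step depending on the cycle; fecundity 14
with near-certain recruitment is explosive) and **independent of k** — the
competition coefficient only positions the equilibrium.  A nominal growth
rate of ≈ 1.1 per step is therefore not attainable by choosing `k`;
`calibrate_k` fits `k` to the equilibrium-size clause by bisection
(monotone in `k`), reports the realized low-density growth rate as a
diagnostic, and raises only in `strict` mode.  The one-significant-digit
table values of `k` leave the short-lived equilibrium ≈ 20% above the
nominal `K` (the exact short-lived solution at `K = 500` is `k ≈ 0.0047`);
the long-lived pairs land within a few percent.

**Initial state.** Hardy–Weinberg genotypes at the scenario's initial
allele frequencies, total size `K`, half adults; adult males receive
strategies from the active mechanism with equal frequencies assumed (all
expected payoffs then tie, so plastic heterozygotes start on a fair coin).

## Genotype-to-phenotype mechanisms

* **Allelic dominance** (`mode="dominance"`): a fixed order, default
  `p > s > m` (all p-carriers are P, `mm` is M, `ss` and `ms` are S).
  The order is configurable; the default is the one consistent with that
  explicit genotype table.
* **Irreversible developmental plasticity** (`mode="plasticity"`):
  homozygotes express their allele; a heterozygote chooses, once at
  recruitment, the better of its two encoded strategies by the expected
  payoff `E(i) = Σ_k f_k W0(i,k)` at the adult-male strategy frequencies
  of that moment (frequencies taken before the step's own recruits join,
  since recruitment precedes mating).  Exact ties fall to a fair coin from
  the simulation RNG.  An alternative criterion
  (`plastic_criterion="realized"`) compares the mean number of females
  actually won per male of each strategy at the previous mating instead.

## The mating game

`W0[i, k]` is the mean number of females a focal male of strategy `i` wins
against males of strategy `k`; the default matrix (rows P: 1, 2, 0.5; M:
0.5, 1, 2; S: 2, 0.5, 1 in (P, M, S) order) closes the cycle P→M→S→P with
equal margins.  The mating phase has three stages:

1. **Neighbourhoods.** Each male draws `Poisson(3)` neighbours uniformly
   among the other males, without replacement, resampled every step
   (no persistence; the home range enters only through these counts).
2. **Harem assembly.** Males draw target harem sizes `Poisson(h)` with
   `h_p = 3`, `h_m = 1`, `h_s = 0.5` (heterozygote means reduced by the
   factor `1 - c`), and claim females uniformly at random from the
   unassigned pool — P males first, then M, then S.  Females are usually
   the limiting resource, so assembly order matters.
3. **Contests.** Contest rounds run in the stated order — S against P
   neighbours, then M against S, then P against M, then within-strategy
   pairs.  Each adjacency of the two strategies contests once, with the
   cycle winner attacking; every eligible female of the opponent transfers
   to the attacker independently with the win probability below.

**Win probability.** Two males of the same strategy contest at exactly
0.5.  Otherwise the focal male's probability of winning each female is the
even-chance baseline plus the difference of the frequency-weighted payoff
terms:

    p_win(i, k) = 0.5 + f_i f_k (W0(i,k) - W0(k,i))            (default)

clipped to [0, 1].  Under this form a *rare* strategy gains essentially no
per-contest edge (the product `f_i f_k` vanishes); its frequency-dependent
advantage comes entirely from encounter rates — a rare S male meets mostly
P neighbours with large harems.  This reading is what makes invasion
asymmetric in the observed way: P invades from rare on the strength of its
harem size, while S cannot.  The alternative ratio form

    p_win(i, k) = f_k W0(i,k) / (f_k W0(i,k) + f_i W0(k,i))    (win_mode="ratio")

drives a rare attacker's win probability toward 1 and is retained as a
config switch; under it a rare sneaker allele invades essentially always,
which contradicts the behaviour this model family is meant to show.

**Steal scope.** By default contests dispute the harems *as assembled*: a
female changes hands at most once per mating phase (she is contested by
her original owner's attacker sequence, first success wins her).  The
alternative (`steal_scope="current"`) lets later rounds re-steal
previously won females; that turns the round order into a conveyor
(S robs P, M robs S's winnings, P robs M's) whose last mover gains a
structural advantage unrelated to the payoff matrix.  Both scopes are
implemented; "assembled" is the default because it preserves the cyclic
balance of the game.  The vectorized engine resolves each round in batch
(per-opponent attacker order is preserved, so it is distribution-identical
to the retained one-contest-at-a-time reference implementation, which the
test suite checks).

**Heterozygote cost `c`** (default scenarios use 0; the costed scenarios
use 0.2): a pure strategist (homozygote) playing a heterozygote gets its
win weight multiplied by `1 + c` and the pair renormalized
(`cost_mode="multiplicative"`; an additive `±c` shift is the config
alternative), and a heterozygote's initial mean harem size is reduced by
`1 - c`.  Heterozygote-vs-heterozygote games are uncosted.  Under
dominance the cost still keys on homo/heterozygosity (configurable via
`cost_under_dominance`).

## Experiment protocols

* **Two-allele runs**: one allele absent; report the winner and the
  time to monomorphism (the cycle winner's fixation is fast here —
  median ≈ 13–55 steps at `K = 500` depending on the pair, because harem
  asymmetries act every step).
* **Maintenance runs**: equal allele frequencies, `T = 300`, maintenance
  = all three alleles present (in either age class) at the horizon; mean
  strategy frequencies are averaged over the final 100 steps of
  maintaining replicates.
* **Invasion runs**: the two resident alleles start at equal frequencies;
  after a 10-step burn-in, 20 resident heterozygotes (any age class) are
  re-genotyped to carry the invader paired with the currently losing
  resident allele (the one whose strategy loses the resident pairing's
  cyclic match-up), and the run continues to the 300-step horizon.  The
  burn-in is deliberately short: resident pairs approach their
  quasi-stationary composition within ~10 steps, and a long burn-in would
  typically already be monomorphic, leaving no heterozygotes to swap.
* **Replicates** are embarrassingly parallel: replicate `i` of a scenario
  with base seed `s` always uses `numpy.random.default_rng([s, i])`, so
  results are bit-identical for a given (config, seed) pair.

## Time-series toolkit

* **Morlet CWT** (`cwt_power`): complex Morlet with central frequency
  `omega0 = 6` (scale ≈ period), dyadic period grid with 8 voices per
  octave, default ceiling `n/16` so the time-averaged global spectrum
  keeps enough cone-of-influence-free cycles to be flat on white noise.
  Power inside the cone of influence (e-folding distance `sqrt(2)·scale`)
  is excluded from the global spectrum.  The wavelet is sampled at
  `precision=14`; the library default undersamples large scales and leaks
  spurious power there.
* **MRA** (`mra_split`): stationary-wavelet (maximal-overlap) multi-
  resolution analysis with the least-asymmetric 8-tap filter (`sym8`);
  series are symmetrically padded to a multiple of `2^level` and cropped,
  so the components still sum exactly to the input.  Component labels use
  the lower period edge of each dyadic band (`D_j ↔ 2^j` covering periods
  `[2^j, 2^{j+1})`).  A sinusoid at an exact dyadic period sits on a
  half-band boundary and splits coherently between the two adjacent
  components (≈ half amplitude each) — a property of any orthogonal
  half-band filter bank, relevant when reading band energies.
* **Cross-correlation** (`cross_correlation`): `r(l) = corr(x_t, y_{t+l})`
  on standardized series; the asymmetry statistic `Σ_{l>0}(r(l) − r(−l))`
  is read as the direction and sign of influence of `x` on `y`.
  Significance uses random circular shifts of `y` (200 permutations by
  default), which preserve both autocorrelations while destroying their
  alignment — appropriate because these series are strongly autocorrelated.
  `band_asymmetries` applies this per MRA band with a lag window of twice
  the band scale.
* **Gain** (`gain_function`): Welch-type estimate `|P_xy| / P_xx` with
  Hann taper, 50% overlap and a default segment length giving about eight
  segments; gain < 1 between a per-strategy male count and total
  population size means the game's cyclical variance is attenuated by
  demographic stochasticity.

## What the defaults were chosen on

The contest rules above contain three genuinely open readings (win
probability, contested pairs, steal scope); all are implemented and
switchable.  The defaults are the combination under which the model
reproduces the qualitative behaviour this family of models is defined by —
near-certain maintenance of the trimorphism under plasticity together with
frequent allele loss under dominance, invasion possible for `p` but not
`s`, and game cycles on the 16/32-step scales driven by the P strategy —
rather than the combination most literally matching any single sentence of
the verbal model description.  They were fixed before the acceptance
quantities were frozen and are not per-experiment knobs.

## Problem sizes

Simulation-backed checks use the desk-scale study conditions throughout:
maintenance grids of 3 carrying capacities × 2 life cycles × 50 replicates
× 300 steps; invasion contrasts of 200 replicates per arm (a difference of
two proportions needs that many for a useful standard error); 2050-step
runs for spectral analysis with 10 maintained replicates for band
attribution; 30 seeds for growth-rate and monomorphism-time estimates.
One full acceptance pass takes a few minutes on one core.

## Known limitations

* The dominance dynamics are more stable here than in the reference
  behaviour this model family reports: the interior state is S-heavy
  (`f_S ≈ 0.55` instead of ≈ 0.4 at the costless dominance equilibrium)
  and large-`K` dominance cells rarely lose alleles within 300 steps, so
  the grid-mean dominance maintenance probability is ≈ 0.76 rather than
  ≈ 0.4.  The heterozygote cost moves `f_S` in the right direction but by
  less than the reported 0.1.
* The density-dependent recruitment cycle under the Ricker form has a
  period of ≈ 2.4 steps (strong overcompensation), not 4; under
  Beverton–Holt the fast cycle disappears entirely.
* The low-density growth rate is ≈ 2.5–4 per step (see above); no value of
  `k` can bring it to 1.1 under this life-cycle structure.
* Band attribution concentrates at the 16-step scale for all strategy
  pairs; only the P→M attribution matches the reported 16 exactly, while
  M–S interactions are also attributed to 16 rather than 32.
* Under dominance at long-lived cells a rare sneaker allele still
  establishes in a majority of attempts (it profits from encounters with
  common large-harem P males at near-even contest odds), whereas the
  reference behaviour has S unable to persist when rare under dominance;
  the monogamous allele correctly fails to invade, and under plasticity
  the invasion asymmetry (p and m can establish, s is the weakest) holds.
* The synthetic populations emulate no empirical dataset; passing tests
  show internal consistency of the model and toolkit under the stated
  assumptions, not correspondence to any real mating system.
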