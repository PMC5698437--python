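# trimorph

Individual-based simulation of a three-morph rock-paper-scissors (RPS)
male mating-strategy game, together with the wavelet / multi-resolution /
cross-correlation toolkit used to detect and attribute cyclical structure
in the resulting strategy-frequency dynamics.

## The problem

Discrete mating-strategy trimorphisms — monogamous guarders (M),
aggressive polygynists (P) and sneakers (S), as in side-blotched lizards
or *Paracerceis* isopods — can be maintained by negative frequency-
dependent selection when the three strategies beat each other cyclically
(P beats M, M beats S, S beats P).  The three strategies are encoded at
one diploid locus with alleles `m`, `p`, `s`, so heterozygotes carry the
information for two strategies, and what a heterozygote *expresses*
becomes a population-genetic question.  `trimorph` compares two
genotype-to-phenotype mechanisms inside a stochastic two-sex, two-age-class
population model:

* **allelic dominance** — a fixed order (default `p > s > m`) decides;
* **irreversible developmental plasticity** — at recruitment a
  heterozygote adopts whichever of its two encoded strategies currently
  has the higher expected payoff `E(i) = Σ_k f_k W0(i,k)`, and keeps it
  for life.

Competition runs through harems and pairwise contests: males draw
`Poisson(3)` neighbours; harems assemble P→M→S with mean sizes
(3, 1, 0.5); contests transfer each of the loser's females to the cycle
winner with probability `0.5 + f_i f_k (W0(i,k) − W0(k,i))`, where `W0`
is the dyadic payoff matrix (rows P: 1, 2, 0.5; M: 0.5, 1, 2;
S: 2, 0.5, 1) and `f` the current adult-male strategy frequencies.
Population turnover is a four-phase life cycle (density-dependent
juvenile recruitment `exp(-kN)`, mating, Poisson reproduction, adult
death), which adds the demographic stochasticity most analytic treatments
leave out.  The package's question: under which mechanism, life cycle and
carrying capacity does the trimorphism survive, and at which time scales
do the game and the demography imprint cycles on the dynamics?

Audience: evolutionary ecologists and population geneticists modelling
alternative reproductive tactics, and anyone needing a compact testbed
for frequency-dependent selection with demographic noise.

## Worked example

```python
import trimorph as tm
from trimorph import tsa

cfg = tm.ScenarioConfig(
    mechanism=tm.GeneticMechanism(mode="plasticity", heterozygote_cost=0.0),
    lifecycle=tm.LifeCycleParams.short_lived(K=500),
    T=300, seed=42,
)
summary = tm.run_maintenance(cfg, n_replicates=20)
print(f"maintenance P = {summary.maintenance_probability:.2f} "
      f"[{summary.ci_low:.2f}, {summary.ci_high:.2f}] "
      f"over {summary.n_replicates} replicates")

two = tm.run_two_allele(cfg.with_(initial_allele_freqs=(0.5, 0.5, 0.0)),
                        n_replicates=20)
print(f"p vs m: winner {two.expected_winner} fixed in "
      f"{two.expected_winner_fraction:.0%} of replicates, "
      f"median time {two.median_time_to_monomorphism:.0f} steps")

rep = tm.run_replicate(
    cfg.with_(T=2050, lifecycle=tm.LifeCycleParams.short_lived(K=2000)), 1)
spec = tsa.cwt_power(rep.series["f_P"].to_numpy())
print("f_P spectral peaks:",
      [(d["band"], round(d["peak_period"], 1))
       for d in tsa.dominant_periods(spec)])
```

prints

```
maintenance P = 0.70 [0.46, 0.88] over 20 replicates
p vs m: winner p fixed in 100% of replicates, median time 44 steps
f_P spectral peaks: [(4, 5.7), (8, 8.0), (16, 16.0), (32, 58.7)]
```

Reading: at the smallest, shortest-lived study condition the plastic
mechanism keeps all three alleles segregating to step 300 in 70% of 20
replicates (exact binomial CI in brackets; the grid mean over all six
study conditions is ≈ 0.96, versus ≈ 0.76 under dominance).  With the `s`
allele removed, the polygynous allele — whose strategy beats M in the
cycle — fixes in every replicate, in a median of 44 steps.  In a long
trimorphic run the P-frequency wavelet spectrum shows the mating-game
cycle at the 16-step scale on top of the faster demographic structure;
the cross-correlation asymmetry of f_P against f_M is negative
(P suppresses M).

## Command line

```bash
trimorph simulate scenario.yaml --out run.csv     # one replicate -> CSV
trimorph grid grid.yaml --out summary.csv         # list-valued keys -> cells
trimorph invade scenario.yaml --invader s         # rare-allele invasion
trimorph analyze run.csv --out-prefix run         # spectra / MRA / CCF / gain
trimorph fixtures --periods 8,32 --out signal.csv # synthetic test signal
```

Config files are flat YAML in the standard nomenclature
(`sigma, s_j, s_a, k, F, K, W0, h_p, h_m, h_s, n_p, n_m, n_s, c,
mechanism, dominance_order, T, R, seed`).

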