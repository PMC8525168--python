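# Methods

## Model overview

`dispersim` implements an annual-lifecycle, asexual, individual-based
metapopulation model in which cognition is part of a developmentally
plastic dispersal syndrome. The genotype holds five loci in [0, 1]:
dispersal tendency `D`, and phenotype-specific pairs for learning
(`L_R`/`L_D`) and exploration (`E_R`/`E_D`). A developmental switch at
birth compares `D` with a uniform draw; the outcome (resident or
disperser) is irreversible and selects which locus pair is expressed.
Because both pairs are carried by every individual, the unexpressed pair
evolves only through its carriers' relatives — which is what makes
mutation–selection balance visible on rarely expressed loci.

Each generation proceeds in a fixed order:

1. developmental switch for the newborn cohort,
2. pre-dispersal foraging phase (`t_before` time steps),
3. instantaneous dispersal (dispersers die with probability `M`,
   survivors relocate to a uniformly random patch, natal patch included),
4. post-dispersal foraging phase (`t_after` steps),
5. census,
6. fitness-proportional recruitment of exactly `n_individuals` offspring
   per occupied patch (sampling with replacement, weight
   `F = max(0, V_total·(1 − L·α))`),
7. independent per-locus mutation (probability `μ`, Gaussian step of SD
   `mutation_sd`, clamped to [0, 1]),
8. periodic patch extinction (`extinction_count` random patches emptied
   every `extinction_every` generations).

Empty patches recruit nothing and can only be recolonized by immigrants.
Global extinction truncates a run and is flagged on the result rather
than raised.

## Foraging economics

Each foraging phase is evaluated in a single closed-form pass per
resource (the intake pipeline is defined on whole-phase aggregates, so
per-time-step agent stepping would add cost without adding information):

* encounters `N = A·T·(1+E)` — individuals move at least every second
  time step, so `E = 0` yields exactly half the encounters of `E = 1`;
* detection `N′ = N·(1 − (1−C)·E)` — fast exploration searches less
  thoroughly, discounting hard-to-detect resources;
* learning `N″ = Σ_{j=a}^{b} max(0, 1 − (H−1)/(j·L))`, where `j` indexes
  lifetime practice with that resource type (`a = prior+1`,
  `b = prior+round(N′)`). The per-item inefficiency `(H−1)/(j·L)` decays
  hyperbolically with practice: resources with `H ≫ 1` yield nothing
  until `j > (H−1)/L` and approach full value only slowly afterwards;
* patch cap `Rmax = T·A·N_individuals/Φ` with the phase's own duration
  and the fixed carrying capacity (not current occupancy);
* competition: when a patch's summed `N″` for a resource exceeds `Rmax`,
  every occupant's amount is scaled by `Rmax/ΣN″`, so the patch total
  equals the cap exactly.

Practice carries over between phases, and across patches whenever the
settlement patch offers the same resource type. The practice ledger
advances by the items practiced (`round(N′)`), not by the
post-competition reward: competition removes payoff, not experience.

## Parameters

| parameter | meaning | preset default | units |
|---|---|---|---|
| `n_patches` | patches in the metapopulation | 12 | — |
| `n_individuals` | per-patch carrying capacity | 100 | individuals |
| `t_before`, `t_after` | phase lengths (season = sum) | experiment axis | time steps |
| `dispersal_mortality` (`M`) | death risk per dispersal attempt | 0.01 | probability |
| `learning_cost` (`α`) | fecundity cost coefficient of expressed `L` | 1.4 | — |
| `mutation_prob` (`μ`) | per-locus mutation probability | 0.1 | probability |
| `mutation_sd` | SD of the mutational step | 0.1 | trait units |
| `competition_factor` (`Φ`) | severity of within-patch competition | 2 (season presets) / 6 (timing presets) | — |
| `extinction_every`, `extinction_count` | patch-erasure schedule | every 2 generations, 1 patch | — |
| resources | easy: `V=1, H=1, C=0.5, A=1`; hard: `V=10, H=300 (season) / 150 (timing), C=0.5, A=5` | | |

The two patch types each pair the easy resource with a *different* hard
resource, so a disperser that switches patch type cannot reuse its
practice. With `α = 1.4`, fecundity is zero for `L ≥ 1/1.4 ≈ 0.714`,
which bounds the economically viable learning investment.

## Numerical choices

* **Learning-curve sum.** Positive terms start at
  `j_min = floor((H−1)/L) + 1` (strict inequality; a term exactly at the
  threshold is zero), so the sum collapses to
  `count − ((H−1)/L)·(ψ(b+1) − ψ(a′))` with `ψ` the digamma function
  (`H_n = ψ(n+1) + γ`). This matches the literal per-item loop to
  ≲ 5e−12 over the tested domain (tolerance 1e−9 in the suite).
  Conventions: `H = 1` ⇒ every term is 1 regardless of `L` (no-learning
  resource); `L = 0` with `H > 1` ⇒ every term is 0 (the `L → 0⁺`
  limit).
* **Rounding.** `round(N′)` rounds half away from zero; inputs are
  rarely exact halves, so the choice is inconsequential but fixed.
* **Fecundity floor.** `F` is clamped at 0: it is a sampling weight.
  An occupied patch whose occupants all have `F = 0` recruits uniformly
  among them rather than going spuriously extinct.
* **Mutation boundaries.** Proposals are clamped to [0, 1]; clamping
  keeps the neutral stationary distribution symmetric about 0.5 (a
  locus pinned at a boundary mutates back inward with probability ½ per
  firing).
* **Census timing.** The generation record is taken after both foraging
  phases and dispersal, before recruitment: the expressed-trait means
  describe exactly the cohort whose fitness differences drive that
  generation's selection.
* **Determinism.** One `numpy` PCG64 generator per run, seeded from the
  config; `(config, seed)` determines every output byte. Replicate `k`
  of a batch uses `SeedSequence([base_seed, k])` (sweep cells add a cell
  key), reduced mod 2³¹.

## Analysis conventions

Equilibrium summaries average the trailing 10% of generations (minimum
10); trajectories settle well before the end of the shipped run lengths,
and a fixed trailing window is a reproducible substitute for visual
equilibrium judgment. The headline comparison — resident vs. disperser
learning — uses population-wide *locus* means (`L_R`, `L_D` averaged
over all carriers), because the mutation–selection-balance behaviour of
a rarely expressed locus is only visible in the locus mean; expressed
phenotype means are emitted alongside for diagnostics. Replicate means
enter a two-sided paired t test (`df = n_replicates − 1`, α = 0.05 by
default, exposed as a flag); the test is cross-checked against
`scipy.stats.ttest_rel` in the suite.

## The neutrality diagnostic

`run_simulation(..., uniform_fitness=True)` replaces every recruitment
weight with 1, switching off fecundity selection while leaving all other
processes untouched. Two caveats discovered and documented here:

* The dispersal-tendency locus is **not** neutral even then: with local
  recruitment, dispersal is an escape from kin competition and `D` is
  selected upward (and further upward by extinction–recolonization).
  The truly selection-free loci in this mode are the learning and
  exploration loci, and the neutral diagnostic config
  (`presets.neutral_drift_config`) additionally disables dispersal
  mortality and patch extinction.
* A neutral locus's population mean drifts slowly; a 100-generation
  window mean varies across replicates with SD ≈ 0.1, so ten-replicate
  averages of a single locus scatter with SE ≈ 0.03. Checks pool the
  four symmetric neutral loci where a decisive verdict is needed.

## Problem sizes used in the suite

Unit and property tests run on miniature worlds (4–10 patches, 10–1000
individuals, ≤ 30 generations). The end-to-end checks use the preset
scale: 12 patches × 100 individuals with 10 replicates per cell — 300
generations per run for the season-length sweep (4 cells), 500 for the
dispersal-timing sweep (3 cells) and the neutrality diagnostic. The full
suite completes in about a minute on one CPU; `scripts/acceptance.py` in
under half a minute.

## Known limitations

* Dispersal is global and spatially implicit; there is no geometry,
  kernel, or distance cost, and patch-type arrangement is therefore
  irrelevant (the presets assign types to index halves).
* Reproduction is asexual and haploid; no recombination between the
  resident and disperser locus sets.
* Predation, condition-dependent dispersal triggers, and heterogeneous
  detectabilities are representable in the configuration but outside the
  shipped presets and untested territory.
* Under the shipped preset economics, the learning threshold
  `(H−1)/L` exceeds any individual's lifetime practice count
  (≈ 5.6 items per season time step at best) for seasons shorter than
  ≈ 130 steps, so in that regime resident–disperser learning differences
  arise from mutation–selection balance on the rarely expressed resident
  locus rather than from realized learning. The learning-driven regime —
  resident learning onset with a collapse in dispersal tendency,
  followed at still longer seasons by dispersers overtaking residents —
  sits at seasons of a few hundred steps (see the directional-reversal
  test in the suite).
* The phase-batched intake has no within-phase feedback: all occupants'
  learning sums are evaluated on pre-phase ledgers, then competition is
  applied once per phase.
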