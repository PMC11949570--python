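# pxarsim

**Should regional species loss be faster or slower than local loss?**
`pxarsim` is a simulation toolkit for studying how the rate of species
extinction scales with the spatial grain *A* (the average area of a grid
cell) when per-individual mortality depends on a species' regional
abundance *N*.

It is aimed at quantitative community ecologists who want to generate,
perturb, and measure virtual communities; everything is seeded and
reproducible, and all inputs are simulated (no external data).

## The model

Two quantities describe species loss between two snapshots of a
community, averaged over grid cells of area *A*:

* **Ex** — the number of species lost per cell (extirpations),
* **Px = Ex / S1** — the per-species probability of extinction, where
  **S1** is the richness per cell before the loss.

Their relationships with grain, **PxAR** and **ExAR**, are summarized by
slopes against ln *A*: an OLS fit of Px, and a Poisson GLM (log link) of
the per-cell Ex counts.

The driver under study is density-dependent mortality. Each individual
of a species with regional abundance *N* dies with probability

```
P_death(N; α, β) = E / ((1−α)/α + E),   E = exp(N · sgn(β) · e^(−1/β))
P_death(N; α, 0) = α
```

where α ∈ (0, 1) is the death probability of a species with no
conspecifics and β controls the direction of density dependence:
mortality decreasing with *N* (negative density dependence — rarity is
penalized, as under Allee effects) or increasing with *N* (positive
density dependence — commonness is penalized, as under Janzen–Connell
dynamics or harvesting). Negative density dependence removes rare
species from the whole region at once, raising regional Px relative to
local Px (a positive PxAR slope); positive density dependence does the
opposite.

Two complementary experiments probe this:

1. **Point patterns** — a lognormal species-abundance distribution
   realized as a Thomas cluster process in the unit square (one mother
   point per species, Gaussian displacement σ, torus wrapping), followed
   by one Bernoulli mortality episode and grain-scaling measurement on
   nested 2×2 … 16×16 grids. The full factorial design crosses
   β, α, SAD unevenness CV_N, aggregation σ, species fraction S_frac and
   community size N_tot: 2646 configurations, 26,460 runs at 10
   replicates.
2. **GLV metacommunity** — M patches of generalized Lotka–Volterra
   dynamics with random interactions, punctuated by stochastic dispersal
   (Levins-style colonization) and disturbances whose shock variance
   follows a Taylor power law in abundance (`var ∝ n^d_z`); `d_z`
   plays the role of β. Occupancy snapshots at t = 10 and 20 give
   per-patch and metacommunity extinction fractions, whose difference
   over the elapsed time is the slope. 132 configurations, 1320 runs.

Experiment outcomes are ranked by random-forest variable importance
(500 trees, 1/3 of predictors and 63% of rows per tree, terminal node
size 5).

## Worked example

Simulate an uneven community (CV_N = 10) under strong negative density
dependence and measure its extinction scaling:

```
$ pxarsim simulate-pp --n-tot 1000 --s-frac 0.1 --cv-n 10 --sigma 0.1 \
      --alpha 0.5 --beta -4 --seed 42 --out demo_pp
 k     area   mean_s1  mean_ex       px
16 0.003906  2.414062 0.023438 0.009709
 8 0.015625  6.640625 0.093750 0.014118
 4 0.062500 15.750000 0.375000 0.023810
 2 0.250000 43.500000 1.500000 0.034483
pxar_slope=0.00606032 exar_slope=1
```

Px rises from ~0.010 in the finest cells to ~0.034 at the coarsest
grain: rare species are wiped out regionally while local cells, mostly
populated by common (hence near-immortal) species, lose little — the
positive PxAR slope (0.006 per unit ln A) predicted for negative density
dependence. Ex still *increases* with area (ExAR slope ≈ 1) because
larger cells hold more species to lose.

The equilibrium counterpart, with rarity-penalizing disturbances
(`d_z = 1`):

```
$ pxarsim simulate-lv --s 10 --m 10 --d-z 1 --seed 42 --out demo_lv
pxar_slope=-0.0453095 exar_slope=-0.16
```

Here the slope is negative: the steady-state system keeps eliminating
rare species every step, so the surviving abundance distribution offers
little rarity for density dependence to act on, and local loss outpaces
regional loss.

Other entry points: `pxarsim experiment` (factorial grids, `--dry-run`
to size them), `pxarsim importance` (random-forest ranking of a results
table), `pxarsim measure` (grain scaling of a user-supplied
`x,y,species,alive_t2` CSV) and `pxarsim plot`. The same functionality
is available as a library (`import pxarsim`).

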