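# bitz

Spatially explicit community simulation of functional solitary-bee types in
agricultural landscapes, built to ask one question: **how much of a
landscape's field edges must become agricultural buffer zones (ABZs) before
wild-bee functional diversity is safe?**

Solitary bees are grouped into *functional types* (FTs) — distinct
combinations of five traits: foraging distance (short/medium/long), diet
breadth (oligolectic/polylectic), flying period (first/second half of the
year, or both), nesting preference (hypogean/endogeic) and parasite-host
status.  Every dynamic parameter of a type is a table lookup on its traits.
The landscape is a raster of 20 m cells in six land-use classes (bare,
arable, forest, grassland, urban, water); an ABZ is an arable cell at the
border to grassland or forest that is set aside: never disturbed, with
nesting capacity and floral resources boosted by `trans_effect_nest` /
`trans_effect_res`.

Each simulated year every population (one type nesting in one cell) goes
through

1. **weather** — a global multiplier `~ N(1, 0.15)` truncated at 0;
2. **growth** — Maynard Smith–Slatkin density dependence with interspecific
   competition.  The heterospecific load in a cell is

   `β_j = Σ_i (1 + (c_j − c_i)/C_total) · N_i`   (nonconspecific `i`,
   overlapping flying periods only; `c` = competition factor, 0 strongest),

   entering twice: through the competition-dependent resource uptake
   `res_uptake = ((β_j + N_j)/N_total) · LU_suitability_forage`, averaged
   over the type's foraging disk, and through the nesting-site term

   `N' = N · R · weather · mean(res_uptake) / (1 + (R−1)·((N + β_nest)/K)^b)`;

3. **dispersal** — a density-dependent fraction
   `min(1, μ·(N/K)^ω)` emigrates; each individual searches with a truncated-
   normal dispersal kernel, accepting cells by nesting-suitability rank
   (pickiness relaxes over `dispersal_tries` attempts) and only below the
   nesting capacity; failed searchers die;
4. **disturbance** — arable patches every year, grassland patches with
   p = 0.8, forest/bare/urban cells with p = 0.3/0.7/0.7; a disturbed
   population is multiplied by `1 − dist_eff` (0.1 survival for soil-nesting
   endogeic types, 0.7 for hypogean ones).  ABZ cells are exempt.

Scenario runs convert 0–100% of the candidate ABZ cells (largest arable
patches first) and track richness, Shannon diversity, quasi-extinction risk
(dipping below an area-scaled threshold — 10,000 individuals per 9 km² — at
least once in the last decade), community-weighted trait means and per-cell
feeding intensity.  A one-at-a-time sensitivity harness perturbs the 16
named model parameters (±10%, ±25%, between-type spread ±50%, categorical
reversals).

## Worked example

```python
import numpy as np
from bitz import (SimulationConfig, SyntheticLandscapeConfig, apply_abz,
                  default_community, generate_synthetic_landscape, run_simulation)
from bitz.metrics import summarize_run

ls = generate_synthetic_landscape(
    SyntheticLandscapeConfig(n_rows=50, n_cols=50, mean_patch_area_cells=80.0, seed=11))
ls = apply_abz(ls, 0.25, np.random.default_rng(0))   # convert 25% of candidate cells
community = default_community(28, seed=1)
result = run_simulation(ls, community, SimulationConfig(years=50, repetitions=3, base_seed=7))
for key, value in summarize_run(result, ls, community).items():
    print(f"{key}: {value:.4f}")
```

prints

```
mean_richness: 5.3333
mean_richness_fraction: 0.1905
mean_shannon: 0.6425
mean_quasi_extinction_risk: 0.9524
cwm_foraging_range: 2.7517
cwm_flying_period: 3.0000
cwm_disturbance_susceptibility: 0.3440
```

meaning: on this 1 km² synthetic landscape about 5 of the 28 types still
have individuals after 50 years, the surviving community is uneven (Shannon
0.64 against a possible ln 28 ≈ 3.33), most types dipped below the
area-scaled quasi-extinction threshold in the last decade, and the survivors
skew towards long-ranging (foraging code near 3), bivoltine,
disturbance-insensitive (hypogean) types.  The `examples/` directory holds
one short script per capability: landscape generation, trait tables,
simulation, the ABZ scenario sweep, feeding-intensity maps and the
sensitivity analysis.  A thin CLI (`bitz gen-landscape / simulate /
scenarios / sensitivity`) wraps the same functions for shell use.

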