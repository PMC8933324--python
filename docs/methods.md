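# Methods

## Model overview

`bitz` simulates yearly dynamics of a community of functional solitary-bee
types (FTs) on a raster landscape.  A *population* is the set of individuals
of one type whose nest sits in one grid cell (default 20 × 20 m).  One
generation per year is assumed; bivoltine behaviour (two flying periods) is
represented through a higher resource uptake rather than a second explicit
generation.

### Traits and parameters

A type is a distinct combination of five traits; all parameters derive from
them by fixed lookups:

| parameter | driven by | values |
|---|---|---|
| growth rate `r` | foraging distance × parasite host | 2.5, 3, 3.5, 4, 4.5, 5 |
| competition factor `c` | foraging distance × diet | 0 (strongest) … 5 |
| forage suitability per class | diet × #flying periods | 0 – 1.5 (water 0) |
| nest suitability per class | nesting preference | 0 – 1 (water 0) |
| dispersal kernel mean/sd (m) | foraging distance | 600/60, 300/30, 100/10 |
| disturbance susceptibility `dist_eff` | nesting preference | hypogean 0.3, endogeic 0.9 |
| ABZ bonuses `trans_effect_nest`, `trans_effect_res` | — | 1.0 each |

The two nesting-suitability rows are used exactly as tabulated (hypogean:
forest-high; endogeic: bare-ground-high).  The alternative reading in which
the soil-nesting guild maps to the open-land row is available via
`derive_parameters(..., swap_nesting_rows=True)`; we do not guess an intent
and keep the tabulated rows as default.

### Yearly cycle

Order within a year: weather draw → growth → dispersal → disturbance.  The
listing order of the processes is the natural reading of the model cycle;
nothing in the dynamics depends on it except through composition.

**Growth.**  Synchronous across all populations (occupancies are computed
from the pre-step state, so the processing order of types is irrelevant).
The heterospecific load of type `j` in a cell is
`β_j = Σ_i (1 + (c_j − c_i)/C_total)·N_i` over nonconspecific types `i`
whose flying period overlaps `j`'s ("both" overlaps everything);
`C_total` sums the competition factors of all types present in the cell
(zero present types ⇒ the `c` correction is dropped), and `β` is clamped at
0.  The load enters twice:

* resource side — per-cell uptake `((β_j + F_j)/N_total) · suitability`,
  with `F` the foraging abundances (each population counts fully in every
  cell of its disk; the disk radius equals the dispersal-kernel mean) and
  `N_total` the overlapping-period foraging total.  The per-cell uptake is
  averaged over the whole foraging disk, including zero-suitability water
  cells; disks are clipped at the landscape border and averaged over
  in-bounds cells only.  `N_total = 0 ⇒` the ratio is 1.  As printed, this
  ratio *increases* with the load carried by weaker competitors; the
  orientation is debatable, so the reciprocal form is available as
  `uptake_form="inverted"` (the default keeps the printed form — see
  "Known limitations");
* nesting side — `β_nest`, the same formula evaluated on the nesting
  populations of the cell only, added 1:1 to the type's own density in the
  Maynard Smith–Slatkin map
  `N' = N·R·weather·mean_uptake / (1 + (R−1)·((N+β_nest)/K)^b)`.

The denominator is parenthesized so that `K` is the competition-free
equilibrium (the standard Maynard Smith–Slatkin form).  Nesting capacity is
`K = k_max · (nest_suitability + trans_effect_nest·abz)`; `K = 0` (water)
extinguishes the cell.  Populations below `extinction_threshold` (default
1.0 individual — one cannot have a fraction of a bee) are removed after
growth.

**Dispersal.**  Emigrant fraction `min(1, μ·(N/K)^ω)` (defaults μ = 0.2,
ω = 2; the simplest monotone form with a scale and a shape parameter),
rounded half-up and capped at ⌊N⌋; `K = 0` empties the cell.  Each emigrant
draws up to `dispersal_tries` (default 10) displacements — distance
truncated-normal (> 0) with the type's kernel, direction uniform, rounded to
the nearest cell.  Semidirected search: the land-use classes present within
the origin's foraging disk are ranked by nesting suitability (ties share a
rank; a flagged ABZ cell counts as its own pseudo-class, with the nesting
bonus, usually rank 1; a class absent from the disk is ranked where its
suitability would place it).  Attempt `k` accepts a target iff its class
rank ≤ `1 + ⌊(k−1)·n_ranks/tries⌋` — the first attempt accepts only the
top-ranked class and the window widens linearly — and the type's own
population there is strictly below its capacity.  Off-grid draws consume an
attempt (absorbing boundary); individuals exhausting their attempts are
removed.

`settle()` implements this per individual.  The engine's `dispersal_step`
processes all emigrants in attempt-synchronous rounds: every still-searching
individual draws its k-th displacement together, contention for the last
capacity slots of a cell is resolved in a seeded random individual order,
and occupancies update between acceptances.  This keeps the per-individual
semantics while allowing vectorization; it reorders individuals' attempts
relative to a strictly sequential walk, which changes no invariant
(conservation, capacity, determinism) and only reshuffles which stochastic
individual wins a contested slot.

**Disturbance.**  Arable and grassland patches are disturbed as wholes
(arable p = 1 yearly, grassland p = 0.8); forest, bare and urban cells
independently (p = 0.3, 0.7, 0.7); water never; ABZ cells never.  A
disturbed population is multiplied by `1 − dist_eff`.  The reduction is
taken as multiplicative survival, the simplest reading of a "type-specific
reduction".

### Scenarios

Candidate ABZ cells are arable cells sharing an edge (4-neighborhood;
8 available via config) with grassland or forest.  `apply_abz` flags
exactly `round_half_up(fraction · candidates)` of them, walking arable
patches in descending area order (ties by ascending patch id), permuting
each patch's candidates randomly and exhausting a patch before opening the
next; the sensitivity variant reverses the walk.  The layout is drawn once
per (landscape, fraction) and shared by all repetitions.  Repetition `r`
runs with seed `base_seed + r`; everything is bit-reproducible.

## Synthetic landscapes

The generator grows a random patch mosaic: class cell quotas are fixed up
front by largest-remainder apportionment of the target fractions (realized
composition is exact to one cell per class), then patches grow by seeded
random region growing with geometric patch sizes around random seed cells;
enclosed leftovers are filled from the remaining quotas.  The default
composition is the study region's (60% arable, 15% forest, 11% grassland,
6% bare, 5% water, 3% urban); the default mean patch area of 80 cells
(3.2 ha) gives a mosaic whose arable–natural edge density leaves roughly
9–10% of cells as ABZ candidates.  What the generator does *not* emulate:
real field geometry (elongated fields, road networks), spatial
autocorrelation between classes (lakes inside forests), and the paper-map
provenance of patch boundaries.  Passing tests on these mosaics therefore
shows the machinery is correct and the qualitative gradient is robust, not
that any specific real landscape would produce the same numbers.

## Analysis metrics

* richness: types with landscape total > 0;
* Shannon diversity: natural log, over positive totals;
* quasi-extinction risk: fraction of repetitions whose total dips below a
  threshold at least once in the last 10 years.  The landscape threshold is
  a density, 10,000 individuals per 9 km², scaled by landscape area so that
  smaller grids remain comparable; the land-use-class threshold is
  0.001 individuals/m² of class area.  Land-use-scale summaries cover all
  arable patches plus forest/grassland patches adjacent to arable land;
* community-weighted means: foraging range coded 1/2/3 (meters optional),
  flying period 1 (early) / 2 (late) / 3 (both), disturbance susceptibility
  = `dist_eff`;
* feeding intensity: per cell, Σ over foraging populations of population
  size × the same competition-dependent uptake used in growth.

## Sensitivity analysis

One parameter at a time: 14 numerical parameters (3 general — weather sd,
dispersal tries, disturbance probabilities; 11 type-specific) scaled by
±10% and ±25%; type-specific ones additionally spread-adjusted by ±50%
relative to the lowest value (`v' = v_min + (v−v_min)·(1±0.5)`); two
categorical reversals (ABZ patch walk ascending; competition factors
`c ↦ 5−c`).  `dispersal_tries` rounds to an integer ≥ 1; parameters with a
[0, 1] domain (`dist_eff`, `emigration_mu`) are clipped after perturbation.
Endpoints are final-year mean richness and Shannon diversity, reported as
relative change against the baseline mean at the same ABZ fraction.  A
spread variant of a parameter that is constant across types is a no-op by
construction and is reported with relative change ≈ 0.

## Numerical choices

* Foraging-disk sums are computed by decomposing the disk into horizontal
  segments over per-row prefix sums — exact zeros are preserved (needed for
  presence masks) and results match direct convolution to ~1e-13.
* The vectorized growth step is cross-checked against a literal per-cell,
  per-type scalar implementation on 1,000 random 5×5 instances (max
  deviation ≤ 1e-10).
* Weather truncation at 0 uses rejection sampling; `weather_std = 0` returns
  exactly 1.
* All randomness flows through explicitly passed `numpy` generators.

## Known limitations

* **Community-level coexistence is knife-edge under the default equation
  set.**  Single types reproduce the intended regime well: run alone on the
  default 1 km² mosaic, roughly half the types persist without ABZs (soil
  nesters are excluded by the yearly disturbance regime) and all 28 persist
  once ≥ 25% of candidate cells are converted, with totals of 10³–10⁴.  In
  the full 28-type community, however, the heterospecific nesting load
  `β_nest` enters the density term with coefficients ≈ 1, which makes
  nesting competition near-neutral-to-hierarchical Lotka–Volterra; combined
  with continuous populations and the 1-individual extinction threshold,
  most types are competitively excluded within 50 years and community
  persistence stays far below the single-type picture at every ABZ
  fraction.  Disabling `β_nest` experimentally restores the single-type
  regime (richness saturating and risks collapsing along the ABZ gradient),
  so conclusions about absolute community-level persistence are sensitive
  to exactly how nesting-site competition is composed into the growth map —
  a genuinely open reading of the model equations.  The package implements
  the printed composition; treat absolute community-level persistence
  percentages with caution and the ABZ gradient's direction as the robust
  result.
* The printed resource-uptake ratio rewards weaker competitors with larger
  uptake; both orientations are provided and neither changes the exclusion
  picture above (the inverted form is harsher).
* No within-year phenology, no distance-weighted foraging, no disturbance
  spill-over between cells, no habitat-connectivity routing of dispersal.
* Problem sizes: the shipped experiments use 50×50-cell (1 km²) landscapes
  with 10 repetitions × 50 years; the engine handles the full 150×150 case
  with identical code (≈ 9× cost).
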