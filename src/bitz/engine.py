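"""Simulation scheduling: initialization, the yearly loop, repetitions and scenarios.

A year consists of (1) a global weather draw, (2) synchronous growth of all
populations, (3) density-dependent emigration and settlement, (4) the yearly
disturbance draw and kill.  A simulation runs a fixed number of years and is
repeated independently; repetition ``r`` uses seed ``base_seed + r``.  A
scenario grid reruns the simulation for a list of buffer-zone fractions; the
buffer-zone layout is drawn once per (landscape, fraction) — seeded
independently of the repetitions — and held fixed, so all repetitions of a
scenario share one layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import SimulationConfig
from .disturbance import apply_disturbance, draw_disturbance_mask
from .dispersal import build_rank_tables, dispersal_step
from .dynamics import PopulationState, draw_weather, growth_step
from .functional_types import FTCommunity
from .landscape import Landscape, LandUseClass, apply_abz

#: land-use classes reported in the land-use-scale summaries
SUMMARY_CLASSES = (LandUseClass.ARABLE, LandUseClass.FOREST, LandUseClass.GRASSLAND)


def initialize(
    ls: Landscape,
    community: FTCommunity,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> PopulationState:
    """Place ``initial_individuals_per_ft`` individuals per type uniformly on non-water cells."""
    habitable = np.flatnonzero((ls.land_use != LandUseClass.WATER).ravel())
    if habitable.size == 0:
        raise ValueError("landscape is all water: nowhere to initialize populations")
    S = community.size
    abundance = np.zeros((S, ls.n_rows, ls.n_cols))
    n = config.initial_individuals_per_ft
    for j in range(S):
        cells = habitable[rng.integers(0, habitable.size, size=n)]
        counts = np.bincount(cells, minlength=ls.n_cells)
        abundance[j] = counts.reshape(ls.n_rows, ls.n_cols)
    return PopulationState(abundance, year=0)


def run_year(
    state: PopulationState,
    ls: Landscape,
    community: FTCommunity,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    rank_tables=None,
) -> PopulationState:
    """One simulated year: weather, growth, dispersal, disturbance."""
    weather = draw_weather(rng, config.weather_std)
    state = growth_step(state, ls, community, weather, config)
    state = dispersal_step(state, ls, community, config, rng, rank_tables=rank_tables)
    mask = draw_disturbance_mask(ls, config.disturbance, rng)
    state = apply_disturbance(state, mask, community)
    state.year += 1
    return state


def included_class_masks(ls: Landscape) -> dict[int, np.ndarray]:
    """Cell masks for land-use-scale analyses.

    All arable cells are included; forest and grassland cells only if their
    patch touches (4-adjacency) an arable cell — buffer zones are arable, so
    patches adjacent only to buffer zones are included too.
    """
    arable = ls.land_use == LandUseClass.ARABLE
    cross = ndimage.generate_binary_structure(2, 1)
    near_arable = ndimage.binary_dilation(arable, structure=cross)
    masks: dict[int, np.ndarray] = {int(LandUseClass.ARABLE): arable}
    for cls in (LandUseClass.FOREST, LandUseClass.GRASSLAND):
        cls_mask = ls.land_use == cls
        touching = np.unique(ls.patch_id[cls_mask & near_arable])
        masks[int(cls)] = cls_mask & np.isin(ls.patch_id, touching)
    return masks


@dataclass
class RunResult:
    """Yearly per-type abundance series over repetitions, plus metadata.

    ``series`` has shape (repetitions, years+1, S) of landscape totals,
    including the initial state; ``landuse_series`` (repetitions, years+1, S,
    3) holds the totals over the included arable / forest / grassland cells.
    """

    series: np.ndarray
    ft_ids: list[str]
    seeds: list[int]
    config_hash: str
    landuse_series: np.ndarray | None = None
    final_abundance: np.ndarray | None = None  # (repetitions, S, R, C)
    abz_fraction: float | None = None
    landscape_id: str | None = None

    @property
    def repetitions(self) -> int:
        return self.series.shape[0]

    @property
    def years(self) -> int:
        return self.series.shape[1] - 1

    def to_frame(self) -> pd.DataFrame:
        reps, t, S = self.series.shape
        rep_i, year_i, ft_i = np.meshgrid(
            np.arange(reps), np.arange(t), np.arange(S), indexing="ij"
        )
        return pd.DataFrame(
            {
                "landscape": self.landscape_id if self.landscape_id is not None else "ls0",
                "fraction": self.abz_fraction if self.abz_fraction is not None else 0.0,
                "repetition": rep_i.ravel(),
                "year": year_i.ravel(),
                "ft": np.array(self.ft_ids)[ft_i.ravel()],
                "abundance": self.series.ravel(),
            }
        )


def run_simulation(
    ls: Landscape,
    community: FTCommunity,
    config: SimulationConfig,
) -> RunResult:
    """Run ``config.repetitions`` independent simulations of ``config.years`` years."""
    S = community.size
    reps, years = config.repetitions, config.years
    series = np.zeros((reps, years + 1, S))
    landuse_series = np.zeros((reps, years + 1, S, len(SUMMARY_CLASSES)))
    final = np.zeros((reps, S, ls.n_rows, ls.n_cols)) if config.store_final_state else None
    masks = included_class_masks(ls)
    mask_list = [masks[int(c)] for c in SUMMARY_CLASSES]
    rank_tables = build_rank_tables(ls, community)
    seeds = [config.base_seed + r for r in range(reps)]

    for rep, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        state = initialize(ls, community, config, rng)
        series[rep, 0] = state.totals()
        for k, m in enumerate(mask_list):
            landuse_series[rep, 0, :, k] = state.abundance[:, m].sum(axis=1)
        for year in range(1, years + 1):
            state = run_year(state, ls, community, config, rng, rank_tables=rank_tables)
            series[rep, year] = state.totals()
            for k, m in enumerate(mask_list):
                landuse_series[rep, year, :, k] = state.abundance[:, m].sum(axis=1)
        if final is not None:
            final[rep] = state.abundance
    return RunResult(
        series=series,
        ft_ids=community.ft_ids(),
        seeds=seeds,
        config_hash=config.config_hash(),
        landuse_series=landuse_series,
        final_abundance=final,
    )


DEFAULT_ABZ_FRACTIONS = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.50, 0.75, 1.0)


@dataclass
class ScenarioSpec:
    """Scenario grid: buffer-zone fractions crossed with landscapes."""

    abz_fractions: tuple[float, ...] = DEFAULT_ABZ_FRACTIONS
    landscapes: list[tuple[str, Landscape]] = field(default_factory=list)

    def __post_init__(self) -> None:
        fr = tuple(sorted(set(float(f) for f in self.abz_fractions)))
        if any(not 0.0 <= f <= 1.0 for f in fr):
            raise ValueError("ABZ fractions must lie in [0, 1]")
        self.abz_fractions = fr


def _abz_rng(base_seed: int, landscape_index: int, fraction: float) -> np.random.Generator:
    # layout seeded by scenario, not repetition: repetitions share one layout
    return np.random.default_rng([base_seed, landscape_index, int(round(fraction * 10_000))])


@dataclass
class ScenarioResults:
    table: pd.DataFrame
    runs: dict[tuple[str, float], RunResult]
    landscapes: dict[tuple[str, float], Landscape]


def run_scenarios(
    spec: ScenarioSpec,
    community: FTCommunity,
    config: SimulationConfig,
) -> ScenarioResults:
    """Apply each buffer-zone fraction once per landscape, then run the simulation."""
    frames = []
    runs: dict[tuple[str, float], RunResult] = {}
    landscapes: dict[tuple[str, float], Landscape] = {}
    for lidx, (lid, ls) in enumerate(spec.landscapes):
        for fraction in spec.abz_fractions:
            ls_abz = apply_abz(
                ls,
                fraction,
                _abz_rng(config.base_seed, lidx, fraction),
                neighborhood=config.abz_neighborhood,
                order=config.abz_order,
            )
            result = run_simulation(ls_abz, community, config)
            result.abz_fraction = fraction
            result.landscape_id = lid
            runs[(lid, fraction)] = result
            landscapes[(lid, fraction)] = ls_abz
            frames.append(result.to_frame())
    table = pd.concat(frames, ignore_index=True)
    return ScenarioResults(table=table, runs=runs, landscapes=landscapes)
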