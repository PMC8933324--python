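"""Population growth: weather, foraging geometry, competition and density dependence.

A population is the set of same-type individuals nesting in one grid cell.
Each year every population

1. forages over a disk of radius equal to its type's dispersal-kernel mean
   (100/300/600 m), experiencing interspecific competition in every visited
   cell through the heterospecific load

       beta_j = sum_i (1 + (c_j - c_i) / C_total) * N_i        (nonconspecific i)

   where ``c`` are the competition factors (0 strongest … 5 weakest) and
   ``C_total`` sums the factors of all types present in the cell; only types
   with overlapping flying periods interact;

2. takes up resources in each visited cell,

       res_uptake = ((beta_j + N_j) / N_total) * LU_suitability_forage,

   averaged over the whole foraging disk (the ``inverted`` form replaces the
   ratio by its reciprocal; see the methods note), buffer-zone cells adding
   ``trans_effect_res`` to the suitability;

3. grows by the Maynard Smith–Slatkin map with the heterospecific nesting
   load added to its own density:

       N' = N * R * weather * mean_uptake / (1 + (R-1) * ((N + beta_nest)/K)^b)

   with nesting capacity ``K = k_max * (LU_suitability_nest + trans_effect_nest
   * abz)``; populations falling below the extinction threshold are removed.

The update is synchronous: all occupancies are computed from the pre-step
state.  ``growth_step`` is the vectorized engine path; the scalar functions
mirror it one cell at a time and are the reference surface for testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .functional_types import FTCommunity, FlyingPeriod
from .landscape import Landscape


@dataclass(frozen=True)
class WeatherState:
    """Global yearly growth multiplier, ~Normal(1, weather_std) truncated at 0."""

    factor: float


def draw_weather(rng: np.random.Generator, weather_std: float) -> WeatherState:
    if weather_std < 0:
        raise ValueError("weather_std must be >= 0")
    if weather_std == 0:
        return WeatherState(1.0)
    while True:  # rejection sampling = truncation at 0
        value = rng.normal(1.0, weather_std)
        if value >= 0:
            return WeatherState(float(value))


@dataclass
class PopulationState:
    """Per-cell, per-type abundances for one year: array (S, n_rows, n_cols)."""

    abundance: np.ndarray
    year: int = 0

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.ndim != 3:
            raise ValueError("abundance must be a 3-D (ft, row, col) array")
        if np.any(self.abundance < 0):
            raise ValueError("abundances must be nonnegative")

    @property
    def n_types(self) -> int:
        return self.abundance.shape[0]

    def totals(self) -> np.ndarray:
        """Per-type landscape totals."""
        return self.abundance.sum(axis=(1, 2))

    def copy(self) -> "PopulationState":
        return PopulationState(self.abundance.copy(), self.year)


# ---------------------------------------------------------------------------
# Foraging geometry
# ---------------------------------------------------------------------------

_KERNEL_CACHE: dict[float, np.ndarray] = {}
_COUNT_CACHE: dict[tuple[float, tuple[int, int]], np.ndarray] = {}


def disk_offsets(radius_cells: float) -> list[tuple[int, int]]:
    """Integer (drow, dcol) offsets with center distance <= radius (includes (0,0))."""
    rmax = int(math.floor(radius_cells))
    out = []
    for dr in range(-rmax, rmax + 1):
        for dc in range(-rmax, rmax + 1):
            if dr * dr + dc * dc <= radius_cells * radius_cells:
                out.append((dr, dc))
    return out


def disk_kernel(radius_cells: float) -> np.ndarray:
    """Binary disk kernel for foraging convolutions (cached)."""
    key = round(float(radius_cells), 9)
    if key not in _KERNEL_CACHE:
        rmax = int(math.floor(radius_cells))
        size = 2 * rmax + 1
        k = np.zeros((size, size), dtype=float)
        for dr, dc in disk_offsets(radius_cells):
            k[dr + rmax, dc + rmax] = 1.0
        _KERNEL_CACHE[key] = k
    return _KERNEL_CACHE[key]


def foraging_radius_cells(disp_mean_m: float, cell_size_m: float) -> float:
    return disp_mean_m / cell_size_m


def foraging_cells(ls: Landscape, cell: tuple[int, int], disp_mean_m: float) -> set[tuple[int, int]]:
    """All in-bounds cells within the foraging radius of ``cell`` (incl. the focal cell)."""
    radius = foraging_radius_cells(disp_mean_m, ls.cell_size_m)
    r0, c0 = cell
    out = set()
    for dr, dc in disk_offsets(radius):
        r, c = r0 + dr, c0 + dc
        if 0 <= r < ls.n_rows and 0 <= c < ls.n_cols:
            out.add((r, c))
    return out


def _conv_disk(field: np.ndarray, radius_cells: float) -> np.ndarray:
    """Sum of ``field`` over the disk around each cell (zero outside the grid).

    The disk is decomposed into horizontal segments; each segment width is a
    sliding box sum over per-row prefix sums.  Exact zeros are preserved (the
    two prefix values of an all-zero interval are identical floats), which the
    presence masks rely on.
    """
    rmax = int(math.floor(radius_cells))
    R, C = field.shape
    r2 = radius_cells * radius_cells
    widths = [int(math.floor(math.sqrt(r2 - dr * dr))) for dr in range(rmax + 1)]

    cs = np.zeros((R, C + 1), dtype=float)
    np.cumsum(field, axis=1, out=cs[:, 1:])
    cols = np.arange(C)
    box: dict[int, np.ndarray] = {}
    for w in set(widths):
        hi = np.minimum(cols + w + 1, C)
        lo = np.maximum(cols - w, 0)
        box[w] = cs[:, hi] - cs[:, lo]

    out = np.zeros_like(field)
    for dr in range(-rmax, rmax + 1):
        if abs(dr) >= R:  # segment row entirely off-grid
            continue
        B = box[widths[abs(dr)]]
        if dr >= 0:
            out[: R - dr] += B[dr:]
        else:
            out[-dr:] += B[: R + dr]
    return out


# ---------------------------------------------------------------------------
# Scalar per-cell operations (reference surface)
# ---------------------------------------------------------------------------


@dataclass
class CellOccupancy:
    """Per-type occupancy of one cell: nesting and foraging abundances.

    ``foraging[i]`` sums all type-i populations whose foraging disk covers the
    cell (which includes any population nesting there).
    """

    nesting: np.ndarray
    foraging: np.ndarray
    community: FTCommunity

    def __post_init__(self) -> None:
        self.nesting = np.asarray(self.nesting, dtype=float)
        self.foraging = np.asarray(self.foraging, dtype=float)

    def _abundance(self, basis: str) -> np.ndarray:
        if basis == "foraging":
            return self.foraging
        if basis == "nesting":
            return self.nesting
        raise ValueError("basis must be 'foraging' or 'nesting'")

    def c_total(self, basis: str = "foraging") -> float:
        """Sum of competition factors of all types present in the cell."""
        if basis == "foraging":
            present = (self.foraging > 0) | (self.nesting > 0)
        else:
            present = self.nesting > 0
        return float(np.sum(self.community.c_array()[present]))

    def n_total(self, j: int) -> float:
        """All individuals foraging in the cell whose flying period overlaps type j."""
        overlap = self.community.overlap_matrix()[j]
        return float(np.sum(self.foraging[overlap]))


def competition_load(occ: CellOccupancy, j: int, basis: str = "foraging") -> float:
    """Heterospecific load beta_j in one cell (types without period overlap excluded)."""
    comm = occ.community
    abundance = occ._abundance(basis)
    c = comm.c_array()
    overlap = comm.overlap_matrix()[j]
    c_total = occ.c_total(basis)
    beta = 0.0
    for i in range(comm.size):
        if i == j or not overlap[i] or abundance[i] == 0:
            continue
        term = 1.0 + ((c[j] - c[i]) / c_total if c_total > 0 else 0.0)
        beta += term * abundance[i]
    return max(beta, 0.0)


def cell_resource_uptake(
    occ: CellOccupancy,
    j: int,
    land_use: int,
    abz_flag: bool,
    form: str = "printed",
) -> float:
    """Competition-dependent resource uptake of type j in one cell."""
    comm = occ.community
    params = comm.parameters[j]
    suit = params.forage_suitability[int(land_use)]
    if abz_flag:
        suit += params.trans_effect_res
    beta = competition_load(occ, j, basis="foraging")
    n_j = float(occ.foraging[j])
    n_total = occ.n_total(j)
    if form == "printed":
        ratio = (beta + n_j) / n_total if n_total > 0 else 1.0
    elif form == "inverted":
        ratio = n_total / (beta + n_j) if (beta + n_j) > 0 else 1.0
    else:
        raise ValueError("form must be 'printed' or 'inverted'")
    return ratio * suit


def _foraging_fields(state: PopulationState, ls: Landscape, community: FTCommunity) -> np.ndarray:
    """(S, R, C) foraging abundance: each population summed over its foraging disk."""
    S = community.size
    out = np.empty_like(state.abundance)
    for j in range(S):
        radius = foraging_radius_cells(community.parameters[j].disp_mean, ls.cell_size_m)
        out[j] = _conv_disk(state.abundance[j], radius)
    return out


def mean_resource_uptake(
    state: PopulationState,
    ls: Landscape,
    nest_cell: tuple[int, int],
    j: int,
    community: FTCommunity,
    form: str = "printed",
) -> float:
    """Average uptake of the population of type j nesting at ``nest_cell`` over its disk.

    Scalar reference implementation: loops over the foraging cells, including
    zero-suitability ones; boundary-clipped disks average in-bounds cells only.
    """
    foraging = _foraging_fields(state, ls, community)
    cells = foraging_cells(ls, nest_cell, community.parameters[j].disp_mean)
    total = 0.0
    for r, c in cells:
        occ = CellOccupancy(
            nesting=state.abundance[:, r, c], foraging=foraging[:, r, c], community=community
        )
        total += cell_resource_uptake(
            occ, j, int(ls.land_use[r, c]), bool(ls.abz[r, c]), form=form
        )
    return total / len(cells)


def nest_capacity(ls: Landscape, cell: tuple[int, int], j: int, community: FTCommunity, k_max: float) -> float:
    """Nesting capacity K of type j in one cell (k_max * suitability, + buffer bonus)."""
    if k_max <= 0:
        raise ValueError("k_max must be > 0")
    params = community.parameters[j]
    suit = params.nest_suitability[int(ls.land_use[cell])]
    if ls.abz[cell]:
        suit += params.trans_effect_nest
    return k_max * suit


def nest_capacity_grids(ls: Landscape, community: FTCommunity, k_max: float) -> np.ndarray:
    """(S, R, C) nesting capacities for every type and cell."""
    suit = community.nest_suit_matrix()[:, ls.land_use]  # (S, R, C)
    bonus = community.trans_nest_array()[:, None, None] * ls.abz[None, :, :]
    return k_max * (suit + bonus)


def grow(
    N: float,
    r: float,
    K: float,
    beta_nest: float,
    mean_uptake: float,
    weather: float,
    b: float = 1.0,
    extinction_threshold: float = 1.0,
) -> float:
    """One Maynard Smith–Slatkin step for a single population (scalar reference)."""
    if N < 0 or K < 0:
        raise ValueError("N and K must be nonnegative")
    if K == 0 or N == 0:
        return 0.0
    dens = (N + beta_nest) / K
    n_next = N * r * weather * mean_uptake / (1.0 + (r - 1.0) * dens**b)
    return n_next if n_next >= extinction_threshold else 0.0


# ---------------------------------------------------------------------------
# Vectorized growth step
# ---------------------------------------------------------------------------

_PERIODS = (FlyingPeriod.FIRST, FlyingPeriod.SECOND, FlyingPeriod.BOTH)


def _period_groups(community: FTCommunity) -> tuple[np.ndarray, list[np.ndarray]]:
    """Period index per type, and for each type the boolean mask of overlapping types."""
    period_idx = np.array([_PERIODS.index(p.flying_period) for p in community.profiles])
    overlap = community.overlap_matrix()
    return period_idx, [overlap[j] for j in range(community.size)]


def _beta_fields(
    abundance: np.ndarray,
    community: FTCommunity,
    presence: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized beta_j and N_total_j fields for every type.

    ``abundance``: (S, R, C) per-type abundance entering the load (foraging or
    nesting); ``presence``: (S, R, C) boolean membership for the C_total sum.
    Returns (beta, n_total), each (S, R, C).
    """
    c = community.c_array()
    overlap = community.overlap_matrix()
    c_total = np.tensordot(c, presence.astype(float), axes=(0, 0))  # (R, C)
    safe_ct = np.where(c_total > 0, c_total, 1.0)

    S = community.size
    beta = np.empty_like(abundance)
    n_total = np.empty_like(abundance)
    # group sums over overlapping types, then remove the conspecific share
    sum_a = np.empty((S,) + abundance.shape[1:])
    sum_ca = np.empty_like(sum_a)
    for j in range(S):
        mask = overlap[j]
        sum_a[j] = abundance[mask].sum(axis=0)
        sum_ca[j] = (c[mask, None, None] * abundance[mask]).sum(axis=0)
    for j in range(S):
        s_n = sum_a[j] - abundance[j]
        s_c = sum_ca[j] - c[j] * abundance[j]
        correction = np.where(c_total > 0, (c[j] * s_n - s_c) / safe_ct, 0.0)
        beta[j] = np.maximum(s_n + correction, 0.0)
        n_total[j] = sum_a[j]
    return beta, n_total


def resource_uptake_fields(
    state: PopulationState,
    ls: Landscape,
    community: FTCommunity,
    form: str = "printed",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell uptake and foraging-abundance fields for every type.

    Returns ``(uptake, foraging)``, each (S, R, C).  ``uptake[j]`` is the
    competition-dependent resource uptake a type-j population realizes in each
    cell; it is only meaningful (and only used) where type j actually forages.
    """
    foraging = _foraging_fields(state, ls, community)
    presence = (foraging > 0) | (state.abundance > 0)
    beta, n_total = _beta_fields(foraging, community, presence)

    suit = community.forage_suit_matrix()[:, ls.land_use]  # (S, R, C)
    suit = suit + community.trans_res_array()[:, None, None] * ls.abz[None, :, :]
    if form == "printed":
        num, den = beta + foraging, n_total
    elif form == "inverted":
        num, den = n_total, beta + foraging
    else:
        raise ValueError("form must be 'printed' or 'inverted'")
    ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
    return ratio * suit, foraging


def growth_step(
    state: PopulationState,
    ls: Landscape,
    community: FTCommunity,
    weather: WeatherState,
    config: SimulationConfig,
) -> PopulationState:
    """Synchronous growth of every population from the pre-step occupancies."""
    N = state.abundance
    uptake, _ = resource_uptake_fields(state, ls, community, form=config.uptake_form)

    S = community.size
    mean_uptake = np.empty_like(N)
    for j in range(S):
        radius = foraging_radius_cells(community.parameters[j].disp_mean, ls.cell_size_m)
        key = (round(radius, 9), N.shape[1:])
        if key not in _COUNT_CACHE:  # in-bounds disk sizes per cell
            _COUNT_CACHE[key] = _conv_disk(np.ones(N.shape[1:]), radius)
        mean_uptake[j] = _conv_disk(uptake[j], radius) / _COUNT_CACHE[key]

    beta_nest, _ = _beta_fields(N, community, N > 0)
    K = nest_capacity_grids(ls, community, config.k_max)
    r = community.r_array()[:, None, None]
    b = community.b_array()[:, None, None]

    safe_K = np.where(K > 0, K, 1.0)
    dens = (N + beta_nest) / safe_K
    n_next = N * r * weather.factor * mean_uptake / (1.0 + (r - 1.0) * dens**b)
    n_next = np.where((K > 0) & (N > 0), n_next, 0.0)
    n_next[n_next < config.extinction_threshold] = 0.0
    return PopulationState(n_next, state.year)
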