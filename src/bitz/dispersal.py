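"""Density-dependent emigration and semidirected random settlement.

Each year a density-dependent fraction of every population emigrates,

    f = min(1, emigration_mu * (N/K)^emigration_omega),

without regard to interspecific competition.  Every emigrant searches for a
new nesting cell by drawing displacements from its type's dispersal kernel
(distance ~ Normal(disp_mean, disp_sd) truncated at 0, uniform direction).
The search is semidirected: land-use classes within the origin's foraging
range are ranked by nesting suitability (a buffer-zone cell counts as its own
class, usually the best), and an attempt succeeds only if the target cell's
class rank is within the acceptance window

    rank <= 1 + floor((k - 1) * n_ranks / dispersal_tries)     (attempt k),

so the first attempt accepts only the top-ranked class and pickiness relaxes
as attempts are used up, and only if the type's nesting
population in the target cell is below its nesting capacity.  Individuals
exhausting ``dispersal_tries`` attempts (out-of-grid draws count as failed
attempts) die or leave the landscape.

``settle`` implements the per-individual search literally.  ``dispersal_step``
processes all emigrants attempt-round by attempt-round: within a round every
still-searching individual draws one displacement, and contention for the last
capacity slots of a cell is resolved in a seeded random individual order, with
occupancies updated as settlers arrive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import DispersalConfig, SimulationConfig
from .dynamics import PopulationState, disk_kernel, foraging_radius_cells, nest_capacity_grids
from .functional_types import FTCommunity, FTParameters
from .landscape import Landscape, LandUseClass, round_half_up

#: pseudo-class index for buffer-zone cells in the settlement ranking
ABZ_CLASS = 6
_N_RANK_CLASSES = 7


def emigrant_count(
    N: float,
    K: float,
    mu: float,
    omega: float,
) -> int:
    """Number of emigrants from a population of size N at capacity K.

    The expected emigrant fraction is min(1, mu * (N/K)^omega); the realized
    count is that fraction of N rounded, never exceeding floor(N).  K = 0
    means the site is uninhabitable and everyone leaves.
    """
    if N <= 0:
        return 0
    frac = 1.0 if K <= 0 else min(1.0, mu * (N / K) ** omega)
    return min(round_half_up(frac * N), int(math.floor(N)))


def sample_displacement(
    ft: FTParameters, rng: np.random.Generator
) -> tuple[float, float]:
    """One kernel draw: (dx_m, dy_m) with |d| ~ TruncNormal(disp_mean, disp_sd, > 0)."""
    while True:
        dist = rng.normal(ft.disp_mean, ft.disp_sd)
        if dist > 0:
            break
    theta = rng.uniform(0.0, 2.0 * math.pi)
    return dist * math.cos(theta), dist * math.sin(theta)


def displacement_cells(dx_m: float, dy_m: float, cell_size_m: float) -> tuple[int, int]:
    """Convert a metric displacement to a (drow, dcol) cell offset (nearest cell)."""
    return round_half_up(dy_m / cell_size_m), round_half_up(dx_m / cell_size_m)


# ---------------------------------------------------------------------------
# Suitability ranking of target classes per origin cell
# ---------------------------------------------------------------------------


def _rank_class_grid(ls: Landscape) -> np.ndarray:
    """Land-use class per cell for ranking purposes (buffer zones as class 6)."""
    cls = ls.land_use.astype(np.int16).copy()
    cls[ls.abz] = ABZ_CLASS
    return cls


def _effective_nest_suits(community: FTCommunity) -> np.ndarray:
    """(S, 7) nesting suitability per ranking class (6 = buffer zone, with bonus)."""
    suits = np.zeros((community.size, _N_RANK_CLASSES))
    suits[:, : _N_RANK_CLASSES - 1] = community.nest_suit_matrix()
    suits[:, ABZ_CLASS] = (
        community.nest_suit_matrix()[:, int(LandUseClass.ARABLE)]
        + community.trans_nest_array()
    )
    return suits


def build_rank_tables(
    ls: Landscape, community: FTCommunity
) -> tuple[np.ndarray, np.ndarray]:
    """Per-type settlement rank tables.

    Returns ``(rank, n_ranks)``: ``rank[j, r, c, cls]`` is the suitability rank
    (1 = best) class ``cls`` would hold among the distinct suitability values of
    the classes present within the foraging range of origin (r, c) for type j;
    ``n_ranks[j, r, c]`` is the number of distinct suitability levels present.
    Classes sharing a suitability value share a rank.
    """
    S = community.size
    shape = ls.land_use.shape
    cls_grid = _rank_class_grid(ls)
    class_masks = [cls_grid == c for c in range(_N_RANK_CLASSES)]
    suits = _effective_nest_suits(community)

    rank = np.zeros((S,) + shape + (_N_RANK_CLASSES,), dtype=np.int8)
    n_ranks = np.zeros((S,) + shape, dtype=np.int8)
    radii = {}
    for j in range(S):
        radius = foraging_radius_cells(community.parameters[j].disp_mean, ls.cell_size_m)
        key = round(radius, 9)
        if key not in radii:
            kernel = disk_kernel(radius).astype(bool)
            radii[key] = [
                ndimage.binary_dilation(m, structure=kernel) if m.any() else np.zeros(shape, bool)
                for m in class_masks
            ]
        present = radii[key]  # class present within range of each origin cell
        values = np.unique(suits[j])
        # presence of each distinct suitability value within range
        value_present = []
        for v in values:
            vm = np.zeros(shape, dtype=bool)
            for c in range(_N_RANK_CLASSES):
                if suits[j, c] == v:
                    vm |= present[c]
            value_present.append(vm)
        n_ranks[j] = np.sum(value_present, axis=0)
        for c in range(_N_RANK_CLASSES):
            better = np.zeros(shape, dtype=np.int8)
            for v, vm in zip(values, value_present):
                if v > suits[j, c]:
                    better += vm
            rank[j, :, :, c] = 1 + better
    return rank, n_ranks


# ---------------------------------------------------------------------------
# Per-individual settlement (reference) and the vectorized step
# ---------------------------------------------------------------------------


def settle(
    origin: tuple[int, int],
    j: int,
    state: PopulationState,
    ls: Landscape,
    community: FTCommunity,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    rank_tables: tuple[np.ndarray, np.ndarray] | None = None,
    capacities: np.ndarray | None = None,
) -> tuple[int, int] | None:
    """Settle one emigrant of type j from ``origin``; None = died / left the landscape."""
    if rank_tables is None:
        rank_tables = build_rank_tables(ls, community)
    rank, n_ranks = rank_tables
    if capacities is None:
        capacities = nest_capacity_grids(ls, community, config.k_max)
    cls_grid = _rank_class_grid(ls)
    tries = config.dispersal.dispersal_tries
    n_levels = int(n_ranks[j][origin])
    params = community.parameters[j]
    for k in range(1, tries + 1):
        dx, dy = sample_displacement(params, rng)
        dr, dc = displacement_cells(dx, dy, ls.cell_size_m)
        r, c = origin[0] + dr, origin[1] + dc
        if not (0 <= r < ls.n_rows and 0 <= c < ls.n_cols):
            continue  # left the grid: attempt consumed
        threshold = 1 + ((k - 1) * n_levels) // tries
        if rank[j, origin[0], origin[1], cls_grid[r, c]] > threshold:
            continue
        if state.abundance[j, r, c] < capacities[j, r, c]:
            state.abundance[j, r, c] += 1
            return (r, c)
    return None


def _emigration_rates(
    community: FTCommunity, config: DispersalConfig
) -> tuple[np.ndarray, np.ndarray]:
    mu = community.emigration_mu_array()
    omega = community.emigration_omega_array()
    if config.emigration_mu is not None:
        mu = np.full_like(mu, config.emigration_mu)
    if config.emigration_omega is not None:
        omega = np.full_like(omega, config.emigration_omega)
    return mu, omega


def dispersal_step(
    state: PopulationState,
    ls: Landscape,
    community: FTCommunity,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    rank_tables: tuple[np.ndarray, np.ndarray] | None = None,
) -> PopulationState:
    """Emigration + settlement for every population; total abundance never increases."""
    if rank_tables is None:
        rank_tables = build_rank_tables(ls, community)
    rank, n_ranks = rank_tables
    K = nest_capacity_grids(ls, community, config.k_max)
    mu, omega = _emigration_rates(community, config.dispersal)

    N = state.abundance.copy()
    safe_K = np.where(K > 0, K, 1.0)
    frac = np.minimum(1.0, mu[:, None, None] * (N / safe_K) ** omega[:, None, None])
    frac = np.where(K > 0, frac, 1.0)
    emigrants = np.minimum(np.floor(frac * N + 0.5), np.floor(N)).astype(np.int64)
    emigrants[N <= 0] = 0
    total = int(emigrants.sum())
    out = PopulationState(N, state.year)
    if total == 0:
        return out

    ft_idx, rows, cols = np.nonzero(emigrants)
    counts = emigrants[ft_idx, rows, cols]
    ind_ft = np.repeat(ft_idx, counts)
    ind_r = np.repeat(rows, counts)
    ind_c = np.repeat(cols, counts)
    N[ft_idx, rows, cols] -= counts

    # seeded random processing priority over all individuals
    order = rng.permutation(total)
    ind_ft, ind_r, ind_c = ind_ft[order], ind_r[order], ind_c[order]

    n_rows, n_cols = ls.n_rows, ls.n_cols
    cls_grid = _rank_class_grid(ls)
    mean = community.disp_mean_array()
    sd = community.disp_sd_array()
    tries = config.dispersal.dispersal_tries
    cell = ls.cell_size_m
    Nflat = N.reshape(-1)
    Kflat = K.reshape(-1)

    alive = np.ones(total, dtype=bool)
    for k in range(1, tries + 1):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        m = idx.size
        ft = ind_ft[idx]
        dist = rng.normal(mean[ft], sd[ft])
        bad = dist <= 0
        while bad.any():  # truncation at 0 by rejection
            dist[bad] = rng.normal(mean[ft][bad], sd[ft][bad])
            bad = dist <= 0
        theta = rng.uniform(0.0, 2.0 * math.pi, m)
        dr = np.floor(dist * np.sin(theta) / cell + 0.5).astype(np.int64)
        dc = np.floor(dist * np.cos(theta) / cell + 0.5).astype(np.int64)
        tr = ind_r[idx] + dr
        tc = ind_c[idx] + dc
        inb = (tr >= 0) & (tr < n_rows) & (tc >= 0) & (tc < n_cols)

        cand = np.flatnonzero(inb)
        if cand.size == 0:
            continue
        ft_c = ft[cand]
        tr_c, tc_c = tr[cand], tc[cand]
        orig_r, orig_c = ind_r[idx][cand], ind_c[idx][cand]
        levels = n_ranks[ft_c, orig_r, orig_c].astype(np.int64)
        thresh = 1 + ((k - 1) * levels) // tries  # relaxes from rank 1 to all ranks
        target_rank = rank[ft_c, orig_r, orig_c, cls_grid[tr_c, tc_c]]
        ok = target_rank <= thresh
        cand = cand[ok]
        if cand.size == 0:
            continue

        # capacity contention: within the round, earlier (higher-priority)
        # individuals claim remaining slots first
        key = (ft[cand] * n_rows + tr[cand]) * n_cols + tc[cand]
        srt = np.argsort(key, kind="stable")
        sk = key[srt]
        starts = np.r_[0, np.flatnonzero(np.diff(sk)) + 1]
        sizes = np.diff(np.r_[starts, sk.size])
        occ = np.arange(sk.size) - np.repeat(starts, sizes)
        room = Kflat[sk] - Nflat[sk]
        accept_sorted = occ < room
        accepted = cand[srt[accept_sorted]]
        if accepted.size:
            akey = key[srt[accept_sorted]]
            np.add.at(Nflat, akey, 1.0)
            alive[idx[accepted]] = False
    return out
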