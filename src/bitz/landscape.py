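"""Landscape data model, raster/patch I/O, synthetic mosaics, and buffer-zone selection.

A landscape is a rectangular grid of 20 m cells, each carrying one of six land-use
classes and a patch id (a patch is a maximal 4-connected set of same-class cells).
Agricultural buffer zones (ABZs) are arable cells bordering grassland or forest that
have been set aside: they are flagged on a separate boolean layer and gain enhanced
nesting capacity and resources and zero disturbance downstream.

Rasters are read and written as ESRI ASCII grids (plain-text ``ncols/nrows/...``
header plus an integer matrix); the patch table is a CSV with columns
``patch_id,land_use,area_cells``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage


class LandUseClass(IntEnum):
    """The six land-use classes, coded 0..5 (fixed bijection)."""

    BARE = 0
    ARABLE = 1
    FOREST = 2
    GRASSLAND = 3
    URBAN = 4
    WATER = 5

    @classmethod
    def from_name(cls, name: str) -> "LandUseClass":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise UnknownLandUseError(f"unknown land-use name: {name!r}") from None


N_CLASSES = len(LandUseClass)

#: Composition of the study region (fractions of total area per class).
STUDY_REGION_COMPOSITION: dict[LandUseClass, float] = {
    LandUseClass.ARABLE: 0.60,
    LandUseClass.FOREST: 0.15,
    LandUseClass.GRASSLAND: 0.11,
    LandUseClass.BARE: 0.06,
    LandUseClass.WATER: 0.05,
    LandUseClass.URBAN: 0.03,
}


class LandscapeError(ValueError):
    """Base class for landscape validation errors."""


class UnknownLandUseError(LandscapeError):
    """A raster or table carries a land-use code outside 0..5."""


class PatchTableError(LandscapeError):
    """Patch table inconsistent with the raster (missing id, class or area mismatch)."""


class CompositionError(LandscapeError):
    """Requested class composition cannot be realized on the grid."""


@dataclass(frozen=True)
class Patch:
    patch_id: int
    land_use: LandUseClass
    area_cells: int


@dataclass
class Landscape:
    """Grid of land-use cells plus the patch partition and the ABZ layer.

    ``land_use`` and ``patch_id`` are integer arrays of shape (n_rows, n_cols);
    ``abz`` is boolean, initially all False.  Row 0 is the top of the raster.
    """

    land_use: np.ndarray
    patch_id: np.ndarray
    patch_table: pd.DataFrame
    abz: np.ndarray = field(default=None)  # type: ignore[assignment]
    cell_size_m: float = 20.0

    def __post_init__(self) -> None:
        self.land_use = np.asarray(self.land_use, dtype=np.int16)
        self.patch_id = np.asarray(self.patch_id, dtype=np.int32)
        if self.abz is None:
            self.abz = np.zeros(self.land_use.shape, dtype=bool)
        self.abz = np.asarray(self.abz, dtype=bool)
        validate_landscape(self)

    @property
    def n_rows(self) -> int:
        return self.land_use.shape[0]

    @property
    def n_cols(self) -> int:
        return self.land_use.shape[1]

    @property
    def n_cells(self) -> int:
        return self.land_use.size

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size_m**2

    @property
    def area_m2(self) -> float:
        return self.n_cells * self.cell_area_m2

    def patches(self) -> list[Patch]:
        return [
            Patch(int(r.patch_id), LandUseClass(int(r.land_use)), int(r.area_cells))
            for r in self.patch_table.itertuples()
        ]

    def class_fractions(self) -> dict[LandUseClass, float]:
        counts = np.bincount(self.land_use.ravel(), minlength=N_CLASSES)
        return {c: counts[c] / self.n_cells for c in LandUseClass}

    def copy(self) -> "Landscape":
        return Landscape(
            land_use=self.land_use.copy(),
            patch_id=self.patch_id.copy(),
            patch_table=self.patch_table.copy(),
            abz=self.abz.copy(),
            cell_size_m=self.cell_size_m,
        )

    def __eq__(self, other: object) -> bool:  # cell-for-cell equality
        if not isinstance(other, Landscape):
            return NotImplemented
        return (
            self.land_use.shape == other.land_use.shape
            and np.array_equal(self.land_use, other.land_use)
            and np.array_equal(self.patch_id, other.patch_id)
            and np.array_equal(self.abz, other.abz)
            and self.cell_size_m == other.cell_size_m
        )


def validate_landscape(ls: Landscape) -> None:
    if ls.land_use.shape != ls.patch_id.shape or ls.land_use.shape != ls.abz.shape:
        raise LandscapeError("land_use, patch_id and abz grids must share one shape")
    if ls.land_use.min() < 0 or ls.land_use.max() >= N_CLASSES:
        bad = sorted(set(np.unique(ls.land_use)) - set(int(c) for c in LandUseClass))
        raise UnknownLandUseError(f"unknown land-use code(s) in raster: {bad}")
    if np.any(ls.abz & (ls.land_use != LandUseClass.ARABLE)):
        raise LandscapeError("abz flag set on a non-arable cell")
    table = ls.patch_table
    required = {"patch_id", "land_use", "area_cells"}
    if not required.issubset(table.columns):
        raise PatchTableError(f"patch table must have columns {sorted(required)}")
    by_id = table.set_index("patch_id")
    ids, counts = np.unique(ls.patch_id, return_counts=True)
    for pid, n in zip(ids, counts):
        if pid not in by_id.index:
            raise PatchTableError(f"patch_id {pid} present in raster but missing from table")
        row = by_id.loc[pid]
        if int(row["area_cells"]) != int(n):
            raise PatchTableError(
                f"patch area mismatch for patch {pid}: table says "
                f"{int(row['area_cells'])}, raster has {int(n)} cells"
            )
        cls = np.unique(ls.land_use[ls.patch_id == pid])
        if len(cls) != 1:
            raise PatchTableError(f"patch {pid} spans multiple land-use classes")
        if int(cls[0]) != int(row["land_use"]):
            raise PatchTableError(
                f"patch {pid} land use mismatch: table {int(row['land_use'])}, "
                f"raster {int(cls[0])}"
            )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "NODATA_value")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an integer ESRI ASCII grid; returns (array, cellsize)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {k.lower() for k in _HEADER_KEYS}:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    body = "\n".join(lines[i:])
    arr = np.loadtxt([ln for ln in body.split("\n") if ln.strip()], dtype=np.int64)
    arr = np.atleast_2d(arr)
    nrows, ncols = int(header.get("nrows", arr.shape[0])), int(header.get("ncols", arr.shape[1]))
    if arr.shape != (nrows, ncols):
        raise LandscapeError(f"grid body {arr.shape} does not match header ({nrows}, {ncols})")
    return arr, header.get("cellsize", 20.0)


def write_ascii_grid(arr: np.ndarray, path: str | Path, cell_size_m: float = 20.0) -> None:
    arr = np.asarray(arr)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {arr.shape[1]}\n")
        fh.write(f"nrows {arr.shape[0]}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cell_size_m:g}\n")
        fh.write("NODATA_value -9999\n")
        for row in arr:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def _abz_path(raster_path: str | Path) -> Path:
    p = Path(raster_path)
    return p.with_name(p.stem + "_abz" + p.suffix)


def _patchid_path(raster_path: str | Path) -> Path:
    p = Path(raster_path)
    return p.with_name(p.stem + "_patchid" + p.suffix)


def load_landscape(raster_path: str | Path, patch_table_path: str | Path) -> Landscape:
    """Load a landscape from an ESRI ASCII land-use raster plus a patch-table CSV.

    Sidecar rasters ``<stem>_patchid.asc`` and ``<stem>_abz.asc`` are read when
    present; otherwise patch ids are derived by 4-connected labelling per class
    and the ABZ layer starts all-False.
    """
    land_use, cellsize = read_ascii_grid(raster_path)
    if land_use.min() < 0 or land_use.max() >= N_CLASSES:
        bad = sorted(set(np.unique(land_use)) - set(int(c) for c in LandUseClass))
        raise UnknownLandUseError(f"unknown land-use code(s) in raster: {bad}")
    table = pd.read_csv(patch_table_path)
    if "area" in table.columns and "area_cells" not in table.columns:
        table = table.rename(columns={"area": "area_cells"})
    pid_path = _patchid_path(raster_path)
    if pid_path.exists():
        patch_id, _ = read_ascii_grid(pid_path)
    else:
        patch_id = label_patches(land_use)
    abz_path = _abz_path(raster_path)
    abz = None
    if abz_path.exists():
        abz_arr, _ = read_ascii_grid(abz_path)
        abz = abz_arr.astype(bool)
    return Landscape(
        land_use=land_use,
        patch_id=patch_id,
        patch_table=table[["patch_id", "land_use", "area_cells"]].copy(),
        abz=abz,
        cell_size_m=cellsize,
    )


def write_landscape(ls: Landscape, raster_path: str | Path, patch_table_path: str | Path) -> None:
    """Write land-use raster + patch table; patch ids and ABZ flags go to sidecar rasters."""
    write_ascii_grid(ls.land_use, raster_path, ls.cell_size_m)
    write_ascii_grid(ls.patch_id, _patchid_path(raster_path), ls.cell_size_m)
    write_ascii_grid(ls.abz.astype(np.int8), _abz_path(raster_path), ls.cell_size_m)
    ls.patch_table.to_csv(patch_table_path, index=False)


# ---------------------------------------------------------------------------
# Patch labelling and synthetic landscapes
# ---------------------------------------------------------------------------

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def label_patches(land_use: np.ndarray) -> np.ndarray:
    """Assign consecutive patch ids (from 1) to 4-connected same-class components."""
    patch_id = np.zeros(land_use.shape, dtype=np.int32)
    next_id = 1
    for cls in range(N_CLASSES):
        mask = land_use == cls
        if not mask.any():
            continue
        lab, n = ndimage.label(mask, structure=_CROSS)
        patch_id[mask] = lab[mask] + next_id - 1
        next_id += n
    return patch_id


def build_patch_table(land_use: np.ndarray, patch_id: np.ndarray) -> pd.DataFrame:
    ids, counts = np.unique(patch_id, return_counts=True)
    rows = []
    for pid, n in zip(ids, counts):
        cls = int(land_use[patch_id == pid][0])
        rows.append({"patch_id": int(pid), "land_use": cls, "area_cells": int(n)})
    return pd.DataFrame(rows, columns=["patch_id", "land_use", "area_cells"])


@dataclass
class SyntheticLandscapeConfig:
    """Recipe for a random patch mosaic emulating an agricultural region.

    ``target_composition`` maps each land-use class to its areal fraction
    (must sum to 1); patches are grown around random seed cells with sizes
    drawn from a geometric distribution with the given mean.
    """

    target_composition: Mapping[LandUseClass, float] = field(
        default_factory=lambda: dict(STUDY_REGION_COMPOSITION)
    )
    mean_patch_area_cells: float = 80.0
    n_rows: int = 150
    n_cols: int = 150
    cell_size_m: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.target_composition.values()))
        if any(f < 0 for f in self.target_composition.values()):
            raise CompositionError("composition fractions must be nonnegative")
        if abs(total - 1.0) > 1e-9:
            raise CompositionError(f"composition fractions must sum to 1 (got {total})")
        if self.mean_patch_area_cells < 1:
            raise CompositionError("mean_patch_area_cells must be >= 1")


def generate_synthetic_landscape(config: SyntheticLandscapeConfig) -> Landscape:
    """Grow a contiguous multi-class patch mosaic with the requested composition.

    Class cell quotas are fixed up front (largest-remainder apportionment of the
    fractions), so realized fractions match the targets to within 1/n_cells per
    class.  Patches are grown one at a time by seeded random region growing over
    unassigned cells; leftover enclosed pockets are filled from the remaining
    quotas at the end.  Bit-reproducible for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    n_rows, n_cols = config.n_rows, config.n_cols
    n_cells = n_rows * n_cols
    quotas = _apportion(config.target_composition, n_cells)
    if sum(quotas.values()) != n_cells:
        raise CompositionError("internal apportionment error")

    land_use = np.full((n_rows, n_cols), -1, dtype=np.int16)
    remaining = dict(quotas)
    unassigned = n_cells
    p_stop = min(1.0, 1.0 / config.mean_patch_area_cells)

    while unassigned > 0:
        classes = [c for c, q in remaining.items() if q > 0]
        weights = np.array([remaining[c] for c in classes], dtype=float)
        cls = classes[rng.choice(len(classes), p=weights / weights.sum())]
        # geometric patch size (mean = mean_patch_area_cells), capped by quota
        size = int(rng.geometric(p_stop)) if p_stop < 1.0 else 1
        size = min(size, remaining[cls])
        free = np.flatnonzero(land_use.ravel() == -1)
        seed_cell = int(free[rng.integers(len(free))])
        grown = _grow_patch(land_use, seed_cell, cls, size, rng)
        remaining[cls] -= grown
        unassigned -= grown

    land_use = land_use.astype(np.int16)
    patch_id = label_patches(land_use)
    return Landscape(
        land_use=land_use,
        patch_id=patch_id,
        patch_table=build_patch_table(land_use, patch_id),
        cell_size_m=config.cell_size_m,
    )


def _apportion(composition: Mapping[LandUseClass, float], n_cells: int) -> dict[LandUseClass, int]:
    """Largest-remainder apportionment of class fractions into integer cell counts."""
    items = sorted(composition.items(), key=lambda kv: int(kv[0]))
    raw = {c: f * n_cells for c, f in items}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    shortfall = n_cells - sum(counts.values())
    by_frac = sorted(items, key=lambda kv: (-(raw[kv[0]] - counts[kv[0]]), int(kv[0])))
    for c, _ in by_frac[:shortfall]:
        counts[c] += 1
    return {c: n for c, n in counts.items() if n > 0}


def _grow_patch(land_use: np.ndarray, seed_cell: int, cls: int, size: int, rng) -> int:
    """Region-grow ``size`` cells of class ``cls`` from ``seed_cell``; returns cells grown."""
    n_rows, n_cols = land_use.shape
    flat = land_use.ravel()
    frontier = [seed_cell]
    in_frontier = {seed_cell}
    grown = 0
    while frontier and grown < size:
        idx = int(rng.integers(len(frontier)))
        cell = frontier.pop(idx)
        in_frontier.discard(cell)
        if flat[cell] != -1:
            continue
        flat[cell] = cls
        grown += 1
        r, c = divmod(cell, n_cols)
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < n_rows and 0 <= cc < n_cols:
                nb = rr * n_cols + cc
                if flat[nb] == -1 and nb not in in_frontier:
                    frontier.append(nb)
                    in_frontier.add(nb)
    return grown


# ---------------------------------------------------------------------------
# ABZ selection
# ---------------------------------------------------------------------------


def potential_abz_cells(ls: Landscape, neighborhood: int = 4) -> set[tuple[int, int]]:
    """Arable cells edge-adjacent to a grassland or forest cell (candidate buffer zones)."""
    natural = (ls.land_use == LandUseClass.GRASSLAND) | (ls.land_use == LandUseClass.FOREST)
    if neighborhood == 4:
        kernel = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.int8)
    elif neighborhood == 8:
        kernel = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.int8)
    else:
        raise ValueError("neighborhood must be 4 or 8")
    n_natural_nb = ndimage.correlate(natural.astype(np.int8), kernel, mode="constant", cval=0)
    mask = (ls.land_use == LandUseClass.ARABLE) & (n_natural_nb > 0)
    rows, cols = np.nonzero(mask)
    return {(int(r), int(c)) for r, c in zip(rows, cols)}


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def apply_abz(
    ls: Landscape,
    fraction: float,
    rng: np.random.Generator,
    *,
    neighborhood: int = 4,
    order: str = "descending",
) -> Landscape:
    """Flag a fraction of the candidate buffer-zone cells, walking arable patches by area.

    Exactly ``round_half_up(fraction * n_candidates)`` cells are flagged.  Patches are
    visited in descending area order (ties by ascending patch id; ``order="ascending"``
    reverses the walk for the sensitivity variant), each patch's candidate cells being
    exhausted in a random order before the next patch is opened.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"ABZ fraction must be in [0, 1], got {fraction}")
    if order not in ("descending", "ascending"):
        raise ValueError("order must be 'descending' or 'ascending'")
    out = ls.copy()
    out.abz[:] = False
    candidates = potential_abz_cells(ls, neighborhood=neighborhood)
    n_target = round_half_up(fraction * len(candidates))
    if n_target == 0:
        return out

    arable = ls.patch_table[ls.patch_table["land_use"] == int(LandUseClass.ARABLE)]
    ascending = order == "ascending"
    patches = arable.sort_values(
        ["area_cells", "patch_id"], ascending=[ascending, True]
    )["patch_id"].tolist()

    flagged = 0
    for pid in patches:
        cells = [rc for rc in candidates if out.patch_id[rc] == pid]
        cells.sort()  # deterministic base order before permutation
        if not cells:
            continue
        perm = rng.permutation(len(cells))
        for k in perm:
            if flagged >= n_target:
                break
            out.abz[cells[k]] = True
            flagged += 1
        if flagged >= n_target:
            break
    return out
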