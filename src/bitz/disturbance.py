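"""Yearly disturbance: patch- or cell-scale draws and type-specific mortality.

Agricultural management (ploughing, mowing, ...) destroys nests.  Arable and
grassland patches are disturbed as wholes — arable every year, grassland with
probability 0.8 — while forest, bare and urban cells are hit independently
(0.3 / 0.7 / 0.7).  Water is never disturbed and buffer-zone cells are exempt
by construction.  A disturbed population loses the fraction ``dist_eff`` of
its individuals (0.9 for endogeic nesters, 0.3 for hypogean ones).
"""

from __future__ import annotations

import numpy as np

from .config import DisturbanceConfig
from .dynamics import PopulationState
from .functional_types import FTCommunity
from .landscape import Landscape


def draw_disturbance_mask(
    ls: Landscape, config: DisturbanceConfig, rng: np.random.Generator
) -> np.ndarray:
    """Boolean grid of cells disturbed this year.

    Patch-scale classes get one Bernoulli draw per patch (patches visited in
    ascending patch-id order), cell-scale classes one draw per cell; buffer
    zones and classes with probability 0 are never disturbed.
    """
    mask = np.zeros(ls.land_use.shape, dtype=bool)
    probs = config.prob_array()

    patch_classes = [c for c, s in sorted(config.scale_by_class.items()) if s == "patch"]
    table = ls.patch_table.sort_values("patch_id")
    for row in table.itertuples():
        cls = int(row.land_use)
        if cls not in patch_classes:
            continue
        p = probs[cls]
        if p <= 0:
            continue
        if rng.random() < p:
            mask |= ls.patch_id == row.patch_id

    cell_classes = [c for c, s in sorted(config.scale_by_class.items()) if s == "cell"]
    u = rng.random(ls.land_use.shape)
    for cls in cell_classes:
        p = probs[cls]
        if p <= 0:
            continue
        mask |= (ls.land_use == cls) & (u < p)

    mask &= ~ls.abz
    return mask


def apply_disturbance(
    state: PopulationState, mask: np.ndarray, community: FTCommunity
) -> PopulationState:
    """Reduce every population in a masked cell by its type's dist_eff fraction."""
    if mask.shape != state.abundance.shape[1:]:
        raise ValueError("disturbance mask shape does not match the grid")
    survival = 1.0 - community.dist_eff_array()
    out = state.abundance.copy()
    out[:, mask] *= survival[:, None]
    return PopulationState(out, state.year)
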