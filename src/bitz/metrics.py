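"""Community summary statistics: richness, Shannon diversity, quasi-extinction
risk, community-weighted trait means, feeding-intensity maps and land-use-scale
summaries.

Quasi-extinction risk is the fraction of repetitions in which a type's
abundance dips below a threshold at least once during the evaluation window
(by default the last 10 simulated years).  The landscape-scale threshold of
10,000 individuals refers to a 3 x 3 km grid; it scales with landscape area
through the implied density 10,000 / 9 km^2, so smaller grids stay comparable.
The land-use-scale threshold is 0.001 individuals per m^2 of the class area.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .dynamics import PopulationState, resource_uptake_fields
from .engine import RunResult, SUMMARY_CLASSES, included_class_masks
from .functional_types import FTCommunity, FlyingPeriod, ForagingDistance
from .landscape import Landscape

#: landscape quasi-extinction threshold expressed as a density (10,000 per 9 km^2)
LANDSCAPE_QE_DENSITY_PER_M2 = 10_000.0 / 9_000_000.0
#: land-use-class quasi-extinction threshold (individuals per m^2)
LANDUSE_QE_DENSITY_PER_M2 = 0.001


class DiversityError(ValueError):
    """Diversity undefined (no individuals)."""


def ft_richness(per_ft_totals: np.ndarray) -> int:
    """Number of types with a strictly positive total."""
    totals = np.asarray(per_ft_totals, dtype=float)
    if np.any(totals < 0):
        raise ValueError("totals must be nonnegative")
    return int(np.count_nonzero(totals > 0))


def shannon(per_ft_totals: np.ndarray) -> float:
    """Shannon diversity H = -sum p ln p (natural log) over positive totals."""
    totals = np.asarray(per_ft_totals, dtype=float)
    if np.any(totals < 0):
        raise ValueError("totals must be nonnegative")
    positive = totals[totals > 0]
    if positive.size == 0:
        raise DiversityError("Shannon diversity is undefined for an all-zero community")
    p = positive / positive.sum()
    return float(-(p * np.log(p)).sum())


def landscape_qe_threshold(ls: Landscape) -> float:
    """Area-scaled landscape quasi-extinction threshold (10,000 on a 3x3 km grid)."""
    return LANDSCAPE_QE_DENSITY_PER_M2 * ls.area_m2


def quasi_extinction_risk(
    trajectories: np.ndarray,
    threshold: float,
    window: tuple[int, int] = (40, 50),
) -> np.ndarray:
    """Per-type risk: fraction of repetitions dipping below ``threshold`` in the window.

    ``trajectories`` is (repetitions, years+1) for one type or (repetitions,
    years+1, S); the window is inclusive in years (year index = time point).
    """
    traj = np.asarray(trajectories, dtype=float)
    squeeze = traj.ndim == 2
    if squeeze:
        traj = traj[:, :, None]
    lo, hi = window
    if not (0 <= lo <= hi <= traj.shape[1] - 1):
        raise ValueError(
            f"window {window} outside simulated years 0..{traj.shape[1] - 1}"
        )
    dipped = (traj[:, lo : hi + 1, :] < threshold).any(axis=1)  # (reps, S)
    risk = dipped.mean(axis=0)
    return float(risk[0]) if squeeze else risk


_FLYING_CODE = {FlyingPeriod.FIRST: 1.0, FlyingPeriod.SECOND: 2.0, FlyingPeriod.BOTH: 3.0}
_FORAGING_CODE = {ForagingDistance.SHORT: 1.0, ForagingDistance.MEDIUM: 2.0, ForagingDistance.LONG: 3.0}


def trait_codings(community: FTCommunity, foraging_coding: str = "ordinal") -> dict[str, np.ndarray]:
    """Coded trait values per type: foraging range (1/2/3 or metres), flying
    period (1 early, 2 late, 3 both) and disturbance susceptibility (dist_eff)."""
    if foraging_coding == "ordinal":
        foraging = np.array([_FORAGING_CODE[p.foraging_distance] for p in community.profiles])
    elif foraging_coding == "meters":
        foraging = community.disp_mean_array()
    else:
        raise ValueError("foraging_coding must be 'ordinal' or 'meters'")
    return {
        "foraging_range": foraging,
        "flying_period": np.array([_FLYING_CODE[p.flying_period] for p in community.profiles]),
        "disturbance_susceptibility": community.dist_eff_array(),
    }


def community_weighted_mean(
    per_ft_totals: np.ndarray,
    codings: Mapping[str, np.ndarray],
) -> dict[str, float]:
    """Abundance-weighted mean of each coded trait; requires a nonempty community."""
    totals = np.asarray(per_ft_totals, dtype=float)
    total = totals.sum()
    if total <= 0:
        raise DiversityError("community-weighted means are undefined at zero abundance")
    return {name: float((totals * x).sum() / total) for name, x in codings.items()}


def feeding_intensity_map(
    state: PopulationState,
    ls: Landscape,
    community: FTCommunity,
    uptake_form: str = "printed",
) -> np.ndarray:
    """Per-cell feeding intensity: sum over foraging populations of size x uptake.

    Every population contributes its full size in every cell of its foraging
    disk, weighted by the competition-dependent resource uptake it realizes
    there (the same quantity that enters the growth function).
    """
    uptake, foraging = resource_uptake_fields(state, ls, community, form=uptake_form)
    return (foraging * uptake).sum(axis=0)


def landuse_scale_summary(
    result: RunResult,
    ls: Landscape,
    window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-class abundance totals, densities and quasi-extinction risks.

    Covers all arable patches plus the forest and grassland patches adjacent
    to arable land (buffer zones included); risks use the 0.001 / m^2 density
    threshold on the class area.
    """
    if result.landuse_series is None:
        raise ValueError("run was recorded without land-use series")
    years = result.years
    if window is None:
        window = (max(0, years - 10), years)
    masks = included_class_masks(ls)
    rows = []
    for k, cls in enumerate(SUMMARY_CLASSES):
        area_m2 = float(masks[int(cls)].sum()) * ls.cell_area_m2
        series = result.landuse_series[:, :, :, k]  # (reps, years+1, S)
        final_total = float(series[:, -1, :].sum(axis=1).mean())
        if area_m2 > 0:
            threshold = LANDUSE_QE_DENSITY_PER_M2 * area_m2
            risks = quasi_extinction_risk(series, threshold, window)
            mean_risk = float(np.mean(risks))
            density = final_total / area_m2
        else:
            mean_risk, density = 1.0, 0.0
        rows.append(
            {
                "land_use": cls.name.lower(),
                "area_m2": area_m2,
                "mean_final_abundance": final_total,
                "density_per_m2": density,
                "mean_quasi_extinction_risk": mean_risk,
            }
        )
    return pd.DataFrame(rows)


def summarize_run(
    result: RunResult,
    ls: Landscape,
    community: FTCommunity,
    window: tuple[int, int] | None = None,
) -> dict[str, float]:
    """Headline landscape-scale metrics of one run, averaged over repetitions."""
    years = result.years
    if window is None:
        window = (max(0, years - 10), years)
    finals = result.series[:, -1, :]  # (reps, S)
    richness = np.array([ft_richness(f) for f in finals], dtype=float)
    shannons = np.array([shannon(f) if f.sum() > 0 else 0.0 for f in finals])
    risks = quasi_extinction_risk(result.series, landscape_qe_threshold(ls), window)
    codings = trait_codings(community)
    cwm_list = [
        community_weighted_mean(f, codings) if f.sum() > 0 else dict.fromkeys(codings, np.nan)
        for f in finals
    ]
    return {
        "mean_richness": float(richness.mean()),
        "mean_richness_fraction": float(richness.mean() / community.size),
        "mean_shannon": float(shannons.mean()),
        "mean_quasi_extinction_risk": float(np.mean(risks)),
        "cwm_foraging_range": float(np.nanmean([c["foraging_range"] for c in cwm_list])),
        "cwm_flying_period": float(np.nanmean([c["flying_period"] for c in cwm_list])),
        "cwm_disturbance_susceptibility": float(
            np.nanmean([c["disturbance_susceptibility"] for c in cwm_list])
        ),
    }
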