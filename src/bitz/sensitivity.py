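"""One-at-a-time local sensitivity analysis over the 16 named model parameters.

Each plan variant changes exactly one parameter relative to the baseline:

* numerical parameters are scaled by -25%, -10%, +10% and +25%;
* type-specific numerical parameters additionally get two "spread" variants
  that shrink or stretch the between-type differences by 50% relative to the
  lowest value, v' = v_min + (v - v_min) * (1 +- 0.5);
* the two non-numerical parameters are reversed: the buffer-zone patch walk
  runs smallest-first, and the competition ranking flips (c -> 5 - c).

Endpoints are the mean type richness and mean Shannon diversity at the final
year; each variant is compared against the baseline mean at the same
buffer-zone fraction as a relative change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .engine import ScenarioSpec, run_scenarios
from .functional_types import FTCommunity
from .landscape import Landscape, round_half_up
from .metrics import ft_richness, shannon

SCALE_DELTAS = (-0.25, -0.10, 0.10, 0.25)
SPREAD_DELTAS = (-0.5, 0.5)

#: general numerical parameters (live on the config)
GENERAL_NUMERICAL = ("weather_std", "dispersal_tries", "disturbance_prob")
#: type-specific numerical parameters (live on the community)
FT_NUMERICAL = (
    "growth_rate",
    "nest_suitability",
    "res_suitability",
    "emigration_mu",
    "emigration_omega",
    "dispersal_mean",
    "dispersal_sd",
    "disturbance_effect",
    "trans_effect_res",
    "trans_effect_nest",
    "trans_effect_nest_res",
)
#: categorical parameters (reversal only)
CATEGORICAL = ("order", "competition_strength")

_FT_FIELDS = {
    "growth_rate": ("r",),
    "nest_suitability": ("nest_suitability",),
    "res_suitability": ("forage_suitability",),
    "emigration_mu": ("emigration_mu",),
    "emigration_omega": ("emigration_omega",),
    "dispersal_mean": ("disp_mean",),
    "dispersal_sd": ("disp_sd",),
    "disturbance_effect": ("dist_eff",),
    "trans_effect_res": ("trans_effect_res",),
    "trans_effect_nest": ("trans_effect_nest",),
    "trans_effect_nest_res": ("trans_effect_nest", "trans_effect_res"),
}
_CLIPPED_01 = {"dist_eff", "emigration_mu"}


@dataclass
class Variant:
    parameter: str
    kind: str  # 'scale' | 'spread' | 'reversal' | 'baseline'
    delta: float
    config: SimulationConfig
    community: FTCommunity


@dataclass
class SensitivityPlan:
    baseline_config: SimulationConfig
    baseline_community: FTCommunity
    variants: list[Variant] = field(default_factory=list)


def _scale_ft_values(values: np.ndarray, factor: float, clip01: bool) -> np.ndarray:
    out = values * factor
    return np.clip(out, 0.0, 1.0) if clip01 else out


def _spread_ft_values(values: np.ndarray, delta: float, clip01: bool) -> np.ndarray:
    vmin = values.min(axis=0)
    out = vmin + (values - vmin) * (1.0 + delta)
    return np.clip(out, 0.0, 1.0) if clip01 else out


def _ft_variant(community: FTCommunity, parameter: str, kind: str, delta: float) -> FTCommunity:
    overrides: dict[str, object] = {}
    for fname in _FT_FIELDS[parameter]:
        if fname in ("nest_suitability", "forage_suitability"):
            values = np.array([getattr(p, fname) for p in community.parameters])
        else:
            values = np.array([getattr(p, fname) for p in community.parameters], dtype=float)
        clip01 = fname in _CLIPPED_01
        if kind == "scale":
            new = _scale_ft_values(values, 1.0 + delta, clip01)
        else:
            new = _spread_ft_values(values, delta, clip01)
        if values.ndim == 2:
            overrides[fname] = [tuple(row) for row in new]
        else:
            overrides[fname] = new
    return community.with_overrides(overrides)


def _config_variant(config: SimulationConfig, parameter: str, delta: float) -> SimulationConfig:
    if parameter == "weather_std":
        return config.replace(weather_std=config.weather_std * (1.0 + delta))
    if parameter == "dispersal_tries":
        tries = max(1, round_half_up(config.dispersal.dispersal_tries * (1.0 + delta)))
        disp = config.dispersal.__class__(
            dispersal_tries=tries,
            emigration_mu=config.dispersal.emigration_mu,
            emigration_omega=config.dispersal.emigration_omega,
        )
        return config.replace(dispersal=disp)
    if parameter == "disturbance_prob":
        dist = config.disturbance
        probs = {c: min(1.0, p * (1.0 + delta)) for c, p in dist.prob_by_class.items()}
        new = dist.__class__(prob_by_class=probs, scale_by_class=dict(dist.scale_by_class))
        return config.replace(disturbance=new)
    raise ValueError(f"unknown general parameter {parameter!r}")


def _reversal_variant(
    config: SimulationConfig, community: FTCommunity, parameter: str
) -> tuple[SimulationConfig, FTCommunity]:
    if parameter == "order":
        return config.replace(abz_order="ascending"), community
    if parameter == "competition_strength":
        c = community.c_array()
        return config, community.with_overrides({"c": (5 - c).astype(int)})
    raise ValueError(f"unknown categorical parameter {parameter!r}")


def build_plan(baseline_config: SimulationConfig, community: FTCommunity) -> SensitivityPlan:
    """All one-at-a-time variants of the 16 tested parameters."""
    plan = SensitivityPlan(baseline_config, community)
    for name in GENERAL_NUMERICAL:
        for delta in SCALE_DELTAS:
            plan.variants.append(
                Variant(name, "scale", delta, _config_variant(baseline_config, name, delta), community)
            )
    for name in FT_NUMERICAL:
        for delta in SCALE_DELTAS:
            plan.variants.append(
                Variant(name, "scale", delta, baseline_config, _ft_variant(community, name, "scale", delta))
            )
        for delta in SPREAD_DELTAS:
            plan.variants.append(
                Variant(name, "spread", delta, baseline_config, _ft_variant(community, name, "spread", delta))
            )
    for name in CATEGORICAL:
        cfg, comm = _reversal_variant(baseline_config, community, name)
        plan.variants.append(Variant(name, "reversal", 0.0, cfg, comm))
    return plan


def _endpoints(series: np.ndarray) -> tuple[float, float]:
    finals = series[:, -1, :]
    richness = float(np.mean([ft_richness(f) for f in finals]))
    shannons = float(np.mean([shannon(f) if f.sum() > 0 else 0.0 for f in finals]))
    return richness, shannons


def run_plan(
    plan: SensitivityPlan,
    ls: Landscape,
    *,
    fractions: tuple[float, ...] | None = None,
    landscape_id: str = "ls0",
) -> pd.DataFrame:
    """Simulate baseline and every variant; return the tidy sensitivity table.

    Columns: parameter, kind, delta, fraction, endpoint, value, baseline,
    relative_change.  The baseline rows carry relative changes of their own
    repetitions' means against themselves (zero by construction).
    """
    if fractions is None:
        fractions = tuple(ScenarioSpec().abz_fractions)
    spec = ScenarioSpec(abz_fractions=fractions, landscapes=[(landscape_id, ls)])

    baseline = run_scenarios(spec, plan.baseline_community, plan.baseline_config)
    base_vals: dict[tuple[float, str], float] = {}
    rows = []
    for fraction in spec.abz_fractions:
        rich, shan = _endpoints(baseline.runs[(landscape_id, fraction)].series)
        base_vals[(fraction, "ft_richness")] = rich
        base_vals[(fraction, "shannon")] = shan
        for endpoint, value in (("ft_richness", rich), ("shannon", shan)):
            rows.append(
                {
                    "parameter": "baseline",
                    "kind": "baseline",
                    "delta": 0.0,
                    "fraction": fraction,
                    "endpoint": endpoint,
                    "value": value,
                    "baseline": value,
                    "relative_change": 0.0,
                }
            )

    for variant in plan.variants:
        res = run_scenarios(spec, variant.community, variant.config)
        for fraction in spec.abz_fractions:
            rich, shan = _endpoints(res.runs[(landscape_id, fraction)].series)
            for endpoint, value in (("ft_richness", rich), ("shannon", shan)):
                base = base_vals[(fraction, endpoint)]
                rel = (value - base) / base if base != 0 else np.nan
                rows.append(
                    {
                        "parameter": variant.parameter,
                        "kind": variant.kind,
                        "delta": variant.delta,
                        "fraction": fraction,
                        "endpoint": endpoint,
                        "value": value,
                        "baseline": base,
                        "relative_change": rel,
                    }
                )
    return pd.DataFrame(rows)
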