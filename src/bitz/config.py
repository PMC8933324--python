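"""Run configuration containers and (de)serialization.

One structured config object carries every engine knob: simulated years,
repetitions, seeding, the weather noise level, the per-cell nesting capacity
scale, the dispersal search settings and the per-class disturbance regime.
All defaults are the study conditions; everything is overridable from a YAML
file mirroring the dataclass fields.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .landscape import LandUseClass, N_CLASSES


@dataclass
class DispersalConfig:
    """Settlement search settings.

    ``dispersal_tries`` is the maximal number of search attempts per emigrant;
    ``emigration_mu``/``emigration_omega`` (scale and shape of the
    density-dependent emigration fraction) override the per-type values when
    set, and default to the type-level parameters otherwise.
    """

    dispersal_tries: int = 10
    emigration_mu: float | None = None
    emigration_omega: float | None = None

    def __post_init__(self) -> None:
        if self.dispersal_tries < 1:
            raise ValueError("dispersal_tries must be >= 1")


def _default_disturbance_probs() -> dict[int, float]:
    return {
        int(LandUseClass.ARABLE): 1.0,
        int(LandUseClass.GRASSLAND): 0.8,
        int(LandUseClass.BARE): 0.7,
        int(LandUseClass.URBAN): 0.7,
        int(LandUseClass.FOREST): 0.3,
        int(LandUseClass.WATER): 0.0,
    }


def _default_disturbance_scales() -> dict[int, str]:
    return {
        int(LandUseClass.ARABLE): "patch",
        int(LandUseClass.GRASSLAND): "patch",
        int(LandUseClass.BARE): "cell",
        int(LandUseClass.URBAN): "cell",
        int(LandUseClass.FOREST): "cell",
        int(LandUseClass.WATER): "cell",
    }


@dataclass
class DisturbanceConfig:
    """Yearly disturbance regime: per-class probability and spatial grain.

    Arable and grassland are managed patch-wise (one draw per patch, arable
    every year); forest, bare and urban cells are hit independently; water is
    never disturbed.  Buffer-zone cells are exempt.
    """

    prob_by_class: dict[int, float] = field(default_factory=_default_disturbance_probs)
    scale_by_class: dict[int, str] = field(default_factory=_default_disturbance_scales)

    def __post_init__(self) -> None:
        for cls, p in self.prob_by_class.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"disturbance probability for class {cls} outside [0,1]: {p}")
        for cls, s in self.scale_by_class.items():
            if s not in ("patch", "cell"):
                raise ValueError(f"disturbance scale must be 'patch' or 'cell', got {s!r}")

    def prob_array(self) -> "list[float]":
        return [float(self.prob_by_class.get(c, 0.0)) for c in range(N_CLASSES)]


@dataclass
class SimulationConfig:
    """Top-level engine configuration (defaults are the study conditions)."""

    years: int = 50
    repetitions: int = 10
    base_seed: int = 0
    initial_individuals_per_ft: int = 1000
    weather_std: float = 0.15
    k_max: float = 50.0  # per-cell nesting capacity scale (individuals)
    extinction_threshold: float = 1.0  # cell populations below this are extinct
    uptake_form: str = "printed"  # 'printed' or 'inverted' resource-uptake ratio
    abz_neighborhood: int = 4
    abz_order: str = "descending"
    store_final_state: bool = True
    dispersal: DispersalConfig = field(default_factory=DispersalConfig)
    disturbance: DisturbanceConfig = field(default_factory=DisturbanceConfig)

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.weather_std < 0:
            raise ValueError("weather_std must be >= 0")
        if self.uptake_form not in ("printed", "inverted"):
            raise ValueError("uptake_form must be 'printed' or 'inverted'")
        if isinstance(self.dispersal, Mapping):
            self.dispersal = DispersalConfig(**self.dispersal)
        if isinstance(self.disturbance, Mapping):
            self.disturbance = DisturbanceConfig(**self.disturbance)

    # -- serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        return cls(**dict(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)
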