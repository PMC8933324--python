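"""Functional bee types: trait profiles and their derived model parameters.

Solitary bee species are grouped into functional types (FTs) by five traits —
foraging distance, diet breadth, flying period, nesting preference and
parasite-host status (whether the species hosts parasitic bees).  All dynamic
parameters of a type are pure lookups on these traits:

* growth rate ``r`` falls with foraging distance (flight costs) and with
  hosting parasites (brood mortality): 2.5 … 5 in steps of 0.5;
* competition factor ``c`` (0 = strongest … 5 = weakest) rises for long
  foragers (they can evade local competition) and polylectic diets;
* land-use suitabilities for foraging depend on diet breadth and the number
  of flying periods, for nesting on the nesting preference;
* dispersal kernel scale (mean/sd in metres) follows foraging distance:
  600/60, 300/30, 100/10;
* disturbance susceptibility ``dist_eff`` is the fraction of a population
  destroyed by a nest disturbance: 0.9 for soil-associated (endogeic)
  nesters, 0.3 for the hypogean class.

The buffer-zone bonuses ``trans_effect_nest`` / ``trans_effect_res`` default
to the conceptual optimum 1.0 for every type.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .landscape import LandUseClass


class ForagingDistance(str, Enum):
    SHORT = "short"
    MEDIUM = "medium"
    LONG = "long"


class Diet(str, Enum):
    OLIGOLECTIC = "oligolectic"
    POLYLECTIC = "polylectic"


class FlyingPeriod(str, Enum):
    FIRST = "first"
    SECOND = "second"
    BOTH = "both"


class Nesting(str, Enum):
    HYPOGEAN = "hypogean"
    ENDOGEIC = "endogeic"


class TraitError(ValueError):
    """Unknown trait level or malformed trait row."""


@dataclass(frozen=True)
class TraitProfile:
    foraging_distance: ForagingDistance
    diet: Diet
    flying_period: FlyingPeriod
    nesting: Nesting
    parasite_host: bool

    def label(self) -> str:
        return "-".join(
            (
                self.foraging_distance.value,
                self.diet.value,
                self.flying_period.value,
                self.nesting.value,
                "host" if self.parasite_host else "nohost",
            )
        )


def all_profiles() -> list[TraitProfile]:
    """The full factorial trait space (3*2*3*2*2 = 72 profiles), in fixed order."""
    return [
        TraitProfile(f, d, p, n, h)
        for f, d, p, n, h in itertools.product(
            ForagingDistance, Diet, FlyingPeriod, Nesting, (False, True)
        )
    ]


# --- trait -> parameter lookup tables (class order: bare, arable, forest,
#     grassland, urban, water) -------------------------------------------------

_GROWTH_RATE = {
    (ForagingDistance.LONG, True): 2.5,
    (ForagingDistance.LONG, False): 3.0,
    (ForagingDistance.MEDIUM, True): 3.5,
    (ForagingDistance.MEDIUM, False): 4.0,
    (ForagingDistance.SHORT, True): 4.5,
    (ForagingDistance.SHORT, False): 5.0,
}

_COMPETITION = {
    (ForagingDistance.LONG, Diet.POLYLECTIC): 0,
    (ForagingDistance.LONG, Diet.OLIGOLECTIC): 1,
    (ForagingDistance.MEDIUM, Diet.POLYLECTIC): 2,
    (ForagingDistance.MEDIUM, Diet.OLIGOLECTIC): 3,
    (ForagingDistance.SHORT, Diet.POLYLECTIC): 4,
    (ForagingDistance.SHORT, Diet.OLIGOLECTIC): 5,
}

_FORAGE_SUIT = {
    (Diet.OLIGOLECTIC, False): (0.0, 0.4, 0.4, 1.0, 0.4, 0.0),
    (Diet.OLIGOLECTIC, True): (0.0, 0.6, 0.6, 1.5, 0.6, 0.0),
    (Diet.POLYLECTIC, False): (0.0, 0.7, 0.6, 1.0, 0.6, 0.0),
    (Diet.POLYLECTIC, True): (0.0, 1.05, 0.9, 1.5, 0.9, 0.0),
}

_NEST_SUIT = {
    Nesting.HYPOGEAN: (0.0, 0.1, 1.0, 0.3, 0.7, 0.0),
    Nesting.ENDOGEIC: (1.0, 0.3, 0.1, 0.7, 0.1, 0.0),
}

_DISPERSAL = {
    ForagingDistance.LONG: (600.0, 60.0),
    ForagingDistance.MEDIUM: (300.0, 30.0),
    ForagingDistance.SHORT: (100.0, 10.0),
}

_DIST_EFF = {Nesting.HYPOGEAN: 0.3, Nesting.ENDOGEIC: 0.9}


@dataclass(frozen=True)
class FTParameters:
    """All per-type model parameters (see module docstring for meaning)."""

    ft_id: str
    r: float
    c: int
    forage_suitability: tuple[float, ...]  # indexed by LandUseClass code
    nest_suitability: tuple[float, ...]
    disp_mean: float  # metres
    disp_sd: float  # metres
    dist_eff: float
    trans_effect_nest: float = 1.0
    trans_effect_res: float = 1.0
    b: float = 1.0
    emigration_mu: float = 0.2
    emigration_omega: float = 2.0


def derive_parameters(
    profile: TraitProfile,
    overrides: Mapping[str, object] | None = None,
    *,
    swap_nesting_rows: bool = False,
) -> FTParameters:
    """Derive a type's parameters from its trait profile (pure table lookup).

    ``overrides`` replaces individual fields after derivation (used by the
    sensitivity harness and by config-level parameter changes).
    ``swap_nesting_rows`` exchanges the two nesting-suitability rows (the
    alternative reading under which soil nesters prefer open land; see the
    methods note) while leaving disturbance susceptibility untouched.
    """
    if not isinstance(profile, TraitProfile):
        raise TraitError(f"expected a TraitProfile, got {type(profile).__name__}")
    two_periods = profile.flying_period is FlyingPeriod.BOTH
    disp_mean, disp_sd = _DISPERSAL[profile.foraging_distance]
    nesting = profile.nesting
    if swap_nesting_rows:
        nesting = Nesting.ENDOGEIC if nesting is Nesting.HYPOGEAN else Nesting.HYPOGEAN
    params = FTParameters(
        ft_id=profile.label(),
        r=_GROWTH_RATE[(profile.foraging_distance, profile.parasite_host)],
        c=_COMPETITION[(profile.foraging_distance, profile.diet)],
        forage_suitability=_FORAGE_SUIT[(profile.diet, two_periods)],
        nest_suitability=_NEST_SUIT[nesting],
        disp_mean=disp_mean,
        disp_sd=disp_sd,
        dist_eff=_DIST_EFF[profile.nesting],
    )
    if overrides:
        unknown = set(overrides) - set(params.__dataclass_fields__)
        if unknown:
            raise TraitError(f"unknown parameter override(s): {sorted(unknown)}")
        params = replace(params, **overrides)  # type: ignore[arg-type]
    return params


def period_set(period: FlyingPeriod) -> frozenset[FlyingPeriod]:
    if period is FlyingPeriod.BOTH:
        return frozenset((FlyingPeriod.FIRST, FlyingPeriod.SECOND))
    return frozenset((period,))


def flying_periods_overlap(p1: FlyingPeriod, p2: FlyingPeriod) -> bool:
    """True iff the activity windows intersect; bivoltine types overlap everyone."""
    return bool(period_set(FlyingPeriod(p1)) & period_set(FlyingPeriod(p2)))


@dataclass
class FTCommunity:
    """Ordered collection of (trait profile, parameters), one entry per distinct profile."""

    profiles: list[TraitProfile]
    parameters: list[FTParameters]
    species_counts: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.profiles) != len(self.parameters):
            raise TraitError("profiles and parameters must have equal length")
        if len(set(self.profiles)) != len(self.profiles):
            raise TraitError("duplicate trait profiles in community")
        ids = [p.ft_id for p in self.parameters]
        if len(set(ids)) != len(ids):
            raise TraitError("duplicate ft_ids in community")
        if not self.species_counts:
            self.species_counts = [1] * len(self.profiles)

    @property
    def size(self) -> int:
        return len(self.profiles)

    def __len__(self) -> int:
        return self.size

    def ft_ids(self) -> list[str]:
        return [p.ft_id for p in self.parameters]

    # vectorized parameter views used by the engine -----------------------------
    def r_array(self) -> np.ndarray:
        return np.array([p.r for p in self.parameters])

    def c_array(self) -> np.ndarray:
        return np.array([p.c for p in self.parameters], dtype=float)

    def b_array(self) -> np.ndarray:
        return np.array([p.b for p in self.parameters])

    def dist_eff_array(self) -> np.ndarray:
        return np.array([p.dist_eff for p in self.parameters])

    def forage_suit_matrix(self) -> np.ndarray:
        """(S, 6) foraging suitability by land-use code."""
        return np.array([p.forage_suitability for p in self.parameters])

    def nest_suit_matrix(self) -> np.ndarray:
        return np.array([p.nest_suitability for p in self.parameters])

    def disp_mean_array(self) -> np.ndarray:
        return np.array([p.disp_mean for p in self.parameters])

    def disp_sd_array(self) -> np.ndarray:
        return np.array([p.disp_sd for p in self.parameters])

    def trans_nest_array(self) -> np.ndarray:
        return np.array([p.trans_effect_nest for p in self.parameters])

    def trans_res_array(self) -> np.ndarray:
        return np.array([p.trans_effect_res for p in self.parameters])

    def emigration_mu_array(self) -> np.ndarray:
        return np.array([p.emigration_mu for p in self.parameters])

    def emigration_omega_array(self) -> np.ndarray:
        return np.array([p.emigration_omega for p in self.parameters])

    def overlap_matrix(self) -> np.ndarray:
        """(S, S) boolean: do types i and j share a flying period?"""
        S = self.size
        out = np.zeros((S, S), dtype=bool)
        for i in range(S):
            for j in range(S):
                out[i, j] = flying_periods_overlap(
                    self.profiles[i].flying_period, self.profiles[j].flying_period
                )
        return out

    def with_overrides(self, overrides: Mapping[str, object]) -> "FTCommunity":
        """New community with per-field overrides applied to every type.

        Values may be scalars (applied to all types) or sequences of length S.
        """
        new_params = []
        for k, p in enumerate(self.parameters):
            subs = {}
            for name, val in overrides.items():
                if isinstance(val, (list, tuple, np.ndarray)) and not isinstance(val, str):
                    if name in ("forage_suitability", "nest_suitability") and np.ndim(val) == 1:
                        subs[name] = tuple(float(v) for v in val)
                    else:
                        entry = val[k]
                        if name in ("forage_suitability", "nest_suitability"):
                            entry = tuple(float(v) for v in entry)
                        subs[name] = entry
                else:
                    subs[name] = val
            new_params.append(replace(p, **subs))
        return FTCommunity(list(self.profiles), new_params, list(self.species_counts))


TRAIT_TABLE_COLUMNS = (
    "species",
    "foraging_distance",
    "diet",
    "flying_period",
    "nesting",
    "parasite_host",
)


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("yes", "true", "1", "y"):
        return True
    if s in ("no", "false", "0", "n"):
        return False
    raise TraitError(f"cannot interpret parasite_host value {value!r}")


def _profile_from_row(row: Mapping[str, object]) -> TraitProfile:
    try:
        return TraitProfile(
            foraging_distance=ForagingDistance(str(row["foraging_distance"]).strip().lower()),
            diet=Diet(str(row["diet"]).strip().lower()),
            flying_period=FlyingPeriod(str(row["flying_period"]).strip().lower()),
            nesting=Nesting(str(row["nesting"]).strip().lower()),
            parasite_host=_parse_bool(row["parasite_host"]),
        )
    except KeyError as exc:
        raise TraitError(f"trait row missing column {exc}") from None
    except ValueError as exc:
        raise TraitError(f"unknown trait level: {exc}") from None


def classify_trait_table(rows: pd.DataFrame | Iterable[Mapping[str, object]]) -> FTCommunity:
    """Collapse a species trait table into a community of distinct functional types.

    Species sharing all five trait levels form one type; the number of species
    behind each type is kept as metadata.
    """
    if isinstance(rows, pd.DataFrame):
        records: Sequence[Mapping[str, object]] = rows.to_dict("records")
    else:
        records = list(rows)
    seen: dict[TraitProfile, int] = {}
    order: list[TraitProfile] = []
    for rec in records:
        profile = _profile_from_row(rec)
        if profile not in seen:
            seen[profile] = 0
            order.append(profile)
        seen[profile] += 1
    if not order:
        import warnings

        warnings.warn("empty trait table: returning an empty community", stacklevel=2)
    return FTCommunity(
        profiles=order,
        parameters=[derive_parameters(p) for p in order],
        species_counts=[seen[p] for p in order],
    )


def read_trait_table(path) -> FTCommunity:
    """Read a species trait CSV (columns: species, five traits) into a community."""
    return classify_trait_table(pd.read_csv(path))


def default_community(n: int = 28, seed: int = 0) -> FTCommunity:
    """A deterministic roster of ``n`` distinct profiles sampled from the 72-profile space.

    Sampling is stratified so that, for n >= 6, every level of every trait is
    represented: a greedy pass over a seeded permutation first picks profiles
    covering still-missing levels, then fills up in permutation order.
    """
    space = all_profiles()
    if not 1 <= n <= len(space):
        raise ValueError(f"n must be in [1, {len(space)}], got {n}")
    rng = np.random.default_rng(seed)
    perm = [space[i] for i in rng.permutation(len(space))]

    def levels(p: TraitProfile) -> set[tuple[str, object]]:
        return {
            ("foraging_distance", p.foraging_distance),
            ("diet", p.diet),
            ("flying_period", p.flying_period),
            ("nesting", p.nesting),
            ("parasite_host", p.parasite_host),
        }

    missing = set().union(*(levels(p) for p in space))
    chosen: list[TraitProfile] = []
    # greedy coverage pass
    for p in perm:
        if len(chosen) >= n:
            break
        cover = levels(p) & missing
        if cover:
            chosen.append(p)
            missing -= cover
    # fill remaining slots in permutation order
    taken = set(chosen)
    for p in perm:
        if len(chosen) >= n:
            break
        if p not in taken:
            chosen.append(p)
            taken.add(p)
    return FTCommunity(profiles=chosen, parameters=[derive_parameters(p) for p in chosen])
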