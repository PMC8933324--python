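import numpy as np
import pytest

from bitz import (
    FTCommunity,
    Landscape,
    ScenarioSpec,
    SimulationConfig,
    SyntheticLandscapeConfig,
    default_community,
    derive_parameters,
    generate_synthetic_landscape,
    run_scenarios,
)
from bitz.functional_types import (
    Diet,
    FlyingPeriod,
    ForagingDistance,
    Nesting,
    TraitProfile,
)
from bitz.landscape import build_patch_table, label_patches


def make_landscape(land_use, cell_size_m: float = 20.0, abz=None) -> Landscape:
    """Build a valid landscape (patch table included) from a land-use array."""
    land_use = np.asarray(land_use, dtype=np.int16)
    patch_id = label_patches(land_use)
    return Landscape(
        land_use=land_use,
        patch_id=patch_id,
        patch_table=build_patch_table(land_use, patch_id),
        abz=abz,
        cell_size_m=cell_size_m,
    )


def profile(
    foraging="short", diet="oligolectic", period="first", nesting="endogeic", host=False
) -> TraitProfile:
    return TraitProfile(
        ForagingDistance(foraging), Diet(diet), FlyingPeriod(period), Nesting(nesting), host
    )


def community_of(*profiles) -> FTCommunity:
    return FTCommunity(list(profiles), [derive_parameters(p) for p in profiles])


@pytest.fixture(scope="session")
def default_community_28() -> FTCommunity:
    return default_community(28, seed=1)


@pytest.fixture(scope="session")
def abz_gradient_results(default_community_28):
    """Buffer-zone scenario gradient on a 1x1 km synthetic landscape.

    50x50 cells with the study region's composition, 28 types, 50 years,
    10 repetitions for each of the nine buffer-zone fractions.  Shared by the
    landscape-scale acceptance checks.
    """
    ls = generate_synthetic_landscape(
        SyntheticLandscapeConfig(n_rows=50, n_cols=50, mean_patch_area_cells=80.0, seed=11)
    )
    config = SimulationConfig(base_seed=2024, store_final_state=False)
    spec = ScenarioSpec(landscapes=[("grad", ls)])
    results = run_scenarios(spec, default_community_28, config)
    return ls, config, results
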