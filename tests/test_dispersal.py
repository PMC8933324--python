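import numpy as np

from bitz.config import DispersalConfig, SimulationConfig
from bitz.dispersal import (
    build_rank_tables,
    dispersal_step,
    displacement_cells,
    emigrant_count,
    sample_displacement,
    settle,
)
from bitz.dynamics import PopulationState
from bitz.functional_types import derive_parameters
from bitz.landscape import LandUseClass

from conftest import community_of, make_landscape, profile

A = int(LandUseClass.ARABLE)
F = int(LandUseClass.FOREST)
G = int(LandUseClass.GRASSLAND)
W = int(LandUseClass.WATER)
B = int(LandUseClass.BARE)


class TestEmigrantCount:
    def test_empty_population(self):
        assert emigrant_count(0.0, 100.0, 0.2, 2.0) == 0

    def test_at_capacity(self):
        # mu * (N/K)^omega = 0.2 -> 20 emigrants out of 100
        assert emigrant_count(100.0, 100.0, 0.2, 2.0) == 20

    def test_vanishing_density(self):
        assert emigrant_count(100.0, 1e12, 0.2, 2.0) == 0

    def test_capped_at_population_size(self):
        assert emigrant_count(3.7, 0.1, 0.9, 2.0) <= 3

    def test_zero_capacity_everyone_leaves(self):
        assert emigrant_count(17.0, 0.0, 0.2, 2.0) == 17


class TestSampleDisplacement:
    def test_kernel_moments_long_type(self):
        params = derive_parameters(profile(foraging="long"))
        rng = np.random.default_rng(3)
        dists = []
        for _ in range(10_000):
            dx, dy = sample_displacement(params, rng)
            dists.append(np.hypot(dx, dy))
        dists = np.array(dists)
        assert abs(dists.mean() - 600) < 2.0
        assert abs(dists.std() - 60) < 2.0

    def test_distances_strictly_positive(self):
        params = derive_parameters(profile(foraging="short"))
        rng = np.random.default_rng(0)
        assert all(np.hypot(*sample_displacement(params, rng)) > 0 for _ in range(500))

    def test_reproducible(self):
        params = derive_parameters(profile())
        a = [sample_displacement(params, np.random.default_rng(9)) for _ in range(3)]
        b = [sample_displacement(params, np.random.default_rng(9)) for _ in range(3)]
        assert a == b

    def test_cell_rounding(self):
        assert displacement_cells(29.0, -31.0, 20.0) == (-2, 1)
        assert displacement_cells(10.0, 10.0, 20.0) == (1, 1)  # half rounds up


class TestRankTables:
    def test_ranks_follow_nest_suitability(self):
        # hypogean: forest (1.0) > urban (0.7) > grassland (0.3) > arable (0.1)
        ls = make_landscape(np.array([[F, int(LandUseClass.URBAN)], [G, A]], dtype=np.int16))
        community = community_of(profile(nesting="hypogean", foraging="short"))
        rank, n_ranks = build_rank_tables(ls, community)
        origin = (0, 0)  # all four classes in range (radius 5 covers the grid)
        assert n_ranks[0][origin] == 4
        assert rank[0][origin][F] == 1
        assert rank[0][origin][int(LandUseClass.URBAN)] == 2
        assert rank[0][origin][G] == 3
        assert rank[0][origin][A] == 4

    def test_abz_ranks_best_when_present(self):
        land_use = np.array([[A, G], [A, A]], dtype=np.int16)
        abz = np.zeros((2, 2), dtype=bool)
        abz[0, 0] = True
        ls = make_landscape(land_use, abz=abz)
        community = community_of(profile(nesting="endogeic", foraging="short"))
        rank, _ = build_rank_tables(ls, community)
        # effective ABZ suitability 0.3 + 1.0 = 1.3 beats grassland 0.7 and arable 0.3
        assert rank[0][1, 1][6] == 1


class TestSettle:
    def test_all_cells_at_capacity_returns_none(self):
        ls = make_landscape(np.full((5, 5), G))
        community = community_of(profile(foraging="short"))
        config = SimulationConfig()
        K = 50.0 * 0.7
        state = PopulationState(np.full((1, 5, 5), K))
        out = settle((2, 2), 0, state, ls, community, config, np.random.default_rng(0))
        assert out is None

    def test_single_try_accepts_only_top_class(self):
        # endogeic: bare (1.0) best; grassland (0.7) second
        land_use = np.full((21, 21), G)
        land_use[:, :10] = B
        ls = make_landscape(land_use)
        community = community_of(profile(foraging="short", nesting="endogeic"))
        config = SimulationConfig(dispersal=DispersalConfig(dispersal_tries=1))
        state = PopulationState(np.zeros((1, 21, 21)))
        rng = np.random.default_rng(1)
        settled = []
        for _ in range(200):
            dest = settle((10, 10), 0, state, ls, community, config, rng)
            if dest is not None:
                settled.append(dest)
        assert settled  # some draws land in bounds on bare ground
        assert all(ls.land_use[rc] == B for rc in settled)

    def test_never_settles_on_water(self):
        land_use = np.full((21, 21), W)
        land_use[10, 10] = G
        ls = make_landscape(land_use)
        community = community_of(profile(foraging="short"))
        config = SimulationConfig()
        state = PopulationState(np.zeros((1, 21, 21)))
        rng = np.random.default_rng(2)
        for _ in range(100):
            dest = settle((10, 10), 0, state, ls, community, config, rng)
            assert dest is None or ls.land_use[dest] != W

    def test_out_of_bounds_draws_fail_attempts(self):
        # a 2x2 island: nearly every 100 m displacement leaves the grid
        ls = make_landscape(np.full((2, 2), G))
        community = community_of(profile(foraging="short"))
        config = SimulationConfig()
        state = PopulationState(np.zeros((1, 2, 2)))
        rng = np.random.default_rng(3)
        outcomes = [settle((0, 0), 0, state, ls, community, config, rng) for _ in range(50)]
        assert outcomes.count(None) > 40


class TestDispersalStep:
    def _setup(self, mu=None):
        ls = make_landscape(np.full((15, 15), G))
        community = community_of(profile(foraging="short"))
        dispersal = DispersalConfig(emigration_mu=mu) if mu is not None else DispersalConfig()
        config = SimulationConfig(dispersal=dispersal)
        rng = np.random.default_rng(8)
        N = np.zeros((1, 15, 15))
        N[0, 7, 7] = 30.0
        N[0, 3, 3] = 20.0
        return ls, community, config, rng, PopulationState(N)

    def test_no_emigration_is_identity(self):
        ls, community, config, rng, state = self._setup(mu=0.0)
        out = dispersal_step(state, ls, community, config, rng)
        np.testing.assert_array_equal(out.abundance, state.abundance)

    def test_total_abundance_never_increases(self):
        for seed in range(5):
            ls, community, config, _, state = self._setup()
            rng = np.random.default_rng(seed)
            before = state.abundance.sum()
            out = dispersal_step(state, ls, community, config, rng)
            assert out.abundance.sum() <= before + 1e-9
            assert (out.abundance >= 0).all()

    def test_bit_identical_under_fixed_seed(self):
        ls, community, config, _, state = self._setup()
        a = dispersal_step(state.copy(), ls, community, config, np.random.default_rng(5))
        b = dispersal_step(state.copy(), ls, community, config, np.random.default_rng(5))
        np.testing.assert_array_equal(a.abundance, b.abundance)

    def test_water_never_colonized(self):
        land_use = np.full((15, 15), G)
        land_use[:, 10:] = W
        ls = make_landscape(land_use)
        community = community_of(profile(foraging="short"))
        config = SimulationConfig()
        N = np.zeros((1, 15, 15))
        N[0, 7, 7] = 40.0
        state = PopulationState(N)
        for seed in range(5):
            out = dispersal_step(state.copy(), ls, community, config, np.random.default_rng(seed))
            assert not out.abundance[0][ls.land_use == W].any()

    def test_empty_suitable_patch_gains_colonists(self):
        """A population beside empty high-suitability habitat sends settlers there."""
        land_use = np.full((15, 15), G)
        land_use[:, 8:] = B  # bare: best endogeic nesting, initially empty
        ls = make_landscape(land_use)
        community = community_of(profile(foraging="short", nesting="endogeic"))
        config = SimulationConfig()
        gains = []
        for seed in range(30):
            N = np.zeros((1, 15, 15))
            N[0, :, 5:8] = 30.0  # crowded grassland strip near the border
            state = PopulationState(N)
            out = dispersal_step(state, ls, community, config, np.random.default_rng(seed))
            gains.append(out.abundance[0][ls.land_use == B].sum())
        assert np.mean(gains) > 0
        assert np.quantile(gains, 0.05) >= 0  # and typically strictly positive
        assert sum(g > 0 for g in gains) >= 27


def test_capacity_respected_during_settlement():
    """Settlers never push a destination population above its nesting capacity."""
    land_use = np.full((9, 9), G)
    ls = make_landscape(land_use)
    community = community_of(profile(foraging="short"))
    config = SimulationConfig(k_max=5.0)  # tiny capacities force contention
    K = 5.0 * 0.7
    N = np.full((1, 9, 9), 3.0)
    state = PopulationState(N)
    out = dispersal_step(state, ls, community, config, np.random.default_rng(0))
    # pre-existing populations were below K; settlement may only fill up to K
    assert out.abundance.max() <= np.ceil(K)
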