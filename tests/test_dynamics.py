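import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bitz.config import SimulationConfig
from bitz.dynamics import (
    CellOccupancy,
    PopulationState,
    cell_resource_uptake,
    competition_load,
    disk_offsets,
    draw_weather,
    foraging_cells,
    grow,
    growth_step,
    mean_resource_uptake,
    nest_capacity,
    nest_capacity_grids,
)
from bitz.functional_types import derive_parameters
from bitz.landscape import LandUseClass

from conftest import community_of, make_landscape, profile

A = int(LandUseClass.ARABLE)
G = int(LandUseClass.GRASSLAND)
W = int(LandUseClass.WATER)
B = int(LandUseClass.BARE)


class TestWeather:
    def test_zero_sd_degenerates_to_one(self):
        assert draw_weather(np.random.default_rng(0), 0.0).factor == 1.0

    def test_monte_carlo_moments(self):
        rng = np.random.default_rng(1)
        draws = np.array([draw_weather(rng, 0.15).factor for _ in range(10_000)])
        assert abs(draws.mean() - 1.0) < 0.01
        assert abs(draws.std() - 0.15) < 0.01
        assert (draws >= 0).all()

    def test_deterministic_sequence(self):
        a = [draw_weather(np.random.default_rng(7), 0.15).factor for _ in range(5)]
        b = [draw_weather(np.random.default_rng(7), 0.15).factor for _ in range(5)]
        assert a == b


class TestForagingGeometry:
    def test_short_type_disk_has_81_cells(self):
        # independent enumeration: offsets with dx^2 + dy^2 <= 5^2
        expected = {
            (dx, dy)
            for dx in range(-5, 6)
            for dy in range(-5, 6)
            if dx * dx + dy * dy <= 25
        }
        assert len(expected) == 81
        assert set(disk_offsets(5.0)) == expected
        ls = make_landscape(np.full((20, 20), G))
        cells = foraging_cells(ls, (10, 10), 100.0)  # 100 m / 20 m = 5 cells
        assert len(cells) == 81

    def test_corner_clipping(self):
        ls = make_landscape(np.full((20, 20), G))
        cells = foraging_cells(ls, (0, 0), 100.0)
        assert len(cells) < 81
        assert all(0 <= r < 20 and 0 <= c < 20 for r, c in cells)

    def test_zero_radius_is_focal_cell(self):
        ls = make_landscape(np.full((3, 3), G))
        assert foraging_cells(ls, (1, 1), 0.0) == {(1, 1)}


class TestCompetitionLoad:
    def _occ(self, foraging, community):
        return CellOccupancy(nesting=np.zeros(len(foraging)), foraging=foraging, community=community)

    def test_conspecifics_only_gives_zero(self):
        community = community_of(profile())
        assert competition_load(self._occ([120.0], community), 0) == 0.0

    def test_strong_competitor_feels_nothing_from_weak(self):
        # c_j=0 (long polylectic) vs c_i=5 (short oligolectic), C_total=5
        community = community_of(
            profile(foraging="long", diet="polylectic"),
            profile(foraging="short", diet="oligolectic"),
        )
        occ = self._occ([50.0, 100.0], community)
        assert competition_load(occ, 0) == pytest.approx(0.0)  # (1 + (0-5)/5) * 100

    def test_weak_competitor_feels_double_load(self):
        community = community_of(
            profile(foraging="long", diet="polylectic"),
            profile(foraging="short", diet="oligolectic"),
        )
        occ = self._occ([50.0, 100.0], community)
        assert competition_load(occ, 1) == pytest.approx(2 * 50.0)  # (1 + (5-0)/5) * 50

    def test_disjoint_flying_periods_do_not_compete(self):
        community = community_of(profile(period="first"), profile(period="second", diet="polylectic"))
        occ = self._occ([100.0, 100.0], community)
        assert competition_load(occ, 0) == 0.0
        assert competition_load(occ, 1) == 0.0


class TestCellResourceUptake:
    def test_sole_forager_on_grassland(self):
        community = community_of(profile(diet="oligolectic", period="first"))
        occ = CellOccupancy(np.zeros(1), np.array([42.0]), community)
        assert cell_resource_uptake(occ, 0, G, False) == pytest.approx(1.0)

    def test_hand_evaluated_printed_form(self):
        # beta=200, N_j=100, N_total=200, suitability 1.5 -> 2.25
        community = community_of(
            profile(foraging="short", diet="oligolectic", period="both"),
            profile(foraging="long", diet="polylectic", period="both"),
        )
        occ = CellOccupancy(np.zeros(2), np.array([100.0, 100.0]), community)
        # c_j=5, c_i=0, C_total=5: beta = (1 + 5/5) * 100 = 200
        got = cell_resource_uptake(occ, 0, G, False, form="printed")
        assert got == pytest.approx((200 + 100) / 200 * 1.5)

    def test_inverted_form_reciprocal(self):
        community = community_of(
            profile(foraging="short", diet="oligolectic", period="both"),
            profile(foraging="long", diet="polylectic", period="both"),
        )
        occ = CellOccupancy(np.zeros(2), np.array([100.0, 100.0]), community)
        got = cell_resource_uptake(occ, 0, G, False, form="inverted")
        assert got == pytest.approx(200 / (200 + 100) * 1.5)

    def test_abz_bonus_added_to_suitability(self):
        community = community_of(profile(diet="polylectic", period="both"))
        occ = CellOccupancy(np.zeros(1), np.array([10.0]), community)
        assert cell_resource_uptake(occ, 0, A, True) == pytest.approx(1.05 + 1.0)


class TestMeanResourceUptake:
    def test_homogeneous_range_equals_cell_uptake(self):
        ls = make_landscape(np.full((15, 15), G))
        community = community_of(profile(diet="oligolectic", period="first"))
        state = PopulationState(np.zeros((1, 15, 15)))
        state.abundance[0, 7, 7] = 10.0
        got = mean_resource_uptake(state, ls, (7, 7), 0, community)
        assert got == pytest.approx(1.0)

    def test_mixed_range_averages_constants(self):
        # rows >= 8 are water (suitability 0); count the in-range split exactly
        land_use = np.full((15, 15), G)
        land_use[8:, :] = W
        ls = make_landscape(land_use)
        community = community_of(profile(diet="oligolectic", period="first"))
        state = PopulationState(np.zeros((1, 15, 15)))
        state.abundance[0, 7, 7] = 10.0
        cells = foraging_cells(ls, (7, 7), 100.0)
        n_grass = sum(1 for r, _ in cells if r < 8)
        expected = n_grass * 1.0 / len(cells)
        assert mean_resource_uptake(state, ls, (7, 7), 0, community) == pytest.approx(expected)

    def test_boundary_clipped_range(self):
        ls = make_landscape(np.full((6, 6), G))
        community = community_of(profile(diet="oligolectic", period="first"))
        state = PopulationState(np.zeros((1, 6, 6)))
        state.abundance[0, 0, 0] = 5.0
        assert mean_resource_uptake(state, ls, (0, 0), 0, community) == pytest.approx(1.0)


class TestNestCapacity:
    def test_endogeic_on_bare(self):
        ls = make_landscape(np.full((3, 3), B))
        community = community_of(profile(nesting="endogeic"))
        assert nest_capacity(ls, (1, 1), 0, community, 50.0) == pytest.approx(50.0)

    def test_endogeic_on_abz_arable(self):
        land_use = np.full((3, 3), A)
        abz = np.zeros((3, 3), dtype=bool)
        abz[1, 1] = True
        ls = make_landscape(land_use, abz=abz)
        community = community_of(profile(nesting="endogeic"))
        assert nest_capacity(ls, (1, 1), 0, community, 50.0) == pytest.approx(65.0)

    def test_water_is_uninhabitable(self):
        ls = make_landscape(np.full((3, 3), W))
        for nesting in ("endogeic", "hypogean"):
            community = community_of(profile(nesting=nesting))
            assert nest_capacity(ls, (0, 0), 0, community, 50.0) == 0.0


class TestGrow:
    def test_equilibrium_at_capacity(self):
        assert grow(N=100, r=5, K=100, beta_nest=0, mean_uptake=1, weather=1) == pytest.approx(100)

    def test_hand_evaluated_step(self):
        # 100 * 5 / (1 + 4 * 2) = 55.56
        got = grow(N=100, r=5, K=100, beta_nest=100, mean_uptake=1, weather=1)
        assert got == pytest.approx(500 / 9, abs=1e-9)

    def test_low_density_limit(self):
        n0 = 1e-4
        got = grow(N=n0, r=4, K=1e9, beta_nest=0, mean_uptake=1.2, weather=0.9,
                   extinction_threshold=0.0)
        assert got / n0 == pytest.approx(4 * 1.2 * 0.9, rel=1e-6)

    def test_zero_capacity_extinguishes(self):
        assert grow(N=50, r=3, K=0, beta_nest=0, mean_uptake=1, weather=1) == 0.0

    def test_extinction_threshold(self):
        assert grow(N=0.5, r=1.0, K=100, beta_nest=0, mean_uptake=1, weather=1) == 0.0

    @given(
        beta=st.floats(0, 500),
        uptake=st.floats(0.1, 2.0),
        weather=st.floats(0.1, 2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotonicity(self, beta, uptake, weather):
        base = grow(100, 4, 200, beta, uptake, weather, extinction_threshold=0.0)
        more_beta = grow(100, 4, 200, beta + 10, uptake, weather, extinction_threshold=0.0)
        more_food = grow(100, 4, 200, beta, uptake + 0.1, weather, extinction_threshold=0.0)
        better_year = grow(100, 4, 200, beta, uptake, weather + 0.1, extinction_threshold=0.0)
        assert more_beta <= base <= more_food
        assert base <= better_year


class TestGrowthStep:
    def _neutral_config(self):
        return SimulationConfig(weather_std=0.0)

    def test_empty_landscape_stays_empty(self):
        ls = make_landscape(np.full((8, 8), G))
        community = community_of(profile())
        state = PopulationState(np.zeros((1, 8, 8)))
        out = growth_step(state, ls, community, draw_weather(np.random.default_rng(0), 0.0),
                          self._neutral_config())
        assert not out.abundance.any()

    def test_single_population_at_capacity_is_fixed_point(self):
        ls = make_landscape(np.full((12, 12), G))
        community = community_of(profile(diet="oligolectic", period="first"))
        K = 50.0 * 0.7  # k_max * grassland endogeic suitability
        state = PopulationState(np.full((1, 12, 12), K))
        out = growth_step(state, ls, community, draw_weather(np.random.default_rng(0), 0.0),
                          self._neutral_config())
        # grassland uptake = 1.0, no competitors: N stays at K everywhere
        assert out.abundance == pytest.approx(state.abundance)

    def test_convergence_to_capacity(self):
        """Single type, uptake 1, no noise: trajectories reach K from any start."""
        ls = make_landscape(np.full((10, 10), G))
        community = community_of(profile(diet="oligolectic", period="first"))
        config = self._neutral_config()
        weather = draw_weather(np.random.default_rng(0), 0.0)
        K = 50.0 * 0.7
        state = PopulationState(np.full((1, 10, 10), 3.0))
        for _ in range(200):
            state = growth_step(state, ls, community, weather, config)
        assert np.abs(state.abundance - K).max() < 1e-6

    def test_symmetric_competitors_grow_less_than_alone(self):
        ls = make_landscape(np.full((9, 9), G))
        p1 = profile(foraging="short", diet="oligolectic", period="both")
        p2 = profile(foraging="short", diet="oligolectic", period="both", host=True)
        config = self._neutral_config().replace(uptake_form="inverted")
        weather = draw_weather(np.random.default_rng(0), 0.0)
        pair = community_of(p1, p2)
        both = PopulationState(np.full((2, 9, 9), 5.0))
        out_both = growth_step(both, ls, pair, weather, config)
        alone = PopulationState(np.full((1, 9, 9), 5.0))
        out_alone = growth_step(alone, ls, community_of(p1), weather, config)
        assert np.all(out_both.abundance[0] < out_alone.abundance[0])

    def test_processing_order_invariance(self):
        """Synchronous update: permuting the community order permutes the output."""
        from bitz.functional_types import FTCommunity

        ls = make_landscape(np.tile([G, A, B, G], (8, 2)))
        profiles = [
            profile(foraging="short", diet="oligolectic", period="both"),
            profile(foraging="medium", diet="polylectic", period="first", nesting="hypogean"),
            profile(foraging="short", diet="polylectic", period="second"),
        ]
        community = community_of(*profiles)
        rng = np.random.default_rng(5)
        N = rng.integers(0, 20, size=(3, 8, 8)).astype(float)
        config = self._neutral_config()
        weather = draw_weather(np.random.default_rng(0), 0.0)
        out = growth_step(PopulationState(N.copy()), ls, community, weather, config)
        perm = [2, 0, 1]
        community_p = community_of(*[profiles[i] for i in perm])
        out_p = growth_step(PopulationState(N[perm].copy()), ls, community_p, weather, config)
        np.testing.assert_allclose(out_p.abundance, out.abundance[perm], rtol=0, atol=1e-12)

    def test_capacity_grids_match_scalar(self):
        land_use = np.array([[A, G], [W, B]], dtype=np.int16)
        abz = np.zeros((2, 2), dtype=bool)
        abz[0, 0] = True
        ls = make_landscape(land_use, abz=abz)
        community = community_of(profile(nesting="endogeic"), profile(nesting="hypogean"))
        grids = nest_capacity_grids(ls, community, 50.0)
        for j in range(2):
            for cell in [(0, 0), (0, 1), (1, 0), (1, 1)]:
                assert grids[(j, *cell)] == pytest.approx(
                    nest_capacity(ls, cell, j, community, 50.0)
                )


def test_vectorized_step_matches_scalar_oracle_small():
    """Spot equivalence of the engine path with the literal per-cell reference."""
    from _oracle import oracle_growth_step, params_from_community

    rng = np.random.default_rng(42)
    profiles = [
        profile(foraging="short", diet="oligolectic", period="first"),
        profile(foraging="short", diet="polylectic", period="both", nesting="hypogean"),
    ]
    # shrink the foraging disk to keep the oracle loops tiny
    from bitz.functional_types import FTCommunity, derive_parameters

    params = [derive_parameters(p, overrides={"disp_mean": 40.0, "disp_sd": 4.0}) for p in profiles]
    params = [p.__class__(**{**p.__dict__, "ft_id": f"ft{i}"}) for i, p in enumerate(params)]
    community = FTCommunity(profiles, params)
    land_use = rng.integers(0, 6, size=(5, 5)).astype(np.int16)
    ls = make_landscape(land_use)
    ls.abz[(ls.land_use == A)] = True
    N = rng.integers(0, 30, size=(2, 5, 5)).astype(float) * (rng.random((2, 5, 5)) < 0.6)
    config = SimulationConfig(weather_std=0.0)
    weather = 0.93
    got = growth_step(
        PopulationState(N.copy()), ls, community,
        type("W", (), {"factor": weather})(), config,
    )
    want = oracle_growth_step(
        N, ls.land_use, ls.abz, params_from_community(community),
        weather, config.k_max, ls.cell_size_m,
    )
    np.testing.assert_allclose(got.abundance, want, rtol=0, atol=1e-10)
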