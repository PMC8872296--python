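import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metroexposure import blank_grid
from metroexposure.pedestrians import (ALIGHTING, BOARDING, DemandSpec,
                                       DensityField, RouteCostWeights,
                                       SpeedModel, Trajectory, _Itinerary,
                                       _fifo_multiserver, _sample_positions,
                                       density_map, derive_sources,
                                       residence_stats, route_cost,
                                       sample_speed, service_level,
                                       simulate_trajectories)
from metroexposure.station import CONCOURSE, FLOOR_CODES, BoundaryConditions


class TestSpeedModel:
    def test_degenerate_spread_returns_mean(self):
        rng = np.random.default_rng(0)
        assert sample_speed(SpeedModel(spread=0.0), rng) == 1.25

    def test_sample_mean_matches_model(self):
        rng = np.random.default_rng(1)
        draws = sample_speed(SpeedModel(), rng, size=100_000)
        se = 0.2 / np.sqrt(draws.size)
        assert abs(draws.mean() - 1.25) < 3 * se
        assert draws.min() >= 0.3 and draws.max() <= 2.5

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            SpeedModel(mean=-1.0)

    def test_variance_interpretation(self):
        m = SpeedModel(interpretation="variance")
        assert m.sd == pytest.approx(np.sqrt(0.2))


class TestRouteCost:
    def test_worked_examples(self):
        w = RouteCostWeights()
        assert route_cost(50, 1.25, 30, 10, w) == pytest.approx(80.0)
        w0 = RouteCostWeights(w_queue=0.0, w_component=0.0)
        assert route_cost(50, 1.25, 30, 10, w0) == pytest.approx(40.0)

    @given(q1=st.floats(0, 500), q2=st.floats(0, 500))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_queue_time(self, q1, q2):
        w = RouteCostWeights()
        lo, hi = sorted([q1, q2])
        assert route_cost(50, 1.25, lo, 5, w) <= route_cost(50, 1.25, hi, 5, w)

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(ValueError):
            route_cost(10, 0.0, 0, 0, RouteCostWeights())


class TestServiceLevel:
    @pytest.mark.parametrize("density,level", [
        (0.0, "A"), (0.370, "A"), (0.4, "B"), (0.435, "B"), (0.5, "C"),
        (0.526, "C"), (0.6, "D"), (0.667, "D"), (0.8, "E"), (1.0, "E"),
        (1.2, "F"),
    ])
    def test_thresholds_closed_upper(self, density, level):
        assert service_level(density) == level

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            service_level(-0.1)


def _stationary_trajectory(pid, x, y, n_seconds, floor=CONCOURSE,
                           direction=BOARDING):
    t = np.arange(n_seconds, dtype=np.int64)
    code = FLOOR_CODES[floor]
    return Trajectory(pid, direction, "exit_A", "psd_CD", t,
                      np.full(n_seconds, x), np.full(n_seconds, y),
                      np.full(n_seconds, code, np.int8))


class TestDensityMap:
    def test_single_stationary_agent_unit_cell(self):
        grid = blank_grid(CONCOURSE, 5, 5, 1.0)
        tr = _stationary_trajectory(0, 2.5, 2.5, 60)
        dens = density_map([tr], grid, (0, 60))
        assert dens.values[2, 2] == pytest.approx(1.0)
        assert dens.values.sum() == pytest.approx(1.0)

    def test_linearity_under_duplication(self):
        grid = blank_grid(CONCOURSE, 5, 5, 1.0)
        tr = _stationary_trajectory(0, 1.5, 3.5, 30)
        d1 = density_map([tr], grid, (0, 30))
        d2 = density_map([tr, tr], grid, (0, 30))
        np.testing.assert_allclose(d2.values, 2 * d1.values)

    def test_integral_equals_mean_occupancy(self, short_sim, grids):
        grid = grids[CONCOURSE]
        window = (100.0, 400.0)
        dens = density_map(short_sim, grid, window)
        integral = dens.values.sum() * grid.cell_area
        # direct oracle: average concurrent head-count on the floor
        code = FLOOR_CODES[CONCOURSE]
        count = sum(
            int(np.sum((tr.t >= window[0]) & (tr.t < window[1])
                       & (tr.floor == code)))
            for tr in short_sim)
        assert integral == pytest.approx(count / (window[1] - window[0]))

    def test_empty_window_rejected(self):
        grid = blank_grid(CONCOURSE, 3, 3, 1.0)
        with pytest.raises(ValueError):
            density_map([], grid, (5.0, 5.0))


class TestDeriveSources:
    def test_emission_is_persons_times_rate(self):
        grid = blank_grid(CONCOURSE, 6, 6, 1.0)
        values = np.zeros(grid.shape)
        values[2:4, 2:4] = 1.25  # 4 m^2 congested region holding 5 persons
        dens = DensityField(grid, values, (0, 60))
        sources = derive_sources(dens, BoundaryConditions(), "C")
        assert len(sources) == 1
        assert sources[0].persons == pytest.approx(5.0)
        assert sources[0].rate_mg_per_h == pytest.approx(50.0)
        assert sources[0].radius_m == pytest.approx(np.sqrt(4 / np.pi))

    def test_uncongested_floor_yields_no_sources(self):
        grid = blank_grid(CONCOURSE, 6, 6, 1.0)
        dens = DensityField(grid, np.full(grid.shape, 0.2), (0, 60))
        assert derive_sources(dens, BoundaryConditions(), "C") == []

    def test_out_of_range_generation_rate_warns(self):
        grid = blank_grid(CONCOURSE, 3, 3, 1.0)
        dens = DensityField(grid, np.zeros(grid.shape), (0, 60))
        with pytest.warns(UserWarning):
            derive_sources(dens, BoundaryConditions(r_per=20.0), "C")


class TestResidenceStats:
    def test_min_max_mean(self):
        trs = [_stationary_trajectory(i, 1, 1, n + 1)
               for i, n in enumerate((50, 100, 150))]
        s = residence_stats(trs)[BOARDING]
        assert (s["min"], s["max"], s["mean"]) == (50.0, 150.0, 100.0)

    def test_single_trajectory_degenerate(self):
        s = residence_stats([_stationary_trajectory(0, 1, 1, 31)])[BOARDING]
        assert s["min"] == s["max"] == s["mean"] == 30.0

    def test_mean_equals_direct_average(self, short_sim):
        stats = residence_stats(short_sim)
        for direction in (BOARDING, ALIGHTING):
            res = [tr.residence_s for tr in short_sim
                   if tr.direction == direction]
            assert stats[direction]["mean"] == pytest.approx(np.mean(res))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            residence_stats([])


class TestKinematics:
    def test_straight_corridor_residence(self):
        """50 m at a fixed 1.25 m/s takes 40 s of 1-s samples."""
        it = _Itinerary(0.0, (0.0, 1.0), 0, 1.25)
        it.walk_to((50.0, 1.0))
        ts, x, y, fl = _sample_positions(it.legs)
        assert abs((ts[-1] - ts[0]) - 40.0) <= 1.0
        steps = np.hypot(np.diff(x), np.diff(y))
        assert np.all(steps <= 1.25 + 1e-9)


class TestFifoQueue:
    def test_no_overtaking_and_service_order(self):
        rng = np.random.default_rng(3)
        arrivals = rng.uniform(0, 100, 40)
        start, depart, qlen = _fifo_multiserver(arrivals, 2, 3.0)
        order = np.argsort(arrivals, kind="stable")
        assert np.all(np.diff(start[order]) >= 0)
        assert np.all(start >= arrivals)
        assert np.all(depart == start + 3.0)


class TestSimulation:
    def test_zero_demand_yields_empty(self, geometry):
        demand = DemandSpec(boarding_per_hour={"CD": 0, "AB": 0},
                            alighting_per_hour={"CD": 0, "AB": 0})
        sim = simulate_trajectories(demand, geometry, duration=300, seed=0)
        assert len(sim) == 0 and sim.spawned == 0

    def test_agent_conservation(self, short_sim):
        assert len(short_sim) + len(short_sim.dropped) == short_sim.spawned

    def test_deterministic_per_seed(self, geometry):
        demand = DemandSpec()
        a = simulate_trajectories(demand, geometry, duration=240, seed=9)
        b = simulate_trajectories(demand, geometry, duration=240, seed=9)
        assert len(a) == len(b)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.t, tb.t)
            np.testing.assert_allclose(ta.x, tb.x)
            np.testing.assert_allclose(ta.y, tb.y)

    def test_trajectory_invariants(self, short_sim, geometry):
        v_max = SpeedModel().bounds[1]
        for tr in list(short_sim)[::17]:
            assert np.all(np.diff(tr.t) == 1)
            same_floor = tr.floor[1:] == tr.floor[:-1]
            steps = np.hypot(np.diff(tr.x), np.diff(tr.y))[same_floor]
            assert np.all(steps <= v_max + 1e-6)
            for code, name in ((0, "concourse"), (1, "platform")):
                sel = tr.floor == code
                if sel.any():
                    assert np.all(geometry.contains(name, tr.x[sel], tr.y[sel]))

    def test_boarding_slower_than_alighting(self, short_sim):
        stats = residence_stats(short_sim)
        assert stats[BOARDING]["n"] >= 200
        assert stats[BOARDING]["mean"] > stats[ALIGHTING]["mean"]

    def test_invalid_duration_rejected(self, geometry):
        with pytest.raises(ValueError):
            simulate_trajectories(DemandSpec(), geometry, duration=0, seed=0)
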