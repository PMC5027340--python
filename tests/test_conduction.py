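import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epimap.conduction import (
    conduction_heterogeneity_index,
    fit_triangle_velocity,
    percentile,
    phase_map,
    wave_propagation_velocity,
)
from epimap.errors import (
    EmptyResultError,
    InvalidParameterError,
    NoEstimateError,
    UndefinedIndexError,
)
from epimap.features import ActivationMap
from epimap.synthetic import make_geometry, simulate_planar_truth


class TestTriangleFit:
    def test_axis_aligned_09(self):
        fit = fit_triangle_velocity([(0, 0), (2.7, 0), (0, 2.7)], [0, 3, 0])
        assert fit.valid
        assert fit.speed_mps == pytest.approx(0.9)
        assert fit.direction_deg == pytest.approx(0.0, abs=1e-9)

    def test_analytic_45_degree_plane(self):
        pos = np.array([(0.0, 0.0), (2.7, 0.0), (0.0, 2.7)])
        times = 0.5 * pos[:, 0] + 0.5 * pos[:, 1] + 2.0
        fit = fit_triangle_velocity(pos, times)
        assert fit.speed_mps == pytest.approx(1.0 / np.sqrt(0.5))
        assert fit.direction_deg == pytest.approx(45.0)

    def test_collinear_invalid(self):
        fit = fit_triangle_velocity([(0, 0), (1, 1), (2, 2)], [0, 1, 2])
        assert not fit.valid
        assert fit.reason == "degenerate geometry"

    def test_equal_times_unresolvable(self):
        fit = fit_triangle_velocity([(0, 0), (2.7, 0), (0, 2.7)], [5.0, 5.0, 5.0])
        assert not fit.valid
        assert fit.reason == "unresolvable gradient"

    def test_speed_bounds(self):
        fit = fit_triangle_velocity([(0, 0), (2.7, 0), (0, 2.7)], [0, 0.01, 0],
                                    speed_bounds=(0.1, 5.0))
        assert not fit.valid
        assert fit.reason == "speed out of bounds"

    def test_wrong_shapes(self):
        with pytest.raises(InvalidParameterError):
            fit_triangle_velocity([(0, 0), (1, 0)], [0, 1])

    @settings(max_examples=60, deadline=None)
    @given(direction=st.floats(0, 359.999), speed=st.floats(0.3, 2.0))
    def test_unbiased_on_noiseless_planes(self, direction, speed):
        g = make_geometry(4, 4, 2.7)
        truth = simulate_planar_truth(g, speed, direction, 5.0)
        am = ActivationMap.from_times(truth.times_ms)
        field = wave_propagation_velocity(am, g)
        assert field.wpv_mps == pytest.approx(speed, rel=1e-9)


class TestWPV:
    def test_noiseless_planar(self, grid16x8, truth_map):
        field = wave_propagation_velocity(truth_map, grid16x8)
        assert field.wpv_mps == pytest.approx(0.9, rel=1e-6)
        assert field.n_valid == 210
        assert np.all(field.valid)
        circ = np.minimum(field.direction_deg[field.valid] % 360.0,
                          360.0 - field.direction_deg[field.valid] % 360.0)
        np.testing.assert_allclose(circ, 0.0, atol=1e-6)

    def test_jittered_within_5_percent(self, grid16x8):
        rng = np.random.default_rng(8)
        truth = simulate_planar_truth(grid16x8, 1.0, 30.0, 20.0)
        am = ActivationMap.from_times(truth.times_ms
                                      + rng.uniform(-0.5, 0.5, 128))
        field = wave_propagation_velocity(am, grid16x8)
        assert field.wpv_mps == pytest.approx(1.0, rel=0.05)

    def test_simultaneous_activation_no_estimate(self, grid16x8):
        am = ActivationMap.from_times(np.full(128, 7.0))
        with pytest.raises(NoEstimateError):
            wave_propagation_velocity(am, grid16x8)

    def test_invalid_vertices_excluded(self, grid16x8, planar_truth):
        valid = np.ones(128, bool)
        valid[:8] = False  # whole first row
        am = ActivationMap.from_times(planar_truth.times_ms, valid=valid)
        field = wave_propagation_velocity(am, grid16x8)
        assert field.n_valid == 14 * 7 * 2
        # the 7 cells between rows 0 and 1 lose both of their triangles
        assert field.rejection_counts()["invalid vertex"] == 7 * 2

    def test_median_summary(self, grid16x8, truth_map):
        field = wave_propagation_velocity(truth_map, grid16x8, summary="median")
        assert field.summary == "median"
        assert field.wpv_mps == pytest.approx(0.9, rel=1e-6)
        with pytest.raises(InvalidParameterError):
            wave_propagation_velocity(truth_map, grid16x8, summary="mode")

    def test_rotation_equivariance(self, grid16x8):
        """Rotating geometry and wavefront rotates directions, not speeds."""
        theta = 25.0
        truth = simulate_planar_truth(grid16x8, 0.8, 10.0, 5.0)
        base = wave_propagation_velocity(
            ActivationMap.from_times(truth.times_ms), grid16x8)
        rot_geom = grid16x8.transformed(rotation_deg=theta)
        rot_truth = simulate_planar_truth(grid16x8, 0.8, 10.0 + theta, 5.0)
        # same activation pattern expressed in the rotated frame
        rot_times = (rot_geom.x_mm * np.cos(np.radians(10.0 + theta))
                     + rot_geom.y_mm * np.sin(np.radians(10.0 + theta))) / 0.8 + 5.0
        rot = wave_propagation_velocity(ActivationMap.from_times(rot_times), rot_geom)
        np.testing.assert_allclose(rot.speed_mps, base.speed_mps, atol=1e-9)
        np.testing.assert_allclose(
            np.mod(rot.direction_deg - base.direction_deg, 360.0), theta, atol=1e-9)
        assert rot_truth.speed_mps == 0.8
        assert base.wpv_mps == pytest.approx(0.8, rel=1e-12)


class TestPhaseMap:
    def test_planar_delays_constant(self, grid16x8, truth_map):
        pm = phase_map(truth_map, grid16x8)
        assert pm.valid.all()
        np.testing.assert_allclose(pm.delay_ms, 3.0)

    def test_single_valid_channel_empty(self, grid16x8, planar_truth):
        valid = np.zeros(128, bool)
        valid[0] = True
        am = ActivationMap.from_times(planar_truth.times_ms, valid=valid)
        with pytest.raises(EmptyResultError):
            phase_map(am, grid16x8)

    def test_random_times_equal_brute_force(self, grid16x8, rng):
        times = rng.normal(50.0, 5.0, 128)
        am = ActivationMap.from_times(times)
        pm = phase_map(am, grid16x8, resolution_ms=None)
        for ch in range(128):  # independent exhaustive neighbor scan
            expected = max(abs(times[j] - times[ch])
                           for j in grid16x8.neighbors[ch])
            assert pm.delay_ms[ch] == pytest.approx(expected, abs=1e-12)

    def test_resolution_snapping(self, grid16x8, rng):
        times = rng.normal(50.0, 5.0, 128)
        am = ActivationMap.from_times(times)
        pm = phase_map(am, grid16x8, resolution_ms=0.04)
        steps = pm.delays / 0.04
        np.testing.assert_allclose(steps, np.round(steps), atol=1e-9)

    def test_channels_without_valid_neighbor_excluded(self, grid4x4):
        valid = np.zeros(16, bool)
        valid[[0, 1, 15]] = True  # 15 is isolated from 0/1
        am = ActivationMap.from_times(np.arange(16.0), valid=valid)
        pm = phase_map(am, grid4x4)
        assert pm.valid[0] and pm.valid[1]
        assert not pm.valid[15]


class TestPercentile:
    def test_median(self):
        assert percentile([1, 2, 3, 4, 5], 50) == 3.0

    def test_interpolated_tails(self):
        assert percentile([1, 2, 3, 4, 5], 5) == pytest.approx(1.2)
        assert percentile([1, 2, 3, 4, 5], 95) == pytest.approx(4.8)

    def test_single_value(self):
        for p in (0, 17.5, 50, 100):
            assert percentile([7.25], p) == 7.25

    def test_errors(self):
        with pytest.raises(InvalidParameterError):
            percentile([], 50)
        with pytest.raises(InvalidParameterError):
            percentile([1.0], 101)

    @settings(max_examples=80, deadline=None)
    @given(values=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50),
           p=st.floats(0, 100))
    def test_matches_numpy_linear(self, values, p):
        expected = np.percentile(values, p, method="linear")
        assert percentile(values, p) == pytest.approx(expected, rel=1e-12, abs=1e-9)


class TestCHI:
    def test_constant_delays_zero(self):
        assert conduction_heterogeneity_index([2.5] * 40) == 0.0

    def test_worked_example_small(self):
        assert conduction_heterogeneity_index([1, 2, 3, 4, 5]) == pytest.approx(1.2)

    def test_worked_example_1_to_100(self):
        chi = conduction_heterogeneity_index(np.arange(1.0, 101.0))
        assert chi == pytest.approx((95.05 - 5.95) / 50.5)

    def test_zero_median_undefined(self):
        with pytest.raises(UndefinedIndexError):
            conduction_heterogeneity_index([0.0] * 30)

    def test_empty_invalid(self):
        with pytest.raises(InvalidParameterError):
            conduction_heterogeneity_index([])

    @settings(max_examples=60, deadline=None)
    @given(delays=st.lists(st.floats(0.1, 100), min_size=3, max_size=40),
           k=st.floats(0.01, 1000))
    def test_scale_invariance(self, delays, k):
        base = conduction_heterogeneity_index(delays)
        scaled = conduction_heterogeneity_index(np.asarray(delays) * k)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)
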