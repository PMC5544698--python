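import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kymoflow import (
    NeuriteSimSpec,
    AlignmentError,
    GrowthConeTrack,
    Kymograph,
    VelocityProfile,
    align_tzone,
    average_profiles,
    calibrate_flow,
    endpoint_velocity,
    estimate_gc_track,
    find_tzone,
    kymoflow,
    linregress,
    mask_beyond_edge,
    profile_from_flow,
    shear_align,
    simulate_neurite_kymograph,
)


class TestGcTrack:
    def test_supplied_trace_gives_exact_slope(self):
        kymo = Kymograph(np.zeros((50, 50)), pixel_size=0.1, frame_interval=5.0)
        trace = np.array([[0.0, 5.0], [49.0, 29.5]])  # 0.5 p/f
        track = estimate_gc_track(kymo, method="trace", trace=trace)
        assert track.velocity == pytest.approx(0.5 * kymo.pf_to_umh)

    def test_edge_method_recovers_generator_velocity(self, sim_cell):
        spec, kymo, truth = sim_cell
        track = estimate_gc_track(kymo, method="edge")
        assert track.velocity == pytest.approx(spec.gc_velocity, abs=2.0)

    def test_static_kymograph_gives_zero_velocity(self):
        grid = np.zeros((40, 60))
        grid[:, :30] = 1.0
        kymo = Kymograph(grid, pixel_size=0.1, frame_interval=5.0)
        assert estimate_gc_track(kymo).velocity == pytest.approx(0.0, abs=1e-9)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            estimate_gc_track(Kymograph(np.ones((4, 4))), method="magic")


class TestShear:
    def test_constant_track_is_identity(self):
        rng = np.random.default_rng(1)
        grid = rng.random((10, 20))
        track = GrowthConeTrack(np.full(10, 7.0), velocity=0.0)
        np.testing.assert_allclose(shear_align(grid, track), grid)

    def test_shear_then_unshear_restores_valid_region(self):
        # a smooth field so double linear interpolation stays near-exact
        t, x = np.meshgrid(np.arange(12.0), np.arange(40.0), indexing="ij")
        grid = np.sin(x / 6.0) + 0.1 * t
        pos = 3.0 + 0.8 * np.arange(12)
        fwd = shear_align(grid, GrowthConeTrack(pos, 0.0))
        back = shear_align(fwd, GrowthConeTrack(2 * pos[0] - pos, 0.0))
        m = np.isfinite(back)
        assert m.sum() > 0.5 * grid.size
        np.testing.assert_allclose(back[m], grid[m], atol=0.02)

    def test_integer_shifts_preserve_velocity_multiset(self):
        rng = np.random.default_rng(3)
        grid = rng.random((8, 30))
        pos = np.arange(8, dtype=float) * 2  # integer shifts: pure relabeling
        sheared = shear_align(grid, GrowthConeTrack(pos, 0.0))
        got = np.sort(sheared[np.isfinite(sheared)])
        lost = 2 * np.arange(8).sum()  # pixels shifted out of range
        assert got.size == grid.size - lost
        full = np.sort(np.concatenate([grid[t, 2 * t:] for t in range(8)]))
        np.testing.assert_allclose(got, full)

    def test_redetected_edge_is_constant_after_shear(self, sim_cell):
        spec, kymo, truth = sim_cell
        track = estimate_gc_track(kymo)
        sheared = shear_align(kymo.grid, track)
        resheared_kymo = Kymograph(
            np.nan_to_num(sheared), pixel_size=kymo.pixel_size, frame_interval=kymo.frame_interval
        )
        track2 = estimate_gc_track(resheared_kymo)
        assert abs(track2.velocity) < 3.0  # μm/h; residual drift ≈ 0

    def test_track_must_cover_rows(self):
        with pytest.raises(ValueError):
            shear_align(np.zeros((5, 5)), GrowthConeTrack(np.zeros(3), 0.0))


class TestProfile:
    def test_uniform_grid_gives_flat_profile(self):
        kymo = Kymograph(np.zeros((6, 10)), pixel_size=1.0, frame_interval=1.0)
        prof = profile_from_flow(np.full((6, 10), 20.0), kymo)
        np.testing.assert_allclose(prof.mean_velocity, 20.0)
        np.testing.assert_allclose(prof.ci95, 0.0)
        assert np.all(prof.n == 6)

    def test_single_valid_row_equals_that_row(self):
        kymo = Kymograph(np.zeros((4, 5)), pixel_size=1.0, frame_interval=1.0)
        grid = np.full((4, 5), np.nan)
        grid[2] = [1.0, 2.0, 3.0, 4.0, 5.0]
        prof = profile_from_flow(grid, kymo)
        # distance 0 is the distal (rightmost) column
        np.testing.assert_allclose(prof.mean_velocity, [5.0, 4.0, 3.0, 2.0, 1.0])

    def test_empty_columns_dropped(self):
        kymo = Kymograph(np.zeros((3, 4)), pixel_size=1.0, frame_interval=1.0)
        grid = np.full((3, 4), np.nan)
        grid[:, 1] = 7.0
        prof = profile_from_flow(grid, kymo)
        assert len(prof.distance) == 1

    def test_mask_beyond_edge_removes_background(self):
        track = GrowthConeTrack(np.full(4, 5.0), 0.0)
        grid = np.ones((4, 10))
        out = mask_beyond_edge(grid, track)
        assert np.isnan(out[:, 7:]).all() and np.isfinite(out[:, :6]).all()


class TestTzone:
    def test_linear_interpolation_arithmetic(self):
        prof = VelocityProfile(
            distance=[0.0, 1.0, 2.0, 3.0],
            mean_velocity=[-100.0, -50.0, 10.0, 20.0],
            ci95=[0.0] * 4,
            n=[1] * 4,
        )
        assert find_tzone(prof) == pytest.approx(1.0 + 50.0 / 60.0)
        aligned = align_tzone(prof)
        np.testing.assert_allclose(
            aligned.distance, np.array([0, 1, 2, 3]) - 1.8333333, atol=1e-6
        )
        assert aligned.aligned

    def test_all_positive_profile_raises(self):
        prof = VelocityProfile([0.0, 1.0], [5.0, 6.0], [0.0, 0.0], [1, 1])
        with pytest.raises(AlignmentError):
            align_tzone(prof)

    def test_flag_mode_returns_unaligned(self):
        prof = VelocityProfile([0.0, 1.0], [5.0, 6.0], [0.0, 0.0], [1, 1])
        out = align_tzone(prof, on_missing="flag")
        assert not out.aligned
        np.testing.assert_allclose(out.distance, prof.distance)

    def test_bin_spacing_preserved(self):
        prof = VelocityProfile(
            [0.0, 0.5, 1.0, 1.5], [-10.0, -1.0, 2.0, 3.0], [0.0] * 4, [1] * 4
        )
        aligned = align_tzone(prof)
        np.testing.assert_allclose(np.diff(aligned.distance), np.diff(prof.distance))

    def test_noisy_crossing_disambiguated_by_smoothing(self):
        # a one-bin positive blip before the true transition must not win
        v = [-100.0, -80.0, 2.0, -60.0, -40.0, -5.0, 15.0, 25.0]
        prof = VelocityProfile(list(range(8)), v, [0.0] * 8, [1] * 8)
        z = find_tzone(prof)
        assert 5.0 < z < 6.0


class TestAverageAndRegression:
    @staticmethod
    def _flat(level, lo=-5.0, hi=5.0):
        d = np.arange(lo, hi + 1)
        return VelocityProfile(d, np.full(d.size, level), np.zeros(d.size), np.ones(d.size), aligned=True)

    def test_identical_profiles_average_to_themselves(self):
        avg = average_profiles([self._flat(10.0), self._flat(10.0)])
        np.testing.assert_allclose(avg.mean_velocity, 10.0)
        np.testing.assert_allclose(avg.ci95, 0.0)

    def test_mean_of_two_flat_profiles(self):
        avg = average_profiles([self._flat(10.0), self._flat(30.0)])
        np.testing.assert_allclose(avg.mean_velocity, 20.0)

    def test_disjoint_supports_rejected(self):
        with pytest.raises(ValueError):
            average_profiles([self._flat(1.0, -10, -6), self._flat(2.0, 6, 10)])

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            average_profiles([self._flat(1.0)])

    def test_perfect_line_regression(self):
        x = np.arange(10.0)
        res = linregress(x, x)
        assert res.slope == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_slope_two_with_vanishing_noise(self):
        rng = np.random.default_rng(0)
        x = np.arange(20.0)
        res = linregress(x, 2 * x + rng.normal(0, 1e-9, 20))
        assert res.slope == pytest.approx(2.0, abs=1e-6)

    def test_constant_response_gives_zero_slope(self):
        res = linregress(np.arange(10.0), np.full(10, 3.0))
        assert res.slope == 0.0
        assert res.r_squared == 0.0

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            linregress(np.full(5, 2.0), np.arange(5.0))


class TestEndpointVelocity:
    def test_worked_example(self):
        # 30 px over 180 frames at 0.1 μm/px, 10 s/frame = 3 μm / 1800 s
        trace = np.array([[0.0, 0.0], [180.0, 30.0]])
        assert endpoint_velocity(trace, 0.1, 10.0) == pytest.approx(6.0)

    def test_stationary_and_retracting(self):
        assert endpoint_velocity(np.array([[0.0, 5.0], [10.0, 5.0]]), 0.1, 5.0) == 0.0
        assert endpoint_velocity(np.array([[0.0, 10.0], [10.0, 4.0]]), 0.1, 5.0) < 0

    def test_zero_elapsed_time_rejected(self):
        with pytest.raises(ValueError):
            endpoint_velocity(np.array([[3.0, 0.0], [3.0, 5.0]]), 0.1, 5.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=12),
        st.lists(st.floats(0.5, 10), min_size=11, max_size=11),
    )
    def test_telescoping_identity(self, positions, gaps):
        # endpoint slope equals the time-weighted mean of segment slopes
        n = len(positions)
        frames = np.concatenate([[0.0], np.cumsum(gaps[: n - 1])])
        trace = np.column_stack([frames, positions])
        v = endpoint_velocity(trace, 0.1, 5.0)
        seg_slopes = np.diff(trace[:, 1]) / np.diff(trace[:, 0])
        weights = np.diff(trace[:, 0])
        expected = np.sum(seg_slopes * weights) / weights.sum() * 0.1 / 5.0 * 3600
        assert v == pytest.approx(expected, rel=1e-9, abs=1e-9)


class TestPipelineRecovery:
    def test_recovery_robust_to_fast_transport_events(self):
        # with fast events superimposed at the default rates, the growth
        # cone, T-zone and axonal bulk flow still recover; the P-domain
        # mean absorbs some contamination from retrograde event streaks
        spec = NeuriteSimSpec(seed=3)
        kymo, truth = simulate_neurite_kymograph(spec)
        track = estimate_gc_track(kymo)
        assert track.velocity == pytest.approx(spec.gc_velocity, abs=2.0)
        sheared = mask_beyond_edge(shear_align(calibrate_flow(kymoflow(kymo), kymo), track), track)
        prof = align_tzone(profile_from_flow(sheared, kymo))
        ax = (prof.distance >= 2) & (prof.distance <= 8)
        expected = spec.bulk_velocity(prof.distance[ax]).mean()
        assert prof.mean_velocity[ax].mean() == pytest.approx(expected, rel=0.15)
        pd_sel = (prof.distance <= -1.5) & (prof.distance >= -4)
        assert prof.mean_velocity[pd_sel].mean() == pytest.approx(spec.retro_velocity, rel=0.30)

    def test_bulk_profile_and_tzone_recovered(self, sim_cell):
        spec, kymo, truth = sim_cell
        track = estimate_gc_track(kymo)
        flow_umh = calibrate_flow(kymoflow(kymo), kymo)
        sheared = mask_beyond_edge(shear_align(flow_umh, track), track)
        prof = profile_from_flow(sheared, kymo)
        tz = find_tzone(prof)
        true_tz = (kymo.shape[1] - 1 - (truth.gc_track[0] - spec.p_domain_width / spec.pixel_size)) * spec.pixel_size
        assert tz == pytest.approx(true_tz, abs=0.5)
        aligned = align_tzone(prof)
        ax = (aligned.distance >= 2) & (aligned.distance <= 8)
        d_ax = aligned.distance[ax]
        expected = spec.bulk_velocity(d_ax)
        resid = aligned.mean_velocity[ax] - expected
        tol = np.maximum(aligned.ci95[ax], 0.1 * np.abs(expected))
        assert np.mean(np.abs(resid) <= tol) >= 0.9
        pd_sel = (aligned.distance <= -1.5) & (aligned.distance >= -4)
        assert aligned.mean_velocity[pd_sel].mean() == pytest.approx(
            spec.retro_velocity, rel=0.10
        )
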