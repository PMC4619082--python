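"""Measurement suite: geometry from moments, speeds and angles, the
persistent-random-walk fit, chemotaxis indices, order index, scanning."""

import numpy as np
import pytest

from actcpm.lattice import LatticeState
from actcpm.track_metrics import (ScanTracker, Track, centroid_and_axes,
                                  chemo_stats, fit_furth,
                                  instantaneous_speed,
                                  mean_squared_displacement, order_index,
                                  orientation_direction_angle, scan_stats,
                                  speeds, stop_durations, turning_angle,
                                  turning_angles)

from conftest import make_track, synthetic_ou_track


def state_with_sites(sites, width=20, height=20, cell_id=1):
    spin = np.zeros((height, width), dtype=np.int32)
    for (x, y) in sites:
        spin[y, x] = cell_id
    return LatticeState(spin=spin, activity=np.zeros_like(spin))


class TestCentroidAndAxes:
    def test_row_of_sites(self):
        g = centroid_and_axes(state_with_sites([(i, 5) for i in range(3, 13)]),
                              1)
        assert g.centroid == pytest.approx((7.5, 5.0))
        assert abs(g.axis[0]) == pytest.approx(1.0)
        assert g.length == pytest.approx(10.0)
        assert not g.degenerate

    def test_square_is_degenerate(self):
        sites = [(x, y) for x in range(4, 8) for y in range(4, 8)]
        g = centroid_and_axes(state_with_sites(sites), 1)
        assert g.degenerate

    def test_single_site(self):
        g = centroid_and_axes(state_with_sites([(3, 4)]), 1)
        assert g.centroid == pytest.approx((3.0, 4.0))
        assert g.length == 1.0 and g.degenerate

    def test_wrapped_cell_matches_translated_copy(self):
        # a row straddling the x boundary vs the same row shifted inland
        wrapped = [(18, 5), (19, 5), (0, 5), (1, 5), (2, 5)]
        inland = [(8, 5), (9, 5), (10, 5), (11, 5), (12, 5)]
        gw = centroid_and_axes(state_with_sites(wrapped), 1)
        gi = centroid_and_axes(state_with_sites(inland), 1)
        assert gw.length == pytest.approx(gi.length)
        assert gw.centroid[0] == pytest.approx((gi.centroid[0] - 10) % 20)
        assert gw.centroid[1] == pytest.approx(gi.centroid[1])


class TestSpeedAndAngles:
    def test_speed_from_pythagorean_step(self):
        tr = make_track([0, 3], [0, 4], dt=20)
        assert instantaneous_speed(tr, 1) == pytest.approx(0.25)

    def test_speed_translation_invariance(self):
        rng = np.random.default_rng(0)
        xy = rng.normal(size=(10, 2)).cumsum(axis=0)
        a = make_track(xy[:, 0], xy[:, 1])
        b = make_track(xy[:, 0] + 100, xy[:, 1] - 40)
        assert speeds(a) == pytest.approx(speeds(b))

    def test_turning_straight_and_reversal(self):
        straight = make_track([0, 1, 2], [0, 0, 0])
        assert turning_angle(straight, 2) == pytest.approx(0.0)
        reverse = make_track([0, 1, 0], [0, 0, 0])
        assert turning_angle(reverse, 2) == pytest.approx(180.0)

    def test_isotropic_steps_average_ninety_degrees(self):
        rng = np.random.default_rng(4)
        steps = rng.normal(size=(4000, 2))
        xy = np.vstack([[0, 0], steps.cumsum(axis=0)])
        tr = make_track(xy[:, 0], xy[:, 1])
        assert np.nanmean(turning_angles(tr)) == pytest.approx(90.0, abs=2.0)

    def test_zero_step_turning_is_nan(self):
        tr = make_track([0, 0, 1], [0, 0, 0])
        assert np.isnan(turning_angle(tr, 2))

    def test_orientation_angle_axis_aligned_and_perpendicular(self):
        tr = make_track([0, 5], [0, 0])  # axis fixed at (1, 0)
        assert orientation_direction_angle(tr, 1) == pytest.approx(0.0)
        tr2 = make_track([0, 0], [0, 5])
        assert orientation_direction_angle(tr2, 1) == pytest.approx(90.0)

    def test_orientation_angle_axial_fold(self):
        tr = make_track([0, 3], [0, 4])
        a1 = orientation_direction_angle(tr, 1)
        tr.axis[:] = -tr.axis  # flipping the axis by 180 deg changes nothing
        a2 = orientation_direction_angle(tr, 1)
        assert a1 == pytest.approx(a2)
        assert 0.0 <= a1 <= 90.0


class TestFurthFit:
    def test_brownian_track_recovers_diffusion(self):
        # pure Brownian motion: msd = 4 D t, so M -> D and P -> 0
        rng = np.random.default_rng(8)
        dt, d_true = 20.0, 0.5
        steps = rng.normal(0, np.sqrt(2 * d_true * dt), size=(3000, 2))
        xy = np.vstack([[0, 0], steps.cumsum(axis=0)])
        fit = fit_furth(make_track(xy[:, 0], xy[:, 1], dt=dt))
        assert fit.converged
        assert fit.motility == pytest.approx(d_true, rel=0.15)
        assert fit.persistence < dt

    def test_ballistic_track_has_long_persistence(self):
        t = np.arange(200) * 20.0
        fit = fit_furth(make_track(0.1 * t, 0.05 * t, dt=20.0))
        assert fit.persistence > 400.0  # far beyond the sampled window

    def test_coordinate_doubling_quadruples_motility(self):
        rng = np.random.default_rng(9)
        _, x, y = synthetic_ou_track(1500, 20.0, 200.0, 0.01, rng)
        f1 = fit_furth(make_track(x, y))
        f2 = fit_furth(make_track(2 * x, 2 * y))
        assert f2.motility == pytest.approx(4 * f1.motility, rel=1e-3)
        assert f2.persistence == pytest.approx(f1.persistence, rel=1e-3)

    def test_recovers_known_persistent_random_walk(self):
        # Ornstein-Uhlenbeck velocity with persistence P and per-axis
        # variance s2 has Fuerth MSD with M = s2 * P
        rng = np.random.default_rng(10)
        p_true, s2 = 200.0, 0.01
        fits_m, fits_p = [], []
        for _ in range(4):
            _, x, y = synthetic_ou_track(3000, 20.0, p_true, s2, rng)
            fit = fit_furth(make_track(x, y))
            fits_m.append(fit.motility)
            fits_p.append(fit.persistence)
        assert np.mean(fits_m) == pytest.approx(s2 * p_true, rel=0.15)
        assert np.mean(fits_p) == pytest.approx(p_true, rel=0.15)

    def test_msd_uses_all_overlapping_windows(self):
        tr = make_track([0, 1, 3, 6], [0, 0, 0, 0], dt=1.0)
        t, msd = mean_squared_displacement(tr)
        assert msd[0] == pytest.approx(np.mean([1.0, 4.0, 9.0]))
        assert msd[1] == pytest.approx(np.mean([9.0, 25.0]))


class TestChemoStats:
    def test_straight_up_gradient(self):
        tr = make_track([0, 0, 0], [0, 2, 4])
        cs = chemo_stats(tr, "y")
        assert cs.chemotactic_index == pytest.approx(1.0)
        assert cs.directed_speed == pytest.approx(2.0 / tr.dt)

    def test_perpendicular_motion(self):
        tr = make_track([0, 2, 4], [0, 0, 0])
        cs = chemo_stats(tr, "y")
        assert cs.directed_speed == 0.0
        assert cs.chemotactic_index == 0.0

    def test_up_then_down(self):
        tr = make_track([0, 0, 0], [0, 30, 20])
        cs = chemo_stats(tr, "y")
        assert cs.chemotactic_index == pytest.approx(20.0 / 40.0)


class TestOrderIndex:
    def test_aligned_cells_give_one(self):
        assert order_index(np.tile([0.0, 2.5], (6, 1))) == pytest.approx(1.0)

    def test_opposite_pair_cancels(self):
        assert order_index(np.array([[1.0, 0.0], [-3.0, 0.0]])) \
            == pytest.approx(0.0)

    def test_null_scaling_with_cell_number(self):
        # independent directions: E|mean unit vector| = sqrt(pi) / (2 sqrt n)
        rng = np.random.default_rng(12)
        for n in (25, 100):
            vals = []
            for _ in range(300):
                theta = rng.uniform(0, 2 * np.pi, n)
                vals.append(order_index(np.column_stack(
                    [np.cos(theta), np.sin(theta)])))
            expected = np.sqrt(np.pi) / (2 * np.sqrt(n))
            assert np.mean(vals) == pytest.approx(expected, rel=0.1)


class TestScanning:
    def test_corridor_toy_run(self):
        # an active cell walks past 2 of 3 tissue cells
        def frame(act_x):
            spin = np.zeros((5, 12), dtype=np.int32)
            spin[2, act_x] = 1          # act cell
            spin[1, 2] = 2              # tissue cells along the corridor
            spin[1, 6] = 3
            spin[4, 10] = 4             # out of reach
            return spin

        history = [frame(x) for x in range(1, 8)]
        assert scan_stats(history, 1, [2, 3, 4]) == pytest.approx(2 / 3)

    def test_monotone_nondecreasing(self):
        rng = np.random.default_rng(3)
        tracker = ScanTracker(1, [2, 3, 4, 5])
        prev = 0.0
        for _ in range(20):
            spin = rng.integers(0, 6, size=(8, 8)).astype(np.int32)
            tracker.update(spin)
            assert tracker.scanned_fraction >= prev
            prev = tracker.scanned_fraction

    def test_never_adjacent_scans_nothing(self):
        spin = np.zeros((9, 9), dtype=np.int32)
        spin[0, 0] = 1
        spin[5, 5] = 2
        assert scan_stats([spin], 1, [2]) == 0.0


class TestStops:
    def test_no_stops_above_threshold(self):
        assert stop_durations([1.0, 2.0, 3.0], 0.5, 20.0) == []

    def test_three_slow_samples_make_one_stop(self):
        trace = [1.0, 0.1, 0.1, 0.1, 1.0]
        assert stop_durations(trace, 0.5, 20.0) == [60.0]

    def test_split_and_merge_invariance(self):
        trace = [1.0, 0.1, 0.1, 1.0, 0.2, 1.0, 0.3, 0.3]
        whole = stop_durations(trace, 0.5, 20.0)
        # splitting at a fast sample (index 3) and concatenating results
        left = stop_durations(trace[:4], 0.5, 20.0)
        right = stop_durations(trace[4:], 0.5, 20.0)
        assert whole == left + right
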