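"""State calls, occupancy, dwell times, cumulative occupancy curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capswitch.engine import to_grid
from capswitch.phenotype import (CAP_HIGH, CAP_LOW, FALLBACK_THRESHOLD,
                                 PhenotypeSegments, choose_threshold,
                                 classify_states, cumulative_occupancy_curve,
                                 heritability_proxy, occupancy_summary)

from conftest import make_ca_trajectory


def square_wave(period=1000.0, high_frac=0.3, n=10, high=200, t0=0.0):
    times, ca = [], []
    for k in range(n):
        times += [t0 + period * k, t0 + period * k + high_frac * period]
        ca += [high, 0]
    return make_ca_trajectory(times, ca, t_end=t0 + period * n)


class TestClassify:
    def test_all_low_trajectory_is_one_segment(self):
        traj = make_ca_trajectory([0.0, 500.0], [0, 0], t_end=1_000.0)
        segs = classify_states(traj, threshold=20)
        assert segs.segments == [(0.0, 1_000.0, CAP_LOW)]
        assert occupancy_summary(segs, traj).fraction_cap_low == 1.0

    def test_square_wave_occupancy_is_exact(self):
        traj = square_wave(high_frac=0.3)
        summ = occupancy_summary(classify_states(traj, 20), traj)
        assert summ.fraction_cap_low == pytest.approx(0.7, abs=1e-12)
        assert summ.fraction_cap_high == pytest.approx(0.3, abs=1e-12)
        assert summ.mean_cap_high == pytest.approx(200.0)
        assert summ.mean_cap_low == pytest.approx(0.0)

    def test_negative_threshold_rejected(self):
        traj = square_wave()
        with pytest.raises(ValueError):
            classify_states(traj, threshold=-1)

    def test_segments_tile_window_and_alternate(self):
        traj = square_wave(n=7)
        segs = classify_states(traj, 20)
        starts = [s[0] for s in segs.segments]
        ends = [s[1] for s in segs.segments]
        assert starts[0] == traj.window[0]
        assert ends[-1] == traj.window[1]
        assert all(a == b for a, b in zip(ends[:-1], starts[1:]))
        states = [s[2] for s in segs.segments]
        assert all(x != y for x, y in zip(states[:-1], states[1:]))

    @settings(max_examples=30, derandomize=True)
    @given(th=st.lists(st.integers(min_value=0, max_value=250),
                       min_size=2, max_size=6))
    def test_low_fraction_monotone_in_threshold(self, th):
        traj = square_wave()
        fracs = [occupancy_summary(classify_states(traj, t), traj).fraction_cap_low
                 for t in sorted(th)]
        assert all(a <= b + 1e-12 for a, b in zip(fracs[:-1], fracs[1:]))


class TestOccupancySummary:
    def test_three_segment_hand_oracle(self):
        # low 10 s, high 20 s, low 10 s
        traj = make_ca_trajectory([0.0, 10.0, 30.0], [0, 100, 0], t_end=40.0)
        summ = occupancy_summary(classify_states(traj, 20), traj)
        assert summ.fraction_cap_low == pytest.approx(0.5)
        assert summ.mean_dwell_low_s == pytest.approx(10.0)
        assert summ.mean_dwell_high_s == pytest.approx(20.0)
        assert summ.n_switches == 2

    def test_single_segment_has_no_switches(self):
        traj = make_ca_trajectory([0.0, 500.0], [50, 60], t_end=1_000.0)
        summ = occupancy_summary(classify_states(traj, 20), traj)
        assert summ.n_switches == 0
        assert summ.mean_dwell_high_s == pytest.approx(1_000.0)
        assert np.isnan(summ.mean_dwell_low_s)

    def test_gridded_trajectory_agrees_within_one_step(self):
        traj = square_wave(period=1000.0, high_frac=0.3, n=8)
        step = 9.0
        g = to_grid(traj, step)
        s_event = occupancy_summary(classify_states(traj, 20), traj)
        s_grid = occupancy_summary(classify_states(g, 20), g)
        window = traj.window[1] - traj.window[0]
        assert abs(s_event.fraction_cap_low - s_grid.fraction_cap_low) \
            <= (s_event.n_switches + 1) * step / window

    def test_mismatched_trajectory_rejected(self):
        t1 = square_wave()
        t2 = make_ca_trajectory([0.0, 10.0], [0, 100], t_end=40.0)
        segs = classify_states(t1, 20)
        with pytest.raises(ValueError, match="derive"):
            occupancy_summary(segs, t2)

    def test_fractions_invariant_to_time_translation(self):
        a = square_wave(t0=0.0)
        b = square_wave(t0=5_000.0)
        sa = occupancy_summary(classify_states(a, 20), a)
        sb = occupancy_summary(classify_states(b, 20), b)
        assert sa.fraction_cap_low == pytest.approx(sb.fraction_cap_low)
        assert sa.fraction_cap_low + sa.fraction_cap_high == pytest.approx(1.0)


class TestCumulativeOccupancy:
    def test_constant_level_curve(self):
        traj = make_ca_trajectory([0.0, 500.0], [5, 5], t_end=1_000.0)
        curve = cumulative_occupancy_curve(traj, [0, 5, 10])
        assert curve[:, 1].tolist() == [0.0, 1_000.0, 1_000.0]

    def test_square_wave_curve_has_two_jumps(self):
        traj = square_wave(high_frac=0.3, high=200)
        levels = np.arange(0, 251)
        curve = cumulative_occupancy_curve(traj, levels)[:, 1]
        window = traj.window[1] - traj.window[0]
        assert curve[0] == pytest.approx(0.7 * window)   # jump at level 0
        assert curve[199] == pytest.approx(0.7 * window)  # flat in between
        assert curve[200] == pytest.approx(window)        # jump at the high mode
        assert np.all(np.diff(curve) >= 0)

    def test_curve_at_max_level_equals_window(self):
        traj = square_wave()
        m = int(traj.series("CA").max())
        curve = cumulative_occupancy_curve(traj, [m])
        assert curve[0, 1] == pytest.approx(traj.window[1] - traj.window[0])

    def test_unsorted_levels_rejected(self):
        traj = square_wave()
        with pytest.raises(ValueError):
            cumulative_occupancy_curve(traj, [10, 5])


class TestHeritabilityProxy:
    def test_dwell_in_division_units(self):
        traj = make_ca_trajectory([0.0, 7_200.0], [0, 100], t_end=14_400.0)
        segs = classify_states(traj, 20)
        out = heritability_proxy(segs, division_time=3_600.0)
        assert out[CAP_LOW] == pytest.approx(2.0)
        assert out[CAP_HIGH] == pytest.approx(2.0)

    def test_nonpositive_division_time_rejected(self):
        traj = square_wave()
        segs = classify_states(traj, 20)
        with pytest.raises(ValueError):
            heritability_proxy(segs, division_time=0.0)


class TestChooseThreshold:
    def test_bimodal_histogram_splits_the_modes(self):
        # 60% at CA=4, 40% at CA=120 -> midpoint threshold near 62
        traj = square_wave(high_frac=0.4, high=120)
        traj.counts[:, traj.species_index("CA")] = np.where(
            traj.series("CA") > 0, 120, 4)
        th = choose_threshold(traj)
        assert 40 <= th <= 90

    def test_unimodal_histogram_falls_back(self):
        traj = make_ca_trajectory([0.0, 500.0], [3, 4], t_end=1_000.0)
        assert choose_threshold(traj) == FALLBACK_THRESHOLD

    def test_threshold_recorded_in_segments(self):
        traj = square_wave()
        segs = classify_states(traj)
        assert segs.threshold == choose_threshold(traj)
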