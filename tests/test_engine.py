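"""Gillespie engine: waiting times, channel choice, exactness, recording."""

import math

import numpy as np
import pytest
from scipy import stats

from capswitch.engine import (Absorbed, SimConfig, SimulationError,
                              draw_next_event, read_trajectory, simulate,
                              to_grid, write_trajectory)
from capswitch.network import (ConfigurationError, RATE_NAMES, RateSet,
                               SpeciesState, build_growth_capsulation_network)

from conftest import birth_death_rates, make_ca_trajectory


def bd_network(a, b):
    return build_growth_capsulation_network(birth_death_rates(a, b))


class TestDrawNextEvent:
    def test_zero_propensity_reports_absorption(self):
        net = bd_network(0.0, 0.1)
        state = SpeciesState.from_dict({"UXP": 0})
        out = draw_next_event(state, net, np.random.default_rng(0))
        assert isinstance(out, Absorbed)
        assert out.waiting_time == math.inf

    def test_waiting_time_is_exponential_with_total_propensity(self):
        # single channel X -> 0 at rate c with X = n: mean wait 1/(c*n)
        c, n, draws = 0.1, 40, 100_000
        net = bd_network(0.0, c)
        state = SpeciesState.from_dict({"UXP": n})
        rng = np.random.default_rng(11)
        waits = np.array([draw_next_event(state, net, rng)[0]
                          for _ in range(draws)])
        expected = 1.0 / (c * n)
        se = expected / math.sqrt(draws)  # exponential sd equals its mean
        assert abs(waits.mean() - expected) < 3 * se

    def test_equal_propensities_split_evenly(self):
        # production at a and drain at b*X chosen so both channels match
        net = bd_network(2.0, 0.1)
        state = SpeciesState.from_dict({"UXP": 20})  # drain = 0.1*20 = 2.0
        rng = np.random.default_rng(12)
        draws = 100_000
        picks = np.array([draw_next_event(state, net, rng)[1]
                          for _ in range(draws)])
        freq = (picks == 0).mean()
        se = 0.5 / math.sqrt(draws)
        assert abs(freq - 0.5) < 3 * se


class TestSimulate:
    def test_birth_death_matches_poisson_stationary_moments(self):
        a, b = 5.0, 0.1  # stationary Poisson(50)
        net = bd_network(a, b)
        init = SpeciesState.from_dict({"UXP": 50})
        traj = simulate(net, init, SimConfig(t_end=60_000, burn_in=2_000, seed=3))
        dur = np.diff(np.append(traj.times, traj.config.t_end))
        x = traj.series("UXP")
        w = dur / dur.sum()
        mean = float((x * w).sum())
        var = float((((x - mean) ** 2) * w).sum())
        # effective sample size ~ window / relaxation time (1/b)
        n_eff = (60_000 - 2_000) * b
        se_mean = math.sqrt(50 / n_eff)
        assert abs(mean - 50.0) < 3 * se_mean
        assert abs(var - 50.0) / 50.0 < 0.15

    def test_stationary_distribution_passes_chi_squared_in_most_seeds(self):
        # widely spaced samples vs Poisson(50); alpha=0.01, >=18/20 seeds
        a, b = 5.0, 0.1
        net = bd_network(a, b)
        init = SpeciesState.from_dict({"UXP": 50})
        edges = [0, 41, 45, 48, 51, 54, 58, 1000]
        pmf = stats.poisson(50)
        probs = np.array([pmf.cdf(edges[i + 1] - 1) - pmf.cdf(edges[i] - 1)
                          for i in range(len(edges) - 1)])
        passed = 0
        for seed in range(20):
            traj = simulate(net, init,
                            SimConfig(t_end=8_200, burn_in=200, seed=seed))
            samples = np.array([traj.state_at(t)[0]
                                for t in np.arange(240, 8_200, 40.0)])
            obs = np.array([((samples >= edges[i]) & (samples < edges[i + 1])).sum()
                            for i in range(len(edges) - 1)])
            chi2 = ((obs - len(samples) * probs) ** 2 /
                    (len(samples) * probs)).sum()
            p = stats.chi2(df=len(obs) - 1).sf(chi2)
            passed += p > 0.01
        assert passed >= 18

    def test_same_seed_gives_bit_identical_trajectories(self, network, init_cfg):
        from capswitch.network import initialize_state
        init = initialize_state(init_cfg, 5)
        cfg = SimConfig(t_end=20_000, burn_in=1_000, seed=9)
        t1 = simulate(network, init, cfg)
        t2 = simulate(network, init, cfg)
        assert np.array_equal(t1.times, t2.times)
        assert np.array_equal(t1.counts, t2.counts)

    def test_degenerate_window_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(t_end=1_000, burn_in=1_000)

    def test_reported_path_starts_at_burn_in_and_increases(self):
        net = bd_network(5.0, 0.1)
        init = SpeciesState.from_dict({"UXP": 0})
        traj = simulate(net, init, SimConfig(t_end=5_000, burn_in=500, seed=1))
        assert traj.times[0] == 500.0
        assert traj.times[-1] <= 5_000.0
        assert np.all(np.diff(traj.times) > 0)
        assert np.all(traj.counts >= 0)

    def test_event_cap_raises_with_partial_trajectory(self):
        net = bd_network(50.0, 1.0)
        init = SpeciesState.from_dict({"UXP": 0})
        with pytest.raises(SimulationError) as err:
            simulate(net, init, SimConfig(t_end=10_000, burn_in=100, seed=0,
                                          max_events=500))
        assert err.value.trajectory is not None

    def test_absorbing_state_holds_to_horizon(self):
        net = bd_network(0.0, 0.5)  # pure death: absorbs at 0
        init = SpeciesState.from_dict({"UXP": 5})
        traj = simulate(net, init, SimConfig(t_end=10_000, burn_in=100, seed=2))
        assert traj.absorbed
        assert traj.series("UXP")[-1] == 0

    def test_event_count_scales_linearly_with_rate(self):
        # catalytic channel mRNAca -> mRNAca + CA with the source clamped:
        # doubling the constant doubles expected firings per unit time
        zeros = {n: 0.0 for n in RATE_NAMES}
        counts = {}
        for k in (0.05, 0.10):
            rs = RateSet.from_dict({**zeros, "k_tl_ca": k})
            net = build_growth_capsulation_network(rs)
            init = SpeciesState.from_dict({"mRNAca": 4})
            traj = simulate(net, init,
                            SimConfig(t_end=50_000, burn_in=0, seed=21))
            counts[k] = traj.n_events
        expected = 0.05 * 4 * 50_000
        assert counts[0.05] == pytest.approx(expected, rel=0.05)
        assert counts[0.10] / counts[0.05] == pytest.approx(2.0, rel=0.05)


class TestGridAndIO:
    def test_constant_trajectory_grids_to_constant(self):
        traj = make_ca_trajectory([0.0, 100.0], [7, 7], t_end=200.0)
        g = to_grid(traj, 10.0)
        assert np.all(g.series("CA") == 7)

    def test_square_wave_occupancy_within_one_grid_step(self):
        # 300 s high, 700 s low, repeated: exact high fraction 0.3
        times, ca = [], []
        for k in range(5):
            times += [1000.0 * k, 1000.0 * k + 300.0]
            ca += [200, 0]
        traj = make_ca_trajectory(times, ca, t_end=5_000.0)
        g = to_grid(traj, 7.0)
        dur = np.diff(np.append(g.times, 5_000.0))
        frac_high = dur[g.series("CA") > 20].sum() / dur.sum()
        assert abs(frac_high - 0.3) <= 7.0 * 5 / 5_000.0 + 1e-12

    def test_step_equal_to_window_keeps_burn_in_state(self):
        traj = make_ca_trajectory([0.0, 40.0], [3, 9], t_end=100.0)
        g = to_grid(traj, 100.0)
        assert len(g.times) == 1
        assert g.series("CA")[0] == 3

    def test_overlong_step_rejected(self):
        traj = make_ca_trajectory([0.0, 40.0], [3, 9], t_end=100.0)
        with pytest.raises(ConfigurationError):
            to_grid(traj, 101.0)

    def test_trajectory_round_trip(self, tmp_path, network, init_cfg):
        from capswitch.network import initialize_state
        init = initialize_state(init_cfg, 3)
        traj = simulate(network, init,
                        SimConfig(t_end=3_000, burn_in=300, seed=4))
        write_trajectory(traj, tmp_path / "traj")
        back = read_trajectory(tmp_path / "traj")
        assert np.array_equal(back.times, traj.times)
        assert np.array_equal(back.counts, traj.counts)
        assert back.rates == traj.rates
        assert back.config == traj.config
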