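"""Growth-rate estimation, capsulation cost, threshold model comparison,
assay statistics and the two-sample testing policy."""

import math

import numpy as np
import pytest

from capswitch.colony_stats import (GrowthFit, capsulation_cost,
                                    estimate_growth_rate, fit_threshold_models,
                                    proportion_capsulated, two_sample_compare)
from capswitch.microcolony import (CAP_LOW, AssayCounts, Cell, LineageTree,
                                   MicrocolonyParams, first_switch_size,
                                   generate_assay, generate_microcolonies,
                                   generate_microcolony)


def synchronous_tree(period=60.0, generations=6):
    """Deterministic tree: every cell divides exactly every *period* minutes."""
    cells = [Cell(0, -1, 0.0, period, [(CAP_LOW, 0.0)])]
    frontier = [0]
    for g in range(1, generations + 1):
        t_birth = g * period
        t_div = (g + 1) * period if g < generations else None
        new = []
        for pid in frontier:
            for _ in range(2):
                cid = len(cells)
                cells.append(Cell(cid, pid, t_birth, t_div, [(CAP_LOW, t_birth)]))
                new.append(cid)
        frontier = new
    params = MicrocolonyParams(per_cell_switch_rate=0.0,
                               total_time=(generations + 1) * period)
    return LineageTree(cells=cells, params=params, seed=-1, threshold=1e9,
                       switch_events=[], end_time=params.total_time)


class TestGrowthRate:
    def test_synchronous_doubling_gives_ln2_over_period(self):
        tree = synchronous_tree(period=60.0, generations=6)
        fit = estimate_growth_rate(tree, CAP_LOW)
        assert fit.rate == pytest.approx(math.log(2) / 60.0, abs=1e-6)
        assert fit.doubling_time_min == pytest.approx(60.0, abs=1e-3)

    def test_generator_trees_recover_default_rate(self):
        ests = []
        for seed in range(20):
            p = MicrocolonyParams(per_cell_switch_rate=0.0, total_time=700.0)
            ests.append(estimate_growth_rate(
                generate_microcolony(p, 100 + seed), CAP_LOW).rate)
        ests = np.array(ests)
        se = ests.std(ddof=1) / math.sqrt(len(ests))
        assert abs(ests.mean() - 0.0116) < 3 * se

    def test_undivided_tree_rejected(self):
        cells = [Cell(0, -1, 0.0, None, [(CAP_LOW, 0.0)])]
        params = MicrocolonyParams(total_time=100.0)
        tree = LineageTree(cells, params, -1, 1e9, [], 100.0)
        with pytest.raises(ValueError):
            estimate_growth_rate(tree, CAP_LOW)


class TestCapsulationCost:
    def test_printed_rates_give_about_three_percent(self):
        low = GrowthFit(0.0116, 6.10e-5, 17, "CAP_LOW")
        high = GrowthFit(0.0113, 2.5e-4, 39, "CAP_HIGH")
        cost = capsulation_cost(low, high)
        assert cost.percent == pytest.approx(100 * (1 - 0.0113 / 0.0116))
        assert round(cost.percent) == 3

    @pytest.mark.parametrize("rh,expected", [(0.01, 0.0), (0.005, 50.0)])
    def test_degenerate_ratios(self, rh, expected):
        low = GrowthFit(0.01, 0.0, 5, "CAP_LOW")
        high = GrowthFit(rh, 0.0, 5, "CAP_HIGH")
        assert capsulation_cost(low, high).percent == pytest.approx(expected)

    def test_doubling_times_match_printed_division_times(self):
        # ln(2)/rate reproduces the ~61.3 and ~59.8 min division times
        assert round(math.log(2) / 0.0113, 1) == 61.3
        assert round(math.log(2) / 0.0116, 1) == 59.8

    def test_nonpositive_reference_rate_rejected(self):
        with pytest.raises(ValueError):
            capsulation_cost(GrowthFit(0.0, 0.0, 5, "CAP_LOW"),
                             GrowthFit(0.01, 0.0, 5, "CAP_HIGH"))


class TestThresholdModels:
    def test_gaussian_generator_prefers_gaussian_and_recovers_mean(self):
        trees = generate_microcolonies(
            MicrocolonyParams(stop_after_first_switch=True), 58, 7)
        sizes = [s for s in map(first_switch_size, trees) if s is not None]
        g, m, preferred = fit_threshold_models(sizes)
        assert preferred == "gaussian"
        assert abs(g.params[0] - 1870.0) < 3 * 660.0 / math.sqrt(len(sizes))

    def test_model_selection_consistency(self):
        # generating mechanism recovered in >= 90% of 50 batches at n=58
        rng = np.random.default_rng(2024)
        hits_mem = sum(
            fit_threshold_models(rng.geometric(1 / 1870.0, 58))[2] == "memoryless"
            for _ in range(50))
        hits_gau = sum(
            fit_threshold_models(np.clip(rng.normal(1870, 660, 58), 1, None))[2]
            == "gaussian" for _ in range(50))
        assert hits_mem >= 45
        assert hits_gau >= 45

    def test_censoring_enters_both_likelihoods(self):
        rng = np.random.default_rng(8)
        sizes = np.clip(rng.normal(1870, 660, 40), 1, None)
        g0, m0, _ = fit_threshold_models(sizes)
        g1, m1, _ = fit_threshold_models(sizes, censored=[3000.0] * 10)
        assert g1.n_censored == 10 and m1.n_censored == 10
        assert g1.loglik < g0.loglik  # censoring terms cost likelihood
        assert m1.params[0] < m0.params[0]

    def test_aic_definition(self):
        rng = np.random.default_rng(9)
        g, m, _ = fit_threshold_models(rng.normal(1870, 660, 30))
        assert g.aic == pytest.approx(2 * 2 - 2 * g.loglik)
        assert m.aic == pytest.approx(2 * 1 - 2 * m.loglik)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            fit_threshold_models([1500.0, 1500.0])
        with pytest.raises(ValueError):
            fit_threshold_models([], censored=[100.0] * 10)


class TestProportions:
    def test_constant_replicates(self):
        assay = AssayCounts(np.array([42] * 5), 500, 0.084, 0)
        mean, se = proportion_capsulated(assay)
        assert mean == pytest.approx(0.084)
        assert se == 0.0

    def test_zero_replicates_give_zero(self):
        assay = AssayCounts(np.array([0, 0, 0]), 500, 0.0, 0)
        assert proportion_capsulated(assay) == (0.0, 0.0)

    def test_ancestor_proportion_grand_mean(self):
        # 300 assays at the ancestral proportion 0.0016
        p = 0.0016
        means = [generate_assay(p, 500, 5, s).proportions.mean()
                 for s in range(300)]
        se = math.sqrt(p * (1 - p) / (500 * 5 * 300))
        assert abs(np.mean(means) - p) < 3 * se


class TestTwoSamplePolicy:
    def test_identical_constant_samples_take_rank_branch_with_p_one(self):
        res = two_sample_compare([1.0] * 5, [1.0] * 5)
        assert res.test == "wilcoxon"
        assert res.pvalue == pytest.approx(1.0)

    def test_identical_normalish_samples_give_zero_t(self):
        x = [0.1, 0.12, 0.09, 0.11, 0.105]
        res = two_sample_compare(x, x)
        assert res.test in ("t", "welch")
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_separated_gaussians_take_parametric_branch(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.08, 0.004, 5)
        y = rng.normal(0.0016, 0.0004, 5)
        res = two_sample_compare(x, y)
        assert res.test in ("t", "welch")
        assert res.pvalue < 0.001

    def test_skewed_tied_samples_take_rank_branch(self):
        x = [0.0, 0.0, 0.0, 0.0, 5.0, 40.0, 200.0, 0.0]
        y = [0.0, 0.0, 1.0, 0.0, 0.0, 90.0, 0.0, 0.0]
        res = two_sample_compare(x, y)
        assert res.test == "wilcoxon"

    def test_undersized_samples_rejected(self):
        with pytest.raises(ValueError):
            two_sample_compare([1.0, 2.0], [1.0, 2.0, 3.0])
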