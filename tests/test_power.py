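"""Power machinery: random splits, split selection and refinement, the
Monte-Carlo power estimator, and the power grid contracts."""

import numpy as np
import pytest

from mdsc import (
    ConfigurationError,
    TestSpec,
    analytic_t_power,
    estimate_power,
    exhaustive_splits,
    power_table,
    random_splits,
    select_split_for_difference,
    smallest_n_for_power,
)
from mdsc.power import refine_split_to_difference
from tests.conftest import make_toy_cohort


class TestRandomSplits:
    def test_study_size_halves_leave_one_out(self, default_cohort):
        pair = next(random_splits(default_cohort, 1, seed=0))
        assert len(pair.group_a_ids) == len(pair.group_b_ids) == 790
        assert not set(pair.group_a_ids) & set(pair.group_b_ids)
        assert pair.achieved_d >= 0

    def test_deterministic_given_seed(self):
        pop = np.arange(8, dtype=float)
        a = [(p.group_a_ids, p.group_b_ids) for p in random_splits(pop, 3, seed=4)]
        b = [(p.group_a_ids, p.group_b_ids) for p in random_splits(pop, 3, seed=4)]
        assert a == b

    def test_membership_symmetry(self):
        # constant scores so the higher-mean orientation never relabels
        # the halves; each patient must land in group A half the time
        pop = np.full(100, 50.0)
        counts = np.zeros(100)
        k = 2000
        for pair in random_splits(pop, k, seed=1):
            counts[list(pair.group_a_ids)] += 1
        assert np.all(np.abs(counts / k - 0.5) < 0.06)

    def test_odd_population_leaves_one_out_uniformly(self):
        pop = np.full(9, 50.0)
        left_out = np.zeros(9)
        for pair in random_splits(pop, 1000, seed=2):
            used = set(pair.group_a_ids) | set(pair.group_b_ids)
            assert len(used) == 8
            left_out[list(set(range(9)) - used)] += 1
        assert np.all(left_out > 0)

    def test_too_small_population_rejected(self):
        with pytest.raises(ConfigurationError):
            next(random_splits(np.array([1.0, 2.0]), 1, seed=0))


class TestSplitSelection:
    def test_exhaustive_toy_reaches_exact_target(self):
        pop = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0])
        best = select_split_for_difference(exhaustive_splits(pop), 10.0)
        assert best.achieved_d == pytest.approx(10.0)
        assert sorted(pop[list(best.group_a_ids)]) == [10.0, 10.0, 10.0]

    def test_exhaustive_toy_best_near_zero(self):
        pop = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0])
        best = select_split_for_difference(exhaustive_splits(pop), 0.0)
        assert best.achieved_d == pytest.approx(10.0 / 3.0)

    def test_single_candidate_returned_for_any_target(self):
        pop = np.arange(6, dtype=float)
        only = list(random_splits(pop, 1, seed=2))
        best = select_split_for_difference(iter(only), 99.0)
        assert best.group_a_ids == only[0].group_a_ids
        assert best.target_d == 99.0

    def test_empty_stream_rejected(self):
        with pytest.raises(ConfigurationError):
            select_split_for_difference(iter(()), 5.0)


class TestSplitRefinement:
    @pytest.mark.parametrize("target", [3.0, 5.0, 8.0, 10.0])
    def test_reaches_target_on_study_cohort(self, default_cohort, target):
        pair = select_split_for_difference(
            random_splits(default_cohort, 50, seed=3), target
        )
        refined = refine_split_to_difference(default_cohort, pair, target)
        assert refined.achieved_d == pytest.approx(target, abs=0.01)
        assert len(refined.group_a_ids) == len(refined.group_b_ids) == 790
        assert not set(refined.group_a_ids) & set(refined.group_b_ids)

    def test_refinement_is_deterministic(self, default_cohort):
        pair = select_split_for_difference(
            random_splits(default_cohort, 20, seed=4), 6.0
        )
        a = refine_split_to_difference(default_cohort, pair, 6.0)
        b = refine_split_to_difference(default_cohort, pair, 6.0)
        assert a.group_a_ids == b.group_a_ids


class TestEstimatePower:
    def test_null_rejection_rate_near_alpha(self, default_cohort):
        scores = default_cohort.gmfm66
        rate = estimate_power(scores, scores, 50, reps=4000, seed=8)
        assert 3.0 < rate < 7.0

    def test_overwhelming_effect_saturates(self):
        rng = np.random.default_rng(9)
        a = rng.normal(100, 1, 500)
        b = rng.normal(50, 1, 500)
        assert estimate_power(a, b, 30, reps=500, seed=0) == 100.0

    def test_sample_size_bounds(self):
        a = np.arange(20, dtype=float)
        with pytest.raises(ConfigurationError):
            estimate_power(a, np.arange(10, dtype=float), 15, reps=10, seed=0)
        with pytest.raises(ConfigurationError):
            estimate_power(a, a, 11, reps=10, seed=0)  # shared pool needs 2n

    @pytest.mark.parametrize("test", ["welch_t", "student_t", "mann_whitney"])
    def test_all_tests_run_and_detect_signal(self, test):
        rng = np.random.default_rng(10)
        a = rng.normal(60, 10, 2000)
        b = rng.normal(50, 10, 2000)
        power = estimate_power(a, b, 100, reps=400, testspec=TestSpec(test=test), seed=1)
        assert power > 95.0

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ConfigurationError):
            TestSpec(alpha=0.7).validate()


class TestAnalyticOracle:
    def test_matches_statsmodels_power(self):
        # independent cross-check of the noncentral-t closed form
        import statsmodels.stats.power as smp

        sd, d, n = 10.0, 5.0, 40
        mine = analytic_t_power(d, sd, sd, n, n, alpha=0.05)
        theirs = 100 * smp.TTestIndPower().power(
            effect_size=d / sd, nobs1=n, ratio=1.0, alpha=0.05, alternative="two-sided"
        )
        assert mine == pytest.approx(theirs, abs=0.2)


@pytest.fixture(scope="module")
def small_cohort_with_mds():
    import pandas as pd

    rng = np.random.default_rng(11)
    spec = [
        (f"p{i}", float(np.clip(rng.normal(50, 18), 0, 100)), 3, {"A"})
        for i in range(400)
    ]
    cohort = make_toy_cohort(spec)
    noisy = np.clip(cohort.gmfm66 + rng.normal(0, 8, 400), 0, 100)
    mds = pd.Series(noisy, index=pd.Index(cohort.ids), name="mds")
    return cohort, mds


class TestPowerTable:
    def test_single_rep_cells_are_degenerate(self, small_cohort_with_mds):
        cohort, mds = small_cohort_with_mds
        grid = power_table(
            cohort, mds, d_list=(5,), n_list=(30,), k_splits=50, reps=1, seed=0
        )
        assert set(grid.frame["power_pct"]) <= {0.0, 100.0}

    def test_identical_sources_give_identical_columns(self, small_cohort_with_mds):
        import pandas as pd

        cohort, _ = small_cohort_with_mds
        same = pd.Series(cohort.gmfm66, index=pd.Index(cohort.ids), name="mds")
        grid = power_table(
            cohort, same, d_list=(4, 8), n_list=(30, 80), k_splits=100, reps=300, seed=1
        )
        pivot = grid.frame.pivot_table(
            index=["n", "target_d"], columns="source", values="power_pct"
        )
        assert np.array_equal(pivot["gmfm"], pivot["mds"])

    def test_oversized_group_request_rejected(self, small_cohort_with_mds):
        cohort, mds = small_cohort_with_mds
        with pytest.raises(ConfigurationError, match="exceed half"):
            power_table(cohort, mds, d_list=(5,), n_list=(500,), k_splits=10, reps=10)

    def test_incomplete_mds_rejected(self, small_cohort_with_mds):
        cohort, mds = small_cohort_with_mds
        with pytest.raises(ConfigurationError, match="every cohort patient"):
            power_table(
                cohort, mds.iloc[:100], d_list=(5,), n_list=(30,), k_splits=10, reps=10
            )

    def test_grid_is_complete(self, small_cohort_with_mds):
        cohort, mds = small_cohort_with_mds
        grid = power_table(
            cohort, mds, d_list=(4, 8), n_list=(30, 80), k_splits=100, reps=100, seed=2
        )
        assert len(grid.frame) == 2 * 2 * 2
        assert grid.cell(30, 8, "gmfm") >= 0.0

    def test_smallest_n_lookup(self, small_cohort_with_mds):
        cohort, mds = small_cohort_with_mds
        grid = power_table(
            cohort, mds, d_list=(10,), n_list=(30, 80, 150), k_splits=200,
            reps=400, seed=3,
        )
        n80 = smallest_n_for_power(grid, 10, "gmfm", 80.0)
        assert n80 in (30, 80, 150, None)
        if n80 is not None:
            assert grid.cell(n80, 10, "gmfm") >= 80.0
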