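"""Inferential core: permutation framework, adjustments, rank and table tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from trioquant.stats import (
    bh_adjust, chi2_independence, dunn_sidak, fisher_exact_enumeration,
    fisher_mc, format_pvalue, kruskal_wallis, mc_shuffles_needed,
    observed_statistic, permutation_pvalue, reciprocity_test, se_proportion,
    shuffle_null, sidak_adjust, within_radius_statistic,
)
from trioquant.synthgen import SynthConfig, make_experiment


@pytest.fixture(scope="module")
def null_experiments():
    cfg = SynthConfig(seed=21, n_L5_cells=0, n_L6_cells=500,
                      l5_reciprocal_multiplier=1.0,
                      l6_reciprocal_multiplier=1.0,
                      n_brainwide_inputs=10, n_starter_cells=10, n_sc_cells=10)
    return [make_experiment(cfg, t, f"{t}n") for t in ("PM", "RL", "LM")]


class TestShuffleNull:
    def test_target_blind_statistic_gives_constant_null(self, null_experiments):
        def total_count(e, target, ref):
            return float(len(e.cells))
        obs = observed_statistic(null_experiments, total_count)
        null = shuffle_null(null_experiments, total_count, n_shuffles=50, seed=0)
        assert np.allclose(null, obs)

    def test_exhaustive_single_experiment_has_five_values(self, null_experiments):
        stat = within_radius_statistic("L6", 400.0)
        null = shuffle_null(null_experiments[:1], stat, exhaustive=True)
        assert len(null) == 5
        obs = observed_statistic(null_experiments[:1], stat)
        assert obs in null  # original configuration is inside the support

    def test_exhaustive_enumerates_product_space(self, null_experiments):
        stat = within_radius_statistic("L6", 400.0)
        null = shuffle_null(null_experiments[:2], stat, exhaustive=True)
        assert len(null) == 25

    def test_two_seeds_differ_but_same_distribution(self, null_experiments):
        stat = within_radius_statistic("L6", 400.0)
        a = shuffle_null(null_experiments, stat, n_shuffles=400, seed=1)
        b = shuffle_null(null_experiments, stat, n_shuffles=400, seed=2)
        assert not np.array_equal(a, b)
        assert sps.ks_2samp(a, b).pvalue > 0.01

    def test_deterministic_given_seed(self, null_experiments):
        stat = within_radius_statistic("L6", 400.0)
        a = shuffle_null(null_experiments, stat, n_shuffles=100, seed=9)
        b = shuffle_null(null_experiments, stat, n_shuffles=100, seed=9)
        assert np.array_equal(a, b)

    def test_exclude_original_target_option(self, null_experiments):
        stat = within_radius_statistic("L6", 400.0)
        null = shuffle_null(null_experiments[:1], stat, exhaustive=True,
                            include_original=False)
        assert len(null) == 4

    def test_unknown_candidate_raises_with_names(self, null_experiments):
        stat = within_radius_statistic("L6", 400.0)
        with pytest.raises(Exception, match="XX"):
            shuffle_null(null_experiments[:1], stat, n_shuffles=5,
                         candidates=("PM", "XX"))

    def test_sampled_null_converges_to_enumeration(self, null_experiments):
        """Sampled p-values approach the exhaustive-enumeration p-value as the
        shuffle count grows (MC error ~ N^-1/2)."""
        stat = within_radius_statistic("L6", 400.0)
        exps = null_experiments[:2]
        enum = shuffle_null(exps, stat, exhaustive=True)
        obs = observed_statistic(exps, stat)
        p_exact = permutation_pvalue(obs, enum, "upper", exhaustive=True)
        errs = []
        for n in (100, 400, 1600, 6400):
            null = shuffle_null(exps, stat, n_shuffles=n, seed=5)
            errs.append(abs(permutation_pvalue(obs, null, "upper") - p_exact))
        assert errs[-1] <= max(errs[0], 3 * np.sqrt(p_exact * (1 - p_exact) / 6400))


class TestPermutationPvalue:
    def test_exhaustive_uses_plain_proportion(self):
        null = np.array([0.1, 0.2, 0.3, 0.4, 0.9])
        assert permutation_pvalue(0.9, null, "upper", exhaustive=True) == 0.2

    def test_observed_below_all_upper_tail_is_one(self):
        null = np.arange(1.0, 10.0)
        assert permutation_pvalue(0.0, null, "upper") == 1.0

    def test_floor_at_ten_thousand_shuffles(self):
        null = np.random.default_rng(0).uniform(size=9_999)
        p = permutation_pvalue(2.0, null, "upper")
        assert p == pytest.approx(1.0e-4, rel=1e-3)
        assert p == 1.0 / (9_999 + 1)

    def test_lower_tail_mirrors_upper(self):
        null = np.arange(10.0)
        assert permutation_pvalue(-1.0, null, "lower") == pytest.approx(1 / 11)
        assert permutation_pvalue(100.0, null, "lower") == 1.0

    def test_report_floor_formatting(self):
        assert format_pvalue(1 / 10_001, 10_000).startswith("<")
        assert format_pvalue(0.0423, 10_000) == "0.0423"


class TestBH:
    def test_stepup_hand_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_equal_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), 0.3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    def test_monotone_dominates_raw_and_matches_stepup_oracle(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        # brute-force step-up: q_i = min over j >= i (sorted) of p_j * m / j
        m = len(ps)
        srt = sorted(range(m), key=lambda i: ps[i])
        expect = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = srt[rank - 1]
            running = min(running, ps[i] * m / rank)
            expect[i] = running
        assert np.allclose(adj, expect)


class TestRankTests:
    def test_kruskal_hand_value(self):
        H, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert H == pytest.approx(7.2)
        assert p == pytest.approx(sps.chi2.sf(7.2, 2))

    def test_identical_groups_h_near_zero(self):
        H, p = kruskal_wallis([[1, 2, 3, 4], [1.5, 2.5, 3.5, 4.5]])
        assert H < 0.5 and p > 0.4

    def test_total_ties_degenerate(self):
        with pytest.raises(ValueError, match="identical"):
            kruskal_wallis([[1, 1], [1, 1]])

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(0, 1, 15), rng.normal(0, 1, 15),
                  rng.normal(8, 1, 15)]
        _, p = kruskal_wallis(groups)
        assert p < 1e-4

    def test_sidak_hand_value(self):
        assert sidak_adjust(0.04, 3) == pytest.approx(0.115264)
        assert sidak_adjust(0.0, 5) == 0.0
        assert sidak_adjust(0.2, 1) == pytest.approx(0.2)

    def test_dunn_gatekeeping(self):
        rng = np.random.default_rng(12)
        same = [rng.normal(0, 1, 10) for _ in range(3)]
        # overwhelmingly nonsignificant omnibus -> no post hoc comparisons
        if kruskal_wallis(same)[1] >= 0.05:
            assert dunn_sidak(same) == []
        shifted = [rng.normal(0, 1, 12), rng.normal(0, 1, 12),
                   rng.normal(6, 1, 12)]
        out = dunn_sidak(shifted, labels=["a", "b", "c"])
        assert len(out) == 3
        by_pair = {tuple(sorted(d["pair"])): d for d in out}
        assert by_pair[("a", "c")]["p_sidak"] < 0.01
        assert by_pair[("a", "b")]["p_sidak"] > 0.05
        for d in out:
            assert d["p_sidak"] >= d["p_raw"] - 1e-12


class TestFisher:
    def test_enumeration_hand_example(self):
        assert fisher_exact_enumeration([[2, 1], [1, 2]]) == pytest.approx(1.0)

    def test_enumeration_matches_scipy_two_by_two(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            t = rng.integers(1, 8, (2, 2))
            ours = fisher_exact_enumeration(t)
            ref = sps.fisher_exact(t).pvalue
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_one_dimensional_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_mc([[1, 2, 3]], n_shuffles=10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_mc([[0, 0], [1, 2]], n_shuffles=10)

    def test_mc_close_to_enumeration(self):
        rng = np.random.default_rng(14)
        within = 0
        n_tables = 20
        for i in range(n_tables):
            shape = (2, 2) if i % 2 else (2, 3)
            while True:
                t = rng.integers(0, 8, shape)
                if t.sum() <= 30 and (t.sum(0) > 0).all() and (t.sum(1) > 0).all():
                    break
            exact = fisher_exact_enumeration(t)
            p, se = fisher_mc(t, n_shuffles=4000, seed=100 + i)
            within += int(abs(p - exact) <= max(3 * se, 3e-3))
        assert within >= int(0.95 * n_tables)

    def test_mc_se_scales_inverse_sqrt(self):
        t = [[5, 2, 3], [1, 6, 4]]
        _, se1 = fisher_mc(t, n_shuffles=1000, seed=1)
        _, se2 = fisher_mc(t, n_shuffles=16_000, seed=1)
        assert se2 < se1


class TestShufflesNeeded:
    def test_published_precision_target(self):
        n = mc_shuffles_needed(0.0001, 0.95)
        assert round(n / 1e7, 1) == 9.6  # 9.6e7 to two significant figures
        assert n == 96_036_472 or abs(n - 9.6036e7) < 1e4

    def test_worst_case_tiny(self):
        assert mc_shuffles_needed(0.5, 0.95) == 4

    def test_quadratic_scaling(self):
        n1 = mc_shuffles_needed(0.01, 0.9)
        n2 = mc_shuffles_needed(0.005, 0.9)
        assert abs(n2 - 4 * n1) <= 4

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            mc_shuffles_needed(0.0, 0.95)
        with pytest.raises(ValueError):
            mc_shuffles_needed(0.1, 1.0)


class TestChi2AndSE:
    def test_independent_table_zero_statistic(self):
        chi2, dof, p = chi2_independence([[10, 10], [10, 10]])
        assert chi2 == 0.0 and dof == 1 and p == pytest.approx(1.0)

    def test_diagonal_table_hand_value(self):
        chi2, dof, _ = chi2_independence([[20, 0], [0, 20]])
        assert chi2 == pytest.approx(40.0) and dof == 1

    def test_row_swap_invariance(self):
        t = [[12, 5, 3], [2, 9, 11]]
        a = chi2_independence(t)[0]
        b = chi2_independence(t[::-1])[0]
        assert a == pytest.approx(b)

    def test_se_proportion_values(self):
        assert se_proportion(0.5, 100) == pytest.approx(0.05)
        assert se_proportion(0.0, 10) == 0.0
        assert se_proportion(0.2, 25) == pytest.approx(0.08)

    def test_se_proportion_domain(self):
        with pytest.raises(ValueError):
            se_proportion(1.2, 10)
        with pytest.raises(ValueError):
            se_proportion(0.5, 0)


class TestReciprocityTest:
    def test_planted_enrichment_detected_single_run(self):
        cfg = SynthConfig(seed=31, n_L5_cells=0, n_L6_cells=1500,
                          l6_reciprocal_multiplier=4.0,
                          n_brainwide_inputs=10, n_starter_cells=10,
                          n_sc_cells=10)
        exps = [make_experiment(cfg, "AL", f"e{i}") for i in range(3)]
        res = reciprocity_test(exps, "L6", "upper", n_shuffles=500, seed=2)
        assert res.p_raw < 0.05
        assert res.observed > np.median(res.null_sample)

    def test_result_serialization_includes_floor_report(self):
        cfg = SynthConfig(seed=32, n_L5_cells=0, n_L6_cells=800,
                          l6_reciprocal_multiplier=6.0,
                          n_brainwide_inputs=10, n_starter_cells=10,
                          n_sc_cells=10)
        exps = [make_experiment(cfg, "LM", f"f{i}") for i in range(4)]
        res = reciprocity_test(exps, "L6", "upper", n_shuffles=200, seed=3)
        d = res.to_dict()
        assert set(d) >= {"statistic", "observed", "p_raw", "p_report",
                          "n_shuffles"}
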