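"""Descriptive quantities: fractions, hexbins, distances, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trioquant.errors import (
    EmptyExperimentError, InsufficientDataError,
)
from trioquant.quantify import (
    DistanceSample, distance_density, distances_to_target, hexbin_density,
    input_fractions, median_mad, pooled_mean_sem, proportion_within_radius,
    relative_strength_matrix, visual_normalized_fractions,
)


class TestInputFractions:
    def test_simple_split(self):
        assert input_fractions({"A": 50, "B": 50}) == {"A": 0.5, "B": 0.5}

    def test_single_region_gets_everything(self):
        assert input_fractions({"SC": 0, "CTX": 12})["CTX"] == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(EmptyExperimentError):
            input_fractions({"A": 0})

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        counts = {f"r{i}": int(c) for i, c in
                  enumerate(rng.integers(0, 100, 12))}
        counts["r0"] += 1
        assert abs(sum(input_fractions(counts).values()) - 1.0) < 1e-12

    def test_multinomial_expectation_recovered(self):
        """Pooled fractions over synthetic experiments recover the generating
        brain-wide weights within 3 SEs."""
        from trioquant.synthgen import SynthConfig, make_experiment
        cfg = SynthConfig(seed=6, n_L5_cells=5, n_L6_cells=5,
                          n_brainwide_inputs=2000, n_starter_cells=10,
                          n_sc_cells=5)
        totals = {}
        n_exp = 12
        for i in range(n_exp):
            e = make_experiment(cfg, "RL", f"m{i}")
            for k, v in e.brainwide_counts.items():
                totals[k] = totals.get(k, 0) + v
        n = sum(totals.values())
        for region, w in cfg.brainwide_weights.items():
            if w == 0:
                continue
            se = np.sqrt(w * (1 - w) / n)
            assert abs(totals[region] / n - w) <= 3 * se, region


class TestVisualNormalized:
    def _cells(self, areas, layer="L5"):
        return pd.DataFrame({
            "layer": layer, "area": areas,
            "x_um": 0.0, "y_um": 0.0,
        })

    def test_all_in_v1(self):
        f, ok = visual_normalized_fractions(self._cells(["V1"] * 5), "L5")
        assert ok and f["V1"] == 1.0

    def test_ninety_ten_split(self):
        f, ok = visual_normalized_fractions(
            self._cells(["V1"] * 90 + ["LM"] * 10), "L5")
        assert ok and f["V1"] == 0.9 and f["LM"] == 0.1

    def test_invariant_to_nonvisual_cells(self):
        base = self._cells(["V1"] * 9 + ["LM"])
        noisy = pd.concat([base, self._cells(["RSP"] * 40)], ignore_index=True)
        fa, _ = visual_normalized_fractions(base, "L5")
        fb, _ = visual_normalized_fractions(noisy, "L5")
        assert fa == fb

    def test_zero_visual_layer_flagged_undefined(self):
        f, ok = visual_normalized_fractions(self._cells(["RSP"] * 3), "L5")
        assert not ok and all(np.isnan(v) for v in f.values())


class TestHexbin:
    def test_identical_points_share_one_bin(self):
        g = hexbin_density(np.array([[10.0, 20.0]] * 3))
        assert len(g.bins) == 1 and g.total == 3

    def test_empty_input_empty_grid(self):
        g = hexbin_density(np.empty((0, 2)))
        assert g.total == 0 and len(g.bins) == 0

    def test_count_conservation(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-5000, 5000, (2345, 2))
        assert hexbin_density(pts).total == 2345

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 2000, (400, 2))
        shift = np.array([722.0, -1311.0])
        a = hexbin_density(pts).bins
        b = hexbin_density(pts + shift, origin=tuple(shift)).bins
        pd.testing.assert_frame_equal(
            a[["q", "r", "count"]], b[["q", "r", "count"]])

    def test_points_assigned_to_nearest_center(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-2000, 2000, (300, 2))
        g = hexbin_density(pts)
        centers = g.bins[["cx_um", "cy_um"]].to_numpy()
        for p in pts[:50]:
            d = np.hypot(centers[:, 0] - p[0], centers[:, 1] - p[1])
            own = g.bins.iloc[int(np.argmin(d))]
            # nearest listed center must be the cell's own bin center,
            # within the circumradius
            assert d.min() <= 180.6 / np.sqrt(3) + 1e-9
            assert own["count"] >= 1

    def test_poisson_dispersion_of_uniform_counts(self):
        """Uniform points give near-Poisson bin counts: variance/mean of
        fully interior bins close to 1."""
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 12000, (30000, 2))
        g = hexbin_density(pts)
        inner = g.bins[(g.bins["cx_um"] > 1000) & (g.bins["cx_um"] < 11000)
                       & (g.bins["cy_um"] > 1000) & (g.bins["cy_um"] < 11000)]
        ratio = inner["count"].var() / inner["count"].mean()
        assert 0.8 < ratio < 1.25


class TestDistances:
    def test_reference_point_distance_zero(self):
        cells = pd.DataFrame({"x_um": [5.0], "y_um": [7.0], "layer": "L6"})
        s = distances_to_target(cells, (5.0, 7.0))
        assert s.distances_um[0] == 0.0

    def test_three_four_five(self):
        cells = pd.DataFrame({"x_um": [300.0], "y_um": [400.0], "layer": "L6"})
        assert distances_to_target(cells, (0.0, 0.0)).distances_um[0] == 500.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        xy = rng.normal(0, 100, (50, 2))
        cells = pd.DataFrame({"x_um": xy[:, 0], "y_um": xy[:, 1], "layer": "L6"})
        shifted = cells.assign(x_um=cells.x_um + 55, y_um=cells.y_um - 44)
        a = distances_to_target(cells, (0.0, 0.0)).distances_um
        b = distances_to_target(shifted, (55.0, -44.0)).distances_um
        assert np.allclose(a, b)

    def test_proportion_within_radius_closed_disc(self):
        s = DistanceSample(np.array([100.0, 300.0, 500.0]))
        assert proportion_within_radius(s, 400.0)[0] == pytest.approx(2 / 3)
        assert proportion_within_radius(s, np.inf)[0] == 1.0
        assert proportion_within_radius(s, 0.0)[0] == 0.0
        assert proportion_within_radius(s, 300.0)[0] == pytest.approx(2 / 3)

    def test_empty_sample_is_undefined_not_zero(self):
        p, n = proportion_within_radius(DistanceSample(np.array([])), 400.0)
        assert np.isnan(p) and n == 0


class TestDistanceDensity:
    def test_integral_is_one_with_reflection(self):
        rng = np.random.default_rng(8)
        s = DistanceSample(np.abs(rng.normal(500, 300, 2000)))
        grid, dens = distance_density(s)
        assert (dens >= 0).all()
        assert abs(np.trapezoid(dens, grid) - 1.0) <= 0.01

    def test_mode_near_true_center(self):
        rng = np.random.default_rng(9)
        s = DistanceSample(rng.normal(2000, 200, 5000).clip(min=0))
        grid, dens = distance_density(s)
        assert abs(grid[np.argmax(dens)] - 2000) <= 100

    def test_bimodal_for_two_far_points(self):
        grid, dens = distance_density(
            DistanceSample(np.array([100.0, 4000.0] * 3)))
        assert abs(np.trapezoid(dens, grid) - 1.0) <= 0.02
        assert dens[np.argmin(np.abs(grid - 100))] > dens[
            np.argmin(np.abs(grid - 2000))]

    def test_single_point_insufficient(self):
        with pytest.raises(InsufficientDataError):
            distance_density(DistanceSample(np.array([5.0])))


class TestSummaries:
    def test_pooled_mean_sem_hand_example(self):
        mean, sem = pooled_mean_sem([0.0, 100.0])
        assert mean == 50.0 and sem == pytest.approx(50.0)

    def test_constant_vector_sem_zero(self):
        assert pooled_mean_sem([3.0, 3.0, 3.0])[1] == 0.0

    def test_median_mad_hand_example(self):
        assert median_mad([1, 2, 3, 4, 100]) == (3.0, 1.0)

    def test_median_mad_degenerate(self):
        assert median_mad([7.0]) == (7.0, 0.0)
        assert median_mad([2.0, 2.0, 2.0]) == (2.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40))
    def test_summaries_match_bruteforce(self, values):
        mean, sem = pooled_mean_sem(values)
        n = len(values)
        bf_mean = sum(values) / n
        bf_var = sum((v - bf_mean) ** 2 for v in values) / (n - 1)
        assert mean == pytest.approx(bf_mean, abs=1e-6)
        assert sem == pytest.approx((bf_var ** 0.5) / n ** 0.5, abs=1e-6)
        med, mad = median_mad(values)
        sv = sorted(values)
        bf_med = (sv[(n - 1) // 2] + sv[n // 2]) / 2
        assert med == pytest.approx(bf_med)
        dev = sorted(abs(v - bf_med) for v in values)
        bf_mad = (dev[(n - 1) // 2] + dev[n // 2]) / 2
        assert mad == pytest.approx(bf_mad)


class TestRelativeStrength:
    def test_column_divided_by_max(self):
        m = pd.DataFrame({"t": [2.0, 4.0, 8.0]})
        out = relative_strength_matrix(m)
        assert list(out["t"]) == [0.25, 0.5, 1.0]

    def test_identity_unchanged(self):
        m = pd.DataFrame(np.eye(3))
        assert np.allclose(relative_strength_matrix(m).to_numpy(), np.eye(3))

    def test_scale_invariance_and_zero_column_flag(self):
        m = pd.DataFrame({"a": [1.0, 3.0], "z": [0.0, 0.0]})
        a = relative_strength_matrix(m)
        b = relative_strength_matrix(m * 17.0)
        assert np.allclose(a["a"], b["a"])
        assert a.attrs["zero_columns"] == ["z"]
        assert (a["z"] == 0).all()
        assert ((a.to_numpy() >= 0) & (a.to_numpy() <= 1)).all()
        assert (a.max(axis=0)[["a"]] == 1.0).all()
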