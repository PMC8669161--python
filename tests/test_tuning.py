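import numpy as np
import pandas as pd
import pytest

import spectune as st
from spectune import tuning as tn
from spectune.synthetic import ARCHETYPE_GROUPS, make_archetype_weights, make_population


@pytest.fixture()
def grid(cones):
    return cones.wavelength_grid_nm


class TestBulkTuning:
    def test_red_only_weight_proportional_to_red_tuning(self, cones):
        W = np.zeros((4, 4))
        W[0, 1] = 2.0
        curve = tn.bulk_tuning(W, cones)
        np.testing.assert_allclose(curve, 2.0 * cones.tuning["red"], atol=1e-12)

    def test_zero_weights_zero_curve(self, cones):
        np.testing.assert_array_equal(tn.bulk_tuning(np.zeros((4, 4)), cones), 0.0)

    def test_green_only_crosses_at_template_crossing(self, cones, grid):
        W = np.zeros((4, 4))
        W[1, :] = 1.0
        curve = tn.bulk_tuning(W, cones)
        xs = tn.find_zero_crossings(curve, grid)
        assert len(xs) == 1
        assert abs(xs[0] - 523.0) <= 2.0

    def test_linear_in_weights(self, cones):
        rng = np.random.default_rng(0)
        A, B = rng.normal(size=(2, 4, 4))
        lhs = tn.bulk_tuning(A + 2 * B, cones)
        rhs = tn.bulk_tuning(A, cones) + 2 * tn.bulk_tuning(B, cones)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_normalization_does_not_move_crossings(self, cones, grid):
        from spectune.decompose import normalize_weights

        W = make_archetype_weights("green-opponent") * 3.7
        x1 = tn.find_zero_crossings(tn.bulk_tuning(W, cones), grid)
        x2 = tn.find_zero_crossings(
            tn.bulk_tuning(normalize_weights(W).w, cones), grid
        )
        np.testing.assert_allclose(x1, x2, atol=1e-9)


class TestFindZeroCrossings:
    def test_linear_curve_crossing_at_500(self):
        grid = np.arange(400.0, 601.0)
        assert tn.find_zero_crossings(grid - 500.0, grid) == [500.0]

    def test_strictly_positive_no_crossings(self):
        grid = np.arange(400.0, 601.0)
        assert tn.find_zero_crossings(np.ones_like(grid), grid) == []

    def test_sine_crossings_recovered(self):
        # constructed to cross at exactly 450 and 520
        grid = np.arange(400.0, 601.0)
        curve = np.sin(np.pi * (grid - 450.0) / 70.0)
        xs = tn.find_zero_crossings(curve, grid)
        assert any(abs(x - 450.0) <= 1.0 for x in xs)
        assert any(abs(x - 520.0) <= 1.0 for x in xs)


class TestClassifyOpponency:
    def _curve(self, lobe_frac):
        grid = np.arange(360.0, 611.0)
        main = np.exp(-0.5 * ((grid - 550) / 20.0) ** 2)
        opp = np.exp(-0.5 * ((grid - 430) / 20.0) ** 2)
        curve = main - opp
        # rescale the negative lobe so its overshoot is exactly lobe_frac of
        # the dominant peak
        neg = curve < 0
        curve[neg] *= lobe_frac * curve.max() / (-curve.min())
        return grid, curve

    def test_exactly_ten_percent_is_opponent(self):
        grid, curve = self._curve(0.10)
        is_opp, xs = tn.classify_opponency(curve, grid)
        assert is_opp and len(xs) >= 1

    def test_five_percent_not_opponent(self):
        grid, curve = self._curve(0.05)
        is_opp, xs = tn.classify_opponency(curve, grid)
        assert not is_opp

    def test_monophasic_not_opponent(self):
        grid = np.arange(360.0, 611.0)
        curve = np.exp(-0.5 * ((grid - 500) / 30.0) ** 2)
        is_opp, xs = tn.classify_opponency(curve, grid)
        assert not is_opp and xs == []

    def test_invariant_to_positive_rescaling(self):
        grid, curve = self._curve(0.3)
        r1 = tn.classify_opponency(curve, grid)
        r2 = tn.classify_opponency(17.3 * curve, grid)
        assert r1[0] == r2[0]
        np.testing.assert_allclose(r1[1], r2[1])

    def test_zero_curve_rejected(self):
        grid = np.arange(360.0, 611.0)
        with pytest.raises(ValueError):
            tn.classify_opponency(np.zeros_like(grid), grid)


class TestAssignSpectralGroup:
    def _tuning(self, curve, grid, cones):
        t = tn.SpectralTuning(curve=curve, wavelength_grid_nm=grid)
        t.is_opponent, t.qualifying_crossings_nm = tn.classify_opponency(curve, grid)
        return t

    def test_crossing_at_448_is_uv_opponent(self, cones, grid):
        curve = -np.tanh((grid - 448.0) / 30.0)
        t = self._tuning(curve, grid, cones)
        assert tn.assign_spectral_group(t, cones) == "uv-opponent"

    def test_crossing_at_497_is_blue_opponent(self, cones, grid):
        curve = -np.tanh((grid - 497.0) / 30.0)
        t = self._tuning(curve, grid, cones)
        assert tn.assign_spectral_group(t, cones) == "blue-opponent"

    def test_crossing_at_523_is_green_opponent(self, cones, grid):
        curve = np.tanh((grid - 523.0) / 30.0)
        t = self._tuning(curve, grid, cones)
        assert tn.assign_spectral_group(t, cones) == "green-opponent"

    def test_flat_negative_curve_is_broad(self, cones, grid):
        t = self._tuning(-np.ones_like(grid), grid, cones)
        assert tn.assign_spectral_group(t, cones) == "broad"

    def test_archetypes_recover_generating_group(self, cones):
        for g in ARCHETYPE_GROUPS:
            t = tn.analyze_tuning(make_archetype_weights(g), cones)
            assert t.spectral_group == g, g

    def test_end_to_end_group_recovery_with_noise(self, cones):
        # six archetype clusters with jittered weights: >= 90% recovered
        rng = np.random.default_rng(1)
        n_ok = n_tot = 0
        for g in ARCHETYPE_GROUPS:
            for _ in range(15):
                W = make_archetype_weights(g) + rng.normal(0, 0.03, (4, 4))
                t = tn.analyze_tuning(W, cones)
                n_tot += 1
                n_ok += t.spectral_group == g
        assert n_ok >= 0.9 * n_tot


class TestZeroCrossingHistogram:
    def test_single_cluster_mass_in_crossing_bin(self, cones):
        t = tn.analyze_tuning(make_archetype_weights("green-opponent"), cones)
        hist, edges = tn.zero_crossing_histogram([t], np.array([100.0]))
        assert hist.sum() == pytest.approx(100.0)
        i = int(np.argmax(hist))
        assert edges[i] <= 523.0 <= edges[i + 1]

    def test_total_mass_counts_opponent_clusters_only(self, cones):
        ts = [
            tn.analyze_tuning(make_archetype_weights(g), cones)
            for g in ("green-opponent", "blue-opponent", "red-cone-like")
        ]
        hist, _ = tn.zero_crossing_histogram(ts, np.array([10.0, 20.0, 40.0]))
        assert hist.sum() == pytest.approx(30.0)  # red-cone-like contributes 0

    def test_trimodal_from_three_archetypes(self, cones):
        pop = make_population(
            groups=("uv-opponent", "blue-opponent", "green-opponent"),
            n_per_group=15, weight_jitter_sd=0.05, seed=0,
        )
        ts = [tn.analyze_tuning(w, cones) for w in pop.weights]
        hist, edges = tn.zero_crossing_histogram(ts, np.ones(pop.n_rois))
        centers = (edges[:-1] + edges[1:]) / 2
        for ref in (450.0, 483.0, 523.0):
            near = np.abs(centers - ref) <= 10.0
            assert hist[near].sum() > 0.2 * hist.sum()


class TestRandomizationControls:
    def test_shuffle_with_identical_cones_is_noop(self, cones):
        same = st.make_cone_tunings(
            mode="measured",
            tuning={c: cones.tuning["red"].copy() for c in cones.tuning},
        )
        rng = np.random.default_rng(0)
        W = rng.normal(size=(5, 4, 4))
        counts = np.ones(5)
        real, edges = tn.zero_crossing_histogram(
            [tn.analyze_tuning(w, same) for w in W], counts
        )
        nulls, _ = tn.randomization_controls(
            W, same, counts, mode="shuffle_across_cones", n_iter=5, seed=0
        )
        for h in nulls:
            np.testing.assert_allclose(h, real)

    def test_trimodality_collapses_under_cone_shuffle(self, cones):
        pop = make_population(
            groups=("uv-opponent", "blue-opponent", "green-opponent"),
            n_per_group=15, weight_jitter_sd=0.05, seed=0,
        )
        counts = np.ones(pop.n_rois)
        ts = [tn.analyze_tuning(w, cones) for w in pop.weights]
        real, _ = tn.zero_crossing_histogram(ts, counts)
        nulls, _ = tn.randomization_controls(
            pop.weights, cones, counts, mode="shuffle_across_cones",
            n_iter=10, seed=1,
        )
        real_score = tn.trimodality_score(real)
        null_scores = [tn.trimodality_score(h) for h in nulls]
        assert real_score > 2 * np.mean(null_scores)

    def test_seed_reproducibility(self, cones):
        rng = np.random.default_rng(2)
        W = rng.normal(size=(4, 4, 4))
        counts = np.ones(4)
        h1, _ = tn.randomization_controls(W, cones, counts, mode="randomize",
                                          n_iter=3, seed=9)
        h2, _ = tn.randomization_controls(W, cones, counts, mode="randomize",
                                          n_iter=3, seed=9)
        np.testing.assert_array_equal(h1, h2)


class TestVarianceExplained:
    def test_perfect_reconstruction(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 300))
        fq = tn.variance_explained(X, X)
        assert fq.variance_explained_pct == pytest.approx(100.0)
        assert fq.residual_variance_pct == pytest.approx(0.0, abs=1e-10)

    def test_zero_reconstruction(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 300))
        fq = tn.variance_explained(X, np.zeros_like(X))
        assert fq.variance_explained_pct == pytest.approx(0.0, abs=1e-10)
        assert fq.residual_variance_pct == pytest.approx(100.0)

    def test_zero_original_variance_rejected(self):
        with pytest.raises(ValueError):
            tn.variance_explained(np.ones((4, 50)), np.ones((4, 50)))


class TestPowerExplained:
    def test_perfect_reconstruction(self):
        rng = np.random.default_rng(0)
        t = np.arange(400) / 42.0
        X = np.sin(2 * np.pi * 0.7 * t)[None] * rng.normal(size=(6, 1))
        fq = tn.power_explained(X, X)
        assert fq.power_explained_pct == pytest.approx(100.0)
        assert fq.residual_power_pct == pytest.approx(0.0, abs=1e-10)

    def test_small_noise_residual_far_below_100(self):
        rng = np.random.default_rng(1)
        t = np.arange(800) / 42.0
        X = np.sin(2 * np.pi * 0.7 * t)[None] * rng.normal(size=(6, 1)) * 5
        recon = X + rng.normal(0, 0.05, X.shape)
        fq = tn.power_explained(X, recon)
        assert fq.residual_power_pct < 20.0

    def test_band_outside_nyquist_rejected(self):
        X = np.random.default_rng(0).normal(size=(4, 100))
        with pytest.raises(ValueError):
            tn.power_explained(X, X, rate_hz=3.0, band_hz=(0.16, 2.0))


class TestWeightStatistics:
    def test_hand_arithmetic_two_clusters(self):
        W = np.zeros((2, 4, 4))
        W[0, 0, :] = [1, -1, 2, -2]   # red |w| mean 1.5
        W[1, 0, :] = [3, 1, 1, 1]     # red |w| mean 1.5
        res = tn.weight_statistics(W)
        red = res["per_cone"].set_index("cone").loc["red", "mean_abs_w"]
        assert red == pytest.approx(1.5)

    def test_red_dominance_detected(self):
        rng = np.random.default_rng(0)
        W = rng.normal(0, 0.5, size=(30, 4, 4))
        W[:, 0, :] *= 3.0
        res = tn.weight_statistics(W)
        tests = res["pairwise_tests"]
        red_rows = tests[(tests.cone_a == "red") | (tests.cone_b == "red")]
        assert (red_rows.p_value < 0.001).all()
        per_cone = res["per_cone"].set_index("cone")["mean_abs_w"]
        assert per_cone["red"] == per_cone.max()

    def test_type_i_error_calibration(self):
        # identical distributions: ~5% rejections at alpha = 0.05
        rng = np.random.default_rng(1)
        n_sims, rejections = 400, 0
        for _ in range(n_sims):
            W = rng.normal(size=(10, 4, 4))
            res = tn.weight_statistics(W)
            p = res["pairwise_tests"].p_value.iloc[0]
            rejections += p < 0.05
        assert rejections / n_sims < 0.10

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            tn.weight_statistics(np.zeros((1, 4, 4)))


class TestWeightCorrelations:
    def test_perfect_correlation(self):
        rng = np.random.default_rng(0)
        W = np.zeros((10, 4, 4))
        x = rng.normal(size=10)
        W[:, 0, :] = x[:, None]
        W[:, 1, :] = x[:, None]
        W[:, 2, :] = rng.normal(size=(10, 4))
        W[:, 3, :] = rng.normal(size=(10, 4))
        res = tn.weight_correlations(W)
        rg = [r for r in res if r.pair == ("red", "green")][0]
        assert rg.rho == pytest.approx(1.0)

    def test_null_calibration(self):
        # independent draws, n = 29 clusters: |rho| < 0.5 in >= 95% of sims
        rng = np.random.default_rng(1)
        small = 0
        n_sims = 200
        for _ in range(n_sims):
            W = rng.normal(size=(29, 4, 4))
            res = tn.weight_correlations(W)
            rg = [r for r in res if r.pair == ("red", "green")][0]
            small += abs(rg.rho) < 0.5
        assert small >= 0.95 * n_sims

    def test_too_few_clusters_rejected(self):
        with pytest.raises(ValueError):
            tn.weight_correlations(np.zeros((3, 4, 4)))

    def test_correlated_population_recovery(self):
        # CI coverage harness: corr(red, blue) = 0.85 by construction
        rng = np.random.default_rng(2)
        hits = 0
        n_sims = 50
        for _ in range(n_sims):
            red = rng.normal(size=29)
            blue = 0.85 * red + np.sqrt(1 - 0.85**2) * rng.normal(size=29)
            W = np.zeros((29, 4, 4))
            W[:, 0, :] = red[:, None]
            W[:, 2, :] = blue[:, None]
            W[:, 1, :] = rng.normal(size=(29, 4))
            W[:, 3, :] = rng.normal(size=(29, 4))
            res = tn.weight_correlations(W)
            rb = [r for r in res if r.pair == ("red", "blue")][0]
            hits += rb.ci95[0] <= 0.85 <= rb.ci95[1]
        assert hits >= 0.9 * n_sims


class TestWeightIplHistogram:
    def test_no_violations_when_lamination_respected(self):
        rng = np.random.default_rng(0)
        n = 40
        depths = rng.uniform(0, 1, n)
        W = np.zeros((n, 4, 4))
        # light weights: negative (Off) above depth 0.5, positive below
        sign = np.where(depths >= 0.5, 1.0, -1.0)
        W[:, :, 0] = sign[:, None] * 0.6
        W[:, :, 1] = sign[:, None] * 0.6
        res = tn.weight_ipl_histogram(W, depths, combine="light")
        assert (res["violations"].violation_frac == 0).all()

    def test_violations_concentrate_where_constructed(self):
        rng = np.random.default_rng(1)
        n = 60
        depths = rng.uniform(0, 1, n)
        W = np.zeros((n, 4, 4))
        sign = np.where(depths >= 0.5, 1.0, -1.0)
        for c in range(4):
            W[:, c, 0] = sign * 0.6
            W[:, c, 1] = sign * 0.6
        # red light weights sign-flipped below depth 2/3 -> violations in
        # the lower third (On sublamina showing Off-signed red input)
        low = depths > 2 / 3
        W[low, 0, 0] *= -1
        W[low, 0, 1] *= -1
        res = tn.weight_ipl_histogram(W, depths, combine="light")
        v = res["violations"]
        red = v[v.cone == "red"].set_index("tercile").violation_frac
        assert red[2] > 0.9
        assert red[0] == 0.0 and red[1] == 0.0

    def test_near_zero_excluded_from_mass(self):
        rng = np.random.default_rng(2)
        n = 50
        depths = rng.uniform(0, 1, n)
        W = rng.normal(0, 1.0, size=(n, 4, 4))
        res = tn.weight_ipl_histogram(W, depths, combine="light")
        for c, cone in enumerate(("red", "green", "blue", "uv")):
            combined = W[:, c, 0] + W[:, c, 1]
            expected = (np.abs(combined) >= 0.5).sum()
            assert res["hists"][cone].sum() == pytest.approx(expected)
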