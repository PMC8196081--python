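import numpy as np
import pandas as pd
import pytest

from copydist import spatial
from copydist.spatial import (
    BinSpec,
    CohortPairs,
    aggregate_final_p,
    binned_means,
    excluded_schemes,
    fit_exponential,
    fit_linear,
    perm_p_fitted_grid,
    perm_p_near_bin,
    perm_p_slope,
    residual_adjust,
    shared_factor_test,
)


def toy_pairs(n=40, seed=0, factor_levels=("F1", "F2", "F3")):
    """Structureless pair container: random locations, elevations, factors."""
    rng = np.random.default_rng(seed)
    ids = [f"i{k:03d}" for k in range(n)]
    G = rng.uniform(0.4, 0.6, size=(n, n))
    G = (G + G.T) / 2
    np.fill_diagonal(G, 1.0)
    factors = pd.DataFrame(
        {f: rng.choice(factor_levels, size=n) for f in spatial.FACTORS}, index=ids
    )
    return CohortPairs(
        ids=ids,
        lat=rng.uniform(4, 14, size=n),
        lon=rng.uniform(34, 44, size=n),
        elev=rng.uniform(500, 3000, size=n),
        G=G,
        factors=factors,
    )


class TestFitExponential:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 1200, size=2000)
        G = 0.80 + 0.10 * np.exp(-0.01 * d)
        fit = fit_exponential(G, d)
        assert fit.params["alpha"] == pytest.approx(0.80, rel=1e-3)
        assert fit.params["beta"] == pytest.approx(0.10, rel=1e-3)
        assert fit.params["lambda"] == pytest.approx(0.01, rel=1e-3)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-9)

    def test_flat_data_degenerate_limit(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0, 1200, size=500)
        G = 0.8 + rng.normal(0, 0.02, size=500)
        fit = fit_exponential(G, d)
        assert fit.fitted.mean() == pytest.approx(G.mean(), abs=1e-3)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(0, 800, size=300)
        G = 0.7 + 0.1 * np.exp(-0.02 * d) + rng.normal(0, 0.01, size=300)
        fit1 = fit_exponential(G, d)
        order = rng.permutation(300)
        fit2 = fit_exponential(G[order], d[order])
        for key in ("alpha", "beta", "lambda"):
            assert fit1.params[key] == pytest.approx(fit2.params[key], rel=1e-6)

    def test_two_stage_variant_anchors_lambda_to_raw_scale(self):
        # with alpha=0, beta=1 data the two variants agree
        rng = np.random.default_rng(3)
        d = rng.uniform(0, 600, size=1000)
        G = np.exp(-0.005 * d)
        fit = fit_exponential(G, d, two_stage=True)
        assert fit.params["lambda"] == pytest.approx(0.005, rel=1e-3)

    def test_too_few_distances_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential(np.array([1.0, 2.0]), np.array([1.0, 1.0]))


class TestFitLinear:
    def test_exact_line_zero_residuals(self):
        x = np.linspace(0, 100, 50)
        G = 0.9 - 0.002 * x
        fit = fit_linear(G, x)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)
        assert fit.params["delta"] == pytest.approx(-0.002)

    def test_planted_slope_recovered_within_ci(self):
        rng = np.random.default_rng(4)
        h = rng.uniform(0, 2400, size=4000)
        G = 0.85 - 2e-5 * h + rng.normal(0, 0.02, size=4000)
        fit = fit_linear(G, h, elevation_cutoff=2500.0)
        from scipy import stats

        res = stats.linregress(h, G)
        assert res.slope - 1.96 * res.stderr <= -2e-5 <= res.slope + 1.96 * res.stderr
        assert fit.params["delta"] == pytest.approx(res.slope)

    def test_cutoff_excludes_exactly_pairs_at_or_above(self):
        x = np.array([100.0, 2499.9, 2500.0, 3000.0])
        G = np.array([0.9, 0.8, 0.7, 0.6])
        fit = fit_linear(G, x, elevation_cutoff=2500.0)
        assert fit.n_excluded == 2
        assert fit.n_pairs == 2

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            fit_linear(np.array([1.0, 2.0, 3.0]), np.array([5.0, 5.0, 5.0]))


class TestResidualAdjust:
    def test_no_confounding_limit(self):
        """With h independent of both d and G, adjusted analysis matches raw."""
        rng = np.random.default_rng(5)
        n = 3000
        d = rng.uniform(0, 1000, size=n)
        h = rng.uniform(0, 2000, size=n)
        G = 0.8 + 0.1 * np.exp(-0.01 * d) + rng.normal(0, 0.01, size=n)
        adj = residual_adjust(G, d, h, "geo_after_elev")
        fit_raw = fit_exponential(G, d)
        fit_adj = fit_exponential(adj["G"] + G.mean(), adj["x"])
        assert fit_adj.params["lambda"] == pytest.approx(fit_raw.params["lambda"], rel=0.1)

    def test_eq4_residuals_orthogonal_to_h(self):
        rng = np.random.default_rng(6)
        n = 500
        h = rng.uniform(0, 2000, size=n)
        d = 100 + 0.3 * h + rng.normal(0, 50, size=n)
        G = rng.uniform(0.5, 0.9, size=n)
        adj = residual_adjust(G, d, h, "geo_after_elev")
        kappa = adj["x"]
        # kappa was shifted to min 0; orthogonality holds for the unshifted residuals
        kappa_centered = kappa - kappa.mean()
        assert abs(np.dot(kappa_centered, h - h.mean())) / n < 1e-6 * np.std(h) * np.std(kappa)

    def test_kappa_shift_preserves_ordering_and_min_zero(self):
        rng = np.random.default_rng(7)
        n = 200
        h = rng.uniform(0, 2000, size=n)
        d = rng.uniform(0, 1000, size=n)
        G = rng.uniform(0.5, 0.9, size=n)
        adj = residual_adjust(G, d, h, "geo_after_elev")
        kappa = adj["x"]
        assert kappa.min() == pytest.approx(0.0, abs=1e-12)
        raw = d - (d - (adj["x"] - adj["x"].min())).mean()  # ordering check below
        order_shifted = np.argsort(kappa)
        fit_dh = np.polyfit(h, d, 1)
        resid = d - np.polyval(fit_dh, h)
        assert np.array_equal(order_shifted, np.argsort(resid))

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            residual_adjust(np.ones(3), np.ones(3), np.ones(3), "nope")


class TestBinnedMeans:
    def test_left_closed_right_open(self):
        G = np.array([1.0, 2.0, 3.0])
        x = np.array([0.0, 24.999, 25.0])
        out = binned_means(G, x, 25.0)
        assert list(out["count"]) == [2, 1]
        assert out["mean"].iloc[0] == pytest.approx(1.5)

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        G = rng.uniform(size=100)
        x = rng.uniform(0, 500, size=100)
        a = binned_means(G, x, 25.0)
        order = rng.permutation(100)
        b = binned_means(G[order], x[order], 25.0)
        pd.testing.assert_frame_equal(a, b)


class TestPermutationSchemes:
    def test_locations_permute_as_whole_records(self):
        """Permutation moves (lat, lon, elevation) together: pair_x under a
        permutation equals recomputing from the permuted records."""
        pairs = toy_pairs(n=12, seed=9)
        perm = np.random.default_rng(0).permutation(12)
        d_perm = pairs.pair_x("geo", perm)
        from copydist.io import haversine_km

        expected = np.array(
            [
                haversine_km(
                    pairs.lat[perm[i]], pairs.lon[perm[i]], pairs.lat[perm[j]], pairs.lon[perm[j]]
                )
                for i, j in zip(pairs.i_idx, pairs.j_idx)
            ]
        )
        np.testing.assert_allclose(d_perm, expected, atol=1e-9)
        h_perm = pairs.pair_x("elev", perm)
        np.testing.assert_allclose(
            h_perm, np.abs(pairs.elev[perm[pairs.i_idx]] - pairs.elev[perm[pairs.j_idx]])
        )

    def test_planted_decay_gives_small_near_bin_p(self, default_pairs):
        p = perm_p_near_bin(default_pairs, n_perm=200, seed=0)
        assert p <= 0.01

    def test_planted_decay_gives_small_slope_p(self, default_pairs):
        p = perm_p_slope(default_pairs, "geo", n_perm=200, seed=0)
        assert p <= 0.01

    def test_null_locations_give_moderate_p(self):
        pairs = toy_pairs(n=40, seed=10)
        p = perm_p_near_bin(pairs, n_perm=99, seed=1, threshold_km=500.0)
        assert 0.0 < p <= 1.0  # single-dataset sanity; calibration tested elsewhere

    def test_any_bin_rule_dominates_all_bin_rule(self):
        """Counting a permutation when ANY grid bin exceeds is more permissive
        than requiring ALL bins to exceed, on identical permutation draws."""
        pairs = toy_pairs(n=30, seed=11)
        grid = BinSpec("geo_km", 25.0, np.linspace(100, 900, 9))
        g = pairs.g
        obs = spatial._grid_fit(g, pairs.pair_x("geo"), np.ones(g.size, bool), grid.centers)
        rng = np.random.default_rng(2)
        any_hits = all_hits = 0
        for _ in range(200):
            perm = rng.permutation(30)
            fit_p = spatial._grid_fit(g, pairs.pair_x("geo", perm), np.ones(g.size, bool), grid.centers)
            any_hits += np.any(fit_p >= obs)
            all_hits += np.all(fit_p >= obs)
        assert all_hits <= any_hits

    def test_single_bin_grid_reduces_to_pointwise(self):
        pairs = toy_pairs(n=25, seed=12)
        grid = BinSpec("geo_km", 25.0, np.array([400.0]))
        p = perm_p_fitted_grid(pairs, "geo", grid=grid, n_perm=99, seed=3)
        # oracle: recompute with an explicit pointwise comparison
        g = pairs.g
        mask = np.ones(g.size, bool)
        a, b, _ = spatial._ols_on(pairs.pair_x("geo")[mask], g[mask])
        obs = a + b * 400.0
        rng = np.random.default_rng(3)
        exceed = 0
        for _ in range(99):
            perm = spatial._stratified_permutation(rng, 25, None)
            aa, bb, _ = spatial._ols_on(pairs.pair_x("geo", perm), g)
            exceed += (aa + bb * 400.0) >= obs
        assert p == pytest.approx(exceed / 99)

    def test_no_near_pair_rejected(self):
        pairs = toy_pairs(n=10, seed=13)
        with pytest.raises(ValueError):
            perm_p_near_bin(pairs, n_perm=10, seed=0, threshold_km=1e-6)


class TestSharedFactorTest:
    def test_fixing_tested_factor_rejected(self):
        pairs = toy_pairs(n=20, seed=14)
        with pytest.raises(ValueError, match="0 effective"):
            shared_factor_test(pairs, "geo", "group", fixed_factor="group", n_perm=10, seed=0)

    def test_planted_group_effect_detected(self, default_pairs):
        p = shared_factor_test(
            default_pairs, "geo", "group", scheme="near_bin", n_perm=200, seed=4
        )
        assert p <= 0.01

    def test_stratified_permutation_respects_strata(self):
        strata = np.array(["a"] * 5 + ["b"] * 5 + ["solo"])
        rng = np.random.default_rng(5)
        for _ in range(10):
            perm = spatial._stratified_permutation(rng, 11, strata)
            assert set(perm[:5]) == set(range(5))
            assert set(perm[5:10]) == set(range(5, 10))
            assert perm[10] == 10  # singleton stratum left unpermuted


class TestAggregateFinalP:
    def test_all_equal_schemes(self):
        table = {s: 0.001 for s in spatial.SCHEME_NAMES if s not in excluded_schemes("geo")}
        assert aggregate_final_p(table, "geo") == 0.001

    @pytest.mark.parametrize(
        "target,excluded",
        [
            ("geo", {"fix_group", "fix_first_language"}),
            ("elev", {"fix_group", "fix_first_language"}),
            ("group", {"fix_group", "fix_first_language"}),
            ("first_language", {"fix_group", "fix_first_language"}),
            ("language_group", {"fix_group", "fix_first_language", "fix_language_group"}),
            ("second_language", {"fix_second_language"}),
            ("religion", {"fix_religion"}),
        ],
    )
    def test_exclusion_table(self, target, excluded):
        assert excluded_schemes(target) == excluded

    def test_excluded_scheme_does_not_drive_max(self):
        table = {"free": 0.01, "fix_group": 0.9, "fix_religion": 0.02}
        assert aggregate_final_p(table, "geo") == 0.02

    def test_max_monotone(self):
        t1 = {"free": 0.01, "fix_religion": 0.02}
        t2 = dict(t1, fix_religion=0.5)
        assert aggregate_final_p(t2, "geo") >= aggregate_final_p(t1, "geo")

    def test_empty_scheme_set_rejected(self):
        with pytest.raises(ValueError):
            aggregate_final_p({"fix_group": 0.5}, "geo")
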