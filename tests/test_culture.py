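import numpy as np
import pandas as pd
import pytest

from copydist import culture, similarity, simulate
from copydist.culture import (
    adjusted_similarity,
    cultural_scores,
    intermix_flags,
    intermix_resample_p,
    mantel,
    partial_mantel,
    trait_category_test,
)


def trait_table(rows, groups, traits=None):
    traits = traits or [f"t{k}" for k in range(len(rows[0]))]
    return pd.DataFrame(rows, index=groups, columns=traits)


class TestCulturalScores:
    def test_all_shared_practices(self):
        tt = trait_table([["Y"] * 31, ["Y"] * 31], ["A", "B"])
        unweighted, weighted = cultural_scores(tt)
        assert unweighted.loc["A", "B"] == 31
        # every trait practiced by H=2 groups: weighted contribution 1/2 each
        assert weighted.loc["A", "B"] == pytest.approx(31 / 2)

    def test_one_over_H_rule(self):
        """A trait practiced by H=4 of 5 groups contributes 0.25 to each of
        its C(4,2)=6 pairs, 1.5 in total."""
        tt = trait_table([["Y"], ["Y"], ["Y"], ["Y"], ["U"]], list("ABCDE"))
        _, weighted = cultural_scores(tt)
        off = weighted.to_numpy()[np.triu_indices(5, 1)]
        assert off.sum() == pytest.approx(1.5)
        assert weighted.loc["A", "B"] == pytest.approx(0.25)
        assert weighted.loc["A", "E"] == 0.0

    def test_all_unreported_scores_zero(self):
        tt = trait_table([["U", "U"], ["U", "U"]], ["A", "B"])
        unweighted, weighted = cultural_scores(tt)
        assert unweighted.loc["A", "B"] == 0
        assert weighted.loc["A", "B"] == 0

    def test_weighted_conservation_per_trait(self):
        """Summed over all pairs, a trait with H practicers contributes
        exactly C(H,2)/H to the weighted total."""
        rng = np.random.default_rng(0)
        states = rng.choice(["Y", "N", "U"], size=(8, 5), p=[0.4, 0.3, 0.3])
        tt = trait_table(states.tolist(), [f"G{k}" for k in range(8)])
        _, weighted = cultural_scores(tt)
        expected = 0.0
        for t in tt.columns:
            for state in ("Y", "N"):
                H = int((tt[t] == state).sum())
                if H >= 2:
                    expected += H * (H - 1) / 2 / H
        assert weighted.to_numpy()[np.triu_indices(8, 1)].sum() == pytest.approx(expected)

    def test_symmetry_and_trait_order_invariance(self):
        rng = np.random.default_rng(1)
        states = rng.choice(["Y", "N", "U"], size=(6, 7))
        tt = trait_table(states.tolist(), [f"G{k}" for k in range(6)])
        u1, w1 = cultural_scores(tt)
        assert np.allclose(u1, u1.T) and np.allclose(w1, w1.T)
        shuffled = tt[list(rng.permutation(tt.columns))]
        u2, w2 = cultural_scores(shuffled)
        pd.testing.assert_frame_equal(u1, u2)
        pd.testing.assert_frame_equal(w1, w2)

    def test_unknown_state_rejected(self):
        tt = trait_table([["Y", "Q"], ["N", "U"]], ["A", "B"])
        with pytest.raises(ValueError, match="invalid state"):
            cultural_scores(tt)


def random_symmetric(rng, n, low=0.0, high=1.0):
    M = rng.uniform(low, high, size=(n, n))
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0.0)
    return M


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(2)
        M = random_symmetric(rng, 6)
        r, p = mantel(M, M, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_matches_naive_double_loop_exactly(self):
        """Same permutation stream through both implementations: identical r
        and p on 6x6 inputs."""
        rng = np.random.default_rng(3)
        A = random_symmetric(rng, 6)
        B = A * 0.5 + random_symmetric(rng, 6) * 0.5
        perms = [np.random.default_rng(k).permutation(6) for k in range(200)]
        r, p = mantel(A, B, permutations=perms)

        # naive oracle: double loop over off-diagonal entries
        def offdiag_corr(X, Y):
            xs, ys = [], []
            for i in range(6):
                for j in range(i + 1, 6):
                    xs.append(X[i][j])
                    ys.append(Y[i][j])
            return np.corrcoef(xs, ys)[0, 1]

        r_oracle = offdiag_corr(A, B)
        exceed = 0
        for perm in perms:
            Bp = B[np.ix_(perm, perm)]
            exceed += offdiag_corr(A, Bp) >= r_oracle
        assert r == pytest.approx(r_oracle, abs=1e-12)
        assert p == pytest.approx(exceed / 200)

    def test_agrees_with_skbio_statistic(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(4)
        A = random_symmetric(rng, 8)
        B = random_symmetric(rng, 8)
        r, _ = mantel(A, B, n_perm=10, seed=0)
        r_ref, _, _ = skbio_stats.mantel(
            skbio_stats.DistanceMatrix(A), skbio_stats.DistanceMatrix(B), permutations=0
        )
        assert r == pytest.approx(r_ref, abs=1e-10)

    def test_label_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        A = random_symmetric(rng, 7)
        B = random_symmetric(rng, 7)
        perm = rng.permutation(7)
        r1, p1 = mantel(A, B, n_perm=200, seed=6)
        r2, p2 = mantel(A[np.ix_(perm, perm)], B[np.ix_(perm, perm)], n_perm=200, seed=6)
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert abs(p1 - p2) < 0.1  # same distribution; draws differ by relabeling

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mantel(np.zeros((3, 3)), np.zeros((4, 4)), n_perm=5)


class TestPartialMantel:
    def test_conditioning_removes_shared_driver(self):
        """M1 and M2 correlated only through M3: partial r near 0, plain r large."""
        rng = np.random.default_rng(6)
        C = random_symmetric(rng, 12)
        A = 0.9 * C + 0.1 * random_symmetric(rng, 12)
        B = 0.9 * C + 0.1 * random_symmetric(rng, 12)
        r_plain, _ = mantel(A, B, n_perm=10, seed=0)
        r_part, _ = partial_mantel(A, B, C, n_perm=10, seed=0)
        assert r_plain > 0.8
        assert abs(r_part) < 0.4

    def test_direct_association_survives_conditioning(self):
        rng = np.random.default_rng(7)
        C = random_symmetric(rng, 10)
        A = random_symmetric(rng, 10)
        B = 0.8 * A + 0.2 * random_symmetric(rng, 10)
        r_part, p = partial_mantel(A, B, C, n_perm=500, seed=1)
        assert r_part > 0.5
        assert p < 0.05


class TestTraitCategoryTest:
    @staticmethod
    def group_sim_from_cohort(coh):
        sim = similarity.similarity_matrix(coh.internal)
        groups = sorted(coh.metadata["group"].unique())
        labels = coh.metadata["group"]
        vals = np.ones((len(groups), len(groups)))
        for i, A in enumerate(groups):
            for j, B in enumerate(groups):
                if i < j:
                    v = similarity.group_similarity(sim, labels, A, B)
                    vals[i, j] = vals[j, i] = v
        return pd.DataFrame(vals, index=groups, columns=groups)

    def test_planted_trait_clique_detected(self):
        coh = simulate.simulate_cohort(
            simulate.trait_scenario(seed=8, n_groups=12, n_per_group=6,
                                    clique=("G02", "G05", "G08", "G11"))
        )
        G = self.group_sim_from_cohort(coh)
        obs, p = trait_category_test(
            coh.traits, G, "shared_practice", "Y", "U", n_perm=2000, seed=9
        )
        assert obs > 0
        assert p <= 0.01

    def test_identical_categories_zero_statistic(self):
        rng = np.random.default_rng(10)
        groups = [f"G{k}" for k in range(6)]
        G = pd.DataFrame(random_symmetric(rng, 6) + np.eye(6), index=groups, columns=groups)
        traits = pd.DataFrame({"t": ["Y", "Y", "Y", "U", "U", "U"]}, index=groups)
        obs, _ = trait_category_test(traits, G, "t", "Y", "Y", n_perm=50, seed=0)
        assert obs == pytest.approx(0.0)

    def test_small_category_skipped(self):
        groups = ["A", "B", "C"]
        G = pd.DataFrame(np.eye(3), index=groups, columns=groups)
        traits = pd.DataFrame({"t": ["Y", "N", "N"]}, index=groups)
        assert trait_category_test(traits, G, "t", "Y", "N", n_perm=10, seed=0) is None


class TestAdjustedSimilarity:
    @staticmethod
    def branch_map(coh):
        return coh.metadata.groupby("group")["language_group"].first()

    def test_null_cohort_deviations_centered(self, default_cohort, default_sim_internal):
        gp = adjusted_similarity(
            default_sim_internal, default_cohort.metadata, self.branch_map(default_cohort)
        )
        assert abs(gp["deviation"].mean()) < 0.01
        # deviations within each branch pairing sum to ~0 by construction
        sums = gp.groupby("branch_pair")["deviation"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 0.0, atol=1e-9)

    def test_planted_cross_branch_similarity_positive_deviation(self):
        coh = simulate.simulate_cohort(
            simulate.trait_scenario(seed=11, n_groups=12, n_per_group=6,
                                    clique=("G01", "G12"), trait_boost=0.06)
        )
        sim = similarity.similarity_matrix(coh.internal)
        branch = self.branch_map(coh)
        if branch["G01"] == branch["G12"]:
            pytest.skip("planted pair landed in one branch for this layout")
        gp = adjusted_similarity(sim, coh.metadata, branch)
        row = gp[(gp.group_a == "G01") & (gp.group_b == "G12")]
        assert row["deviation"].iloc[0] > 0.02

    def test_missing_branch_rejected(self, default_cohort, default_sim_internal):
        branch = self.branch_map(default_cohort).copy()
        branch[:] = pd.NA
        with pytest.raises(ValueError):
            adjusted_similarity(default_sim_internal, default_cohort.metadata, branch)


def segment_frame(rows):
    return pd.DataFrame(rows, columns=["iid1", "iid2", "total_cM", "n_segments"])


class TestIntermixFlags:
    def test_infinite_threshold_never_flags(self, default_cohort):
        flags = intermix_flags(
            default_cohort.segments, default_cohort.metadata["group"], threshold_cM=np.inf
        )
        assert not flags["flagged"].any()

    def test_planted_admixture_pair_flagged(self):
        coh = simulate.simulate_cohort(
            simulate.admixture_scenario(seed=12, n_groups=10, n_per_group=6)
        )
        flags = intermix_flags(coh.segments, coh.metadata["group"])
        row = flags[(flags.group_a == "G01") & (flags.group_b == "G05")]
        assert bool(row["flagged"].iloc[0])

    def test_iid_segments_flag_rate_near_null(self):
        """With iid exponential segment lengths the per-pair flag rate matches
        the tail mass beyond median + 2.5 cM."""
        rng = np.random.default_rng(13)
        groups = {f"i{k}": f"G{k % 10}" for k in range(60)}
        rows = []
        ids = list(groups)
        for a in range(60):
            for b in range(a + 1, 60):
                if groups[ids[a]] != groups[ids[b]]:
                    n = 40
                    rows.append((ids[a], ids[b], rng.gamma(n, 0.7), n))
        seg = segment_frame(rows)
        flags = intermix_flags(seg, pd.Series(groups), threshold_cM=2.5)
        # mean segment ~ Gamma(40, 0.7)/40: sd ~ 0.11, so +2.5 cM is far out
        assert flags["flagged"].mean() < 0.02

    def test_resample_p_small_for_planted_pair(self):
        coh = simulate.simulate_cohort(
            simulate.admixture_scenario(seed=14, n_groups=12, n_per_group=5)
        )
        flags = intermix_flags(coh.segments, coh.metadata["group"])
        obs, p = intermix_resample_p(flags, ["G01", "G05"], n_resamples=2000, seed=0)
        assert obs >= 1
        assert p <= 0.05

    def test_positive_segment_count_required(self):
        seg = segment_frame([("a", "b", 1.0, 0)])
        with pytest.raises(ValueError):
            intermix_flags(seg, {"a": "A", "b": "B"})
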