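import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from repliscope import (ReplicateDesign, anova_tukey, hellinger,
                        linear_regression, pcoa, procrustes_m2,
                        procrustes_test, replicate_split_resample, spearman,
                        within_between_test)


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, [10, 8, 6, 4, 2])[0] == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base, _ = spearman(x, y)
        assert spearman(np.exp(x), y)[0] == pytest.approx(base)
        assert spearman(x, y ** 3)[0] == pytest.approx(base)


class TestReplicateSplitResample:
    def test_identical_replicates_give_rho_one(self):
        vals = {f"S{i}": {"a": float(i), "b": float(i), "c": float(i)}
                for i in range(1, 8)}
        res = replicate_split_resample(vals, repeats=50, seed=0)
        assert np.allclose(res.rho_values, 1.0)
        assert res.all_significant()

    def test_pure_noise_mean_rho_near_zero(self):
        rng = np.random.default_rng(1)
        vals = {f"S{i}": {"a": rng.normal(), "b": rng.normal()}
                for i in range(30)}
        res = replicate_split_resample(vals, repeats=400, seed=2)
        se = res.rho_values.std(ddof=1) / np.sqrt(res.rho_values.size)
        # repeats are correlated draws of the same data; allow wide slack
        assert abs(res.rho_values.mean()) < max(3 * se, 0.25)

    def test_two_replicate_splits_match_exhaustive_enumeration(self):
        # a 2-replicate design admits exactly 2^n_samples distinct splits;
        # every resampled rho must appear in the brute-force enumeration
        rng = np.random.default_rng(3)
        data = {f"S{i}": {"a": float(rng.normal()), "b": float(rng.normal())}
                for i in range(8)}
        keys = list(data)
        exhaustive = set()
        for bits in itertools.product([0, 1], repeat=len(keys)):
            a = [list(data[k].values())[b] for k, b in zip(keys, bits)]
            b = [list(data[k].values())[1 - bb] for k, bb in zip(keys, bits)]
            exhaustive.add(round(spearman(a, b)[0], 9))
        res = replicate_split_resample(data, repeats=200, seed=4)
        assert res.rho_values.size == 200
        for rho in res.rho_values:
            assert round(float(rho), 9) in exhaustive

    def test_summary_recomputable(self):
        vals = {f"S{i}": {"a": float(i), "b": float(i + (-1) ** i)}
                for i in range(10)}
        res = replicate_split_resample(vals, repeats=99, seed=5)
        assert res.summary["mean"] == pytest.approx(res.rho_values.mean())
        assert res.summary["sd"] == pytest.approx(res.rho_values.std(ddof=1))

    def test_sample_with_single_replicate_errors(self):
        with pytest.raises(ValueError):
            replicate_split_resample({"S1": {"a": 1.0},
                                      "S2": {"a": 1.0, "b": 2.0},
                                      "S3": {"a": 1.0, "b": 2.0}})


class TestWithinBetween:
    def _design_and_matrix(self, within_vals, between_vals, samples="ABC"):
        # len(samples) samples x 2 replicates
        import pandas as pd

        ids = [f"{s}{r}" for s in samples for r in "12"]
        design = ReplicateDesign({s: [f"{s}1", f"{s}2"] for s in samples})
        m = len(ids)
        D = np.zeros((m, m))
        wit = iter(within_vals)
        bet = iter(between_vals)
        for i, j in itertools.combinations(range(m), 2):
            same = ids[i][0] == ids[j][0]
            D[i, j] = D[j, i] = next(wit) if same else next(bet)
        return pd.DataFrame(D, index=ids, columns=ids), design

    def test_perfect_separation_minimal_p(self):
        D, design = self._design_and_matrix([0, 0, 0], np.linspace(.5, .9, 12))
        stat, p, means = within_between_test(D, design)
        assert means["within"] < means["between"]
        # attainable minimum of one-sided exact MWU with 3 vs 12
        assert p == pytest.approx(1 / 455, rel=1e-6)

    def test_permutation_method_agrees_directionally(self):
        D, design = self._design_and_matrix([.1, .12, .09, .11, .1],
                                            np.linspace(.5, .9, 40),
                                            samples="ABCDE")
        _, p_mwu, _ = within_between_test(D, design)
        _, p_perm, _ = within_between_test(D, design, method="permutation",
                                           permutations=499, seed=0)
        assert p_mwu < 0.05 and p_perm < 0.05

    def test_empty_group_errors(self):
        import pandas as pd

        ids = ["A1", "A2"]
        D = pd.DataFrame([[0, .5], [.5, 0]], index=ids, columns=ids)
        design = ReplicateDesign({"A": ids})
        with pytest.raises(ValueError):
            within_between_test(D, design)


class TestLinearRegression:
    def test_exact_line(self):
        x = np.array([0., 1, 2, 3])
        slope, intercept, r2, adj = linear_regression(x, 2 * x + 1)
        assert (slope, intercept) == pytest.approx((2.0, 1.0))
        assert r2 == pytest.approx(1.0)
        assert adj == pytest.approx(1.0)

    def test_hand_ols_algebra(self):
        slope, intercept, r2, adj = linear_regression([1, 2, 3], [1, 2, 4])
        assert slope == pytest.approx(1.5)
        assert intercept == pytest.approx(-2 / 3)
        assert r2 == pytest.approx(27 / 28)

    def test_noise_adjusted_below_r2(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        _, _, r2, adj = linear_regression(x, y)
        assert r2 < 0.05
        assert adj <= r2

    def test_constant_x_errors(self):
        with pytest.raises(ValueError):
            linear_regression([1, 1, 1], [1, 2, 3])


class TestHellinger:
    def test_rows_unit_squared_sum(self):
        H = hellinger(np.array([[1, 1, 1, 1], [9, 16, 0, 0]]))
        assert np.allclose((H ** 2).sum(axis=1), 1.0)
        assert H[0, 0] == pytest.approx(0.5)
        assert H[1, :2] == pytest.approx([0.6, 0.8])

    def test_single_feature_row(self):
        assert hellinger(np.array([[5]]))[0, 0] == pytest.approx(1.0)

    def test_zero_row_errors(self):
        with pytest.raises(ValueError):
            hellinger(np.array([[0, 0]]))


class TestPcoa:
    def test_line_points_isometry(self):
        pts = np.array([[0.0], [3.0], [7.0]])
        D = squareform(pdist(pts))
        coords, eigvals = pcoa(D)
        got = squareform(pdist(coords[:, :1]))
        assert np.allclose(got, D, atol=1e-9)

    def test_all_zero_distances(self):
        coords, eigvals = pcoa(np.zeros((4, 4)))
        assert coords.shape[1] == 0 or np.allclose(coords, 0)

    def test_plane_points_round_trip(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 2))
        D = squareform(pdist(pts))
        coords, _ = pcoa(D, k=2)
        assert np.allclose(squareform(pdist(coords)), D, atol=1e-9)

    def test_asymmetric_input_errors(self):
        D = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            pcoa(D)

    def test_matches_skbio_ordination(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        from skbio import DistanceMatrix

        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 3))
        D = squareform(pdist(pts))
        ours, eig = pcoa(D, k=3)
        theirs = skbio_pcoa(DistanceMatrix(D), number_of_dimensions=3)
        ref = theirs.samples.to_numpy()
        for ax in range(3):  # eigenvectors defined up to sign
            assert (np.allclose(ours[:, ax], ref[:, ax], atol=1e-8)
                    or np.allclose(ours[:, ax], -ref[:, ax], atol=1e-8))


class TestProcrustes:
    def test_identity_gives_zero_m2(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(12, 2))
        assert procrustes_m2(X, X) < 1e-14

    def test_similarity_transform_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(15, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        Y = 3.7 * X @ R + np.array([5.0, -2.0])
        assert procrustes_m2(X, Y) < 1e-10
        assert procrustes_m2(Y, X) < 1e-10

    def test_matches_scipy_disparity(self):
        from scipy.spatial import procrustes as scipy_procrustes

        rng = np.random.default_rng(12)
        X = rng.normal(size=(9, 2))
        Y = rng.normal(size=(9, 2))
        _, _, disparity = scipy_procrustes(X, Y)
        assert procrustes_m2(X, Y) == pytest.approx(disparity, rel=1e-9)

    def test_perfect_fit_p_at_minimum(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(10, 2))
        res = procrustes_test(X, X.copy(), permutations=999, seed=0)
        assert res.m2 < 1e-10
        assert res.p_value == pytest.approx(0.001)

    def test_independent_configurations_rarely_significant(self):
        rng = np.random.default_rng(14)
        hits = 0
        trials = 100
        for _ in range(trials):
            X = rng.normal(size=(10, 2))
            Y = rng.normal(size=(10, 2))
            res = procrustes_test(X, Y, permutations=99,
                                  seed=int(rng.integers(2 ** 31)))
            if res.p_value <= 0.05:
                hits += 1
        assert hits <= trials * 0.10  # ~5% expected under the null

    def test_mismatched_rows_error(self):
        with pytest.raises(ValueError):
            procrustes_m2(np.zeros((4, 2)), np.zeros((5, 2)))


class TestAnovaTukey:
    def test_textbook_f_value(self):
        F, p, _ = anova_tukey({"g1": [1, 2, 3], "g2": [101, 102, 103]})
        assert F == pytest.approx(15000.0)
        assert p < 1e-6

    def test_tukey_adjustment_monotone(self):
        rng = np.random.default_rng(15)
        groups = {g: rng.normal(size=8).tolist() for g in "abc"}
        _, _, pairwise = anova_tukey(groups)
        from scipy import stats

        for (g1, g2), adj in pairwise.items():
            raw = stats.ttest_ind(groups[g1], groups[g2]).pvalue
            assert adj >= raw - 1e-9

    def test_degenerate_variance_errors(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": [1, 1], "b": [1, 1]})
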