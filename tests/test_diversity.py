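import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repliscope import (FeatureTable, ReplicateDesign, bray_curtis,
                        alpha_summary, dissimilarity_matrix,
                        dissimilarity_summary, prr, richness, shannon)

counts_vectors = st.lists(st.integers(min_value=0, max_value=200),
                          min_size=2, max_size=10)


class TestRichness:
    @pytest.mark.parametrize("vec,expected", [
        ((0, 0, 0), 0),
        ((5, 0, 1, 2), 3),
        ((1,), 1),
    ])
    def test_counts_positive_entries(self, vec, expected):
        assert richness(vec) == expected


class TestShannon:
    def test_single_feature_zero(self):
        assert shannon([42]) == 0.0

    def test_equal_abundances_max_entropy(self):
        assert shannon([7, 7, 7, 7]) == pytest.approx(math.log(4))

    def test_direct_evaluation(self):
        expected = -(0.5 * math.log(0.5) + 0.3 * math.log(0.3)
                     + 0.2 * math.log(0.2))
        assert shannon([50, 30, 20]) == pytest.approx(expected)
        assert shannon([50, 30, 20]) == pytest.approx(1.029653, abs=1e-6)

    def test_log_base_option(self):
        assert shannon([1, 1], base=2) == pytest.approx(1.0)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    def test_matches_skbio(self):
        import skbio.diversity.alpha as alpha

        vec = [50, 30, 12, 5, 1, 1]
        assert shannon(vec) == pytest.approx(float(alpha.shannon(vec, base=math.e)))

    @settings(max_examples=50, deadline=None)
    @given(counts_vectors.filter(lambda v: sum(v) > 0),
           st.integers(min_value=2, max_value=7))
    def test_invariant_under_count_scaling(self, vec, factor):
        scaled = [c * factor for c in vec]
        assert shannon(scaled) == pytest.approx(shannon(vec))


class TestPRR:
    @pytest.mark.parametrize("vals,expected", [
        ((10, 10, 10), 0.0),
        ((10, 20), 100 * 10 / 15),
        ((5, 10, 15), 100.0),
    ])
    def test_range_over_mean(self, vals, expected):
        assert prr(vals) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ValueError):
            prr([5])
        with pytest.raises(ValueError):
            prr([0, 0])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.1, max_value=1e4), min_size=2,
                    max_size=8),
           st.floats(min_value=0.01, max_value=100))
    def test_scale_invariance(self, vals, c):
        assert prr([c * v for v in vals]) == pytest.approx(prr(vals),
                                                           rel=1e-9)


class TestBrayCurtis:
    def test_identical_vectors_zero(self):
        assert bray_curtis([3, 1, 4], [3, 1, 4]) == 0.0

    @pytest.mark.parametrize("mode", ["occurrence", "abundance"])
    def test_disjoint_supports_one(self, mode):
        assert bray_curtis([5, 0, 2, 0], [0, 1, 0, 9], mode=mode) == \
            pytest.approx(1.0)

    def test_log1p_hand_values(self):
        e1 = math.e - 1
        assert bray_curtis([e1, 0], [0, e1]) == pytest.approx(1.0)
        assert bray_curtis([e1, e1], [e1, 0]) == pytest.approx(1 / 3)

    def test_occurrence_equals_sorensen_contingency(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            x = rng.integers(0, 5, size=12)
            y = rng.integers(0, 5, size=12)
            if x.sum() == 0 or y.sum() == 0:
                continue
            a = int(((x > 0) & (y > 0)).sum())
            b = int(((x > 0) & (y == 0)).sum())
            c = int(((x == 0) & (y > 0)).sum())
            expected = 1 - 2 * a / (2 * a + b + c)
            assert bray_curtis(x, y, mode="occurrence") == \
                pytest.approx(expected)

    def test_abundance_matches_scipy_on_transformed(self):
        from scipy.spatial.distance import braycurtis

        rng = np.random.default_rng(5)
        x = rng.integers(0, 50, size=20) + 1
        y = rng.integers(0, 50, size=20) + 1
        assert bray_curtis(x, y) == pytest.approx(
            float(braycurtis(np.log1p(x), np.log1p(y))))

    @settings(max_examples=50, deadline=None)
    @given(counts_vectors, counts_vectors)
    def test_symmetric_and_bounded(self, x, y):
        n = max(len(x), len(y))
        x = (x + [0] * n)[:n]
        y = (y + [0] * n)[:n]
        if sum(x) == 0 or sum(y) == 0:
            return
        d = bray_curtis(x, y)
        assert 0 <= d <= 1
        assert d == pytest.approx(bray_curtis(y, x))

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [1, 2])


class TestDissimilaritySummary:
    def test_identical_replicates_all_zero(self, identical_replicates):
        table, design = identical_replicates
        bs = dissimilarity_summary(table, design, warn_unequal_totals=False)
        assert bs.stats["mean"] == pytest.approx(0.0)
        assert (bs.within_sample["mean_dissimilarity"] == 0).all()
        # degenerate PRR flagged, reported as 0
        assert (bs.within_sample["prr"] == 0).all()
        assert bs.within_sample["prr_degenerate"].all()

    def test_pairwise_matrix_invariants(self, small_study):
        table, design, _ = small_study
        D = dissimilarity_matrix(table)
        V = D.to_numpy()
        assert np.allclose(V, V.T)
        assert np.allclose(np.diag(V), 0)
        assert (V >= 0).all() and (V <= 1).all()

    def test_two_replicate_prr_undefined(self, tiny_table, tiny_design):
        bs = dissimilarity_summary(tiny_table, tiny_design,
                                   warn_unequal_totals=False)
        assert bs.within_sample["prr"].isna().all()
        assert bs.prr_m is None

    def test_within_below_all_pairs_on_synthetic(self, small_study):
        table, design, _ = small_study
        for mode in ("occurrence", "abundance"):
            bs = dissimilarity_summary(table, design, mode=mode,
                                       warn_unequal_totals=False)
            assert bs.stats["mean"] < bs.all_m
            assert bs.between_m > bs.stats["mean"]

    def test_warns_on_unequal_totals(self, tiny_design):
        t = FeatureTable(["S1a", "S1b", "S2a", "S2b"], ["f1", "f2"],
                         np.array([[5, 5], [9, 9], [4, 4], [7, 7]]))
        with pytest.warns(UserWarning, match="rarefy"):
            dissimilarity_summary(t, tiny_design)


class TestAlphaSummary:
    def test_per_sample_prr_values(self, identical_replicates):
        table, design = identical_replicates
        al = alpha_summary(table, design)
        assert (al.per_sample_prr["prr_richness"] == 0).all()
        assert (al.per_sample_prr["prr_shannon"] == 0).all()

    def test_richness_prr_hand_case(self):
        t = FeatureTable(["a", "b"], ["f1", "f2", "f3"],
                         np.array([[1, 1, 1], [4, 5, 0]]))
        d = ReplicateDesign({"S": ["a", "b"]})
        al = alpha_summary(t, d)
        # richness 3 vs 2 -> PRR = 1/2.5*100 = 40
        assert al.per_sample_prr.loc["S", "prr_richness"] == pytest.approx(40)
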