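import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from coexhub import (
    ExpressionMatrix,
    correlation_matrix,
    drop_silent_genes,
    normalize,
    quantile_normalize,
    top_correlates,
)


def raw(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), stage="raw")


def qn_stage(values, genes=None):
    m = raw(values, genes)
    return ExpressionMatrix(m.data, stage="quantile_normalized")


def naive_pearson(x, y):
    """Two-pass textbook Pearson correlation (independent oracle)."""
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


class TestDropSilentGenes:
    def test_all_zero_rows_removed_others_kept_in_order(self):
        m = raw([[0, 0, 0], [0, 0, 1], [2, 0, 0]])
        out = drop_silent_genes(m)
        assert out.gene_ids == ["G1", "G2"]

    def test_no_silent_genes_is_identity(self):
        m = raw([[1, 2], [3, 4]])
        assert drop_silent_genes(m) is m

    def test_entirely_silent_matrix_rejected(self):
        with pytest.raises(ValueError, match="all genes are silent"):
            drop_silent_genes(raw([[0, 0], [0, 0]]))


class TestQuantileNormalize:
    def test_hand_example_two_samples(self):
        # Sorted means: ((1+4)/2, (2+5)/2, (3+6)/2) = (2.5, 3.5, 4.5).
        out = quantile_normalize(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        np.testing.assert_allclose(out, [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_identical_samples_unchanged(self):
        x = np.array([[3.0, 3.0], [1.0, 1.0], [7.0, 7.0]])
        np.testing.assert_allclose(quantile_normalize(x), x)

    def test_matches_limma_reference_with_ties(self):
        # Frozen oracle: limma::normalizeQuantiles(ties=TRUE) on this matrix
        # agrees with these values to < 1e-10.
        x = np.array(
            [
                [6.251, 8.972, 7.757],
                [2.252, 3.002, 8.736],
                [0.053, 8.212, 7.971],
                [4.679, 3.030, 2.784],
                [2.549, 4.451, 5.045],
                [5.535, 9.955, 7.927],
            ]
        )
        expected = np.array(
            [
                [8.314, 7.49266667, 4.919],
                [3.44233333, 1.94633333, 8.314],
                [1.94633333, 6.93933333, 7.49266667],
                [6.93933333, 3.44233333, 1.94633333],
                [4.919, 4.919, 3.44233333],
                [7.49266667, 8.314, 6.93933333],
            ]
        )
        np.testing.assert_allclose(quantile_normalize(x), expected, atol=1e-8)

    def test_sorted_columns_identical_after_normalization(self):
        rng = np.random.default_rng(5)
        out = quantile_normalize(rng.uniform(0, 100, (100, 20)))
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_normalize_requires_two_samples(self):
        with pytest.raises(ValueError, match="at least 2 samples"):
            normalize(raw([[1.0], [2.0]]))


class TestCorrelationMatrix:
    def test_perfect_positive_and_negative_pairs(self):
        m = qn_stage([[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]])
        c = correlation_matrix(m, theta=0.3)
        assert c.r("G0", "G1") == pytest.approx(1.0)
        assert c.r("G0", "G2") == pytest.approx(-1.0)

    def test_below_threshold_pair_is_exactly_zero(self):
        # Both genes expressed in 1/4 samples: unfiltered r would be 1.
        m = qn_stage([[0, 0, 0, 5], [0, 0, 0, 7], [1, 2, 3, 4]])
        c = correlation_matrix(m, theta=0.3)
        assert c.r("G0", "G1") == 0.0
        # G2 passes prevalence, so its pairs with G0/G1 are computed.
        assert c.r("G0", "G2") != 0.0

    def test_matches_naive_two_pass_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.uniform(0.1, 50, (50, 30))  # strictly positive: no filtering
        c = correlation_matrix(qn_stage(X), theta=0.3)
        for i in range(0, 50, 7):
            for j in range(0, 50, 11):
                expected = 1.0 if i == j else naive_pearson(X[i], X[j])
                assert abs(c.data.iat[i, j] - expected) < 1e-10

    def test_zero_variance_row_correlates_zero_everywhere(self):
        m = qn_stage([[5, 5, 5, 5], [1, 2, 3, 4]])
        c = correlation_matrix(m, theta=0.3)
        assert (c.data.loc["G0"] == 0).all()

    def test_theta_outside_unit_interval_rejected(self):
        m = qn_stage([[1, 2], [3, 4]])
        for theta in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="prevalence threshold"):
                correlation_matrix(m, theta=theta)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        arrays(np.float64, (12, 8), elements=st.floats(0, 10, allow_nan=False)),
        st.floats(0.05, 1.0),
    )
    def test_symmetry_bounds_and_filter_monotonicity(self, X, theta):
        c_lo = correlation_matrix(qn_stage(X), theta=min(theta, 0.3))
        c_hi = correlation_matrix(qn_stage(X), theta=max(theta, 0.3))
        for c in (c_lo, c_hi):
            v = c.data.to_numpy()
            np.testing.assert_allclose(v, v.T)
            assert (v >= -1 - 1e-12).all() and (v <= 1 + 1e-12).all()
        # Raising theta only zeroes entries, never changes a surviving value.
        lo, hi = c_lo.data.to_numpy(), c_hi.data.to_numpy()
        surviving = hi != 0
        np.testing.assert_allclose(hi[surviving], lo[surviving])


class TestTopCorrelates:
    corr_pairs = {("A", "B"): 0.9, ("A", "C"): 0.5, ("A", "D"): -0.7}

    def make(self):
        from conftest import make_corr

        return make_corr(self.corr_pairs)

    def test_positive_and_negative_directions(self):
        c = self.make()
        top, _ = top_correlates(c, "A", 1, "positive")
        assert top == [("B", 0.9)]
        bottom, _ = top_correlates(c, "A", 1, "negative")
        assert bottom == [("D", -0.7)]

    def test_equal_r_breaks_ties_lexicographically(self):
        from conftest import make_corr

        c = make_corr({("A", "C"): 0.5, ("A", "B"): 0.5})
        top, _ = top_correlates(c, "A", 1, "positive")
        assert top == [("B", 0.5)]

    def test_k_beyond_available_returns_all_with_flag(self):
        c = self.make()
        got, truncated = top_correlates(c, "A", 10, "positive")
        assert len(got) == 3 and truncated

    def test_restrict_limits_candidates(self):
        c = self.make()
        got, _ = top_correlates(c, "A", 2, "positive", restrict={"C", "D"})
        assert got[0][0] == "C"

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            top_correlates(self.make(), "Z", 1)
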