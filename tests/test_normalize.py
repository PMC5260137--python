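import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gfscore import (
    DegenerateSampleError,
    ExpressionMatrix,
    GfsParams,
    ParameterError,
    get_transform,
    gfs_transform,
    mean_scale,
    median_scale,
    quantile_normalize,
    quantile_rank,
    rank_within_sample,
    zscore_normalize,
)
from .conftest import random_matrix


def brute_force_ranks(values):
    """O(G^2) pairwise-comparison fractional ranks (mean tie handling)."""
    values = np.asarray(values, dtype=float)
    out = np.empty(len(values))
    for i, v in enumerate(values):
        below = np.sum(values < v)
        ties = np.sum(values == v)
        out[i] = below + (ties + 1) / 2.0
    return out


def gfs_per_gene(values, theta1=0.05, theta2=0.15):
    """Direct three-branch evaluation of the fuzzy score, gene by gene."""
    ranks = brute_force_ranks(values)
    G = len(values)
    q1, q2 = (1 - theta1) * G, (1 - theta2) * G
    out = np.empty(G)
    for i, r in enumerate(ranks):
        if r >= q1:
            out[i] = 1.0
        elif r >= q2:
            out[i] = (r - q2) / (q1 - q2)
        else:
            out[i] = 0.0
    return out


def single_sample(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix.from_arrays(
        [f"g{i}" for i in range(len(values))], ["s"], values[:, None]
    )


class TestRanks:
    def test_sorted_order_case(self):
        np.testing.assert_array_equal(rank_within_sample([5, 1, 3]), [3, 1, 2])

    def test_tie_midpoint(self):
        np.testing.assert_array_equal(rank_within_sample([2, 2, 7]), [1.5, 1.5, 3])

    def test_empty_vector_rejected(self):
        with pytest.raises(ParameterError):
            rank_within_sample(np.array([]))

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False).map(lambda x: round(x, 2)),
            min_size=1,
            max_size=60,
        )
    )
    def test_matches_pairwise_oracle(self, values):
        np.testing.assert_allclose(
            rank_within_sample(values), brute_force_ranks(values)
        )

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=2, max_size=40))
    def test_rank_sum_invariant(self, values):
        g = len(values)
        assert rank_within_sample(values).sum() == pytest.approx(g * (g + 1) / 2)


class TestQuantileRank:
    @pytest.mark.parametrize(
        "g, theta, expected",
        [(1000, 0.05, 950.0), (1000, 0.15, 850.0), (100, 0.10, 90.0)],
    )
    def test_arithmetic(self, g, theta, expected):
        assert quantile_rank(g, theta) == expected

    @pytest.mark.parametrize("theta", [0.0, 1.0, -0.1, 1.5])
    def test_theta_out_of_range(self, theta):
        with pytest.raises(ParameterError):
            quantile_rank(100, theta)


class TestGfsTransform:
    def test_top_ten_percent_boundary_scores_half(self):
        # tie-free 1000-gene sample: the rank-900 gene sits midway between
        # q(0.15)=850 and q(0.05)=950 and must score exactly 0.5
        values = np.random.default_rng(5).permutation(1000).astype(float)
        scores = gfs_transform(single_sample(values)).values[:, 0]
        ranks = rank_within_sample(values)
        assert scores[ranks == 900][0] == 0.5

    def test_extreme_genes(self):
        values = np.random.default_rng(1).permutation(50).astype(float)
        scores = gfs_transform(single_sample(values)).values[:, 0]
        assert scores[np.argmax(values)] == 1.0
        assert scores[np.argmin(values)] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_gene_branch_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.lognormal(3, 1, 20).round(1)  # rounding induces ties
        got = gfs_transform(single_sample(values)).values[:, 0]
        np.testing.assert_allclose(got, gfs_per_gene(values))

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            GfsParams(theta1=0.15, theta2=0.05)
        with pytest.raises(ParameterError):
            GfsParams(theta1=0.05, theta2=1.2)

    def test_constant_sample_warns_and_applies_formula(self, caplog):
        m = ExpressionMatrix.from_arrays(
            ["a", "b", "c", "d"], ["s"], np.full((4, 1), 7.0)
        )
        with caplog.at_level(logging.WARNING):
            out = gfs_transform(m)
        assert any("constant" in r.message for r in caplog.records)
        # all genes share rank 2.5 -> one common score from the formula
        expected = gfs_per_gene(np.full(4, 7.0))
        np.testing.assert_allclose(out.values[:, 0], expected)

    @settings(derandomize=True, max_examples=40)
    @given(
        values=st.lists(
            st.floats(0.01, 1e4, allow_nan=False), min_size=5, max_size=50, unique=True
        ),
        data=st.data(),
    )
    def test_invariant_under_monotone_transform(self, values, data):
        # any strictly increasing map of a sample leaves its scores unchanged
        values = np.asarray(values)
        increments = data.draw(
            st.lists(
                st.floats(1e-3, 10.0),
                min_size=len(values),
                max_size=len(values),
            )
        )
        order = np.argsort(values)
        mapped = np.empty_like(values)
        mapped[order] = np.cumsum(increments)  # strictly increasing in rank
        base = gfs_transform(single_sample(values)).values
        np.testing.assert_allclose(
            gfs_transform(single_sample(mapped)).values, base
        )

    @pytest.mark.parametrize("g", [20, 101, 1000])
    def test_branch_counts_on_tie_free_sample(self, g):
        values = np.random.default_rng(g).permutation(g).astype(float)
        scores = gfs_transform(single_sample(values)).values[:, 0]
        q1, q2 = quantile_rank(g, 0.05), quantile_rank(g, 0.15)
        ranks = rank_within_sample(values)
        assert np.all((scores >= 0) & (scores <= 1))
        assert (scores == 1.0).sum() == np.sum(ranks >= q1)
        assert (scores == 0.0).sum() == np.sum(ranks < q2) + np.sum(
            (ranks == q2)
        )  # interpolation value at exactly q2 is 0

    def test_monotone_within_sample(self, rng):
        values = rng.lognormal(3, 1, 200)
        scores = gfs_transform(single_sample(values)).values[:, 0]
        order = np.argsort(values)
        assert np.all(np.diff(scores[order]) >= 0)


class TestScalingNormalizers:
    def test_mean_scale_two_sample_arithmetic(self):
        m = ExpressionMatrix.from_arrays(
            ["a", "b"], ["s1", "s2"], np.array([[1.0, 3.0], [3.0, 5.0]])
        )
        out = mean_scale(m)  # means 2 and 4 -> grand mean 3
        np.testing.assert_allclose(out.values.mean(axis=0), [3.0, 3.0])

    def test_mean_scale_identity_on_equal_means(self, rng):
        m = random_matrix(rng, 20, 4)
        centered = m.with_values(m.values - m.values.mean(axis=0) + 5.0)
        np.testing.assert_allclose(mean_scale(centered).values, centered.values)

    def test_median_scale_equalizes_medians(self):
        m = ExpressionMatrix.from_arrays(
            ["a", "b", "c"], ["s1", "s2"],
            np.array([[0.0, 2.0], [1.0, 3.0], [9.0, 4.0]]),
        )
        out = median_scale(m)  # medians 1 and 3 -> grand value 2
        np.testing.assert_allclose(np.median(out.values, axis=0), [2.0, 2.0])

    def test_zscore_moments(self):
        m = ExpressionMatrix.from_arrays(
            ["a", "b", "c"], ["s"], np.array([[1.0], [2.0], [3.0]])
        )
        out = zscore_normalize(m)
        assert out.values.mean() == pytest.approx(0, abs=1e-12)
        assert out.values.std() == pytest.approx(1, abs=1e-12)

    def test_zscore_idempotent_on_standardized(self, rng):
        m = random_matrix(rng, 30, 5, positive=False)
        once = zscore_normalize(m)
        np.testing.assert_allclose(
            zscore_normalize(once).values, once.values, atol=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_contracts_on_random_matrices(self, seed):
        m = random_matrix(np.random.default_rng(seed), 40, 7)
        grand_mean = m.values.mean(axis=0).mean()
        np.testing.assert_allclose(
            mean_scale(m).values.mean(axis=0), grand_mean, rtol=1e-9
        )
        grand_median = np.median(m.values, axis=0).mean()
        np.testing.assert_allclose(
            np.median(median_scale(m).values, axis=0), grand_median, rtol=1e-9
        )
        z = zscore_normalize(m).values
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0), 1, rtol=1e-9)

    def test_degenerate_samples_rejected(self):
        zero_mean = ExpressionMatrix.from_arrays(
            ["a", "b"], ["s"], np.array([[-1.0], [1.0]])
        )
        with pytest.raises(DegenerateSampleError):
            mean_scale(zero_mean)
        constant = ExpressionMatrix.from_arrays(
            ["a", "b"], ["s"], np.array([[2.0], [2.0]])
        )
        with pytest.raises(DegenerateSampleError):
            zscore_normalize(constant)


class TestQuantileNormalize:
    def test_identical_samples_unchanged(self):
        col = np.array([3.0, 1.0, 2.0])
        m = ExpressionMatrix.from_arrays(
            ["a", "b", "c"], ["s1", "s2"], np.column_stack([col, col])
        )
        np.testing.assert_allclose(quantile_normalize(m).values, m.values)

    def test_hand_computed_rank_means(self):
        m = ExpressionMatrix.from_arrays(
            ["a", "b", "c"], ["s1", "s2"],
            np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]),
        )
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out.values[:, 1], [2.5, 3.5, 4.5])

    def test_tie_rule_averages_reference_span(self):
        # sample 2 has a tie at the two lowest ranks: both get the mean of
        # the two lowest reference values
        m = ExpressionMatrix.from_arrays(
            ["a", "b", "c"], ["s1", "s2"],
            np.array([[1.0, 7.0], [2.0, 7.0], [3.0, 9.0]]),
        )
        out = quantile_normalize(m)
        ref = np.sort(m.values, axis=0).mean(axis=1)  # [4, 4.5, 6]
        np.testing.assert_allclose(out.values[:, 1], [4.25, 4.25, 6.0])
        np.testing.assert_allclose(out.values[:, 0], ref)

    @pytest.mark.parametrize("seed", range(5))
    def test_sorted_columns_identical(self, seed):
        m = random_matrix(np.random.default_rng(seed), 50, 6)
        out = quantile_normalize(m).values
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, out.shape[1]):
            np.testing.assert_array_equal(sorted_cols[:, j], sorted_cols[:, 0])


class TestTransformRegistry:
    @pytest.mark.parametrize(
        "name", ["raw", "gfs", "mean", "median", "zscore", "quantile"]
    )
    def test_all_preserve_shape_and_ids(self, name, rng):
        m = random_matrix(rng, 25, 5)
        out = get_transform(name)(m)
        assert out.gene_ids == m.gene_ids
        assert out.sample_ids == m.sample_ids
        # deterministic
        np.testing.assert_array_equal(out.values, get_transform(name)(m).values)

    def test_unknown_method_rejected(self):
        with pytest.raises(ParameterError, match="valid"):
            get_transform("loess")
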