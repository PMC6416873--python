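"""Normalization chains: fixed points, hand-derived examples, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffgc import (ExpressionMatrix, GeneStandardizer, QuantileNormalizer,
                    ValidationError, cpm, log2_transform, median_center,
                    normalize_rnaseq, pool_datasets, quantile_normalize,
                    zscore_within_dataset)


def em(values, scale="counts", genes=None, samples=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            scale=scale)


class TestCPM:
    def test_direct_definition(self):
        out = cpm(em([[100], [300], [600]]))
        assert out.data.iloc[:, 0].tolist() == [1e5, 3e5, 6e5]

    def test_hand_two_by_two(self):
        out = cpm(em([[1, 2], [3, 2]]))
        assert out.data.iloc[:, 0].tolist() == [2.5e5, 7.5e5]
        assert out.data.iloc[:, 1].tolist() == [5e5, 5e5]

    def test_column_sums_and_fixed_point(self):
        counts = em(np.arange(1, 13).reshape(4, 3))
        out = cpm(counts)
        assert np.allclose(out.data.sum(axis=0), 1e6)
        again = out.with_values(out.data, "counts")  # already summing to 1e6
        assert np.allclose(cpm(again).data, out.data)

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValidationError):
            cpm(em([[1, 0], [2, 0]]))


class TestQuantileNormalize:
    def test_mean_of_order_statistics_by_hand(self):
        out = quantile_normalize(em([[1, 3], [2, 4]], scale="cpm"))
        assert out.data.iloc[:, 0].tolist() == [2.0, 3.0]
        assert out.data.iloc[:, 1].tolist() == [2.0, 3.0]

    def test_identical_columns_are_a_fixed_point(self):
        matrix = em(np.tile([[5.0], [1.0], [3.0]], (1, 4)), scale="cpm")
        out = quantile_normalize(matrix)
        assert np.allclose(out.data, matrix.data)

    def test_idempotent_and_shared_order_statistics(self):
        rng = np.random.default_rng(0)
        matrix = em(rng.gamma(2, 10, size=(50, 6)), scale="cpm")
        once = quantile_normalize(matrix)
        twice = quantile_normalize(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)
        sorted_cols = np.sort(once.data.to_numpy(), axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, [0]])

    def test_preserves_within_column_ranks(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(30, 4))
        out = quantile_normalize(em(values, scale="cpm")).data.to_numpy()
        for j in range(4):
            assert (np.argsort(values[:, j]) == np.argsort(out[:, j])).all()

    def test_ties_get_mean_of_reference_values(self):
        # column 0 has a tie at ranks 1-2: both get the mean of ref[0:2]
        out = quantile_normalize(em([[1, 10], [1, 20], [5, 30]], scale="cpm"))
        ref = np.sort(np.array([[1, 10], [1, 20], [5, 30]]), axis=0).mean(axis=1)
        assert out.data.iloc[0, 0] == out.data.iloc[1, 0] == pytest.approx(
            (ref[0] + ref[1]) / 2)


class TestLog2AndMedianCenter:
    def test_log2_values(self):
        out = log2_transform(em([[0], [7]], scale="cpm"), pseudocount=1)
        assert out.data.iloc[:, 0].tolist() == [0.0, 3.0]
        assert out.scale == "log2"

    def test_log2_rejects_negative(self):
        with pytest.raises(ValidationError):
            log2_transform(em([[-1.0]], scale="log2"))

    def test_median_center_single_row(self):
        out = median_center(em([[1.0, 2.0, 4.0]], scale="log2"))
        assert out.data.iloc[0].tolist() == [0.0, 0.0, 0.0]

    def test_median_center_constant_matrix(self):
        out = median_center(em(np.full((3, 3), 7.0), scale="log2"))
        assert (out.data.to_numpy() == 0).all()

    def test_median_center_fixed_point(self):
        values = np.array([[-1.0, 0.0, 1.0], [0.0, 0.0, 0.0], [1.0, 0.0, -1.0]])
        out = median_center(em(values, scale="log2"))
        assert np.allclose(out.data, values)


class TestZScoreAndPooling:
    def test_row_standardization_by_hand(self):
        out = zscore_within_dataset(em([[1.0, 2.0, 3.0]], scale="log2"))
        assert out.data.iloc[0].tolist() == [-1.0, 0.0, 1.0]

    def test_idempotent_and_moments(self):
        rng = np.random.default_rng(2)
        matrix = em(rng.normal(size=(40, 8)), scale="log2")
        once = zscore_within_dataset(matrix)
        values = once.data.to_numpy()
        assert np.abs(values.mean(axis=1)).max() <= 1e-12
        assert np.abs(values.std(axis=1, ddof=1) - 1).max() <= 1e-12
        assert np.allclose(zscore_within_dataset(once).data, values, atol=1e-12)

    def test_constant_row_becomes_zero(self):
        out = zscore_within_dataset(em([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]],
                                       scale="log2"))
        assert out.data.iloc[0].tolist() == [0.0, 0.0, 0.0]

    def test_pooling_intersects_genes_and_prefixes_samples(self):
        d1 = em(np.random.default_rng(3).normal(size=(3, 4)), scale="standardized",
                genes=["A", "B", "C"])
        d2 = em(np.random.default_rng(4).normal(size=(3, 4)), scale="standardized",
                genes=["B", "C", "D"])
        pooled = pool_datasets([d1, d2], ["x", "y"])
        assert list(pooled.genes) == ["B", "C"]
        assert all(":" in s for s in pooled.samples)
        assert pooled.shape == (2, 8)

    def test_pooling_order_invariant_up_to_column_permutation(self):
        rng = np.random.default_rng(5)
        d1 = em(rng.normal(size=(10, 5)), scale="standardized")
        d2 = em(rng.normal(size=(10, 6)), scale="standardized",
                samples=[f"t{j}" for j in range(6)])
        ab = pool_datasets([d1, d2], ["x", "y"])
        ba = pool_datasets([d2, d1], ["y", "x"])
        pd.testing.assert_frame_equal(ab.data, ba.data[ab.samples])

    def test_empty_intersection_rejected(self):
        d1 = em([[1.0, 2.0]], scale="standardized", genes=["A"])
        d2 = em([[1.0, 2.0]], scale="standardized", genes=["B"])
        with pytest.raises(ValidationError):
            pool_datasets([d1, d2])


def test_full_chain_stage_order_and_scale_tags(small_fixture):
    counts = small_fixture.expression
    step = cpm(counts)
    assert step.scale == "cpm"
    step = quantile_normalize(step)
    step = log2_transform(step)
    assert step.scale == "log2"
    chained = median_center(step)
    direct = normalize_rnaseq(counts)
    pd.testing.assert_frame_equal(direct.data, chained.data)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_chain_output_invariant_under_sample_relabeling(seed):
    """Normalization treats samples exchangeably: permuting columns before
    the chain equals permuting them after."""
    rng = np.random.default_rng(seed)
    counts = rng.poisson(30, size=(20, 5)) + 1
    matrix = em(counts)
    perm = rng.permutation(5)
    permuted = ExpressionMatrix(matrix.data.iloc[:, perm], scale="counts")
    out1 = normalize_rnaseq(permuted).data
    out2 = normalize_rnaseq(matrix).data.iloc[:, perm]
    pd.testing.assert_frame_equal(out1, out2)


class TestSklearnTransformers:
    def test_quantile_normalizer_freezes_training_reference(self):
        rng = np.random.default_rng(6)
        train = rng.normal(size=(10, 30))
        normalizer = QuantileNormalizer().fit(train)
        new = rng.normal(5, 3, size=(2, 30))  # wildly different distribution
        out = normalizer.transform(new)
        assert np.allclose(np.sort(out, axis=1), normalizer.reference_)

    def test_gene_standardizer_frozen_statistics(self):
        rng = np.random.default_rng(7)
        train = rng.normal(3, 2, size=(20, 5))
        scaler = GeneStandardizer().fit(train)
        transformed = scaler.transform(train)
        assert np.abs(transformed.mean(axis=0)).max() < 1e-12
        shifted = scaler.transform(train + 2)
        assert np.allclose(shifted.mean(axis=0) - transformed.mean(axis=0),
                           2 / scaler.sds_)

    def test_transformers_are_clonable(self):
        from sklearn.base import clone
        clone(QuantileNormalizer())
        clone(GeneStandardizer())
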