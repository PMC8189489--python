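"""Masking protocol, recovery correlations, strata, CV, distance ratio."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from graphimpute import (
    ExpressionMatrix,
    MaskingSpec,
    binomial_mask,
    cell_wise_spearman,
    cv_per_gene,
    gene_wise_pearson,
    inter_intra_ratio,
    run_downsample_benchmark,
    stratify_genes,
)


def as_em(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        tuple(f"g{j}" for j in range(values.shape[1])),
        tuple(f"c{i}" for i in range(values.shape[0])),
    )


class TestBinomialMask:
    def test_certain_and_no_masking(self, small_counts):
        all_zero = binomial_mask(small_counts, MaskingSpec(p_mask=1.0, seed=0))
        assert np.all(all_zero.values == 0)
        unchanged = binomial_mask(small_counts, MaskingSpec(p_mask=0.0, seed=0))
        np.testing.assert_array_equal(unchanged.values, small_counts.values)

    def test_non_integer_input_is_error(self):
        X = as_em([[1.5, 2.0]])
        with pytest.raises(ValueError, match="integer"):
            binomial_mask(X, MaskingSpec(p_mask=0.5, seed=0))

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_output_bounded_by_input_and_integer(self, seed):
        rng = np.random.default_rng(seed)
        X = as_em(rng.poisson(5.0, size=(6, 4)))
        out = binomial_mask(X, MaskingSpec(p_mask=0.7, seed=seed))
        assert np.all(out.values <= X.values)
        assert out.is_count

    def test_seed_reproducibility(self, small_counts):
        a = binomial_mask(small_counts, MaskingSpec(p_mask=0.5, seed=9))
        b = binomial_mask(small_counts, MaskingSpec(p_mask=0.5, seed=9))
        np.testing.assert_array_equal(a.values, b.values)

    def test_binomial_moments(self):
        # entry 10 masked at 0.8 over many replicates: mean ~ 2, var ~ Bin(10, .2)
        X = as_em([[10]])
        n_rep = 10_000
        draws = np.array(
            [binomial_mask(X, MaskingSpec(p_mask=0.8, seed=s)).values[0, 0] for s in range(n_rep)]
        )
        mean_se = np.sqrt(10 * 0.2 * 0.8 / n_rep)
        assert abs(draws.mean() - 2.0) < 3 * mean_se
        # variance of the sample variance of a binomial, normal approximation
        var = draws.var(ddof=1)
        assert abs(var - 1.6) < 4 * var * np.sqrt(2 / (n_rep - 1)) + 0.05


class TestCorrelations:
    def test_pearson_identity_and_anticorrelation(self):
        A = as_em([[1, 3], [2, 2], [3, 1]])
        np.testing.assert_allclose(gene_wise_pearson(A, A), [1.0, 1.0])
        B = as_em([[3, 1], [2, 2], [1, 3]])
        np.testing.assert_allclose(gene_wise_pearson(A, B), [-1.0, -1.0])

    def test_pearson_known_value(self):
        a = as_em(np.array([[1, 2, 3, 4]]).T)
        b = as_em(np.array([[1, 3, 2, 4]]).T)
        assert gene_wise_pearson(a, b)[0] == pytest.approx(0.8)

    def test_constant_gene_is_nan(self):
        a = as_em([[1, 1], [2, 1], [3, 1]])
        r = gene_wise_pearson(a, a)
        assert r[0] == pytest.approx(1.0)
        assert np.isnan(r[1])

    def test_pearson_matches_scipy_per_gene(self, rng):
        a, b = rng.gamma(2, 1, size=(2, 12, 5))
        r = gene_wise_pearson(as_em(a), as_em(b))
        for j in range(5):
            assert r[j] == pytest.approx(stats.pearsonr(a[:, j], b[:, j])[0], abs=1e-12)

    def test_spearman_rank_invariance_and_reversal(self):
        a = as_em([[1.0, 5.0, 2.0], [4.0, 1.0, 9.0]])
        b_mono = as_em(np.exp(a.values))  # strictly increasing transform
        np.testing.assert_allclose(cell_wise_spearman(a, b_mono), [1.0, 1.0])
        b_rev = as_em(-a.values + 10.0)
        np.testing.assert_allclose(cell_wise_spearman(a, b_rev), [-1.0, -1.0])

    def test_spearman_with_ties_matches_scipy(self):
        a = as_em([[1.0, 1.0, 2.0]])
        b = as_em([[1.0, 2.0, 2.0]])
        expected = stats.spearmanr(a.values[0], b.values[0]).statistic
        assert cell_wise_spearman(a, b)[0] == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            gene_wise_pearson(np.ones((2, 2)), np.ones((3, 2)))


class TestStratifyGenes:
    def test_boundary_conventions(self):
        # detection fractions: 0.85 -> widely, 0.80 -> mildly, 0.10 -> rarely,
        # 0.30 -> mildly (boundaries inclusive in the middle bin)
        n = 20
        fracs = [0.85, 0.80, 0.10, 0.30]
        vals = np.zeros((n, 4))
        for j, f in enumerate(fracs):
            vals[: int(round(f * n)), j] = 1.0
        labels, counts = stratify_genes(as_em(vals))
        assert list(labels) == ["widely", "mildly", "rarely", "mildly"]
        assert counts == {"widely": 1, "mildly": 2, "rarely": 1}

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_counts_partition_genes(self, seed):
        rng = np.random.default_rng(seed)
        X = as_em(rng.poisson(0.8, size=(15, 9)))
        _, counts = stratify_genes(X)
        assert sum(counts.values()) == 9

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            stratify_genes(as_em(np.ones((3, 2))), lower=0.8, upper=0.3)


class TestCvPerGene:
    def test_constant_gene_zero_cv(self):
        assert cv_per_gene(as_em([[5.0], [5.0], [5.0]]))[0] == 0.0

    def test_sample_sd_convention(self):
        # values (2, 4): mean 3, sd(ddof=1) = sqrt(2) -> CV = sqrt(2)/3
        assert cv_per_gene(as_em([[2.0], [4.0]]))[0] == pytest.approx(np.sqrt(2) / 3)

    def test_single_nonzero_cell_is_undefined(self):
        r = cv_per_gene(as_em([[0.0], [0.0], [5.0]]), cells="nonzero")
        assert np.isnan(r[0])

    def test_zero_mean_is_undefined(self):
        assert np.isnan(cv_per_gene(as_em([[0.0], [0.0]]))[0])


class TestInterIntraRatio:
    def test_degenerate_intra_distance_is_error(self):
        scores = np.array([[0.0], [0.0], [10.0], [10.0]])
        labels = ["a", "a", "b", "b"]
        with pytest.raises(ValueError, match="intra"):
            inter_intra_ratio(scores, labels, k_max=1)

    def test_enumerated_four_cell_example(self):
        # subtypes {0,1} and {10,11}: intra mean 1, inter mean (10+11+9+10)/4=10
        scores = np.array([[0.0], [1.0], [10.0], [11.0]])
        ratios = inter_intra_ratio(scores, ["a", "a", "b", "b"], k_max=1)
        assert ratios[0] == pytest.approx(10.0)

    def test_rotation_and_relabel_invariance(self, rng):
        scores = rng.normal(size=(20, 3))
        labels = np.array(["x"] * 10 + ["y"] * 10)
        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        base = inter_intra_ratio(scores, labels, k_max=3)
        rotated = inter_intra_ratio(scores @ R.T, labels, k_max=3)
        relabeled = inter_intra_ratio(scores, np.where(labels == "x", "q", "p"), k_max=3)
        # rotation mixes coordinates so only the full-K ratio is preserved
        assert rotated[2] == pytest.approx(base[2], rel=1e-9)
        np.testing.assert_allclose(relabeled, base, rtol=1e-12)

    def test_random_labels_concentrate_near_one(self, rng):
        scores = rng.normal(size=(40, 2))
        ratios = []
        for _ in range(200):
            labels = rng.permutation(["a"] * 20 + ["b"] * 20)
            ratios.append(inter_intra_ratio(scores, labels, k_max=1)[0])
        assert abs(np.median(ratios) - 1.0) < 0.05

    def test_subtype_with_single_cell_is_error(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            inter_intra_ratio(np.zeros((3, 1)), ["a", "a", "b"])


class TestRunDownsampleBenchmark:
    def test_no_masking_gives_perfect_baseline(self, tiny_benchmark):
        rep = run_downsample_benchmark(
            tiny_benchmark.X_true,
            MaskingSpec(p_mask=0.0, seed=0),
            impute_kwargs={"t": 1},
        )
        r = rep.baseline_gene_correlations
        assert np.all(np.isclose(r[~np.isnan(r)], 1.0))

    def test_fixed_seed_reproducible(self, tiny_benchmark):
        kw = dict(spec=MaskingSpec(p_mask=0.8, seed=5), impute_kwargs={"t": 1})
        rep1 = run_downsample_benchmark(tiny_benchmark.X_true, **kw)
        rep2 = run_downsample_benchmark(tiny_benchmark.X_true, **kw)
        np.testing.assert_array_equal(rep1.gene_correlations, rep2.gene_correlations)
        np.testing.assert_array_equal(rep1.cell_correlations, rep2.cell_correlations)
        assert rep1.summary() == rep2.summary()

    def test_report_is_well_formed(self, tiny_benchmark):
        rep = run_downsample_benchmark(
            tiny_benchmark.X_true, MaskingSpec(p_mask=0.8, seed=5)
        )
        assert sum(rep.strata_counts.values()) == tiny_benchmark.X_true.n_genes
        for arr in (rep.gene_correlations, rep.baseline_gene_correlations,
                    rep.cell_correlations, rep.baseline_cell_correlations):
            finite = arr[~np.isnan(arr)]
            assert np.all((finite >= -1 - 1e-12) & (finite <= 1 + 1e-12))
        assert rep.t_star >= 1
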