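import numpy as np
import pytest

from mbsparse import (
    MatrixMask,
    SyntheticSpec,
    identification_rate,
    inject_dropout,
    masked_mse,
    per_taxon_correlation,
    recovery_report,
    sma_fit,
    synthesize_count_matrix,
)
from mbsparse.impute import ImputationResult
from mbsparse.preprocess import inverse_transform, log_transform, normalize_library_size


class TestMaskedMse:
    def test_identity_is_zero(self, rng):
        a = rng.random((4, 5))
        assert masked_mse(a, a, "all") == 0.0

    def test_uniform_offset(self, rng):
        a = rng.random((4, 5))
        assert masked_mse(a, a + 1.0, "all") == pytest.approx(1.0)

    def test_two_entry_mask(self):
        a = np.zeros((2, 2))
        b = np.array([[1.0, 0.0], [0.0, 3.0]])
        mask = MatrixMask(np.array([[0, 0], [1, 1]]), (2, 2))
        assert masked_mse(a, b, mask) == pytest.approx(5.0)

    def test_symmetric(self, rng):
        a, b = rng.random((3, 4)), rng.random((3, 4))
        assert masked_mse(a, b) == masked_mse(b, a)

    def test_empty_mask_rejected(self, rng):
        a = rng.random((3, 3))
        with pytest.raises(ValueError, match="empty"):
            masked_mse(a, a, MatrixMask(np.empty((0, 2)), (3, 3)))


class TestPerTaxonCorrelation:
    def test_affine_map_gives_perfect_pearson(self, rng):
        a = rng.random((10, 6))
        _, mean, n_excl = per_taxon_correlation(a, 2 * a + 3, "pearson")
        assert mean == pytest.approx(1.0)
        assert n_excl == 0

    def test_negation_gives_minus_one(self, rng):
        a = rng.random((10, 4))
        vec, _, _ = per_taxon_correlation(a, -a, "pearson")
        assert np.allclose(vec, -1.0)

    def test_monotone_map_spearman_one_pearson_below(self, rng):
        a = rng.random((30, 5)) * 3
        b = a**3  # monotone but not affine
        _, sp_mean, _ = per_taxon_correlation(a, b, "spearman")
        _, pe_mean, _ = per_taxon_correlation(a, b, "pearson")
        assert sp_mean == pytest.approx(1.0)
        assert pe_mean < 1.0

    def test_constant_columns_flagged_not_zeroed(self, rng):
        a = rng.random((8, 3))
        b = a.copy()
        b[:, 1] = 5.0
        vec, mean, n_excl = per_taxon_correlation(a, b, "pearson")
        assert np.isnan(vec[1])
        assert n_excl == 1
        assert mean == pytest.approx(1.0)  # remaining identical columns

    def test_symmetry_in_arguments(self, rng):
        a, b = rng.random((12, 7)), rng.random((12, 7))
        for method in ("pearson", "spearman"):
            va, _, _ = per_taxon_correlation(a, b, method)
            vb, _, _ = per_taxon_correlation(b, a, method)
            assert np.allclose(va, vb, equal_nan=True)


class TestSmaFit:
    def test_exact_doubling_line(self):
        slope, intercept, r = sma_fit(np.array([1.0, 2, 3]), np.array([2.0, 4, 6]))
        assert (slope, intercept, r) == (pytest.approx(2.0), pytest.approx(0.0), pytest.approx(1.0))

    def test_negative_exact_line(self):
        slope, intercept, r = sma_fit(np.array([1.0, 2, 3]), np.array([6.0, 4, 2]))
        assert slope == pytest.approx(-2.0)
        assert intercept == pytest.approx(8.0)
        assert r == pytest.approx(-1.0)

    def test_swap_inverts_slope_on_collinear_data(self):
        x, y = np.array([1.0, 2, 3, 4]), np.array([3.0, 5, 7, 9])
        s_xy, _, _ = sma_fit(x, y)
        s_yx, _, _ = sma_fit(y, x)
        assert s_yx == pytest.approx(1.0 / s_xy)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sma_fit(np.array([1.0, 1, 1]), np.array([1.0, 2, 3]))

    def test_matches_eigendecomposition_oracle(self):
        """Standardize, take the principal axis of the 2x2 correlation matrix
        (sign-aligned with r), map the slope back through the sd ratio."""
        rng = np.random.default_rng(77)
        for _ in range(100):
            x = rng.normal(0, rng.uniform(0.5, 3), 50)
            y = rng.uniform(-2, 2) * x + rng.normal(0, 1, 50)
            slope, intercept, r = sma_fit(x, y)
            corr = np.corrcoef((x - x.mean()) / x.std(ddof=1),
                               (y - y.mean()) / y.std(ddof=1))
            w, v = np.linalg.eigh(corr)
            major = v[:, np.argmax(w)]
            std_slope = major[1] / major[0]
            if np.sign(std_slope) != np.sign(r) and r != 0:
                # principal axis of a 2x2 correlation matrix is +/-45 degrees
                std_slope = np.sign(r) * abs(std_slope)
            expected = std_slope * (y.std(ddof=1) / x.std(ddof=1))
            assert slope == pytest.approx(expected, rel=1e-9)


def make_result(imputed_logged, corrupted_values, sample_ids, taxon_ids, target=1e6):
    zero_mask = MatrixMask.from_boolean(corrupted_values == 0)
    return ImputationResult(
        imputed_logged=imputed_logged,
        imputed_normalized=inverse_transform(imputed_logged),
        filled_mask=MatrixMask.from_boolean((corrupted_values == 0) & (imputed_logged > 0)),
        input_zero_mask=zero_mask,
        sample_ids=sample_ids,
        taxon_ids=taxon_ids,
        config_snapshot={"target_library_size": target},
        seed=0,
    )


class TestIdentificationRate:
    @pytest.fixture
    def setup(self):
        spec = SyntheticSpec(n_samples=20, n_taxa=30, zero_inflation=0.1, seed=50)
        complete = synthesize_count_matrix(spec)
        exp = inject_dropout(complete, 0.3, seed=51)
        corrupted_logged = log_transform(normalize_library_size(exp.corrupted, 1e6))
        return exp, corrupted_logged

    def test_all_filled_gives_one(self, setup):
        exp, R = setup
        imputed = R.copy()
        idx = exp.injected_mask.indices
        imputed[idx[:, 0], idx[:, 1]] = 1.0
        res = make_result(imputed, exp.corrupted.values, exp.corrupted.sample_ids,
                          exp.corrupted.taxon_ids)
        assert identification_rate(res, exp.injected_mask) == 1.0

    def test_none_filled_gives_zero(self, setup):
        exp, R = setup
        res = make_result(R, exp.corrupted.values, exp.corrupted.sample_ids,
                          exp.corrupted.taxon_ids)
        assert identification_rate(res, exp.injected_mask) == 0.0

    def test_partial_fill_fraction(self, setup):
        exp, R = setup
        imputed = R.copy()
        idx = exp.injected_mask.indices
        n_fill = (9 * len(exp.injected_mask)) // 10
        imputed[idx[:n_fill, 0], idx[:n_fill, 1]] = 1.0
        res = make_result(imputed, exp.corrupted.values, exp.corrupted.sample_ids,
                          exp.corrupted.taxon_ids)
        assert identification_rate(res, exp.injected_mask) == pytest.approx(
            n_fill / len(exp.injected_mask))


class TestRecoveryReport:
    @pytest.fixture
    def setup(self):
        spec = SyntheticSpec(n_samples=25, n_taxa=40, zero_inflation=0.15, seed=60)
        complete = synthesize_count_matrix(spec)
        exp = inject_dropout(complete, 0.25, seed=61)
        return complete, exp

    def test_perfect_recovery(self, setup):
        complete, exp = setup
        # imputed equals the complete matrix wherever corrupted is zero
        C = log_transform(normalize_library_size(complete, 1e6))
        R = log_transform(normalize_library_size(exp.corrupted, 1e6))
        imputed = np.where(exp.corrupted.values == 0, C, R)
        # for a clean "perfect" report also align retained entries
        imputed = C.copy()
        imputed[(exp.corrupted.values == 0) & (complete.values == 0)] = 0.0
        res = make_result(imputed, exp.corrupted.values, exp.corrupted.sample_ids,
                          exp.corrupted.taxon_ids)
        report = recovery_report(exp, res)
        assert report.mse == pytest.approx(0.0, abs=1e-20)
        assert report.identification_rate == 1.0

    def test_noop_imputation_equals_baseline(self, setup):
        _, exp = setup
        R = log_transform(normalize_library_size(exp.corrupted, 1e6))
        res = make_result(R, exp.corrupted.values, exp.corrupted.sample_ids,
                          exp.corrupted.taxon_ids)
        report = recovery_report(exp, res)
        assert report.identification_rate == 0.0
        assert report.mse == pytest.approx(report.baseline_mse)
        assert report.mean_pearson == pytest.approx(report.baseline_mean_pearson)

    def test_taxon_permutation_invariance(self, setup):
        from mbsparse import CountMatrix
        from mbsparse.simulate import CorruptionExperiment

        complete, exp = setup
        R = log_transform(normalize_library_size(exp.corrupted, 1e6))
        res = make_result(R, exp.corrupted.values, exp.corrupted.sample_ids,
                          exp.corrupted.taxon_ids)
        base = recovery_report(exp, res)

        perm = np.random.default_rng(1).permutation(complete.n_taxa)
        taxa = tuple(complete.taxon_ids[j] for j in perm)

        def permute(cm):
            return CountMatrix(cm.values[:, perm], cm.sample_ids, taxa)

        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        mask_idx = exp.injected_mask.indices.copy()
        mask_idx[:, 1] = inv[mask_idx[:, 1]]
        exp_p = CorruptionExperiment(
            complete=permute(complete), corrupted=permute(exp.corrupted),
            injected_mask=MatrixMask(mask_idx, complete.shape),
            rate=exp.rate, seed=exp.seed,
        )
        res_p = make_result(R[:, perm], exp_p.corrupted.values,
                            exp_p.corrupted.sample_ids, exp_p.corrupted.taxon_ids)
        permuted = recovery_report(exp_p, res_p)
        assert permuted.mse == pytest.approx(base.mse)
        assert permuted.mean_pearson == pytest.approx(base.mean_pearson)

    def test_provenance_mismatch_rejected(self, setup):
        complete, exp = setup
        R = log_transform(normalize_library_size(exp.corrupted, 1e6))
        res = make_result(R, exp.corrupted.values,
                          tuple(f"x{i}" for i in range(complete.n_samples)),
                          exp.corrupted.taxon_ids)
        with pytest.raises(ValueError, match="derive"):
            recovery_report(exp, res)
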