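import numpy as np
import pytest

from mbsparse import (
    CountMatrix,
    SyntheticSpec,
    downsample_depth,
    inject_dropout,
    make_complete_scheme1,
    make_complete_scheme2,
    make_outlier,
    synthesize_count_matrix,
)
from mbsparse.simulate import restore_from_mask


class TestSynthesize:
    def test_no_inflation_large_means_few_zeros(self):
        """With zero inflation off and generous means, only rare sampling
        zeros remain (counted empirically)."""
        spec = SyntheticSpec(n_samples=50, n_taxa=100, zero_inflation=0.0,
                             base_mean=5000.0, seed=1)
        cm = synthesize_count_matrix(spec)
        assert cm.zero_fraction() < 0.01

    def test_high_inflation_hits_binomial_bound(self):
        """At 90% inflation the observed zero fraction must sit within the
        3-sigma binomial band above 0.9 (sampling zeros only add)."""
        spec = SyntheticSpec(n_samples=50, n_taxa=100, zero_inflation=0.9, seed=2)
        cm = synthesize_count_matrix(spec)
        sigma = np.sqrt(0.9 * 0.1 / (50 * 100))
        assert cm.zero_fraction() >= 0.9 - 3 * sigma

    def test_seeded_reproducibility(self):
        spec = SyntheticSpec(seed=7, n_samples=20, n_taxa=30)
        assert np.array_equal(
            synthesize_count_matrix(spec).values, synthesize_count_matrix(spec).values
        )

    def test_rows_always_normalizable(self):
        spec = SyntheticSpec(n_samples=30, n_taxa=20, zero_inflation=0.97, seed=3)
        cm = synthesize_count_matrix(spec)
        assert np.all(cm.values.sum(axis=1) > 0)

    def test_group_effect_shifts_da_taxa(self):
        spec = SyntheticSpec(n_samples=100, n_taxa=200, zero_inflation=0.0,
                             n_groups=2, effect_size=2.0, n_da_taxa=50, seed=4)
        cm = synthesize_count_matrix(spec)
        groups = np.arange(100) % 2
        logged = np.log10(cm.values + 1)
        da_shift = logged[groups == 1][:, :50].mean() - logged[groups == 0][:, :50].mean()
        null_shift = logged[groups == 1][:, 50:].mean() - logged[groups == 0][:, 50:].mean()
        assert da_shift > 0.3
        assert abs(null_shift) < 0.2

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="latent_rank"):
            SyntheticSpec(n_samples=5, n_taxa=5, latent_rank=10).validate()
        with pytest.raises(ValueError, match="zero_inflation"):
            SyntheticSpec(zero_inflation=1.5).validate()


@pytest.fixture
def block_matrix():
    """12x30 matrix: columns 0-19 dense on rows 0-9, everything else sparse."""
    rng = np.random.default_rng(11)
    values = np.zeros((12, 30))
    values[:10, :20] = rng.integers(1, 100, size=(10, 20))
    values[10:, 20:] = rng.integers(1, 10, size=(2, 10))
    return CountMatrix(values, tuple(f"s{i}" for i in range(12)),
                       tuple(f"t{j}" for j in range(30)))


class TestCompleteSchemes:
    def test_scheme1_recovers_dense_block(self, block_matrix):
        sub = make_complete_scheme1(block_matrix, 20 / 30)
        assert sub.shape == (10, 20)
        assert np.all(sub.values > 0)
        assert sub.taxon_ids == block_matrix.taxon_ids[:20]

    def test_scheme1_identity_on_zero_free_matrix(self, rng):
        values = rng.integers(1, 50, size=(5, 8)).astype(float)
        cm = CountMatrix(values, tuple(f"s{i}" for i in range(5)),
                         tuple(f"t{j}" for j in range(8)))
        sub = make_complete_scheme1(cm, 1.0)
        assert np.array_equal(sub.values, cm.values)

    def test_scheme1_output_has_no_zeros(self, block_matrix):
        assert make_complete_scheme1(block_matrix, 0.5).zero_fraction() == 0.0

    def test_scheme1_rejects_impossible_extraction(self):
        values = np.eye(4) * 5  # no 2x2 zero-free submatrix at high proportion
        cm = CountMatrix(values, tuple(f"s{i}" for i in range(4)),
                         tuple(f"t{j}" for j in range(4)))
        with pytest.raises(ValueError, match="zero-free"):
            make_complete_scheme1(cm, 1.0)

    def test_scheme2_rows_sum_to_depth(self, block_matrix):
        sub = make_complete_scheme2(block_matrix, 0.5, depth=2000, seed=5)
        assert np.all(sub.values.sum(axis=1) == 2000)

    def test_scheme2_large_depth_preserves_relative_abundance(self, block_matrix):
        extracted = make_complete_scheme1(block_matrix, 0.5)
        deep = make_complete_scheme2(block_matrix, 0.5, depth=10**6, seed=6)
        p_true = extracted.values / extracted.values.sum(axis=1, keepdims=True)
        p_deep = deep.values / deep.values.sum(axis=1, keepdims=True)
        assert np.max(np.abs(p_deep - p_true) / p_true) < 0.05

    def test_scheme2_seeded(self, block_matrix):
        a = make_complete_scheme2(block_matrix, 0.5, 1000, seed=9)
        b = make_complete_scheme2(block_matrix, 0.5, 1000, seed=9)
        assert np.array_equal(a.values, b.values)


class TestInjectDropout:
    @pytest.fixture
    def fifty_nonzero(self):
        values = np.zeros((10, 10))
        idx = np.unravel_index(np.arange(0, 100, 2), (10, 10))
        values[idx] = np.arange(1, 51)
        return CountMatrix(values, tuple(f"s{i}" for i in range(10)),
                           tuple(f"t{j}" for j in range(10)))

    def test_exact_count_zeroed(self, fifty_nonzero):
        exp = inject_dropout(fifty_nonzero, 0.1, seed=1)
        assert len(exp.injected_mask) == 5

    def test_rate_zero_is_identity(self, fifty_nonzero):
        exp = inject_dropout(fifty_nonzero, 0.0, seed=1)
        assert np.array_equal(exp.corrupted.values, fifty_nonzero.values)
        assert len(exp.injected_mask) == 0

    def test_mask_coordinates_were_nonzero(self, fifty_nonzero):
        exp = inject_dropout(fifty_nonzero, 0.3, seed=2)
        idx = exp.injected_mask.indices
        assert np.all(fifty_nonzero.values[idx[:, 0], idx[:, 1]] > 0)

    def test_restore_from_mask_is_identity(self, fifty_nonzero):
        exp = inject_dropout(fifty_nonzero, 0.4, seed=3)
        assert np.array_equal(restore_from_mask(exp).values, fifty_nonzero.values)

    def test_rate_one_rejected(self, fifty_nonzero):
        with pytest.raises(ValueError, match="rate"):
            inject_dropout(fifty_nonzero, 1.0)


class TestDownsampleDepth:
    def test_rows_sum_to_depth(self, rng):
        values = rng.integers(1, 1000, size=(8, 40)).astype(float)
        cm = CountMatrix(values, tuple(f"s{i}" for i in range(8)),
                         tuple(f"t{j}" for j in range(40)))
        down = downsample_depth(cm, 1234, seed=0)
        assert np.all(down.values.sum(axis=1) == 1234)

    def test_deeper_sequencing_means_fewer_zeros(self):
        """Averaged over 30 seeds, depth 10,000 leaves no more zeros than
        depth 1,000 (simulation oracle for the depth trend)."""
        spec = SyntheticSpec(n_samples=15, n_taxa=80, zero_inflation=0.0, seed=44)
        cm = synthesize_count_matrix(spec)
        shallow = np.mean([downsample_depth(cm, 1000, s).zero_fraction() for s in range(30)])
        deep = np.mean([downsample_depth(cm, 10000, s).zero_fraction() for s in range(30)])
        assert deep <= shallow

    def test_seeded(self, rng):
        values = rng.integers(1, 100, size=(4, 10)).astype(float)
        cm = CountMatrix(values, tuple(f"s{i}" for i in range(4)),
                         tuple(f"t{j}" for j in range(10)))
        assert np.array_equal(downsample_depth(cm, 500, 7).values,
                              downsample_depth(cm, 500, 7).values)


class TestMakeOutlier:
    @pytest.fixture
    def cohort(self):
        spec = SyntheticSpec(n_samples=40, n_taxa=60, zero_inflation=0.2, seed=21)
        return synthesize_count_matrix(spec)

    def test_target_row_nonzero_exactly_on_chosen_taxa(self, cohort):
        out = make_outlier(cohort, 3, "auto", seed=1)
        row = out.values[3]
        means = cohort.values.mean(axis=0)
        eligible = (means < np.median(means)) & (np.sum(cohort.values > 0, axis=0) >= 10)
        assert np.array_equal(row > 0, eligible)

    def test_rare_taxon_never_chosen(self, cohort):
        # force one taxon below the 10-nonzero eligibility floor
        values = cohort.values.copy()
        values[5:, 0] = 0.0
        values[:5, 0] = 1.0
        cm = cohort.with_values(values)
        out = make_outlier(cm, 2, "auto", seed=2)
        assert out.values[2, 0] == 0.0

    def test_injected_values_from_top100_pool(self, cohort):
        out = make_outlier(cohort, 0, "auto", seed=3)
        row = out.values[0]
        for j in np.flatnonzero(row > 0):
            col = cohort.values[:, j]
            pool = np.sort(col[col > 0])[::-1][:100]
            assert row[j] in pool

    def test_requesting_too_many_taxa_rejected(self, cohort):
        with pytest.raises(ValueError, match="eligible"):
            make_outlier(cohort, 0, 10_000, seed=0)

    def test_other_rows_untouched(self, cohort):
        out = make_outlier(cohort, 7, "auto", seed=4)
        others = np.delete(np.arange(40), 7)
        assert np.array_equal(out.values[others], cohort.values[others])
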