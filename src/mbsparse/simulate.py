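"""Synthetic count matrices and the corruption protocols used for benchmarking.

The generator draws zero-inflated, low-rank-correlated counts emulating WGS
species profiles: a log-normal mean surface with sample effects, taxon
effects and a rank-r interaction term; gamma-Poisson (negative-binomial)
counts around those means; and independent extra zeroing at a configurable
rate to mimic technical dropout, which can push overall sparsity to the
90% regime seen in real gut metagenomes.

Corruption protocols give ground truth for recovery scoring:

* complete-data extraction (dense-taxon selection, optionally followed by
  multinomial resampling at a fixed depth),
* dropout injection (zeroing a known fraction of non-zero entries),
* depth downsampling (multinomial resample of each sample at a target depth),
* outlier-sample construction (a sample rebuilt from high quantiles of
  low-abundance taxa, everything else zeroed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .matrix import CountMatrix, MatrixMask

__all__ = [
    "SyntheticSpec",
    "CorruptionExperiment",
    "synthesize_count_matrix",
    "make_complete_scheme1",
    "make_complete_scheme2",
    "inject_dropout",
    "downsample_depth",
    "make_outlier",
    "restore_from_mask",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the zero-inflated low-rank count generator.

    ``zero_inflation`` is the probability that an entry is zeroed on top of
    whatever sampling zeros the count draw produces.  ``dispersion`` is the
    negative-binomial overdispersion (variance = mu + dispersion * mu^2).
    With ``n_groups > 1``, the first ``n_da_taxa`` taxa get a log-scale
    abundance shift of ``effect_size`` in the non-reference groups,
    emulating spiked-in differentially abundant taxa.
    """

    n_samples: int = 100
    n_taxa: int = 300
    latent_rank: int = 5
    zero_inflation: float = 0.3
    dispersion: float = 0.5
    n_groups: int = 1
    effect_size: float = 0.0
    n_da_taxa: int = 0
    base_mean: float = 200.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_taxa < 2:
            raise ValueError("need at least 2 samples and 2 taxa")
        if not (1 <= self.latent_rank <= min(self.n_samples, self.n_taxa)):
            raise ValueError("latent_rank must be in [1, min(n_samples, n_taxa)]")
        if not (0.0 <= self.zero_inflation <= 1.0):
            raise ValueError("zero_inflation must lie in [0, 1]")
        if self.dispersion <= 0 or self.base_mean <= 0:
            raise ValueError("dispersion and base_mean must be positive")
        if self.n_groups < 1 or self.effect_size < 0:
            raise ValueError("n_groups >= 1 and effect_size >= 0 required")
        if not (0 <= self.n_da_taxa <= self.n_taxa):
            raise ValueError("n_da_taxa must lie in [0, n_taxa]")


@dataclass(frozen=True)
class CorruptionExperiment:
    """A complete matrix, its corrupted version and the injected-zero mask."""

    complete: CountMatrix
    corrupted: CountMatrix
    injected_mask: MatrixMask
    rate: float
    seed: int

    def __post_init__(self) -> None:
        if self.complete.shape != self.corrupted.shape:
            raise ValueError("complete and corrupted shapes differ")
        mask = self.injected_mask.to_boolean()
        if np.any(self.corrupted.values[mask] != 0):
            raise ValueError("corrupted matrix is non-zero on the injected mask")
        if np.any(self.complete.values[mask] == 0):
            raise ValueError("complete matrix is zero on the injected mask")
        if np.any(self.complete.values[~mask] != self.corrupted.values[~mask]):
            raise ValueError("corrupted differs from complete outside the mask")


def synthesize_count_matrix(spec: SyntheticSpec) -> CountMatrix:
    """Draw a zero-inflated, low-rank-correlated count matrix.

    Reproducible by ``spec.seed``.  Rows that end up all-zero (possible at
    extreme zero inflation) have their single largest pre-zeroing count
    restored so every sample remains normalizable.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m, r = spec.n_samples, spec.n_taxa, spec.latent_rank

    sample_eff = rng.normal(0.0, 0.4, size=n)
    taxon_eff = rng.normal(0.0, 0.8, size=m)
    U = rng.normal(0.0, 1.0, size=(n, r))
    V = rng.normal(0.0, 1.0, size=(r, m))
    log_mu = (
        math.log(spec.base_mean)
        + sample_eff[:, None]
        + taxon_eff[None, :]
        + (U @ V) * (0.6 / math.sqrt(r))
    )
    if spec.n_groups > 1 and spec.n_da_taxa > 0 and spec.effect_size > 0:
        groups = np.arange(n) % spec.n_groups
        shift = np.zeros((n, m))
        shift[np.ix_(groups > 0, np.arange(spec.n_da_taxa))] = spec.effect_size
        log_mu = log_mu + shift
    mu = np.exp(np.clip(log_mu, None, 20.0))

    # gamma-Poisson mixture = negative binomial with the given overdispersion
    lam = rng.gamma(shape=1.0 / spec.dispersion, scale=mu * spec.dispersion)
    counts = rng.poisson(lam).astype(float)
    if spec.zero_inflation > 0:
        dropout = rng.random((n, m)) < spec.zero_inflation
        zeroed = counts.copy()
        zeroed[dropout] = 0.0
    else:
        zeroed = counts

    dead = np.flatnonzero(zeroed.sum(axis=1) == 0)
    for i in dead:
        j = int(np.argmax(counts[i]))
        zeroed[i, j] = max(counts[i, j], 1.0)

    sample_ids = tuple(f"S{i:04d}" for i in range(n))
    taxon_ids = tuple(f"T{j:04d}" for j in range(m))
    return CountMatrix(zeroed, sample_ids, taxon_ids)


def make_complete_scheme1(matrix: CountMatrix, proportion: float) -> CountMatrix:
    """Extract a zero-free submatrix: the densest ceil(proportion * m) taxa,
    then every sample on which all of them are non-zero."""
    if not (0.0 < proportion <= 1.0):
        raise ValueError("proportion must lie in (0, 1]")
    m = matrix.n_taxa
    n_sel = math.ceil(proportion * m)
    zero_counts = np.sum(matrix.values == 0, axis=0)
    taxa = np.sort(np.argsort(zero_counts, kind="stable")[:n_sel])
    rows = np.flatnonzero(np.all(matrix.values[:, taxa] > 0, axis=1))
    if rows.size < 2 or taxa.size < 2:
        raise ValueError(
            f"no zero-free submatrix of at least 2x2 at proportion {proportion} "
            f"({rows.size} samples x {taxa.size} taxa survive)"
        )
    return CountMatrix(
        matrix.values[np.ix_(rows, taxa)],
        tuple(matrix.sample_ids[i] for i in rows),
        tuple(matrix.taxon_ids[j] for j in taxa),
    )


def make_complete_scheme2(
    matrix: CountMatrix, proportion: float, depth: int, seed: int = 0
) -> CountMatrix:
    """Extraction followed by sampling: scheme-1 submatrix, then a multinomial
    resample of each sample at the given depth (rows sum to ``depth``)."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    extracted = make_complete_scheme1(matrix, proportion)
    return downsample_depth(extracted, depth, seed)


def inject_dropout(complete: CountMatrix, rate: float, seed: int = 0) -> CorruptionExperiment:
    """Zero floor(rate * #nonzero) non-zero entries uniformly without replacement."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("dropout rate must lie in [0, 1)")
    nz = np.argwhere(complete.values > 0)
    if nz.shape[0] == 0:
        raise ValueError("complete matrix has no non-zero entries")
    n_drop = int(math.floor(rate * nz.shape[0]))
    rng = np.random.default_rng(seed)
    chosen = nz[rng.choice(nz.shape[0], size=n_drop, replace=False)] if n_drop else nz[:0]
    corrupted = complete.values.copy()
    if n_drop:
        corrupted[chosen[:, 0], chosen[:, 1]] = 0.0
    return CorruptionExperiment(
        complete=complete,
        corrupted=complete.with_values(corrupted),
        injected_mask=MatrixMask(chosen, complete.shape),
        rate=rate,
        seed=seed,
    )


def restore_from_mask(experiment: CorruptionExperiment) -> CountMatrix:
    """Undo a corruption using its mask; returns a matrix equal to ``complete``."""
    values = experiment.corrupted.values.copy()
    mask = experiment.injected_mask.to_boolean()
    values[mask] = experiment.complete.values[mask]
    return experiment.corrupted.with_values(values)


def downsample_depth(matrix: CountMatrix, depth: int, seed: int = 0) -> CountMatrix:
    """Multinomial resample of each sample at a fixed sequencing depth.

    Each row is redrawn as Multinomial(depth, row / row_sum); row sums equal
    ``depth`` exactly.  Lower depths produce more sampling zeros.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    row_sums = matrix.values.sum(axis=1)
    if np.any(row_sums == 0):
        i = int(np.flatnonzero(row_sums == 0)[0])
        raise ValueError(f"sample {matrix.sample_ids[i]!r} has zero total count")
    rng = np.random.default_rng(seed)
    out = np.empty_like(matrix.values)
    for i in range(matrix.n_samples):
        out[i] = rng.multinomial(depth, matrix.values[i] / row_sums[i])
    return matrix.with_values(out)


def make_outlier(
    matrix: CountMatrix,
    sample_index: int,
    n_outlier_taxa: int | str = "auto",
    seed: int = 0,
) -> CountMatrix:
    """Turn one sample into an outlier.

    Eligible taxa have mean abundance below the across-taxa median of means
    and at least 10 non-zero entries.  Each chosen taxon's value in the target
    sample is drawn uniformly from that taxon's top-100 observed non-zero
    abundances (or all of them when fewer than 100 exist); every other taxon
    in the sample is set to zero.
    """
    if not (0 <= sample_index < matrix.n_samples):
        raise ValueError("sample_index out of range")
    values = matrix.values
    means = values.mean(axis=0)
    eligible = np.flatnonzero(
        (means < np.median(means)) & (np.sum(values > 0, axis=0) >= 10)
    )
    if n_outlier_taxa == "auto":
        chosen_count = eligible.size
    else:
        chosen_count = int(n_outlier_taxa)
    if chosen_count > eligible.size or chosen_count < 1:
        raise ValueError(
            f"requested {chosen_count} outlier taxa but only {eligible.size} are eligible"
        )
    rng = np.random.default_rng(seed)
    chosen = (
        eligible
        if chosen_count == eligible.size
        else np.sort(rng.choice(eligible, size=chosen_count, replace=False))
    )
    new_row = np.zeros(matrix.n_taxa)
    for j in chosen:
        col = values[:, j]
        pool = np.sort(col[col > 0])[::-1][:100]
        new_row[j] = rng.choice(pool)
    out = values.copy()
    out[sample_index] = new_row
    return matrix.with_values(out)
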