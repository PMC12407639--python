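"""Recovery scoring: masked MSE, per-taxon correlations, identification rate
and standard major axis (SMA) regression.

All comparisons default to logged space -- log10 of the TSS-normalized
matrices -- which is where the pipeline operates and where correlation-based
recovery is conventionally reported for abundance data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .impute import ImputationResult
from .matrix import MatrixMask
from .preprocess import log_transform, normalize_library_size
from .simulate import CorruptionExperiment

__all__ = [
    "EvaluationReport",
    "masked_mse",
    "per_taxon_correlation",
    "identification_rate",
    "sma_fit",
    "recovery_report",
]


def masked_mse(a: np.ndarray, b: np.ndarray, mask: MatrixMask | str = "all") -> float:
    """Mean squared difference over the mask coordinates (or all entries)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must have equal shapes")
    if isinstance(mask, str):
        if mask != "all":
            raise ValueError("mask must be a MatrixMask or 'all'")
        diff = a - b
    else:
        if len(mask) == 0:
            raise ValueError("mask is empty")
        idx = mask.indices
        diff = a[idx[:, 0], idx[:, 1]] - b[idx[:, 0], idx[:, 1]]
    return float(np.mean(diff * diff))


def per_taxon_correlation(
    a: np.ndarray, b: np.ndarray, method: str = "pearson"
) -> tuple[np.ndarray, float, int]:
    """Column-wise correlation between two matrices.

    Returns ``(per_column, mean_over_defined, n_excluded)``.  Columns with
    zero variance in either matrix are undefined (NaN) and excluded from the
    mean rather than silently zeroed, which would bias it.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must have equal shapes")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    m = a.shape[1]
    out = np.full(m, np.nan)
    for j in range(m):
        x, y = a[:, j], b[:, j]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        if method == "pearson":
            out[j] = stats.pearsonr(x, y).statistic
        else:
            out[j] = stats.spearmanr(x, y).statistic
    defined = np.isfinite(out)
    mean = float(np.mean(out[defined])) if defined.any() else float("nan")
    return out, mean, int(m - defined.sum())


def identification_rate(result: ImputationResult, mask: MatrixMask) -> float:
    """Fraction of injected zeros that imputation restored to non-zero values."""
    if len(mask) == 0:
        raise ValueError("mask is empty")
    if not mask.is_subset_of(result.input_zero_mask):
        raise ValueError("mask contains coordinates that were not zero in the input")
    idx = mask.indices
    return float(np.mean(result.imputed_logged[idx[:, 0], idx[:, 1]] > 0))


def sma_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Standard major axis regression: slope = sign(r) * sd(y) / sd(x).

    Returns (slope, intercept, pearson_r).  SMA is symmetric in x and y up to
    slope inversion, which makes it the conventional fit for comparing two
    abundance measurements that are both subject to error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors with >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("SMA regression is undefined for constant input")
    r = float(stats.pearsonr(x, y).statistic)
    slope = float(np.sign(r) if r != 0 else 1.0) * float(np.std(y, ddof=1) / np.std(x, ddof=1))
    intercept = float(np.mean(y) - slope * np.mean(x))
    return slope, intercept, r


@dataclass(frozen=True)
class EvaluationReport:
    """Recovery metrics for one corruption experiment + imputation run."""

    space: str
    mse: float
    baseline_mse: float
    pearson_per_taxon: np.ndarray
    spearman_per_taxon: np.ndarray
    mean_pearson: float
    mean_spearman: float
    baseline_mean_pearson: float
    baseline_mean_spearman: float
    identification_rate: float
    n_excluded_taxa: int
    provenance: dict

    def to_flat_dict(self) -> dict[str, float]:
        return {
            "space": self.space,
            "mse": self.mse,
            "baseline_mse": self.baseline_mse,
            "mean_pearson": self.mean_pearson,
            "mean_spearman": self.mean_spearman,
            "baseline_mean_pearson": self.baseline_mean_pearson,
            "baseline_mean_spearman": self.baseline_mean_spearman,
            "identification_rate": self.identification_rate,
            "n_excluded_taxa": self.n_excluded_taxa,
        }

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, value in self.to_flat_dict().items():
                fh.write(f"{key}\t{value}\n")


def _logged_view(values: np.ndarray, target: float) -> np.ndarray:
    from .matrix import CountMatrix

    # normalize_library_size needs a CountMatrix only for sample names in errors;
    # build a thin wrapper
    n, m = values.shape
    cm = CountMatrix(values, tuple(map(str, range(n))), tuple(f"t{j}" for j in range(m)))
    return log_transform(normalize_library_size(cm, target))


def recovery_report(
    experiment: CorruptionExperiment,
    result: ImputationResult,
    space: str = "logged",
) -> EvaluationReport:
    """Score an imputation run against the ground-truth complete matrix.

    Computes the masked MSE of imputed vs complete on the injected-zero mask,
    per-taxon Pearson/Spearman of imputed vs complete alongside the
    corrupted-vs-complete (non-imputed) baseline, and the identification rate.
    ``space`` selects logged (default) or normalized-count values.
    """
    if space not in ("logged", "normalized"):
        raise ValueError("space must be 'logged' or 'normalized'")
    if experiment.corrupted.sample_ids != result.sample_ids or (
        experiment.corrupted.taxon_ids != result.taxon_ids
    ):
        raise ValueError("imputation result does not derive from this experiment's matrix")
    corrupted_zeros = MatrixMask.from_boolean(experiment.corrupted.values == 0)
    if not np.array_equal(corrupted_zeros.indices, result.input_zero_mask.indices):
        raise ValueError(
            "imputation result's zero pattern does not match the corrupted matrix"
        )

    target = float(result.config_snapshot.get("target_library_size", 1e6))
    if space == "logged":
        complete = _logged_view(experiment.complete.values, target)
        corrupted = _logged_view(experiment.corrupted.values, target)
        imputed = result.imputed_logged
    else:
        complete = normalize_library_size(experiment.complete, target)
        corrupted = normalize_library_size(experiment.corrupted, target)
        imputed = result.imputed_normalized

    mask = experiment.injected_mask
    pearson, mean_pearson, n_excl = per_taxon_correlation(imputed, complete, "pearson")
    spearman, mean_spearman, _ = per_taxon_correlation(imputed, complete, "spearman")
    _, base_pearson, _ = per_taxon_correlation(corrupted, complete, "pearson")
    _, base_spearman, _ = per_taxon_correlation(corrupted, complete, "spearman")

    return EvaluationReport(
        space=space,
        mse=masked_mse(imputed, complete, mask),
        baseline_mse=masked_mse(corrupted, complete, mask),
        pearson_per_taxon=pearson,
        spearman_per_taxon=spearman,
        mean_pearson=mean_pearson,
        mean_spearman=mean_spearman,
        baseline_mean_pearson=base_pearson,
        baseline_mean_spearman=base_spearman,
        identification_rate=identification_rate(result, mask),
        n_excluded_taxa=n_excl,
        provenance={
            "rate": experiment.rate,
            "corruption_seed": experiment.seed,
            "imputation_seed": result.seed,
            "n_masked": len(mask),
        },
    )
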