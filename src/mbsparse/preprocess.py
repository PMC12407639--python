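"""Library-size normalization and log transform.

Every sample (row) is scaled to a common total count -- total-sum scaling to
10^6 by default -- and then mapped through log10(x + 1).  All model training
and imputation happen in the logged space X; the inverse map recovers the
normalized-count scale on demand.  Zeros are fixed points of the whole chain,
so the input's zero pattern is exactly the zero pattern of X.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import CountMatrix, MatrixMask

__all__ = [
    "TransformedMatrix",
    "normalize_library_size",
    "log_transform",
    "inverse_transform",
    "transform",
]

DEFAULT_LIBRARY_SIZE = 1e6


def normalize_library_size(matrix: CountMatrix, target: float = DEFAULT_LIBRARY_SIZE) -> np.ndarray:
    """Scale each sample so its total count equals ``target`` (TSS).

    M'_ij = target * M_ij / sum_j' M_ij'.  Rows summing to zero cannot be
    normalized and are rejected by name.
    """
    if target <= 0:
        raise ValueError(f"target library size must be positive, got {target}")
    row_sums = matrix.values.sum(axis=1)
    zero_rows = np.flatnonzero(row_sums == 0)
    if zero_rows.size:
        raise ValueError(
            f"sample {matrix.sample_ids[zero_rows[0]]!r} has zero total count "
            "and cannot be library-size normalized"
        )
    return target * matrix.values / row_sums[:, None]


def log_transform(normalized: np.ndarray) -> np.ndarray:
    """X_ij = log10(M'_ij + 1); zeros map to zeros."""
    normalized = np.asarray(normalized, dtype=float)
    if np.any(normalized < 0):
        raise ValueError("log transform requires non-negative input")
    return np.log10(normalized + 1.0)


def inverse_transform(logged: np.ndarray) -> np.ndarray:
    """Inverse of :func:`log_transform`: 10^X - 1, back on the normalized-count scale."""
    logged = np.asarray(logged, dtype=float)
    if np.any(logged < 0):
        raise ValueError("inverse transform requires non-negative input")
    return np.power(10.0, logged) - 1.0


@dataclass(frozen=True)
class TransformedMatrix:
    """Normalized (M') and logged (X) views of a count matrix, plus its zero mask."""

    source: CountMatrix
    normalized: np.ndarray
    logged: np.ndarray
    target_library_size: float
    zero_mask: MatrixMask

    @property
    def shape(self) -> tuple[int, int]:
        return self.logged.shape


def transform(
    matrix: CountMatrix,
    target_library_size: float = DEFAULT_LIBRARY_SIZE,
    method: str = "log_tss",
) -> TransformedMatrix:
    """Full preprocessing chain: TSS normalization then log10(x+1).

    ``method="none"`` skips normalization (the caller pre-normalized) but still
    applies the log transform, keeping all downstream stages in logged space.
    """
    if method not in ("log_tss", "none"):
        raise ValueError(f"unknown normalization method {method!r}")
    if method == "log_tss":
        normalized = normalize_library_size(matrix, target_library_size)
    else:
        normalized = matrix.values.astype(float).copy()
    logged = log_transform(normalized)
    zero_mask = MatrixMask.from_boolean(matrix.values == 0)
    return TransformedMatrix(
        source=matrix,
        normalized=normalized,
        logged=logged,
        target_library_size=target_library_size,
        zero_mask=zero_mask,
    )
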