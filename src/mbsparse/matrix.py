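"""Count-matrix data model and delimited-text / BIOM I/O.

The shared in-memory container for every stage of the pipeline is
:class:`CountMatrix`: a dense samples x taxa array of non-negative reals with
unique string labels on both axes.  Zeros are meaningful (they are the
imputation target), so there is no separate missing-value sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "MatrixMask", "read_count_matrix", "write_count_matrix"]

Orientation = Literal["samples_as_rows", "taxa_as_rows"]


@dataclass(frozen=True)
class CountMatrix:
    """Observed taxonomic counts: rows are samples, columns are taxa.

    Entries may be real-valued (relative-abundance profiles from taxonomic
    profilers are not integers); integer-ness is never assumed downstream.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))
        if values.ndim != 2:
            raise ValueError(f"count matrix must be 2-D, got {values.ndim}-D")
        n, m = values.shape
        if n < 2 or m < 2:
            raise ValueError(
                f"need at least 2 samples and 2 taxa, got {n} samples x {m} taxa"
            )
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.taxon_ids) != m:
            raise ValueError(f"{len(self.taxon_ids)} taxon ids for {m} columns")
        for kind, ids in (("sample", self.sample_ids), ("taxon", self.taxon_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if list(ids).count(x) > 1})
                raise ValueError(f"duplicate {kind} ids: {dupes[:5]}")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite entry at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative entry {values[i, j]} at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def zero_fraction(self) -> float:
        return float(np.mean(self.values == 0))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.taxon_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(df.to_numpy(dtype=float), tuple(df.index.astype(str)), tuple(df.columns.astype(str)))

    def with_values(self, values: np.ndarray) -> "CountMatrix":
        """Same labels, new values (shape must match)."""
        return CountMatrix(values, self.sample_ids, self.taxon_ids)

    def transpose(self) -> "CountMatrix":
        return CountMatrix(self.values.T, self.taxon_ids, self.sample_ids)


@dataclass(frozen=True)
class MatrixMask:
    """A set of (sample_index, taxon_index) coordinates within an n x m matrix.

    Used to record which zeros a corruption experiment injected, and which
    zeros an imputation run filled.
    """

    indices: np.ndarray  # (k, 2) int array, unique rows
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int).reshape(-1, 2)
        idx = np.unique(idx, axis=0) if idx.size else idx
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "shape", (int(self.shape[0]), int(self.shape[1])))
        if idx.size:
            if idx.min() < 0 or np.any(idx[:, 0] >= self.shape[0]) or np.any(
                idx[:, 1] >= self.shape[1]
            ):
                raise ValueError("mask coordinates fall outside the matrix shape")

    def __len__(self) -> int:
        return self.indices.shape[0]

    def __contains__(self, coord: tuple[int, int]) -> bool:
        if len(self) == 0:
            return False
        return bool(np.any((self.indices[:, 0] == coord[0]) & (self.indices[:, 1] == coord[1])))

    def to_boolean(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        if len(self):
            out[self.indices[:, 0], self.indices[:, 1]] = True
        return out

    def is_disjoint(self, other: "MatrixMask") -> bool:
        if self.shape != other.shape:
            raise ValueError("masks have different shapes")
        return not np.any(self.to_boolean() & other.to_boolean())

    def is_subset_of(self, other: "MatrixMask") -> bool:
        if self.shape != other.shape:
            raise ValueError("masks have different shapes")
        return bool(np.all(~self.to_boolean() | other.to_boolean()))

    @classmethod
    def from_boolean(cls, mask: np.ndarray) -> "MatrixMask":
        mask = np.asarray(mask, dtype=bool)
        return cls(np.argwhere(mask), mask.shape)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]], shape: tuple[int, int]) -> "MatrixMask":
        arr = np.array(list(pairs), dtype=int).reshape(-1, 2)
        return cls(arr, shape)


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    if path.suffix.lower() == ".csv":
        return ","
    return "\t"


def read_count_matrix(
    path: str | Path,
    orientation: Orientation = "samples_as_rows",
    delimiter: str | None = None,
) -> CountMatrix:
    """Read a count matrix from delimited text (TSV/CSV) or BIOM 2.x.

    The on-disk convention is one header row of labels and one leading label
    column; ``orientation`` states which axis the file's rows represent, and
    the returned matrix is always samples x taxa.  BIOM files (``.biom``)
    follow the BIOM convention (observations/taxa as rows) and ignore
    ``orientation``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".biom":
        return _read_biom(path)

    sep = _infer_delimiter(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate column labels in {path}: {dupes[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell {df.iat[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"missing cell at row {df.index[i]!r}, column {df.columns[j]!r} in {path}")
    matrix = CountMatrix.from_dataframe(numeric)
    if orientation == "taxa_as_rows":
        matrix = matrix.transpose()
    return matrix


def _read_biom(path: Path) -> CountMatrix:
    try:
        import biom
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading .biom files requires the biom-format package "
            "(pip install mbsparse[biom])"
        ) from exc
    table = biom.load_table(str(path))
    # BIOM stores observations (taxa) as rows, samples as columns.
    values = np.asarray(table.matrix_data.todense(), dtype=float).T
    return CountMatrix(values, tuple(table.ids("sample")), tuple(table.ids("observation")))


def write_count_matrix(
    matrix: CountMatrix,
    path: str | Path,
    precision: int = 6,
    delimiter: str | None = None,
) -> None:
    """Write a count matrix as delimited text (rows = samples).

    Round-tripping through :func:`read_count_matrix` preserves labels exactly
    and values to within ``10**-precision``.
    """
    path = Path(path)
    df = matrix.to_dataframe()
    df.index.name = "sample_id"
    try:
        df.to_csv(
            path,
            sep=_infer_delimiter(path, delimiter),
            float_format=f"%.{precision}f" if precision > 0 else "%.0f",
        )
    except OSError as exc:
        raise OSError(f"could not write count matrix to {path}: {exc}") from exc
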