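"""The end-to-end imputation pipeline and the zero-filling rule.

Zero filling: for every entry with X_ij = 0, the imputed value is the average
over the k neighbors of sample i of the real neighbor value and the neighbor's
conditional sample value,

    X_ij <- (1 / 2K) * sum_{k in N_i} (X_kj + X^c_kj),

while every non-zero entry keeps its original value bit-exactly.  A filled
zero can remain zero: if all neighbors (real and conditional) are zero for
that taxon, the entry is treated as a plausible biological zero.

Ablation variants are first-class pipeline modes:

* ``no_fae``  -- the KNN graph is built on the raw logged profiles instead of
  autoencoder embeddings;
* ``no_cvae`` -- the filling rule degenerates to the real-neighbor mean
  (1/K) sum X_kj;
* ``neither`` -- both substitutions at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .config import PipelineConfig
from .cvae import generate_conditional_samples, make_training_pairs, train_cvae
from .fae import embed, train_fae
from .graph import SampleGraph, build_knn_graph
from .matrix import CountMatrix, MatrixMask
from .preprocess import inverse_transform, transform

__all__ = ["ImputationResult", "fill_zeros", "run_mbsparse"]


@dataclass(frozen=True)
class ImputationResult:
    """Imputed matrices (logged and normalized-count scale) plus provenance."""

    imputed_logged: np.ndarray
    imputed_normalized: np.ndarray
    filled_mask: MatrixMask        # zeros that became non-zero
    input_zero_mask: MatrixMask    # zeros of the input (imputation targets)
    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    config_snapshot: dict[str, Any]
    seed: int
    stage_log: dict[str, Any] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.imputed_logged.shape

    def n_filled(self) -> int:
        return len(self.filled_mask)


def fill_zeros(
    X: np.ndarray,
    graph: SampleGraph,
    X_cond: np.ndarray | None,
) -> tuple[np.ndarray, MatrixMask]:
    """Apply the zero-filling rule in logged space.

    With ``X_cond`` present each zero gets (1/2K) sum_k (X_kj + X^c_kj) over
    the k = |N_i| neighbors of its sample; with ``X_cond=None`` (the no-CVAE
    variant) it gets the plain neighbor mean (1/K) sum_k X_kj.  Non-zero
    entries are returned untouched.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if graph.n != n:
        raise ValueError("graph and matrix disagree on the number of samples")
    if graph.k == 0 or np.any(graph.out_degrees() == 0):
        raise ValueError("every sample needs at least one neighbor")
    A = graph.adjacency.astype(float)
    K = float(graph.k)
    if X_cond is None:
        fill = (A @ X) / K
    else:
        X_cond = np.asarray(X_cond, dtype=float)
        if X_cond.shape != X.shape:
            raise ValueError("conditional matrix shape does not match X")
        fill = (A @ (X + X_cond)) / (2.0 * K)

    zero = X == 0
    imputed = np.where(zero, fill, X)
    filled = MatrixMask.from_boolean(zero & (imputed > 0))
    return imputed, filled


def run_mbsparse(matrix: CountMatrix, config: PipelineConfig | None = None) -> ImputationResult:
    """Run the full pipeline: normalize -> log -> embed -> KNN graph -> CVAE ->
    conditional samples -> zero filling.

    Fully reproducible given ``config.seed``; per-stage summaries (loss traces,
    graph stats, fill counts) are collected in ``stage_log``.
    """
    config = (config or PipelineConfig()).resolve_seeds()
    if config.k >= matrix.n_samples:
        raise ValueError(
            f"k={config.k} requires more than {matrix.n_samples} samples"
        )
    log: dict[str, Any] = {}

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    tm = stage("preprocess", transform, matrix, config.target_library_size, config.normalize_method)
    X = tm.logged
    log["zero_fraction"] = matrix.zero_fraction()
    log["shape"] = matrix.shape

    if config.variant in ("no_fae", "neither"):
        Z = X
        log["fae"] = "skipped (variant)"
    else:
        fae_model = stage("fae", train_fae, X, config.fae)
        Z = stage("embed", embed, fae_model, X)
        log["fae"] = {
            "loss_first": fae_model.training_loss_trace[0],
            "loss_last": fae_model.training_loss_trace[-1],
        }

    graph = stage("graph", build_knn_graph, Z, config.k)
    log["graph"] = {"k": graph.k, "mean_knn_distance": float(graph.distances.mean())}

    if config.variant in ("no_cvae", "neither"):
        X_cond = None
        log["cvae"] = "skipped (variant)"
    else:
        pairs = stage("pairs", make_training_pairs, graph)
        cvae_model = stage("cvae", train_cvae, X, pairs, config.cvae)
        rng = np.random.default_rng(config.generation_seed())
        X_cond = stage("generate", generate_conditional_samples, cvae_model, X, rng)
        log["cvae"] = {
            "elbo_first": cvae_model.elbo_trace[0],
            "elbo_last": cvae_model.elbo_trace[-1],
            "n_pairs": len(pairs),
        }

    imputed_logged, filled = stage("fill", fill_zeros, X, graph, X_cond)
    log["n_zeros"] = len(tm.zero_mask)
    log["n_filled"] = len(filled)

    return ImputationResult(
        imputed_logged=imputed_logged,
        imputed_normalized=inverse_transform(imputed_logged),
        filled_mask=filled,
        input_zero_mask=tm.zero_mask,
        sample_ids=matrix.sample_ids,
        taxon_ids=matrix.taxon_ids,
        config_snapshot=config.to_dict(),
        seed=config.seed,
        stage_log=log,
    )
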