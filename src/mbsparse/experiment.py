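"""Scripted end-to-end benchmarks: simulate -> corrupt -> impute -> evaluate.

Each runner repeats its protocol over R replicates with per-replicate seeds
derived from one global seed, and returns per-replicate reports plus
mean +/- standard-deviation summaries.  These are the programmatic backbone of
the ``mbsparse experiment`` CLI subcommand and of the acceptance script.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .config import PipelineConfig, derive_seed
from .evaluate import EvaluationReport, masked_mse, recovery_report
from .impute import run_mbsparse
from .matrix import MatrixMask
from .preprocess import log_transform, normalize_library_size
from .simulate import (
    CorruptionExperiment,
    SyntheticSpec,
    downsample_depth,
    inject_dropout,
    make_outlier,
    synthesize_count_matrix,
)

__all__ = [
    "ReplicateSummary",
    "summarize",
    "run_recovery_replicates",
    "run_depth_benchmark",
    "run_ablation_benchmark",
    "run_outlier_benchmark",
    "run_experiment",
]


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean and standard deviation of a metric over replicates."""

    name: str
    values: tuple[float, ...]
    mean: float
    sd: float

    @classmethod
    def of(cls, name: str, values: Sequence[float]) -> "ReplicateSummary":
        arr = np.asarray(values, dtype=float)
        return cls(name, tuple(arr.tolist()), float(arr.mean()),
                   float(arr.std(ddof=1)) if arr.size > 1 else 0.0)


def summarize(per_replicate: Sequence[dict[str, float]]) -> dict[str, ReplicateSummary]:
    keys = [k for k, v in per_replicate[0].items() if isinstance(v, (int, float))]
    return {
        k: ReplicateSummary.of(k, [rep[k] for rep in per_replicate]) for k in keys
    }


def _one_recovery_replicate(
    spec: SyntheticSpec,
    dropout_rate: float,
    config: PipelineConfig,
    replicate: int,
    global_seed: int,
    variant: str = "full",
) -> tuple[CorruptionExperiment, EvaluationReport]:
    spec_rep = replace(spec, seed=derive_seed(global_seed, "simulate", replicate))
    complete = synthesize_count_matrix(spec_rep)
    exp = inject_dropout(complete, dropout_rate, seed=derive_seed(global_seed, "dropout", replicate))
    cfg = replace_config(config, variant=variant, seed=derive_seed(global_seed, "impute", replicate))
    result = run_mbsparse(exp.corrupted, cfg)
    return exp, recovery_report(exp, result)


def replace_config(config: PipelineConfig, **updates: Any) -> PipelineConfig:
    data = config.to_dict()
    data.update(updates)
    return PipelineConfig.from_dict(data)


def run_recovery_replicates(
    spec: SyntheticSpec,
    dropout_rate: float = 0.2,
    n_replicates: int = 10,
    seed: int = 0,
    config: PipelineConfig | None = None,
    variant: str = "full",
) -> tuple[list[dict[str, float]], dict[str, ReplicateSummary]]:
    """Dropout-recovery benchmark: per-replicate recovery reports + summary."""
    config = config or PipelineConfig()
    reports = []
    for rep in range(n_replicates):
        _, report = _one_recovery_replicate(spec, dropout_rate, config, rep, seed, variant)
        reports.append(report.to_flat_dict())
    return reports, summarize(reports)


def run_ablation_benchmark(
    spec: SyntheticSpec,
    dropout_rate: float = 0.2,
    n_replicates: int = 10,
    seed: int = 0,
    config: PipelineConfig | None = None,
    variants: Sequence[str] = ("full", "no_fae", "no_cvae", "neither"),
) -> dict[str, dict[str, ReplicateSummary]]:
    """Run the recovery benchmark once per pipeline variant on shared data.

    The same complete matrices and dropout masks are reused across variants so
    differences reflect the pipeline, not the corruption draw.
    """
    config = config or PipelineConfig()
    out: dict[str, list[dict[str, float]]] = {v: [] for v in variants}
    for rep in range(n_replicates):
        spec_rep = replace(spec, seed=derive_seed(seed, "simulate", rep))
        complete = synthesize_count_matrix(spec_rep)
        exp = inject_dropout(complete, dropout_rate, seed=derive_seed(seed, "dropout", rep))
        for variant in variants:
            cfg = replace_config(config, variant=variant,
                                 seed=derive_seed(seed, "impute", rep))
            result = run_mbsparse(exp.corrupted, cfg)
            out[variant].append(recovery_report(exp, result).to_flat_dict())
    return {v: summarize(reps) for v, reps in out.items()}


def run_depth_benchmark(
    spec: SyntheticSpec | None = None,
    depths: Sequence[int] = (1000, 2000, 5000, 10000),
    n_replicates: int = 10,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> dict[int, dict[str, ReplicateSummary]]:
    """Sequencing-depth robustness: downsample a dense complete matrix at each
    depth, impute, and score against the complete matrix on the logged scale.

    Downsampling perturbs every entry (resampling noise) besides introducing
    sampling zeros, so the primary score (``mse``) is taken over all entries;
    ``mse_sampling_zeros`` restricts to the coordinates the downsampling
    zeroed (non-zero in the complete matrix, zero after downsampling).
    """
    spec = spec or SyntheticSpec(n_samples=60, n_taxa=200, zero_inflation=0.0)
    config = config or PipelineConfig()
    target = config.target_library_size
    out: dict[int, list[dict[str, float]]] = {d: [] for d in depths}
    for rep in range(n_replicates):
        spec_rep = replace(spec, seed=derive_seed(seed, "simulate", rep))
        complete = synthesize_count_matrix(spec_rep)
        complete_logged = log_transform(normalize_library_size(complete, target))
        for depth in depths:
            down = downsample_depth(
                complete, depth, seed=derive_seed(seed, f"depth{depth}", rep)
            )
            mask_bool = (complete.values > 0) & (down.values == 0)
            if not mask_bool.any():
                continue
            mask = MatrixMask.from_boolean(mask_bool)
            cfg = replace_config(config, seed=derive_seed(seed, "impute", rep))
            result = run_mbsparse(down, cfg)
            down_logged = log_transform(normalize_library_size(down, target))
            out[depth].append(
                {
                    "mse": masked_mse(result.imputed_logged, complete_logged, "all"),
                    "baseline_mse": masked_mse(down_logged, complete_logged, "all"),
                    "mse_sampling_zeros": masked_mse(result.imputed_logged, complete_logged, mask),
                    "baseline_mse_sampling_zeros": masked_mse(down_logged, complete_logged, mask),
                    "zero_fraction": down.zero_fraction(),
                    "n_masked": float(len(mask)),
                }
            )
    return {d: summarize(reps) for d, reps in out.items() if reps}


def run_outlier_benchmark(
    spec: SyntheticSpec,
    dropout_rate: float = 0.2,
    n_outliers: Sequence[int] = (1, 2, 3),
    n_replicates: int = 10,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> dict[int, dict[str, ReplicateSummary]]:
    """Outlier robustness: corrupt, then rebuild 0..max outlier samples.

    Masked coordinates falling in outlier rows are excluded from scoring
    (those rows no longer carry recoverable signal by construction).  The key
    0 is the outlier-free reference on the identical corruption draws.
    """
    config = config or PipelineConfig()
    target = config.target_library_size
    levels = [0, *n_outliers]
    out: dict[int, list[dict[str, float]]] = {lv: [] for lv in levels}
    for rep in range(n_replicates):
        spec_rep = replace(spec, seed=derive_seed(seed, "simulate", rep))
        complete = synthesize_count_matrix(spec_rep)
        exp = inject_dropout(complete, dropout_rate, seed=derive_seed(seed, "dropout", rep))
        complete_logged = log_transform(normalize_library_size(complete, target))
        rng = np.random.default_rng(derive_seed(seed, "outlier-pick", rep))
        outlier_rows = rng.choice(complete.n_samples, size=max(n_outliers), replace=False)
        for level in levels:
            matrix = exp.corrupted
            for idx, row in enumerate(outlier_rows[:level]):
                matrix = make_outlier(
                    matrix, int(row), "auto",
                    seed=derive_seed(seed, f"outlier{idx}", rep),
                )
            keep = ~np.isin(exp.injected_mask.indices[:, 0], outlier_rows[:level])
            mask = MatrixMask(exp.injected_mask.indices[keep], complete.shape)
            if len(mask) == 0:
                continue
            cfg = replace_config(config, seed=derive_seed(seed, "impute", rep))
            result = run_mbsparse(matrix, cfg)
            corrupted_logged = log_transform(normalize_library_size(matrix, target))
            out[level].append(
                {
                    "mse": masked_mse(result.imputed_logged, complete_logged, mask),
                    "baseline_mse": masked_mse(corrupted_logged, complete_logged, mask),
                    "n_masked": float(len(mask)),
                }
            )
    return {lv: summarize(reps) for lv, reps in out.items() if reps}


def run_experiment(
    out_dir: str | Path,
    spec: SyntheticSpec | None = None,
    dropout_rate: float = 0.2,
    n_replicates: int = 5,
    seed: int = 0,
    config: PipelineConfig | None = None,
    variant: str = "full",
) -> Path:
    """Run the recovery protocol and write per-replicate + summary artifacts.

    The output directory gets a config snapshot, one report TSV per replicate
    and a ``summary.json`` with mean +/- sd per metric.  Deterministic in
    (seed, config): a rerun writes byte-identical artifacts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = spec or SyntheticSpec()
    config = config or PipelineConfig()
    reports, summary = run_recovery_replicates(
        spec, dropout_rate, n_replicates, seed, config, variant
    )
    snapshot = {
        "pipeline": config.to_dict(),
        "spec": spec.__dict__,
        "dropout_rate": dropout_rate,
        "n_replicates": n_replicates,
        "seed": seed,
        "variant": variant,
    }
    (out_dir / "config_snapshot.json").write_text(json.dumps(snapshot, indent=2, sort_keys=True))
    for rep, report in enumerate(reports):
        with open(out_dir / f"replicate_{rep:03d}.tsv", "w") as fh:
            for key, value in report.items():
                fh.write(f"{key}\t{value}\n")
    summary_payload = {
        name: {"mean": s.mean, "sd": s.sd, "values": list(s.values)}
        for name, s in summary.items()
    }
    (out_dir / "summary.json").write_text(json.dumps(summary_payload, indent=2, sort_keys=True))
    return out_dir
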