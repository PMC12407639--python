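import numpy as np
import pytest

from mbsparse import CountMatrix, CVAEConfig, FAEConfig, PipelineConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_counts() -> CountMatrix:
    """A 4x5 integer count matrix with a few zeros."""
    values = np.array(
        [
            [10, 0, 3, 7, 0],
            [2, 5, 0, 1, 4],
            [0, 8, 6, 0, 2],
            [9, 1, 4, 3, 0],
        ],
        dtype=float,
    )
    return CountMatrix(values, ("s1", "s2", "s3", "s4"), ("t1", "t2", "t3", "t4", "t5"))


def tiny_pipeline_config(seed: int = 0, variant: str = "full", k: int = 3) -> PipelineConfig:
    """A pipeline config scaled for matrices with a few dozen taxa, for fast tests."""
    return PipelineConfig(
        fae=FAEConfig(hidden_dim=32, embedding_dim=8, epochs=60, seed=seed),
        cvae=CVAEConfig(latent_dim=4, hidden_dim=32, condition_proj_dim=4, epochs=60, seed=seed),
        k=k,
        variant=variant,
        seed=seed,
    )


def random_counts(rng: np.random.Generator, n: int = 20, m: int = 30,
                  zero_fraction: float = 0.3) -> CountMatrix:
    values = rng.integers(1, 500, size=(n, m)).astype(float)
    mask = rng.random((n, m)) < zero_fraction
    values[mask] = 0.0
    # keep every row normalizable
    values[values.sum(axis=1) == 0, 0] = 1.0
    return CountMatrix(values, tuple(f"s{i}" for i in range(n)), tuple(f"t{j}" for j in range(m)))
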