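"""Feature autoencoder: per-sample embeddings from logged abundance profiles.

The encoder maps each sample's m-dimensional logged profile through a 512-unit
hidden layer to a d-dimensional (default 128) non-negative embedding Z; the
decoder mirrors it back (128 -> 512 -> m).  Training minimizes the squared
reconstruction error between X and the decoder output.  The embeddings feed
the KNN sample-correlation graph, so all that matters downstream is that
nearby samples have similar profiles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._nn import Adam, Dense, minibatches, relu, relu_grad, softplus, softplus_grad

__all__ = ["FAEConfig", "FAEModel", "train_fae", "embed"]


@dataclass
class FAEConfig:
    hidden_dim: int = 512
    embedding_dim: int = 128
    epochs: int = 150
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0

    def validate(self, n_taxa: int) -> None:
        if self.embedding_dim <= 0 or self.hidden_dim <= 0:
            raise ValueError("dimensions must be positive")
        if self.embedding_dim >= n_taxa:
            raise ValueError(
                f"embedding_dim ({self.embedding_dim}) must be smaller than the "
                f"number of taxa ({n_taxa})"
            )
        if self.hidden_dim < self.embedding_dim:
            raise ValueError("hidden_dim must be at least embedding_dim")
        if self.epochs <= 0 or self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("epochs, learning_rate and batch_size must be positive")


class FAEModel:
    """Trained encoder/decoder parameters plus the per-epoch loss trace."""

    def __init__(self, n_taxa: int, config: FAEConfig, rng: np.random.Generator):
        h, d = config.hidden_dim, config.embedding_dim
        self.n_taxa = n_taxa
        self.config = config
        self.enc1 = Dense(rng, n_taxa, h)
        self.enc2 = Dense(rng, h, d)
        self.dec1 = Dense(rng, d, h)
        self.dec2 = Dense(rng, h, n_taxa)
        self.training_loss_trace: list[float] = []

    @property
    def layers(self) -> list[Dense]:
        return [self.enc1, self.enc2, self.dec1, self.dec2]

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Row-wise map to the non-negative embedding space (n x d)."""
        h = relu(self.enc1.forward(X))
        return relu(self.enc2.forward(h))

    def decode(self, Z: np.ndarray) -> np.ndarray:
        h = relu(self.dec1.forward(Z))
        return softplus(self.dec2.forward(h))

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(X))

    def save(self, path) -> None:
        """Persist parameters + config to a self-describing .npz container."""
        arrays = {}
        for i, layer in enumerate(self.layers):
            arrays[f"W{i}"] = layer.W
            arrays[f"b{i}"] = layer.b
        np.savez(
            path,
            kind="fae",
            n_taxa=self.n_taxa,
            config=np.array([json.dumps(asdict(self.config))]),
            loss_trace=np.array(self.training_loss_trace),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "FAEModel":
        data = np.load(path, allow_pickle=False)
        if str(data["kind"]) != "fae":
            raise ValueError(f"{path} is not a feature-autoencoder checkpoint")
        config = FAEConfig(**json.loads(str(data["config"][0])))
        model = cls(int(data["n_taxa"]), config, np.random.default_rng(0))
        for i, layer in enumerate(model.layers):
            layer.W = data[f"W{i}"]
            layer.b = data[f"b{i}"]
        model.training_loss_trace = data["loss_trace"].tolist()
        return model

    def _forward_backward(self, X: np.ndarray) -> float:
        """One gradient evaluation on a batch; returns the batch SSE."""
        a1 = self.enc1.forward(X)
        h1 = relu(a1)
        a2 = self.enc2.forward(h1)
        z = relu(a2)
        a3 = self.dec1.forward(z)
        h2 = relu(a3)
        a4 = self.dec2.forward(h2)
        xhat = softplus(a4)

        resid = xhat - X
        sse = float(np.sum(resid * resid))
        # optimize the element-mean of the squared error; the recorded trace
        # stays on the Eq-style sum-of-squares scale
        g = (2.0 / resid.size) * resid
        g = g * softplus_grad(a4)
        g = self.dec2.backward(h2, g)
        g = g * relu_grad(a3)
        g = self.dec1.backward(z, g)
        g = g * relu_grad(a2)
        g = self.enc2.backward(h1, g)
        g = g * relu_grad(a1)
        self.enc1.backward(X, g)
        return sse


def train_fae(X: np.ndarray, config: FAEConfig | None = None) -> FAEModel:
    """Train the feature autoencoder on the logged matrix X (n x m).

    The per-epoch trace records the summed squared reconstruction error
    accumulated over the epoch's batches (evaluated before each update).
    Training is a pure function of (X, config.seed).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x taxa)")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    config = config or FAEConfig()
    config.validate(m)

    rng = np.random.default_rng(config.seed)
    model = FAEModel(m, config, rng)
    params = [p for layer in model.layers for p in layer.params]
    opt = Adam(params, lr=config.learning_rate)

    for epoch in range(config.epochs):
        epoch_sse = 0.0
        for batch in minibatches(n, config.batch_size, rng):
            sse = model._forward_backward(X[batch])
            if not np.isfinite(sse):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            epoch_sse += sse
            opt.step([g for layer in model.layers for g in layer.grads])
        model.training_loss_trace.append(epoch_sse)
    return model


def embed(model: FAEModel, X: np.ndarray) -> np.ndarray:
    """Embed samples with a trained model; deterministic, row-wise."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_taxa:
        raise ValueError(
            f"expected {model.n_taxa} taxa columns, got shape {X.shape}"
        )
    return model.encode(X)
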