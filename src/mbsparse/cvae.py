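"""Conditional variational autoencoder over sample-graph edges.

For each directed edge v -> u of the sample-correlation graph, the CVAE learns
the conditional distribution p(X_u | X_v): the recognition network
q_phi(z | X_u, X_v) maps the concatenated pair through a 256-unit hidden layer
to a diagonal-Gaussian posterior over a 10-d latent z; the decoder consumes
z concatenated with a learned 10-d linear projection of the condition X_v
(decoder input width 20) and maps 20 -> 256 -> m with a softplus output so
generated profiles stay non-negative.

Training maximizes the ELBO with a standard-normal prior over z and a
fixed-unit-variance Gaussian reconstruction likelihood in logged space:

    ELBO = -KL(q_phi(z|X_u,X_v) || N(0,I))
           + (1/S) sum_l [ -1/2 ||X_u - decode(z_l, X_v)||^2 - (m/2) log(2*pi) ]

with z_l = mu + sigma * e_l, e_l ~ N(0, I) (reparameterization).  After
training, one conditional sample X^c_v per node is generated by decoding a
prior draw z ~ N(0, I) conditioned on X_v alone, so conditional neighbors
mirror the real neighborhood structure one-for-one.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from ._nn import Adam, Dense, minibatches, relu, relu_grad, softplus, softplus_grad
from .graph import SampleGraph

__all__ = [
    "CVAEConfig",
    "CVAEModel",
    "TrainingPairSet",
    "make_training_pairs",
    "kl_gaussian",
    "elbo",
    "train_cvae",
    "generate_conditional_samples",
]

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class CVAEConfig:
    latent_dim: int = 10
    hidden_dim: int = 256
    condition_proj_dim: int = 10
    epochs: int = 150
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0
    n_mc_samples: int = 1  # Monte-Carlo draws per pair for the reconstruction term

    def validate(self) -> None:
        for name in ("latent_dim", "hidden_dim", "condition_proj_dim", "epochs",
                     "batch_size", "n_mc_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def decoder_input_dim(self) -> int:
        return self.latent_dim + self.condition_proj_dim


@dataclass(frozen=True)
class TrainingPairSet:
    """Directed-edge training pairs (condition index v, target index u), u in N_v."""

    pairs: np.ndarray  # (n_pairs, 2) int: column 0 = v (condition), 1 = u (target)

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        object.__setattr__(self, "pairs", pairs)
        if np.any(pairs[:, 0] == pairs[:, 1]):
            raise ValueError("training pairs must not contain self-loops")

    def __len__(self) -> int:
        return self.pairs.shape[0]


def make_training_pairs(graph: SampleGraph) -> TrainingPairSet:
    """One (v, u) pair per directed edge of the graph: |pairs| = n * k."""
    v = np.repeat(np.arange(graph.n), graph.k)
    u = graph.neighborhoods.ravel()
    return TrainingPairSet(np.column_stack([v, u]))


def kl_gaussian(mu: np.ndarray, logvar: np.ndarray) -> float | np.ndarray:
    """KL( N(mu, diag(exp(logvar))) || N(0, I) ), closed form.

    For batched input (b x d) returns a length-b vector; for 1-D input a float.
    Always >= 0, and 0 exactly when mu = 0 and logvar = 0.
    """
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    kl = 0.5 * np.sum(np.exp(logvar) + mu * mu - 1.0 - logvar, axis=-1)
    return float(kl) if kl.ndim == 0 else kl


class CVAEModel:
    """Recognition (phi) and generative (theta) parameters plus the ELBO trace."""

    def __init__(self, n_taxa: int, config: CVAEConfig, rng: np.random.Generator):
        config.validate()
        L, H, P = config.latent_dim, config.hidden_dim, config.condition_proj_dim
        self.n_taxa = n_taxa
        self.config = config
        # recognition network q_phi(z | X_u, X_v)
        self.enc1 = Dense(rng, 2 * n_taxa, H)
        self.mu_head = Dense(rng, H, L)
        self.lv_head = Dense(rng, H, L)
        # generative network p_theta(X_u | X_v, z)
        self.cond_proj = Dense(rng, n_taxa, P)
        self.dec1 = Dense(rng, L + P, H)
        self.dec2 = Dense(rng, H, n_taxa)
        self.elbo_trace: list[float] = []

    @property
    def layers(self) -> list[Dense]:
        return [self.enc1, self.mu_head, self.lv_head, self.cond_proj, self.dec1, self.dec2]

    def save(self, path) -> None:
        """Persist parameters + config to a self-describing .npz container
        (same scheme as the feature-autoencoder checkpoints)."""
        arrays = {}
        for i, layer in enumerate(self.layers):
            arrays[f"W{i}"] = layer.W
            arrays[f"b{i}"] = layer.b
        np.savez(
            path,
            kind="cvae",
            n_taxa=self.n_taxa,
            config=np.array([json.dumps(asdict(self.config))]),
            elbo_trace=np.array(self.elbo_trace),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "CVAEModel":
        data = np.load(path, allow_pickle=False)
        if str(data["kind"]) != "cvae":
            raise ValueError(f"{path} is not a CVAE checkpoint")
        config = CVAEConfig(**json.loads(str(data["config"][0])))
        model = cls(int(data["n_taxa"]), config, np.random.default_rng(0))
        for i, layer in enumerate(model.layers):
            layer.W = data[f"W{i}"]
            layer.b = data[f"b{i}"]
        model.elbo_trace = data["elbo_trace"].tolist()
        return model

    def encode(self, X_u: np.ndarray, X_v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior parameters (mu, logvar) for target X_u given condition X_v."""
        e_in = np.concatenate([np.atleast_2d(X_u), np.atleast_2d(X_v)], axis=1)
        h = relu(self.enc1.forward(e_in))
        return self.mu_head.forward(h), self.lv_head.forward(h)

    def decode(self, z: np.ndarray, X_v: np.ndarray) -> np.ndarray:
        """Decode latent z under condition X_v; non-negative output of width m."""
        z = np.atleast_2d(z)
        c = self.cond_proj.forward(np.atleast_2d(X_v))
        h = relu(self.dec1.forward(np.concatenate([z, c], axis=1)))
        return softplus(self.dec2.forward(h))


def elbo(
    model: CVAEModel,
    X_u: np.ndarray,
    X_v: np.ndarray,
    n_mc_samples: int = 1,
    rng: np.random.Generator | int | None = 0,
) -> float:
    """Single-pair ELBO estimate; deterministic given the rng seed.

    The Monte-Carlo noise is drawn once as
    ``rng.standard_normal((n_mc_samples, latent_dim))``, so the estimate can be
    reproduced (and decomposed into -KL - mean SSE/2 - (m/2) log 2pi) from the
    same seed via :meth:`CVAEModel.encode` / :meth:`CVAEModel.decode`.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X_u = np.asarray(X_u, dtype=float).reshape(1, -1)
    X_v = np.asarray(X_v, dtype=float).reshape(1, -1)
    if X_u.shape[1] != model.n_taxa or X_v.shape[1] != model.n_taxa:
        raise ValueError("pair width does not match the model's taxon count")
    mu, lv = model.encode(X_u, X_v)
    kl = kl_gaussian(mu[0], lv[0])
    sigma = np.exp(0.5 * lv)
    eps = rng.standard_normal((n_mc_samples, model.config.latent_dim))
    recon = 0.0
    for e in eps:
        out = model.decode(mu + sigma * e, X_v)
        recon += -0.5 * float(np.sum((X_u - out) ** 2))
    recon /= n_mc_samples
    value = -kl + recon - 0.5 * model.n_taxa * LOG_2PI
    if not np.isfinite(value):
        raise RuntimeError("non-finite ELBO")
    return float(value)


def _batch_step(model: CVAEModel, X_u: np.ndarray, X_v: np.ndarray,
                eps: np.ndarray) -> tuple[float, list[np.ndarray]]:
    """Forward/backward on a batch of pairs; returns (batch mean ELBO, grads).

    ``eps`` has shape (S, b, L): S Monte-Carlo draws per pair.  The minimized
    loss is the batch mean of KL + (1/S) sum_l SSE_l / 2 (the negative ELBO up
    to its additive constant).
    """
    b = X_u.shape[0]
    S = eps.shape[0]
    e_in = np.concatenate([X_u, X_v], axis=1)
    a_e = model.enc1.forward(e_in)
    h_e = relu(a_e)
    mu = model.mu_head.forward(h_e)
    lv = model.lv_head.forward(h_e)
    sigma = np.exp(0.5 * lv)
    c = model.cond_proj.forward(X_v)

    kl_mean = float(np.mean(kl_gaussian(mu, lv)))
    dmu = mu / b                       # KL gradient wrt mu
    dlv = 0.5 * (np.exp(lv) - 1.0) / b  # KL gradient wrt logvar
    dc = np.zeros_like(c)

    acc: dict[int, list[np.ndarray]] = {}

    def accumulate(layer_idx: int, grads: list[np.ndarray]) -> None:
        if layer_idx not in acc:
            acc[layer_idx] = [g.copy() for g in grads]
        else:
            for a, g in zip(acc[layer_idx], grads):
                a += g

    recon_mean = 0.0
    L = model.config.latent_dim
    for l in range(S):
        z = mu + sigma * eps[l]
        d_in = np.concatenate([z, c], axis=1)
        a_d = model.dec1.forward(d_in)
        h_d = relu(a_d)
        a_o = model.dec2.forward(h_d)
        out = softplus(a_o)
        resid = out - X_u
        recon_mean += 0.5 * float(np.sum(resid * resid)) / (b * S)

        g = resid / (b * S) * softplus_grad(a_o)
        g = model.dec2.backward(h_d, g)
        accumulate(5, model.dec2.grads)
        g = g * relu_grad(a_d)
        g = model.dec1.backward(d_in, g)
        accumulate(4, model.dec1.grads)
        dz, dc_l = g[:, :L], g[:, L:]
        dc += dc_l
        dmu = dmu + dz
        dlv = dlv + dz * eps[l] * 0.5 * sigma

    model.cond_proj.backward(X_v, dc)
    accumulate(3, model.cond_proj.grads)
    g_h = model.mu_head.backward(h_e, dmu)
    accumulate(1, model.mu_head.grads)
    g_h = g_h + model.lv_head.backward(h_e, dlv)
    accumulate(2, model.lv_head.grads)
    g_h = g_h * relu_grad(a_e)
    model.enc1.backward(e_in, g_h)
    accumulate(0, model.enc1.grads)

    grads: list[np.ndarray] = []
    for idx in range(len(model.layers)):
        grads.extend(acc[idx])
    batch_elbo = -kl_mean - recon_mean - 0.5 * model.n_taxa * LOG_2PI
    return batch_elbo, grads


def train_cvae(
    X: np.ndarray,
    pairs: TrainingPairSet,
    config: CVAEConfig | None = None,
) -> CVAEModel:
    """Train the CVAE on directed-edge pairs from the logged matrix X.

    The trace records the per-epoch mean ELBO over training pairs (evaluated
    batch-wise before each update).  Training is a pure function of
    (X, pairs, config.seed); divergence aborts with the epoch index.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x taxa)")
    n, m = X.shape
    if pairs.pairs.size and pairs.pairs.max() >= n:
        raise ValueError("pair indices exceed the number of samples in X")
    config = config or CVAEConfig()
    config.validate()

    rng = np.random.default_rng(config.seed)
    model = CVAEModel(m, config, rng)
    params = [p for layer in model.layers for p in layer.params]
    opt = Adam(params, lr=config.learning_rate)

    n_pairs = len(pairs)
    for epoch in range(config.epochs):
        epoch_elbo = 0.0
        n_seen = 0
        for batch in minibatches(n_pairs, config.batch_size, rng):
            vu = pairs.pairs[batch]
            eps = rng.standard_normal((config.n_mc_samples, len(batch), config.latent_dim))
            batch_elbo, grads = _batch_step(model, X[vu[:, 1]], X[vu[:, 0]], eps)
            if not np.isfinite(batch_elbo):
                raise RuntimeError(f"non-finite ELBO at epoch {epoch}")
            epoch_elbo += batch_elbo * len(batch)
            n_seen += len(batch)
            opt.step(grads)
        model.elbo_trace.append(epoch_elbo / n_seen)
    return model


def generate_conditional_samples(
    model: CVAEModel,
    X: np.ndarray,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Generate one conditional sample X^c_v per node.

    For each sample v, a single latent z ~ N(0, I) is drawn and decoded with
    X_v as the condition; the output (n x m, non-negative) aligns row-for-row
    with X, so conditional neighbors inherit the real graph structure.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_taxa:
        raise ValueError(
            f"expected {model.n_taxa} taxa columns, got shape {X.shape}"
        )
    z = rng.standard_normal((X.shape[0], model.config.latent_dim))
    return model.decode(z, X)
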