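"""Sparse autoencoder: single hidden layer, KL-divergence sparsity penalty.

The encoder maps a feature block X (rows = nodes) through a sigmoid hidden
layer ``h = sigma(X W_enc + b_enc)``; the decoder reconstructs
``x_hat = sigma(h W_dec + b_dec)``. The cost is

    F = MSE(x_hat, X) + delta * sum_units KL(rho || rho_hat_unit)

where ``rho_hat`` is the per-unit mean hidden activation over rows and

    KL(rho || r) = rho ln(rho/r) + (1-rho) ln((1-rho)/(1-r))

keeps average activations near the small sparsity target rho. Training is
plain full-batch gradient descent; the two node classes (whose raw widths
differ) are compressed by separate autoencoders to a shared latent width so
that one GCN feature table can be stacked.

Gradients are derived by hand (numpy); tests check them against independent
scalar-loop and finite-difference oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_CLAMP = 1e-8  # keeps the KL term finite at saturated units


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class SAEConfig:
    hidden_dim: int = 128
    rho: float = 0.05  # sparsity target
    delta: float = 1e-3  # penalty weight
    lr: float = 0.01
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (0, 1)")
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class SAEModel:
    W_enc: np.ndarray
    b_enc: np.ndarray
    W_dec: np.ndarray
    b_dec: np.ndarray
    config: SAEConfig

    @classmethod
    def initialize(cls, input_dim: int, config: SAEConfig) -> "SAEModel":
        # seeded uniform +/- 1/sqrt(fan_in), untied weights
        rng = np.random.default_rng(config.seed)
        d = config.hidden_dim
        s_enc = 1.0 / np.sqrt(input_dim)
        s_dec = 1.0 / np.sqrt(d)
        return cls(
            W_enc=rng.uniform(-s_enc, s_enc, size=(input_dim, d)),
            b_enc=np.zeros(d),
            W_dec=rng.uniform(-s_dec, s_dec, size=(d, input_dim)),
            b_dec=np.zeros(input_dim),
            config=config,
        )


@dataclass
class TrainingTrace:
    total: list[float] = field(default_factory=list)
    reconstruction: list[float] = field(default_factory=list)
    penalty: list[float] = field(default_factory=list)


def sae_forward(model: SAEModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hidden activations and reconstruction; both sigmoid, hence in (0,1)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.W_enc.shape[0]:
        raise ValueError(
            f"input width {X.shape[1]} does not match encoder ({model.W_enc.shape[0]})"
        )
    hidden = _sigmoid(X @ model.W_enc + model.b_enc)
    recon = _sigmoid(hidden @ model.W_dec + model.b_dec)
    return hidden, recon


def kl_penalty(rho: float, rho_hat: np.ndarray) -> float:
    """Sum over hidden units of KL(rho || rho_hat).

    Zero iff every unit's average activation equals the target; grows
    monotonically as any unit departs from it on either side. Inputs are
    clamped away from {0, 1} to stay finite.
    """
    rho_hat = np.clip(np.asarray(rho_hat, dtype=float), _CLAMP, 1.0 - _CLAMP)
    rho = min(max(rho, _CLAMP), 1.0 - _CLAMP)
    return float(
        np.sum(rho * np.log(rho / rho_hat) + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rho_hat)))
    )


def sae_cost(model: SAEModel, X: np.ndarray) -> tuple[float, dict[str, float]]:
    """Total cost = mean squared reconstruction error + delta * KL penalty."""
    X = np.asarray(X, dtype=float)
    hidden, recon = sae_forward(model, X)
    mse = float(np.mean((recon - X) ** 2))
    rho_hat = hidden.mean(axis=0)
    ps = kl_penalty(model.config.rho, rho_hat)
    total = mse + model.config.delta * ps
    return total, {"reconstruction": mse, "penalty": ps}


def _gradients(
    model: SAEModel, X: np.ndarray
) -> tuple[dict[str, np.ndarray], float, float, float]:
    n, width = X.shape
    cfg = model.config
    hidden, recon = sae_forward(model, X)

    mse = float(np.mean((recon - X) ** 2))
    rho_hat = hidden.mean(axis=0)
    ps = kl_penalty(cfg.rho, rho_hat)
    total = mse + cfg.delta * ps

    d_recon = 2.0 * (recon - X) / recon.size
    dZ2 = d_recon * recon * (1.0 - recon)
    gW_dec = hidden.T @ dZ2
    gb_dec = dZ2.sum(axis=0)

    d_hidden = dZ2 @ model.W_dec.T
    # KL path: d ps / d rho_hat, zero where clamping is active
    rh = np.clip(rho_hat, _CLAMP, 1.0 - _CLAMP)
    d_kl = np.where(
        (rho_hat > _CLAMP) & (rho_hat < 1.0 - _CLAMP),
        -cfg.rho / rh + (1.0 - cfg.rho) / (1.0 - rh),
        0.0,
    )
    d_hidden = d_hidden + cfg.delta * d_kl / n

    dZ1 = d_hidden * hidden * (1.0 - hidden)
    gW_enc = X.T @ dZ1
    gb_enc = dZ1.sum(axis=0)
    grads = {"W_enc": gW_enc, "b_enc": gb_enc, "W_dec": gW_dec, "b_dec": gb_dec}
    return grads, total, mse, ps


def sae_train(X: np.ndarray, config: SAEConfig) -> tuple[SAEModel, TrainingTrace]:
    """Full-batch gradient descent on the sparse-autoencoder cost."""
    X = np.asarray(X, dtype=float)
    if X.size == 0 or not np.all(np.isfinite(X)):
        raise ValueError("training data must be non-empty and finite")
    model = SAEModel.initialize(X.shape[1], config)
    trace = TrainingTrace()
    for _epoch in range(config.epochs):
        grads, total, mse, ps = _gradients(model, X)
        if not np.isfinite(total):
            raise FloatingPointError(
                f"non-finite autoencoder cost at epoch {_epoch}: {total}"
            )
        trace.total.append(total)
        trace.reconstruction.append(mse)
        trace.penalty.append(ps)
        model.W_enc -= config.lr * grads["W_enc"]
        model.b_enc -= config.lr * grads["b_enc"]
        model.W_dec -= config.lr * grads["W_dec"]
        model.b_dec -= config.lr * grads["b_dec"]
    return model, trace


def sae_encode(model: SAEModel, X: np.ndarray) -> np.ndarray:
    """Latent representation: the hidden activations (rows x hidden_dim)."""
    hidden, _ = sae_forward(model, X)
    return hidden


def minmax_scale(X: np.ndarray) -> np.ndarray:
    """Per-column min-max scaling to [0, 1] (constant columns -> 0).

    The raw feature blocks mix k-mer frequencies (order 1/4^k) with kernel
    similarities (order 1); without rescaling the sigmoid encoder sees
    near-zero pre-activations and the latents carry almost no node signal.
    """
    X = np.asarray(X, dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (X - lo) / span


def encode_node_table(
    circ_features: np.ndarray,
    mirna_features: np.ndarray,
    config: SAEConfig,
    standardize: bool = True,
) -> np.ndarray:
    """Compress each node class with its own autoencoder and stack into the
    (C + M) x hidden_dim table that seeds the GCN (circRNAs first).

    Inputs are min-max scaled per column; the stacked latent table is
    z-scored per column (``standardize``) so downstream inner products and
    ReLU propagation see mixed-sign, unit-scale coordinates -- sigmoid
    latents are strictly positive, and an all-positive feature table makes
    the zero embedding an absorbing state of ReLU GCN training.
    """
    cfg_c = SAEConfig(**{**config.__dict__})
    cfg_m = SAEConfig(**{**config.__dict__, "seed": config.seed + 1})
    Xc = minmax_scale(circ_features)
    Xm = minmax_scale(mirna_features)
    model_c, _ = sae_train(Xc, cfg_c)
    model_m, _ = sae_train(Xm, cfg_m)
    H0 = np.vstack([sae_encode(model_c, Xc), sae_encode(model_m, Xm)])
    if standardize:
        sd = H0.std(axis=0)
        H0 = (H0 - H0.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    return H0
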