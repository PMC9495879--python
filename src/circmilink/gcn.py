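"""Layer-attention graph convolution over the bipartite association graph.

The combined node set stacks circRNAs first, then miRNAs; the undirected
adjacency is ``A = [[0, B], [B^T, 0]]``. After adding self-loops
(``A_hat = A + I``) the propagation operator is the symmetric normalisation
``A_tilde = D^-1/2 A_hat D^-1/2`` (spectral radius <= 1). Layers follow

    H^(l+1) = ReLU(A_tilde H^(l) W^(l))

and the final embedding is the attention-weighted sum over layer outputs
``M = sum_l n_l H^(l)`` (the input H^(0) excluded). Pair scores are the
sigmoid inner product ``S = sigmoid(M M^T)``, and training minimises a
weighted cross-entropy over the labelled pairs (positives + sampled
negatives), with the positive class weighted by the negative:positive
ratio omega.

Training is full-batch adaptive-moment (Adam) gradient descent with
hand-derived gradients; a finite-difference check in the test suite guards
the backward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_ATTENTION = (0.7, 0.2, 0.1)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class GCNConfig:
    n_layers: int = 3
    hidden_dim: int = 64  # shared across layers (layer sum requires it)
    attention: str = "fixed"  # "fixed" | "learnable"
    attention_weights: tuple[float, ...] | None = DEFAULT_ATTENTION
    lr: float = 0.01
    epochs: int = 200
    weight_decay: float = 5e-3  # L2 on layer weights; set by CV on the synthetic benchmark
    seed: int = 0
    omega: float | None = None  # None -> negatives/positives ratio of the data

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.attention not in ("fixed", "learnable"):
            raise ValueError(f"unknown attention mode {self.attention!r}")
        if self.attention_weights is not None:
            w = tuple(float(x) for x in self.attention_weights)
            if len(w) != self.n_layers:
                raise ValueError(
                    f"{len(w)} attention weights for {self.n_layers} layers"
                )
            if any(x < 0 for x in w):
                raise ValueError("attention weights must be non-negative")
            self.attention_weights = w

    def resolved_weights(self) -> np.ndarray:
        if self.attention_weights is not None:
            return np.array(self.attention_weights, dtype=float)
        return np.full(self.n_layers, 1.0 / self.n_layers)


@dataclass
class NormalizedAdjacency:
    matrix: np.ndarray


@dataclass
class GCNModel:
    weights: list[np.ndarray]  # W^(l), l = 0..L-1
    attention_logits: np.ndarray | None  # softmax parameters (learnable mode)
    config: GCNConfig

    @classmethod
    def initialize(cls, input_dim: int, config: GCNConfig) -> "GCNModel":
        rng = np.random.default_rng(config.seed)
        dims = [input_dim] + [config.hidden_dim] * config.n_layers
        weights = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            s = np.sqrt(6.0 / (d_in + d_out))  # Glorot uniform
            weights.append(rng.uniform(-s, s, size=(d_in, d_out)))
        logits = None
        if config.attention == "learnable":
            logits = np.log(np.maximum(config.resolved_weights(), 1e-8))
        return cls(weights, logits, config)

    def attention_vector(self) -> np.ndarray:
        if self.config.attention == "learnable":
            e = np.exp(self.attention_logits - self.attention_logits.max())
            return e / e.sum()
        return self.config.resolved_weights()


@dataclass
class ScoreMatrix:
    """Sigmoid inner-product scores over the full node set."""

    matrix: np.ndarray  # (C+M, C+M)
    n_circ: int

    def circ_mirna_block(self) -> np.ndarray:
        """The C x M view used for ranking and evaluation."""
        return self.matrix[: self.n_circ, self.n_circ :]


def build_combined_adjacency(B: np.ndarray) -> np.ndarray:
    """(C+M) square symmetric adjacency with B in the off-diagonal blocks."""
    B = np.asarray(B, dtype=float)
    C, M = B.shape
    A = np.zeros((C + M, C + M))
    A[:C, C:] = B
    A[C:, :C] = B.T
    return A


def add_self_loops(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    return A + np.eye(A.shape[0])


def normalize_adjacency(A_hat: np.ndarray) -> NormalizedAdjacency:
    """Symmetric normalisation D^-1/2 A_hat D^-1/2 with D = row sums."""
    A_hat = np.asarray(A_hat, dtype=float)
    deg = A_hat.sum(axis=1)
    if np.any(deg <= 0):
        raise ValueError("zero row sum; add self-loops first")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return NormalizedAdjacency(A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :])


def gcn_forward(
    model: GCNModel, A_tilde: NormalizedAdjacency | np.ndarray, H0: np.ndarray
) -> list[np.ndarray]:
    """Per-layer embeddings [H^(1), ..., H^(L)]."""
    At = A_tilde.matrix if isinstance(A_tilde, NormalizedAdjacency) else np.asarray(A_tilde)
    H = np.asarray(H0, dtype=float)
    if H.shape[0] != At.shape[0]:
        raise ValueError("feature rows must equal node count")
    out = []
    for W in model.weights:
        if H.shape[1] != W.shape[0]:
            raise ValueError("layer width mismatch")
        H = np.maximum(At @ H @ W, 0.0)
        out.append(H)
    return out


def layer_attention_combine(
    embeddings: list[np.ndarray], weights: np.ndarray
) -> np.ndarray:
    """M = sum_l n_l H^(l) over layer outputs (equal shapes required)."""
    weights = np.asarray(weights, dtype=float)
    if len(embeddings) != len(weights):
        raise ValueError(f"{len(weights)} weights for {len(embeddings)} layers")
    shapes = {e.shape for e in embeddings}
    if len(shapes) != 1:
        raise ValueError(f"layer embeddings differ in shape: {shapes}")
    M = np.zeros_like(embeddings[0])
    for w, H in zip(weights, embeddings):
        M += w * H
    return M


def inner_product_decode(M_cm: np.ndarray, n_circ: int | None = None) -> ScoreMatrix:
    M_cm = np.asarray(M_cm, dtype=float)
    S = _sigmoid(M_cm @ M_cm.T)
    return ScoreMatrix(S, n_circ if n_circ is not None else M_cm.shape[0])


def weighted_bce_loss(labels: np.ndarray, logits: np.ndarray, omega: float = 1.0) -> float:
    """Mean weighted cross-entropy; positives weighted by omega."""
    b = np.asarray(labels, dtype=float)
    p = np.clip(_sigmoid(np.asarray(logits, dtype=float)), 1e-12, 1.0 - 1e-12)
    return float(np.mean(-(b * np.log(p) * omega + (1.0 - b) * np.log(1.0 - p))))


def pair_logits(M_cm: np.ndarray, node_pairs: np.ndarray) -> np.ndarray:
    a, b = node_pairs[:, 0], node_pairs[:, 1]
    return np.sum(M_cm[a] * M_cm[b], axis=1)


def to_node_pairs(pairs, n_circ: int) -> np.ndarray:
    """(circ_index, mirna_index) -> combined node indexing (miRNAs offset)."""
    arr = np.asarray(sorted(pairs) if isinstance(pairs, set) else list(pairs), dtype=int)
    out = arr.copy()
    out[:, 1] += n_circ
    return out


@dataclass
class TrainTrace:
    loss: list[float] = field(default_factory=list)


def _loss_and_grads(
    model: GCNModel,
    At: np.ndarray,
    H0: np.ndarray,
    node_pairs: np.ndarray,
    labels: np.ndarray,
    omega: float,
) -> tuple[float, list[np.ndarray], np.ndarray | None]:
    L = model.config.n_layers
    attn = model.attention_vector()

    # forward, caching pre-activations
    Hs: list[np.ndarray] = [np.asarray(H0, dtype=float)]
    Zs: list[np.ndarray] = []
    for W in model.weights:
        Z = At @ Hs[-1] @ W
        Zs.append(Z)
        Hs.append(np.maximum(Z, 0.0))
    M = layer_attention_combine(Hs[1:], attn)

    a_idx, b_idx = node_pairs[:, 0], node_pairs[:, 1]
    logits = np.sum(M[a_idx] * M[b_idx], axis=1)
    b = labels.astype(float)
    p = _sigmoid(logits)
    loss = float(
        np.mean(
            -(
                b * np.log(np.clip(p, 1e-12, None)) * omega
                + (1.0 - b) * np.log(np.clip(1.0 - p, 1e-12, None))
            )
        )
    )

    # d loss / d logit, then scatter into dM
    g = (-(b * omega) * (1.0 - p) + (1.0 - b) * p) / len(b)
    dM = np.zeros_like(M)
    np.add.at(dM, a_idx, g[:, None] * M[b_idx])
    np.add.at(dM, b_idx, g[:, None] * M[a_idx])

    d_attn = np.array([float(np.sum(dM * Hs[l + 1])) for l in range(L)])

    gW: list[np.ndarray] = [np.empty(0)] * L
    dH_next = attn[L - 1] * dM  # gradient w.r.t. H^(L)
    for l in range(L - 1, -1, -1):
        dZ = dH_next * (Zs[l] > 0)
        gW[l] = (At @ Hs[l]).T @ dZ
        if l >= 1:
            dH_next = attn[l - 1] * dM + At.T @ (dZ @ model.weights[l].T)

    g_logits = None
    if model.config.attention == "learnable":
        # softmax Jacobian: da_i = n_i (dn_i - sum_j n_j dn_j)
        g_logits = attn * (d_attn - float(np.dot(attn, d_attn)))
    return loss, gW, g_logits


def train_model(
    H0: np.ndarray,
    A_tilde: NormalizedAdjacency | np.ndarray,
    train_pairs,
    labels: np.ndarray,
    config: GCNConfig,
    n_circ: int | None = None,
) -> tuple[GCNModel, TrainTrace]:
    """Fit layer weights (and attention, in learnable mode) by full-batch
    Adam on the weighted cross-entropy over the labelled pairs.

    ``train_pairs`` may be (circ_index, mirna_index) tuples with ``n_circ``
    given, or pairs already in combined node indexing.
    """
    At = A_tilde.matrix if isinstance(A_tilde, NormalizedAdjacency) else np.asarray(A_tilde)
    H0 = np.asarray(H0, dtype=float)
    labels = np.asarray(labels)
    if n_circ is not None:
        node_pairs = to_node_pairs(train_pairs, n_circ)
    else:
        node_pairs = np.asarray(list(train_pairs), dtype=int)
    if node_pairs.size and node_pairs.max() >= At.shape[0]:
        raise ValueError("train pair indexes a node outside the graph")

    if config.omega is not None:
        omega = config.omega
    else:
        n_pos = int(labels.sum())
        n_neg = len(labels) - n_pos
        omega = n_neg / n_pos if n_pos else 1.0

    model = GCNModel.initialize(H0.shape[1], config)
    trace = TrainTrace()

    # Adam state
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    params: list[np.ndarray] = list(model.weights)
    if model.attention_logits is not None:
        params.append(model.attention_logits)
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]

    for t in range(1, config.epochs + 1):
        loss, gW, g_logits = _loss_and_grads(model, At, H0, node_pairs, labels, omega)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at epoch {t}: {loss}")
        trace.loss.append(loss)
        if config.weight_decay:
            gW = [g_ + config.weight_decay * W for g_, W in zip(gW, model.weights)]
        grads = list(gW)
        if g_logits is not None:
            grads.append(g_logits)
        for p, g, m, v in zip(params, grads, m_state, v_state):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g**2
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            p -= config.lr * m_hat / (np.sqrt(v_hat) + eps)
    return model, trace


def embed(model: GCNModel, A_tilde, H0: np.ndarray) -> np.ndarray:
    """Final node embedding M = attention-weighted layer sum."""
    return layer_attention_combine(gcn_forward(model, A_tilde, H0), model.attention_vector())


def rank_candidates(
    S: ScoreMatrix, known_positives: set[tuple[int, int]]
) -> list[tuple[int, int, float]]:
    """All circRNA x miRNA pairs not already known, by descending score;
    ties broken by ascending (circ_index, mirna_index)."""
    block = S.circ_mirna_block()
    C, M = block.shape
    items = [
        (i, j, float(block[i, j]))
        for i in range(C)
        for j in range(M)
        if (i, j) not in known_positives
    ]
    items.sort(key=lambda t: (-t[2], t[0], t[1]))
    return items
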