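"""Node featurization: k-mer profiles, similarity kernels, and fusion.

Two feature channels per node class:

* **k-mer profiles** -- occurrence frequencies of every length-k substring
  over {A, C, G, U}, scanned with a stride-1 window (columns in
  lexicographic order). Frequencies rather than raw counts, because
  circRNA lengths span orders of magnitude.
* **similarity kernels** on interaction profiles LP(.) -- the rows
  (circRNAs) / columns (miRNAs) of the bipartite adjacency B:

  - Gaussian interaction profile (GIP) kernel
    ``G[i,j] = exp(-alpha * ||LP_i - LP_j||^2)`` with bandwidth
    ``alpha = alpha' / mean_i ||LP_i||^2``;
  - sigmoid kernel ``K[i,j] = tanh(<x_i, x_j> / V)`` with V the profile
    dimension.

  The two kernels are fused entrywise: averaged where both are nonzero,
  summed otherwise (so a single nonzero value passes through unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io_data import BipartiteAdjacency

RNA_ALPHABET = "ACGU"

DEFAULT_ALPHA_PRIME = 0.5  # GIP bandwidth numerator, both node classes
DEFAULT_K_CIRC = 5
DEFAULT_K_MIRNA = 2


@dataclass
class KmerProfile:
    matrix: np.ndarray  # (n_nodes, 4**k)
    k: int
    ids: list[str]
    normalized: bool

    @property
    def columns(self) -> list[str]:
        return ["".join(p) for p in product(RNA_ALPHABET, repeat=self.k)]


@dataclass
class KernelMatrix:
    matrix: np.ndarray
    kind: str  # "gip" | "sigmoid"


@dataclass
class FusedSimilarity:
    matrix: np.ndarray


@dataclass
class NodeFeatureBlock:
    """Per-class feature blocks [k-mer | fused similarity].

    The two blocks have incompatible widths across classes
    (4^k_c + C vs 4^k_m + M); they are kept separate until the sparse
    autoencoder compresses both to a shared latent width.
    """

    circ: np.ndarray  # (C, .)
    mirna: np.ndarray  # (M, .)


def kmer_matrix(
    seqs: dict[str, str], k: int, normalize: bool = True, circular: bool = False
) -> KmerProfile:
    """Count all L-k+1 stride-1 windows of each sequence.

    Windows containing IUPAC ambiguity codes (anything outside ACGU) are not
    counted; the frequency denominator stays L-k+1. With ``circular`` the
    first k-1 nucleotides are appended before scanning (L windows), so
    k-mers spanning a back-splice junction are counted too.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    index = {"".join(p): c for c, p in enumerate(product(RNA_ALPHABET, repeat=k))}
    ids = list(seqs)
    mat = np.zeros((len(ids), 4**k))
    for row, name in enumerate(ids):
        seq = seqs[name]
        if len(seq) < k:
            raise ValueError(f"sequence {name!r} shorter than k={k}")
        if circular:
            seq = seq + seq[: k - 1]
        n_windows = len(seq) - k + 1
        for start in range(n_windows):
            col = index.get(seq[start : start + k])
            if col is not None:
                mat[row, col] += 1.0
        if normalize:
            mat[row] /= n_windows
    return KmerProfile(mat, k, ids, normalize)


def gip_kernel(profiles: np.ndarray, alpha_prime: float = DEFAULT_ALPHA_PRIME) -> KernelMatrix:
    """Gaussian interaction profile kernel over rows of ``profiles``.

    Bandwidth ``alpha = alpha_prime / mean squared row norm``; errors when
    every profile is all-zero (bandwidth undefined).
    """
    profiles = np.asarray(profiles, dtype=float)
    mean_sq_norm = float(np.mean(np.sum(profiles**2, axis=1)))
    if mean_sq_norm == 0.0:
        raise ValueError("all interaction profiles are zero; GIP bandwidth undefined")
    alpha = alpha_prime / mean_sq_norm
    if profiles.shape[0] == 1:
        sq = np.zeros((1, 1))
    else:
        sq = squareform(pdist(profiles, metric="sqeuclidean"))
    G = np.exp(-alpha * sq)
    np.fill_diagonal(G, 1.0)
    return KernelMatrix(G, "gip")


def sigmoid_kernel(vectors: np.ndarray) -> KernelMatrix:
    """tanh of the inner product scaled by 1/V, V = feature dimension."""
    vectors = np.asarray(vectors, dtype=float)
    V = vectors.shape[1]
    if V == 0:
        raise ValueError("feature dimension V must be >= 1")
    K = np.tanh(vectors @ vectors.T / V)
    return KernelMatrix(0.5 * (K + K.T), "sigmoid")


def fuse_similarities(G: KernelMatrix, K: KernelMatrix) -> FusedSimilarity:
    """Entrywise fusion: mean where both kernels are nonzero, sum otherwise.

    The zero test is exact (an entry absent from a kernel is exactly 0.0;
    GIP entries are never 0), so a lone nonzero value passes through.
    """
    g, k = G.matrix, K.matrix
    if g.shape != k.shape:
        raise ValueError(f"kernel shape mismatch: {g.shape} vs {k.shape}")
    both = (g != 0.0) & (k != 0.0)
    return FusedSimilarity(np.where(both, (g + k) / 2.0, g + k))


def interaction_profiles(B: BipartiteAdjacency) -> tuple[np.ndarray, np.ndarray]:
    """LP vectors per class: rows of B for circRNAs, columns for miRNAs."""
    return B.matrix, B.matrix.T


def fused_profile_similarity(profiles: np.ndarray, alpha_prime: float = DEFAULT_ALPHA_PRIME) -> FusedSimilarity:
    return fuse_similarities(gip_kernel(profiles, alpha_prime), sigmoid_kernel(profiles))


def assemble_node_features(
    km_c: KmerProfile,
    F_c: FusedSimilarity,
    km_m: KmerProfile,
    F_m: FusedSimilarity,
) -> NodeFeatureBlock:
    """Concatenate [k-mer | fused similarity] per node class."""
    if km_c.matrix.shape[0] != F_c.matrix.shape[0]:
        raise ValueError("circRNA k-mer and similarity row counts differ")
    if km_m.matrix.shape[0] != F_m.matrix.shape[0]:
        raise ValueError("miRNA k-mer and similarity row counts differ")
    return NodeFeatureBlock(
        circ=np.hstack([km_c.matrix, F_c.matrix]),
        mirna=np.hstack([km_m.matrix, F_m.matrix]),
    )


def sequence_features(
    B: BipartiteAdjacency,
    circ_seqs: dict[str, str],
    mirna_seqs: dict[str, str],
    k_circ: int = DEFAULT_K_CIRC,
    k_mirna: int = DEFAULT_K_MIRNA,
    alpha_prime: float = DEFAULT_ALPHA_PRIME,
) -> NodeFeatureBlock:
    """Full sequence-mode features: k-mer blocks + fused kernel similarities.

    Sequence catalogs are re-ordered to the adjacency's id order; every node
    id must be present in its catalog.
    """
    missing_c = [c for c in B.circ_ids if c not in circ_seqs]
    missing_m = [m for m in B.mirna_ids if m not in mirna_seqs]
    if missing_c or missing_m:
        raise ValueError(f"sequences missing for ids: {(missing_c + missing_m)[:5]}")
    km_c = kmer_matrix({c: circ_seqs[c] for c in B.circ_ids}, k_circ)
    km_m = kmer_matrix({m: mirna_seqs[m] for m in B.mirna_ids}, k_mirna)
    lp_c, lp_m = interaction_profiles(B)
    return assemble_node_features(
        km_c,
        fused_profile_similarity(lp_c, alpha_prime),
        km_m,
        fused_profile_similarity(lp_m, alpha_prime),
    )


def profile_only_features(
    B: BipartiteAdjacency, alpha_prime: float = DEFAULT_ALPHA_PRIME
) -> NodeFeatureBlock:
    """Profile-only mode (no sequences, e.g. circRNA-disease): fused kernel
    similarity on interaction profiles is the entire attribute feature."""
    lp_c, lp_m = interaction_profiles(B)
    return NodeFeatureBlock(
        circ=fused_profile_similarity(lp_c, alpha_prime).matrix,
        mirna=fused_profile_similarity(lp_m, alpha_prime).matrix,
    )
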