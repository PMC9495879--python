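"""Five-fold cross-validation, metrics, ablation, and sweep harnesses.

The CV protocol partitions the *positive* pairs into k folds; negatives are
sampled fresh per fold (train and test sets separately), always disjoint
from every known positive. Each fold rebuilds the adjacency, kernels,
autoencoder and GCN from training positives only, so no test edge ever
leaks into the features or the propagation graph. Reported metrics are
per-fold and mean accuracy/precision/recall at a 0.5 cutoff, plus AUC and
AUPR on the held-out scored pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .featurization import profile_only_features, sequence_features
from .gcn import (
    GCNConfig,
    build_combined_adjacency,
    add_self_loops,
    embed,
    inner_product_decode,
    normalize_adjacency,
    train_model,
)
from .io_data import InteractionDataset, build_bipartite_adjacency, sample_negative_pairs
from .sparse_autoencoder import SAEConfig, encode_node_table

Pair = tuple[int, int]


@dataclass
class FoldSplit:
    fold: int
    train_pos: set[Pair]
    test_pos: set[Pair]
    train_neg: set[Pair]
    test_neg: set[Pair]
    seed: int


@dataclass
class MetricsReport:
    """Per-fold metrics plus the arithmetic mean across folds."""

    folds: pd.DataFrame  # columns: fold, acc, precision, recall, auc, aupr
    scores: pd.DataFrame | None = None  # fold, circ_index, mirna_index, label, score

    def mean(self) -> pd.Series:
        return self.folds.drop(columns="fold").mean()

    def summary(self) -> pd.DataFrame:
        """Fold rows plus a trailing 'mean' row (the final model score)."""
        mean_row = self.mean()
        mean_row["fold"] = "mean"
        return pd.concat(
            [self.folds, mean_row.to_frame().T[self.folds.columns]], ignore_index=True
        )


def _fold_seed(seed: int, fold: int, salt: int = 0) -> int:
    return int(np.random.SeedSequence([seed, fold, salt]).generate_state(1)[0] % (2**31))


def kfold_split(ds: InteractionDataset, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Seeded random partition of positives into k near-equal test sets,
    with per-fold negative sampling (train and test negatives disjoint)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    positives = sorted(ds.positive_pairs)
    if len(positives) < k:
        raise ValueError(f"{len(positives)} positives cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    chunks = np.array_split(order, k)
    splits = []
    for f, chunk in enumerate(chunks):
        test_pos = {positives[i] for i in chunk}
        train_pos = set(positives) - test_pos
        fold_seed = _fold_seed(seed, f)
        neg_rng = np.random.default_rng(fold_seed)
        train_neg = sample_negative_pairs(ds, len(train_pos), neg_rng)
        test_neg = sample_negative_pairs(ds, len(test_pos), neg_rng, exclude=train_neg)
        splits.append(FoldSplit(f, train_pos, test_pos, train_neg, test_neg, fold_seed))
    return splits


def compute_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Accuracy, precision, recall at a score cutoff."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    acc = (tp + tn) / len(labels)
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision undefined", stacklevel=2)
        precision = float("nan")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no true positives in labels; recall undefined", stacklevel=2)
        recall = float("nan")
    else:
        recall = tp / (tp + fn)
    return {"acc": acc, "precision": precision, "recall": recall}


def auc_aupr(labels: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """ROC AUC (rank statistic, tie-averaged) and AUPR (PR step integration)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required for AUC/AUPR")
    return float(roc_auc_score(labels, scores)), float(average_precision_score(labels, scores))


def _fold_scores(
    ds: InteractionDataset,
    fold: FoldSplit,
    mode: str,
    circ_seqs: dict[str, str] | None,
    mirna_seqs: dict[str, str] | None,
    sae_config: SAEConfig,
    gcn_config: GCNConfig,
    use_gcn: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Train on the fold's training pairs, score its held-out pairs."""
    train_ds = ds.subset_pairs(fold.train_pos)
    B = build_bipartite_adjacency(train_ds)
    if mode == "sequence":
        if circ_seqs is None or mirna_seqs is None:
            raise ValueError("sequence mode requires both sequence catalogs")
        feats = sequence_features(B, circ_seqs, mirna_seqs)
    elif mode == "profile-only":
        feats = profile_only_features(B)
    else:
        raise ValueError(f"unknown feature mode {mode!r}")

    H0 = encode_node_table(feats.circ, feats.mirna, replace(sae_config, seed=fold.seed))

    if use_gcn:
        At = normalize_adjacency(add_self_loops(build_combined_adjacency(B.matrix)))
        train_pairs = sorted(fold.train_pos) + sorted(fold.train_neg)
        train_labels = np.array([1] * len(fold.train_pos) + [0] * len(fold.train_neg))
        model, _ = train_model(
            H0, At, train_pairs, train_labels, replace(gcn_config, seed=fold.seed), ds.n_circ
        )
        M = embed(model, At, H0)
    else:  # ablation: decode the autoencoder latents directly
        M = H0

    block = inner_product_decode(M, ds.n_circ).circ_mirna_block()
    test_pairs = sorted(fold.test_pos) + sorted(fold.test_neg)
    labels = np.array([1] * len(fold.test_pos) + [0] * len(fold.test_neg))
    scores = np.array([block[i, j] for i, j in test_pairs])
    return labels, scores


def cross_validate(
    ds: InteractionDataset,
    mode: str = "sequence",
    circ_seqs: dict[str, str] | None = None,
    mirna_seqs: dict[str, str] | None = None,
    sae_config: SAEConfig | None = None,
    gcn_config: GCNConfig | None = None,
    k: int = 5,
    seed: int = 0,
    use_gcn: bool = True,
) -> MetricsReport:
    """k-fold CV of the full pipeline; everything refit per fold."""
    sae_config = sae_config or SAEConfig()
    gcn_config = gcn_config or GCNConfig()
    rows = []
    score_rows = []
    for fold in kfold_split(ds, k, seed):
        labels, scores = _fold_scores(
            ds, fold, mode, circ_seqs, mirna_seqs, sae_config, gcn_config, use_gcn
        )
        auc, aupr = auc_aupr(labels, scores)
        rows.append({"fold": fold.fold, **compute_metrics(labels, scores), "auc": auc, "aupr": aupr})
        test_pairs = sorted(fold.test_pos) + sorted(fold.test_neg)
        for (i, j), lab, sc in zip(test_pairs, labels, scores):
            score_rows.append(
                {"fold": fold.fold, "circ_index": i, "mirna_index": j, "label": int(lab), "score": sc}
            )
    return MetricsReport(pd.DataFrame(rows), pd.DataFrame(score_rows))


def ablate_no_gcn(
    ds: InteractionDataset,
    mode: str = "sequence",
    circ_seqs: dict[str, str] | None = None,
    mirna_seqs: dict[str, str] | None = None,
    sae_config: SAEConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> MetricsReport:
    """CV with the graph-convolution stage removed: the sigmoid inner
    product is applied to the autoencoder latents directly."""
    return cross_validate(
        ds, mode, circ_seqs, mirna_seqs, sae_config, GCNConfig(), k, seed, use_gcn=False
    )


def sweep_layers(
    ds: InteractionDataset,
    layer_counts: list[int],
    seed: int = 0,
    mode: str = "sequence",
    circ_seqs: dict[str, str] | None = None,
    mirna_seqs: dict[str, str] | None = None,
    sae_config: SAEConfig | None = None,
    gcn_config: GCNConfig | None = None,
    k: int = 5,
) -> pd.DataFrame:
    """One CV per layer count, all else fixed. Layer counts other than the
    default use uniform attention weights (1/L each)."""
    base = gcn_config or GCNConfig()
    rows = []
    for L in layer_counts:
        if L < 1:
            raise ValueError("layer counts must be >= 1")
        weights = base.attention_weights if L == base.n_layers else None
        cfg = replace(base, n_layers=L, attention_weights=weights)
        rep = cross_validate(ds, mode, circ_seqs, mirna_seqs, sae_config, cfg, k, seed)
        m = rep.mean()
        rows.append({"layers": L, "auc": m["auc"], "aupr": m["aupr"]})
    return pd.DataFrame(rows)


def sweep_attention(
    ds: InteractionDataset,
    weight_triples: list[tuple[float, ...]],
    seed: int = 0,
    mode: str = "sequence",
    circ_seqs: dict[str, str] | None = None,
    mirna_seqs: dict[str, str] | None = None,
    sae_config: SAEConfig | None = None,
    gcn_config: GCNConfig | None = None,
    k: int = 5,
) -> pd.DataFrame:
    """One CV per fixed attention triple; per-fold AUC columns plus mean."""
    base = gcn_config or GCNConfig()
    rows = []
    for weights in weight_triples:
        cfg = replace(
            base, n_layers=len(weights), attention="fixed", attention_weights=tuple(weights)
        )
        rep = cross_validate(ds, mode, circ_seqs, mirna_seqs, sae_config, cfg, k, seed)
        row = {"weights": str(tuple(weights))}
        for _, r in rep.folds.iterrows():
            row[f"fold_{int(r['fold'])}"] = r["auc"]
        row["mean"] = rep.mean()["auc"]
        rows.append(row)
    return pd.DataFrame(rows)
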