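# circmilink

Prediction of circRNA–miRNA associations by multi-source node
featurization and a layer-attention graph convolutional network.

Circular RNAs act as miRNA "sponges": by binding miRNAs they lift the
repression of the miRNAs' target genes, which ties circRNA–miRNA pairing
to cancer biology and makes large-scale *in silico* ranking of candidate
pairs a useful prior for wet-lab validation. `circmilink` frames this as
link prediction on the bipartite graph of known associations and is aimed
at computational biologists who have an interaction table (and optionally
sequences) and want ranked candidate pairs plus a rigorous cross-validated
estimate of predictive power.

## Model

Let `B ∈ {0,1}^{C×M}` be the known circRNA–miRNA adjacency.

1. **Node attributes.** Each RNA sequence is summarised by its k-mer
   frequency profile (5-mers for circRNAs, 2-mers for miRNAs; columns
   lexicographic over A,C,G,U). Each node's *interaction profile* `LP(·)`
   (its row/column of `B`) feeds two similarity kernels:
   Gaussian interaction profile `G_ij = exp(−α‖LP_i−LP_j‖²)` with
   `α = α′ / mean‖LP‖²` (α′ = 0.5), and a sigmoid kernel
   `K_ij = tanh(⟨LP_i,LP_j⟩/V)`. The kernels are fused entrywise —
   averaged where both are nonzero, summed otherwise — and concatenated
   with the k-mer block. A profile-only mode (for circRNA–disease or
   circRNA–gene tables without sequences) uses the fused kernels alone.
2. **Compression.** A sparse autoencoder per node class (single sigmoid
   hidden layer, KL-divergence penalty `Σ KL(ρ‖ρ̂)` holding mean hidden
   activation near ρ = 0.05) maps both classes to a shared 128-dim latent
   table `H⁽⁰⁾`.
3. **Propagation.** On the combined graph `A = [[0,B],[Bᵀ,0]]` with
   self-loops and symmetric normalisation `Ã = D̃^{−1/2}ÂD̃^{−1/2}`, layers
   follow `H^{(l+1)} = ReLU(Ã H^{(l)} W^{(l)})`; the final embedding is the
   layer-attention sum `M = Σ_l n_l H^{(l)}` (default 3 layers, weights
   0.7/0.2/0.1, optionally learned).
4. **Decoding and training.** Scores are `S = sigmoid(M Mᵀ)`; training
   minimises weighted cross-entropy over known positives plus an equal
   number of sampled non-edges, with the positive class weighted by the
   negative:positive ratio ω.

Evaluation is 5-fold cross-validation over positives with per-fold
negative resampling; kernels, autoencoders and the GCN are refit inside
every fold from training edges only, so held-out pairs never leak into
the features or the graph.

## Worked example

Generate a seeded synthetic benchmark (60 circRNAs × 40 miRNAs, four
planted interaction blocks, shared sequence motifs per block) and
cross-validate the full pipeline:

```bash
$ circmilink simulate --preset strong --seed 1 --out demo
wrote 307 pairs, 60 circRNAs, 40 miRNAs

$ circmilink cv --interactions demo/interactions.tsv \
    --circ-fasta demo/circ.fa --mirna-fasta demo/mirna.fa \
    --seed 1 --out demo/cv
fold  acc precision recall       auc      aupr
   0  0.5       0.5    1.0  0.783819     0.767
   1  0.5       0.5    1.0  0.813736  0.749505
   2  0.5       0.5    1.0  0.865628  0.827803
   3  0.5       0.5    1.0  0.866971  0.865028
   4  0.5       0.5    1.0  0.834991  0.784829
mean  0.5       0.5    1.0  0.833029  0.798833
```

Mean held-out AUC ≈ 0.83 / AUPR ≈ 0.80: the model recovers the planted
block structure from training edges and sequence motifs alone. (The
accuracy columns are degenerate at the default 0.5 cutoff because
ReLU-based embeddings make every score ≥ 0.5 — see
`docs/methods.md`; AUC/AUPR are the informative metrics.) On the
structureless `null` preset the same pipeline scores ≈ 0.5, i.e. chance.

`circmilink train` fits on all known pairs and `predict --top 10` emits a
ranked TSV (`circRNA_id, miRNA_id, score, rank`) of novel candidates.
`ablate` (GCN removed), `sweep-layers` and `sweep-attention` reproduce the
standard diagnostic experiments. Real datasets are ingested from any
two-column id table (`circRNA id, miRNA id`; TSV or CSV) plus FASTA files,
e.g. tables assembled from circBank or circR2Cancer exports.

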