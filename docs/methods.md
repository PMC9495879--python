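# Methods

## Problem setting

`circmilink` predicts unobserved circRNA–miRNA associations from a known
bipartite interaction set, optionally augmented with RNA sequences. The
same machinery runs in a profile-only mode for circRNA–disease or
circRNA–gene tables where no molecular sequence exists for one side.
Everything below applies per cross-validation fold: all quantities derived
from the graph are computed from *training* edges only.

## Featurization

**k-mer profiles.** A sequence of length L is scanned with a stride-1
window; the profile is the count of each of the 4^k windows divided by
L−k+1. Frequencies rather than raw counts are used because circRNA lengths
span orders of magnitude (200 nt to several kb) and raw counts would
encode length, not composition. Defaults k=5 for circRNAs (1024 columns)
and k=2 for miRNAs (16 columns), reflecting typical lengths (a ~21 nt
miRNA has too few windows to populate a 5-mer table). Windows containing
IUPAC ambiguity codes are skipped; the denominator is unchanged. Scanning
is linear by default; `kmer_matrix(..., circular=True)` appends the first
k−1 nucleotides so windows spanning a circRNA's back-splice junction are
counted too.

**Similarity kernels.** With LP(·) the interaction-profile vector of a
node (row/column of the training adjacency):

- GIP kernel `G_ij = exp(−α‖LP_i−LP_j‖²)`, `α = α′ / mean_i‖LP_i‖²`,
  α′ = 0.5 for both classes. The bandwidth therefore adapts to the graph's
  density. All-zero profile sets are rejected (bandwidth undefined).
- Sigmoid kernel `K_ij = tanh(⟨LP_i, LP_j⟩ / V)` with V the profile
  length. This is the standard sigmoid kernel on the same vectors.

Fusion is entrywise: `(G+K)/2` where both entries are nonzero, `G+K`
otherwise, with an exact-zero test (GIP entries are never 0, so the branch
effectively passes a lone sigmoid value through). The zero test is
set-membership, not a tolerance: an entry is "absent" only when it is
exactly 0.0.

**Scaling.** Each per-class feature block `[k-mer | fused similarity]` is
min–max scaled per column before compression. The blocks mix scales
(k-mer frequencies of order 4^−k against kernel values of order 1);
without rescaling the sigmoid encoder operates in its flat region and the
latents are nearly constant across nodes.

## Sparse autoencoder

One sigmoid hidden layer, untied decoder, trained by full-batch gradient
descent on

    F = MSE(x̂, x) + δ · Σ_units KL(ρ ‖ ρ̂_unit),
    KL(ρ‖r) = ρ ln(ρ/r) + (1−ρ) ln((1−ρ)/(1−r)),

with ρ̂ the per-unit mean hidden activation. Defaults: hidden width
d = 128, ρ = 0.05, δ = 1e−3, learning rate 0.01, 100 epochs, seeded
uniform ±1/√fan_in initialisation. ρ̂ is clamped to [1e−8, 1−1e−8] so the
penalty stays finite at saturated units. Because the circRNA and miRNA
raw blocks have incompatible widths, each class gets its own autoencoder
with the shared latent width; the encodings are stacked (circRNAs first)
into the (C+M)×d table H⁽⁰⁾.

The stacked table is then z-scored per column. This is deliberate, not
cosmetic: sigmoid latents are strictly positive, the propagation operator
is non-negative, and ReLU layers under those conditions have the all-dead
state (every embedding exactly zero) as an absorbing fixed point of
gradient training — a column of first-layer weights driven all-negative
silences a unit for every node simultaneously. Centring the latents
removes the coordinated sign pressure; empirically it is the difference
between chance-level and strong held-out AUC. Gradients were verified
against finite differences before this diagnosis.

## Graph convolution and decoding

Nodes are ordered circRNAs then miRNAs; `A = [[0,B],[Bᵀ,0]]`,
`Â = A + I` (literal addition, no idempotence guard),
`Ã = D̃^{−1/2} Â D̃^{−1/2}` with D̃ the row sums of Â. Ã is symmetric with
spectrum in [−1, 1]. Layers: `H^{(l+1)} = ReLU(Ã H^{(l)} W^{(l)})`, all
layer widths equal (default 64) as required by the attention sum
`M = Σ_{l≥1} n_l H^{(l)}` (H⁽⁰⁾ excluded; three layers with fixed weights
0.7/0.2/0.1 by default). In learnable mode the weights are a softmax over
free logits, so they stay non-negative and sum to one.

Scores are `S = sigmoid(M Mᵀ)`; the C×M block is used for ranking and
evaluation, ties broken by ascending (circ, miRNA) index. The training
loss over labelled pairs (positives + an equal number of uniformly sampled
non-edges) is

    −mean[ b·ω·log σ(b*) + (1−b)·log(1−σ(b*)) ]

with ω defaulting to the negative:positive ratio of the training set
(1 under balanced sampling) and b* the inner-product logit. Optimisation
is full-batch Adam (lr 0.01, 200 epochs) with hand-derived gradients
(finite-difference-checked to 1e−5 in the suite) and L2 weight decay
5e−3 on the layer weights. The decay strength was set by held-out
cross-validation on the synthetic benchmark, where the unregularised model
overfits the training edges badly (train AUC ≈ 0.998 against held-out
≈ 0.81); 5e−3 raises held-out AUC by ~0.05 without affecting anything
else.

## Cross-validation protocol

Positives are randomly partitioned into five folds; per fold, training
negatives (|train positives| of them) and test negatives
(|test positives|) are sampled uniformly from non-edges, disjoint from all
positives and from each other. The adjacency, kernels, autoencoders and
GCN are all rebuilt from the fold's training positives, so a held-out
edge influences neither the features nor the propagation graph. Metrics:
accuracy/precision/recall at a 0.5 cutoff, AUC (tie-averaged rank
statistic) and AUPR (precision–recall step integration), per fold and
averaged. The ablation harness skips propagation entirely and decodes the
z-scored latents directly, isolating the GCN's contribution.

## Synthetic benchmarks

The generator emulates the statistical structure the model assumes: a
planted-block bipartite graph (round-robin block assignment, edge
probability p within blocks, q elsewhere) and uniform-random RNA
sequences in realistic length ranges (circRNAs 200–2000 nt, miRNAs
18–25 nt). With motif planting on, each block's members share a random
6-mer inserted once per ~100 nt of circRNA and once per miRNA, so the
block signal is visible to the k-mer channel as well as to the
interaction-profile kernels. Presets: `strong` (60×40, 4 blocks, p=0.5,
q=0.01, motifs) and `null` (p=q=0.05, no motifs). The sizes keep a full
five-fold, five-seed evaluation under a few minutes on one CPU; they are
the problem sizes used throughout the test suite.

What the benchmark does *not* emulate: real base composition and
secondary structure, degree heterogeneity of curated databases, and
node-level heterogeneity *within* communities. The last point matters for
depth experiments: the planted blocks are dense and nearly disconnected
from one another, so repeated propagation converges toward per-block
means — which is exactly the planted signal — and held-out AUC increases
(then saturates) with depth on this benchmark. The over-smoothing decline
reported for large sparse real interaction graphs, where deep propagation
mixes unrelated nodes, does not reproduce here; a depth sweep on real
data is expected to behave differently from the synthetic one.

On the `null` preset mean held-out AUC sits slightly above 0.5 (~0.52)
rather than exactly at chance: even in a structureless graph, node degree
is informative about held-out positives (high-degree nodes are more
likely to carry additional edges), a real statistical signal, not leakage.

## Numerical choices and edge cases

- Log arguments in the cross-entropy are clamped at 1e−12; KL inputs at
  1e−8. GIP diagonals are set to exactly 1.
- Seeds: every stochastic step (negative sampling, fold partition,
  parameter initialisation) derives from an explicit integer seed;
  per-fold seeds come from `SeedSequence([seed, fold, salt])`, keeping
  runs bit-reproducible and folds independent.
- Duplicate interaction rows are dropped with a logged warning; id order
  is first appearance, so index maps never depend on sort order.
- Degenerate metric cases (no predicted positives / no true positives)
  yield NaN with a warning rather than an exception.

## Known limitations

- Every score lies in [0.5, 1): embeddings are sums of ReLU outputs,
  hence entrywise non-negative, so inner-product logits are ≥ 0. At the
  default 0.5 cutoff every pair is predicted positive and the
  accuracy/precision/recall columns are degenerate (0.5/0.5/1.0 under
  balanced evaluation); this is a structural property of the
  architecture, shared by the design it follows, not a bug in scoring.
  Threshold-free metrics (AUC/AUPR) carry the evaluation; a practitioner
  wanting calibrated decisions should choose a cutoff from the score
  distribution, e.g. the balanced-accuracy point on training scores.
- The sigmoid-kernel reading (standard kernel on interaction profiles) is
  one documented interpretation of an under-specified construction; the
  fusion rule's "both nonzero" branch is likewise a documented choice.
- Training is full-batch and dense; the implementation targets datasets
  up to a few thousand nodes per class, not genome-scale graphs.
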