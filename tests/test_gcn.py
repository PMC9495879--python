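import math

import numpy as np
import pytest

from circmilink.gcn import (
    GCNConfig,
    GCNModel,
    ScoreMatrix,
    add_self_loops,
    build_combined_adjacency,
    embed,
    gcn_forward,
    inner_product_decode,
    layer_attention_combine,
    normalize_adjacency,
    pair_logits,
    rank_candidates,
    to_node_pairs,
    train_model,
    weighted_bce_loss,
)
from circmilink.gcn import _loss_and_grads
from oracles import bce_oracle, decode_oracle, gcn_forward_oracle, normalize_oracle


class TestSelfLoops:
    def test_zero_matrix_becomes_identity(self):
        assert np.array_equal(add_self_loops(np.zeros((3, 3))), np.eye(3))

    def test_literal_addition_no_idempotence(self):
        out = add_self_loops(np.eye(2))
        assert np.array_equal(np.diag(out), [2, 2])

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            add_self_loops(np.zeros((2, 3)))


class TestNormalization:
    def test_two_node_edge(self):
        A_hat = add_self_loops(np.array([[0.0, 1.0], [1.0, 0.0]]))
        At = normalize_adjacency(A_hat).matrix
        assert np.allclose(At, 0.5)

    def test_isolated_node_diagonal_one(self):
        A_hat = add_self_loops(np.zeros((1, 1)))
        assert normalize_adjacency(A_hat).matrix[0, 0] == 1.0

    def test_matches_loop_oracle_and_symmetry(self, rng):
        B = rng.integers(0, 2, (4, 3)).astype(float)
        A_hat = add_self_loops(build_combined_adjacency(B))
        got = normalize_adjacency(A_hat).matrix
        want = normalize_oracle(A_hat.tolist())
        assert np.abs(got - want).max() < 1e-10
        assert np.allclose(got, got.T)

    def test_spectrum_within_unit_interval(self, rng):
        for _ in range(5):
            B = rng.integers(0, 2, (6, 5)).astype(float)
            At = normalize_adjacency(add_self_loops(build_combined_adjacency(B))).matrix
            eig = np.linalg.eigvalsh(At)
            assert eig.min() >= -1 - 1e-10 and eig.max() <= 1 + 1e-10

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="zero row"):
            normalize_adjacency(np.array([[1.0, 0.0], [0.0, 0.0]]))


class TestForward:
    def test_identity_propagation(self):
        cfg = GCNConfig(n_layers=1, hidden_dim=3, attention_weights=(1.0,))
        model = GCNModel.initialize(3, cfg)
        model.weights[0] = np.eye(3)
        H0 = np.abs(np.random.default_rng(0).normal(size=(4, 3)))
        out = gcn_forward(model, np.eye(4), H0)
        assert np.allclose(out[0], H0)

    def test_outputs_non_negative(self, rng):
        cfg = GCNConfig(n_layers=3, hidden_dim=4, attention_weights=None)
        model = GCNModel.initialize(5, cfg)
        B = rng.integers(0, 2, (3, 2)).astype(float)
        At = normalize_adjacency(add_self_loops(build_combined_adjacency(B)))
        for H in gcn_forward(model, At, rng.normal(size=(5, 5))):
            assert (H >= 0).all()

    def test_matches_triple_loop_oracle(self, rng):
        cfg = GCNConfig(n_layers=2, hidden_dim=3, attention_weights=None, seed=5)
        model = GCNModel.initialize(2, cfg)
        B = rng.integers(0, 2, (2, 2)).astype(float)
        At = normalize_adjacency(add_self_loops(build_combined_adjacency(B))).matrix
        H0 = rng.normal(size=(4, 2))
        got = gcn_forward(model, At, H0)
        want = gcn_forward_oracle(At.tolist(), H0.tolist(), [W.tolist() for W in model.weights])
        for g, w in zip(got, want):
            assert np.abs(g - w).max() < 1e-10


class TestAttention:
    def test_single_layer_weight_one(self, rng):
        H = rng.normal(size=(3, 2))
        assert np.array_equal(layer_attention_combine([H], np.array([1.0])), H)

    def test_identical_embeddings_convex_weights(self, rng):
        H = rng.normal(size=(4, 3))
        out = layer_attention_combine([H, H, H], np.array([0.7, 0.2, 0.1]))
        assert np.allclose(out, H)

    def test_default_fixed_weights(self):
        assert GCNConfig().resolved_weights() == pytest.approx([0.7, 0.2, 0.1])

    def test_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="weights"):
            layer_attention_combine([rng.normal(size=(2, 2))], np.array([0.5, 0.5]))

    def test_learnable_weights_simplex(self):
        cfg = GCNConfig(attention="learnable")
        model = GCNModel.initialize(4, cfg)
        w = model.attention_vector()
        assert w.sum() == pytest.approx(1.0) and (w >= 0).all()


class TestDecoder:
    def test_zero_embeddings_half_scores(self):
        S = inner_product_decode(np.zeros((3, 2)))
        assert np.allclose(S.matrix, 0.5)

    def test_orthonormal_rows(self):
        S = inner_product_decode(np.eye(2))
        assert S.matrix[0, 1] == pytest.approx(0.5)
        assert S.matrix[0, 0] == pytest.approx(1 / (1 + math.exp(-1)))

    def test_symmetric_and_matches_loop(self, rng):
        M = rng.normal(size=(5, 3))
        S = inner_product_decode(M).matrix
        assert np.allclose(S, S.T)
        assert np.abs(S - decode_oracle(M.tolist())).max() < 1e-10


class TestLoss:
    @pytest.mark.parametrize(
        "label, logit, omega, expected",
        [(1, 0.0, 1.0, math.log(2)), (0, 0.0, 1.0, math.log(2)), (1, 50.0, 1.0, 0.0)],
    )
    def test_hand_values(self, label, logit, omega, expected):
        got = weighted_bce_loss(np.array([label]), np.array([logit]), omega)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_matches_loop_oracle(self, rng):
        labels = rng.integers(0, 2, 20)
        logits = rng.normal(size=20)
        got = weighted_bce_loss(labels, logits, 2.5)
        assert got == pytest.approx(bce_oracle(labels.tolist(), logits.tolist(), 2.5), abs=1e-12)


class TestTrainingGradients:
    def test_finite_difference_check(self, rng):
        B = rng.integers(0, 2, (3, 2)).astype(float)
        At = normalize_adjacency(add_self_loops(build_combined_adjacency(B))).matrix
        H0 = rng.normal(size=(5, 4))
        cfg = GCNConfig(
            n_layers=2, hidden_dim=3, attention="learnable", attention_weights=(0.6, 0.4), seed=0
        )
        model = GCNModel.initialize(4, cfg)
        pairs = np.array([[0, 3], [1, 4], [2, 3], [0, 4]])
        labels = np.array([1, 0, 1, 0])
        _, gW, gl = _loss_and_grads(model, At, H0, pairs, labels, 1.5)
        eps = 1e-6

        def loss_now():
            return _loss_and_grads(model, At, H0, pairs, labels, 1.5)[0]

        for li, W in enumerate(model.weights):
            flat = W.reshape(-1)
            for idx in range(flat.size):
                flat[idx] += eps
                up = loss_now()
                flat[idx] -= 2 * eps
                down = loss_now()
                flat[idx] += eps
                assert abs((up - down) / (2 * eps) - gW[li].reshape(-1)[idx]) < 1e-5
        for idx in range(len(model.attention_logits)):
            model.attention_logits[idx] += eps
            up = loss_now()
            model.attention_logits[idx] -= 2 * eps
            down = loss_now()
            model.attention_logits[idx] += eps
            assert abs((up - down) / (2 * eps) - gl[idx]) < 1e-5


class TestTraining:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        n_c = n_m = 10
        blocks_c = np.arange(n_c) % 2
        blocks_m = np.arange(n_m) % 2
        B = (blocks_c[:, None] == blocks_m[None, :]).astype(float)
        B *= rng.random(B.shape) < 0.8
        At = normalize_adjacency(add_self_loops(build_combined_adjacency(B)))
        H0 = rng.normal(size=(n_c + n_m, 6))
        pos = [(i, j) for i in range(n_c) for j in range(n_m) if B[i, j]]
        neg = [(i, j) for i in range(n_c) for j in range(n_m) if not B[i, j]][: len(pos)]
        pairs = pos + neg
        labels = np.array([1] * len(pos) + [0] * len(neg))
        return At, H0, pairs, labels, n_c

    def test_seeded_loss_traces_identical(self):
        At, H0, pairs, labels, n_c = self._setup()
        cfg = GCNConfig(n_layers=2, hidden_dim=4, attention_weights=None, epochs=30, seed=3)
        _, t1 = train_model(H0, At, pairs, labels, cfg, n_c)
        _, t2 = train_model(H0, At, pairs, labels, cfg, n_c)
        assert t1.loss == t2.loss

    def test_loss_decreases_on_planted_signal(self):
        At, H0, pairs, labels, n_c = self._setup()
        cfg = GCNConfig(n_layers=2, hidden_dim=4, attention_weights=None, epochs=100, seed=3)
        _, trace = train_model(H0, At, pairs, labels, cfg, n_c)
        assert trace.loss[-1] < trace.loss[0]

    def test_zero_epochs_leaves_model_at_init(self):
        At, H0, pairs, labels, n_c = self._setup()
        cfg = GCNConfig(n_layers=2, hidden_dim=4, attention_weights=None, epochs=0, seed=3)
        model, trace = train_model(H0, At, pairs, labels, cfg, n_c)
        ref = GCNModel.initialize(H0.shape[1], cfg)
        for a, b in zip(model.weights, ref.weights):
            assert np.array_equal(a, b)
        assert trace.loss == []

    def test_out_of_range_pair_rejected(self):
        At, H0, pairs, labels, n_c = self._setup()
        with pytest.raises(ValueError, match="outside"):
            train_model(H0, At, [(0, 99)], np.array([1]), GCNConfig(), n_c)


class TestRanking:
    def test_tie_break_index_order(self):
        S = ScoreMatrix(np.full((4, 4), 0.5), n_circ=2)
        ranked = rank_candidates(S, set())
        assert [(i, j) for i, j, _ in ranked] == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_highest_score_first_and_known_excluded(self):
        mat = np.full((4, 4), 0.1)
        mat[0, 3] = 0.9  # circ 0 x mirna 1
        S = ScoreMatrix(mat, n_circ=2)
        ranked = rank_candidates(S, {(1, 1)})
        assert ranked[0][:2] == (0, 1)
        assert (1, 1) not in [(i, j) for i, j, _ in ranked]

    def test_logit_helper_offsets_mirna_indices(self, rng):
        M = rng.normal(size=(5, 3))
        pairs = to_node_pairs({(0, 1), (2, 0)}, n_circ=3)
        logits = pair_logits(M, pairs)
        assert logits[0] == pytest.approx(M[0] @ M[4])  # sorted: (0,1) first
        assert logits[1] == pytest.approx(M[2] @ M[3])

    def test_embed_combines_layers(self, rng):
        cfg = GCNConfig(n_layers=2, hidden_dim=3, attention_weights=(0.5, 0.5), seed=1)
        model = GCNModel.initialize(4, cfg)
        At = np.eye(6)
        H0 = rng.normal(size=(6, 4))
        layers = gcn_forward(model, At, H0)
        assert np.allclose(embed(model, At, H0), 0.5 * layers[0] + 0.5 * layers[1])
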