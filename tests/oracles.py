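"""Independent brute-force oracles: scalar loops and direct definitions,
deliberately sharing no code with the package implementation."""

import math

import numpy as np


def gip_oracle(profiles, alpha_prime):
    n = len(profiles)
    mean_sq = sum(sum(x * x for x in row) for row in profiles) / n
    alpha = alpha_prime / mean_sq
    G = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            sq = sum((a - b) ** 2 for a, b in zip(profiles[i], profiles[j]))
            G[i, j] = math.exp(-alpha * sq)
    return G


def sigmoid_kernel_oracle(vectors):
    n, V = len(vectors), len(vectors[0])
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = math.tanh(sum(a * b for a, b in zip(vectors[i], vectors[j])) / V)
    return K


def normalize_oracle(A_hat):
    n = len(A_hat)
    deg = [sum(A_hat[i]) for i in range(n)]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = A_hat[i][j] / math.sqrt(deg[i]) / math.sqrt(deg[j])
    return out


def gcn_forward_oracle(At, H0, weight_list):
    """Triple-loop matrix products with ReLU between layers."""
    H = [list(row) for row in H0]
    outputs = []
    for W in weight_list:
        n, d_in = len(H), len(H[0])
        d_out = len(W[0])
        AH = [[sum(At[i][k] * H[k][j] for k in range(n)) for j in range(d_in)] for i in range(n)]
        Z = [
            [sum(AH[i][k] * W[k][j] for k in range(d_in)) for j in range(d_out)]
            for i in range(n)
        ]
        H = [[max(z, 0.0) for z in row] for row in Z]
        outputs.append(np.array(H))
    return outputs


def decode_oracle(M):
    n = len(M)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            dot = sum(a * b for a, b in zip(M[i], M[j]))
            S[i, j] = 1.0 / (1.0 + math.exp(-dot))
    return S


def bce_oracle(labels, logits, omega):
    total = 0.0
    for b, x in zip(labels, logits):
        p = 1.0 / (1.0 + math.exp(-x))
        p = min(max(p, 1e-12), 1 - 1e-12)
        total += -(b * math.log(p) * omega + (1 - b) * math.log(1 - p))
    return total / len(labels)


def auc_oracle(labels, scores):
    """Concordant-pair count with half credit for ties."""
    pos = [s for s, b in zip(scores, labels) if b == 1]
    neg = [s for s, b in zip(scores, labels) if b == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def aupr_oracle(labels, scores):
    """Step integration sum_n (R_n - R_{n-1}) P_n over descending unique
    score thresholds."""
    n_pos = sum(labels)
    thresholds = sorted(set(scores), reverse=True)
    area, prev_recall = 0.0, 0.0
    for t in thresholds:
        tp = sum(1 for s, b in zip(scores, labels) if s >= t and b == 1)
        fp = sum(1 for s, b in zip(scores, labels) if s >= t and b == 0)
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def sae_cost_oracle(W_enc, b_enc, W_dec, b_dec, X, rho, delta):
    """Element-wise forward pass + cost, scalar loops only."""
    n, width = len(X), len(X[0])
    d = len(b_enc)
    hidden = []
    for i in range(n):
        row = []
        for h in range(d):
            z = b_enc[h] + sum(X[i][v] * W_enc[v][h] for v in range(width))
            row.append(1.0 / (1.0 + math.exp(-z)))
        hidden.append(row)
    sq_err = 0.0
    for i in range(n):
        for v in range(width):
            z = b_dec[v] + sum(hidden[i][h] * W_dec[h][v] for h in range(d))
            recon = 1.0 / (1.0 + math.exp(-z))
            sq_err += (recon - X[i][v]) ** 2
    mse = sq_err / (n * width)
    penalty = 0.0
    for h in range(d):
        rho_hat = sum(hidden[i][h] for i in range(n)) / n
        penalty += rho * math.log(rho / rho_hat) + (1 - rho) * math.log((1 - rho) / (1 - rho_hat))
    return mse + delta * penalty
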