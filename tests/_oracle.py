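"""Independent scalar-loop re-implementation of every pipeline formula.

Everything here uses plain Python lists, floats and explicit loops --
no numpy matrix operations -- so it can serve as an oracle for the
vectorized library without sharing any code path with it.
"""

from __future__ import annotations

import math


def unit(v):
    n = math.sqrt(sum(x * x for x in v))
    return [x / n for x in v]


def matmul(A, B):
    n, k, m = len(A), len(B), len(B[0])
    return [[sum(A[i][t] * B[t][j] for t in range(k)) for j in range(m)] for i in range(n)]


def transpose(A):
    return [list(col) for col in zip(*A)]


def softmax_row(row):
    mx = max(row)
    ex = [math.exp(x - mx) for x in row]
    s = sum(ex)
    return [e / s for e in ex]


# --- text fusion -----------------------------------------------------------


def intra_attention(X, normalize=True):
    """Returns (S, A, AW, a): similarities, attention weights, weighted
    rows, and the fused (optionally unit) vector."""
    M, D = len(X), len(X[0])
    S = [[sum(X[i][d] * X[j][d] for d in range(D)) for j in range(M)] for i in range(M)]
    A = [softmax_row(r) for r in S]
    AW = matmul(A, X)
    a = [sum(AW[i][d] for i in range(M)) / M for d in range(D)]
    if normalize:
        a = unit(a)
    return S, A, AW, a


def average_fusion(X, normalize=True):
    M, D = len(X), len(X[0])
    a = [sum(X[i][d] for i in range(M)) / M for d in range(D)]
    return unit(a) if normalize else a


# --- cache core ------------------------------------------------------------


def zero_shot(f, W, scale=1.0):
    return [scale * sum(f[d] * w[d] for d in range(len(f))) for w in W]


def channel_scores(W):
    """Inter-class dispersion per channel: sum_{i != j} (W_id - W_jd)^2 / (C(C-1))."""
    C, D = len(W), len(W[0])
    out = []
    for d in range(D):
        s = 0.0
        for i in range(C):
            for j in range(C):
                if i != j:
                    s += (W[i][d] - W[j][d]) ** 2
        out.append(s / (C * (C - 1)))
    return out


def refine(W, E):
    scores = channel_scores(W)
    ranked = sorted(range(len(scores)), key=lambda d: (-scores[d], d))
    return sorted(ranked[:E])


def mask_renorm(v, mask):
    return unit([v[d] for d in mask])


def affinity(fp, Fp, beta):
    return [
        math.exp(-beta * (1.0 - sum(fp[e] * row[e] for e in range(len(fp))))) for row in Fp
    ]


def kl_cache_scores(Fp, Wp, L, gamma, scale=1.0, eps=1e-6):
    C = len(Wp)
    out = []
    for k in range(len(Fp)):
        logits = zero_shot(Fp[k], Wp, scale)
        p = softmax_row(logits)
        q = [(1.0 - eps) * L[k][c] + eps / C for c in range(C)]
        d = sum(q[c] * (math.log(q[c]) - math.log(p[c])) for c in range(C))
        out.append(math.exp(gamma * d))
    return out


def tip_logits(f, W, F, L, alpha, beta, scale=1.0):
    base = zero_shot(f, W, scale)
    aff = affinity(f, F, beta)
    C = len(W)
    return [base[c] + alpha * sum(aff[k] * L[k][c] for k in range(len(F))) for c in range(C)]


def trilateral_logits(f, W, F, L, mask, alpha, beta, gamma, scale=1.0):
    """Training-free final logits; returns (logits, intermediates)."""
    base = zero_shot(f, W, scale)
    fp = mask_renorm(f, mask)
    Fp = [mask_renorm(row, mask) for row in F]
    Wp = [mask_renorm(row, mask) for row in W]
    aff = affinity(fp, Fp, beta)
    scores = kl_cache_scores(Fp, Wp, L, gamma, scale)
    C = len(W)
    logits = [
        base[c] + alpha * sum(aff[k] * scores[k] * L[k][c] for k in range(len(F)))
        for c in range(C)
    ]
    return logits, {"r_fw": base, "aff": aff, "scores": scores, "fp": fp}


# --- SE / residual branch --------------------------------------------------


def sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def se_forward(W, W1, W2):
    """Returns (y, h, lam, W_att) of the squeeze-excite gate."""
    C, D = len(W), len(W[0])
    y = [sum(W[i][d] for i in range(C)) / C for d in range(D)]
    hidden = len(W1)
    u = [sum(W1[t][d] * y[d] for d in range(D)) for t in range(hidden)]
    h = [max(x, 0.0) for x in u]
    lam = [sigmoid(sum(W2[d][t] * h[t] for t in range(hidden))) for d in range(D)]
    W_att = [[W[i][d] * lam[d] for d in range(D)] for i in range(C)]
    return y, h, lam, W_att


def pad(res, mask, D):
    C = len(res)
    out = [[0.0] * D for _ in range(C)]
    for i in range(C):
        for j, d in enumerate(mask):
            out[i][d] = res[i][j]
    return out


def expand(res, K):
    out = []
    for row in res:
        out.extend([list(row)] * K)
    return out


def vlcdt_logits(f, W, F, L, mask, res, scores, W1, W2, alpha, beta, scale=1.0, use_se=True):
    C, D = len(W), len(W[0])
    if use_se:
        _, _, _, W_att = se_forward(W, W1, W2)
    else:
        W_att = [list(row) for row in W]
    padded = pad(res, mask, D)
    W_eff = [[W_att[i][d] + padded[i][d] for d in range(D)] for i in range(C)]
    base = zero_shot(f, W_eff, scale)
    fp = mask_renorm(f, mask)
    Fp = [mask_renorm(row, mask) for row in F]
    K = len(F) // C
    exp_res = expand(res, K)
    F_eff = [
        [Fp[k][e] + exp_res[k][e] for e in range(len(mask))] for k in range(len(F))
    ]
    aff = affinity(fp, F_eff, beta)
    return [
        base[c] + alpha * sum(aff[k] * scores[k] * L[k][c] for k in range(len(F)))
        for c in range(C)
    ]


def cross_entropy(logits_rows, labels):
    total = 0.0
    for row, lab in zip(logits_rows, labels):
        p = softmax_row(row)
        total -= math.log(p[lab])
    return total / len(labels)
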