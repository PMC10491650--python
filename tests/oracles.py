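"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain scalar loops (or exhaustive enumeration),
deliberately sharing no code path with the package.
"""

import math

import numpy as np


def conv1d_loops(x, kernels, biases):
    """Nested-loop valid cross-correlation: x (Cin, T), kernels (Cout, Cin, K)."""
    c_out, c_in, k = kernels.shape
    t_out = x.shape[1] - k + 1
    u = np.zeros((c_out, t_out))
    for m in range(c_out):
        for t in range(t_out):
            acc = biases[m]
            for n in range(c_in):
                for j in range(k):
                    acc += x[n, t + j] * kernels[m, n, j]
            u[m, t] = acc
    return u


def maxpool_loops(x, size, stride, scale=1.0, bias=0.0):
    c, t = x.shape
    starts = list(range(0, t - size + 1, stride))
    out = np.zeros((c, len(starts)))
    for ch in range(c):
        for i, s in enumerate(starts):
            out[ch, i] = scale * max(x[ch, s : s + size]) + bias
    return out


def _sig(v):
    return 1.0 / (1.0 + math.exp(-v))


def lstm_step_loops(x_t, h_prev, c_prev, W_f, W_i, W_o, W_C, b_f, b_i, b_o, b_C):
    """Scalar evaluation of the five gate equations on z = [h_prev, x_t]."""
    z = list(h_prev) + list(x_t)
    hidden = len(h_prev)
    f = [0.0] * hidden
    i_g = [0.0] * hidden
    o = [0.0] * hidden
    ct = [0.0] * hidden
    c = [0.0] * hidden
    h = [0.0] * hidden
    for r in range(hidden):
        sf = si = so = sc = 0.0
        for j, zj in enumerate(z):
            sf += W_f[r][j] * zj
            si += W_i[r][j] * zj
            so += W_o[r][j] * zj
            sc += W_C[r][j] * zj
        f[r] = _sig(sf + b_f[r])
        i_g[r] = _sig(si + b_i[r])
        o[r] = _sig(so + b_o[r])
        ct[r] = math.tanh(sc + b_C[r])
        c[r] = f[r] * c_prev[r] + i_g[r] * ct[r]
        h[r] = o[r] * math.tanh(c[r])
    return np.array(f), np.array(i_g), np.array(o), np.array(ct), np.array(c), np.array(h)


def lstm_forward_loops(seq, W_f, W_i, W_o, W_C, b_f, b_i, b_o, b_C):
    hidden = len(b_f)
    h = np.zeros(hidden)
    c = np.zeros(hidden)
    for x_t in seq:
        *_, c, h = lstm_step_loops(x_t, h, c, W_f, W_i, W_o, W_C, b_f, b_i, b_o, b_C)
    return h


def softmax_loops(u):
    m = max(u)
    e = [math.exp(v - m) for v in u]
    s = sum(e)
    return np.array([v / s for v in e])


def confusion_loops(truths, preds, k):
    A = np.zeros((k, k), dtype=int)
    for t, p in zip(truths, preds):
        A[t][p] += 1
    return A


def auc_pair_counting(scores, positives):
    """Mann-Whitney statistic by exhaustive pair enumeration, ties counted 1/2."""
    pos = [s for s, p in zip(scores, positives) if p]
    neg = [s for s, p in zip(scores, positives) if not p]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pr_points_brute(scores, positives):
    """Precision/recall at every distinct threshold via per-threshold recount."""
    n_pos = sum(positives)
    out = []
    for thr in sorted(set(scores), reverse=True):
        tp = sum(1 for s, p in zip(scores, positives) if p and s >= thr)
        fp = sum(1 for s, p in zip(scores, positives) if not p and s >= thr)
        out.append((thr, tp / (tp + fp), tp / n_pos))
    return np.array(out)


def ovr_specificity_loops(A, g):
    """One-vs-rest true-negative rate of group g from a confusion table."""
    k = A.shape[0]
    tn = fp = 0
    for i in range(k):
        for j in range(k):
            if i != g:
                if j == g:
                    fp += A[i][j]
                else:
                    tn += A[i][j]
    return tn / (tn + fp)


def ovr_recall_loops(A, g):
    row = sum(A[g])
    return A[g][g] / row
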