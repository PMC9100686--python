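"""Independent brute-force oracles: scalar-loop implementations of every
numerical contract, kept deliberately naive and separate from the package
code paths they check."""

from __future__ import annotations

import math

import numpy as np


def pearson_oracle(values: np.ndarray) -> np.ndarray:
    """Textbook Pearson coefficient, element by element."""
    m, n = values.shape
    out = np.empty((n, n))
    means = [sum(values[:, j]) / m for j in range(n)]
    for i in range(n):
        for j in range(n):
            num = sum(
                (values[t, i] - means[i]) * (values[t, j] - means[j]) for t in range(m)
            )
            den_i = sum((values[t, i] - means[i]) ** 2 for t in range(m))
            den_j = sum((values[t, j] - means[j]) ** 2 for t in range(m))
            out[i, j] = num / math.sqrt(den_i * den_j)
    return out


def knn_oracle(b: np.ndarray, k: int, absolute: bool = True) -> np.ndarray:
    """Exhaustive sort-and-select top-k per node, then OR symmetrization."""
    n = b.shape[0]
    strength = np.abs(b) if absolute else b.copy()
    adj = np.zeros((n, n))
    for i in range(n):
        candidates = [(-strength[i, j], j) for j in range(n) if j != i]
        candidates.sort()
        for _, j in candidates[:k]:
            adj[i, j] = 1.0
    out = np.maximum(adj, adj.T)
    np.fill_diagonal(out, 0.0)
    return out


def threshold_oracle(b: np.ndarray, q: float, absolute: bool = True) -> np.ndarray:
    n = b.shape[0]
    strength = np.abs(b) if absolute else b
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and strength[i, j] > q:
                out[i, j] = 1.0
    return out


def normalize_oracle(a: np.ndarray) -> np.ndarray:
    """Explicit D^{-1/2} (A + I) D^{-1/2} from scalar loops."""
    n = a.shape[0]
    a_hat = a + np.eye(n)
    deg = [sum(a_hat[i, j] for j in range(n)) for i in range(n)]
    out = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = a_hat[i, j] / math.sqrt(deg[i] * deg[j])
    return out


def gcn_layer_oracle(a: np.ndarray, h: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Three-nested-loop matrix products with ReLU."""
    n, d_in = h.shape
    d_out = w.shape[1]
    s = np.zeros((n, d_in))
    for i in range(n):
        for j in range(d_in):
            s[i, j] = sum(a[i, t] * h[t, j] for t in range(n))
    z = np.zeros((n, d_out))
    for i in range(n):
        for j in range(d_out):
            z[i, j] = max(0.0, sum(s[i, t] * w[t, j] for t in range(d_in)))
    return z


def readout_oracle(z: np.ndarray) -> np.ndarray:
    n, d = z.shape
    mean = [sum(z[i, j] for i in range(n)) / n for j in range(d)]
    mx = [max(z[i, j] for i in range(n)) for j in range(d)]
    return np.array(mean + mx)


def conv3d_oracle(
    x: np.ndarray, w: np.ndarray, b: np.ndarray, pad: int
) -> np.ndarray:
    """Seven-nested-loop same-padding stride-1 3-D convolution.

    x: (C_in, H, W, D); w: (C_out, C_in, k, k, k); returns (C_out, H, W, D).
    """
    c_in, h, wd, d = x.shape
    c_out, _, k, _, _ = w.shape
    xp = np.zeros((c_in, h + 2 * pad, wd + 2 * pad, d + 2 * pad))
    xp[:, pad : pad + h, pad : pad + wd, pad : pad + d] = x
    out = np.zeros((c_out, h, wd, d))
    for co in range(c_out):
        for i in range(h):
            for j in range(wd):
                for l in range(d):
                    acc = b[co]
                    for ci in range(c_in):
                        for a in range(k):
                            for bb in range(k):
                                for c in range(k):
                                    acc += w[co, ci, a, bb, c] * xp[ci, i + a, j + bb, l + c]
                    out[co, i, j, l] = acc
    return out


def maxpool_oracle(x: np.ndarray) -> np.ndarray:
    """2x2x2 stride-2 floor max pooling on (C, H, W, D)."""
    c, h, w, d = x.shape
    out = np.empty((c, h // 2, w // 2, d // 2))
    for ci in range(c):
        for i in range(h // 2):
            for j in range(w // 2):
                for l in range(d // 2):
                    out[ci, i, j, l] = x[
                        ci, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2, 2 * l : 2 * l + 2
                    ].max()
    return out


def gap_oracle(x: np.ndarray) -> np.ndarray:
    c, h, w, d = x.shape
    return np.array(
        [
            sum(x[ci, i, j, l] for i in range(h) for j in range(w) for l in range(d))
            / (h * w * d)
            for ci in range(c)
        ]
    )


def mmd_linear_oracle(f: np.ndarray, s: np.ndarray) -> float:
    """Mean-then-norm, one scalar at a time."""
    d = f.shape[1]
    diff = [
        sum(f[i, j] for i in range(f.shape[0])) / f.shape[0]
        - sum(s[i, j] for i in range(s.shape[0])) / s.shape[0]
        for j in range(d)
    ]
    return math.sqrt(sum(x * x for x in diff))


def cross_entropy_oracle(pairs: list[tuple[int, float]]) -> float:
    total = 0.0
    for y, p in pairs:
        p = min(max(p, 1e-7), 1 - 1e-7)
        total += y * math.log(p) + (1 - y) * math.log(1 - p)
    return -total / len(pairs)


def auc_pairwise_oracle(y: np.ndarray, p: np.ndarray) -> float:
    """O(n^2) Mann-Whitney AUC with half-credit ties."""
    pos = p[y == 1]
    neg = p[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def t_statistic_oracle(diffs: np.ndarray) -> float:
    n = len(diffs)
    mean = sum(diffs) / n
    var = sum((x - mean) ** 2 for x in diffs) / (n - 1)
    return mean / math.sqrt(var / n)


def affine_oracle(x: np.ndarray, w: np.ndarray, b: np.ndarray, relu: bool) -> np.ndarray:
    """Scalar-loop affine map, optionally through ReLU."""
    out = np.empty(w.shape[1])
    for j in range(w.shape[1]):
        acc = b[j]
        for i in range(w.shape[0]):
            acc += x[i] * w[i, j]
        out[j] = max(acc, 0.0) if relu else acc
    return out
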