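"""Independent brute-force oracles used by the tests.

Everything here is written as plain nested loops over explicit indices —
deliberately naive, so the vectorized implementations are checked against a
computation whose correctness is visible by inspection.
"""

from __future__ import annotations

import math

import numpy as np


def softmax_2d_loops(logits: np.ndarray) -> np.ndarray:
    """Spatial softmax of an (H, W) logit grid by explicit summation."""
    h, w = logits.shape
    m = max(logits[i][j] for i in range(h) for j in range(w))
    total = 0.0
    for i in range(h):
        for j in range(w):
            total += math.exp(logits[i][j] - m)
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = math.exp(logits[i][j] - m) / total
    return out


def conv1d_loops(row: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-padded same-length 1-D correlation by explicit index walking."""
    n, k = len(row), len(kernel)
    pad = k // 2
    out = np.zeros(n)
    for i in range(n):
        for j in range(k):
            src = i + j - pad
            if 0 <= src < n:
                out[i] += kernel[j] * row[src]
    return out


def conv1d_2row_loops(top: np.ndarray, bot: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Two-row selection convolution by explicit loops (kernel is (2, k))."""
    return conv1d_loops(top, kernel[0]) + conv1d_loops(bot, kernel[1])


def silu(z: np.ndarray) -> np.ndarray:
    return z / (1.0 + np.exp(-z))


def gcli_a_loops(x: np.ndarray, wk: np.ndarray, bias: float,
                 k7: np.ndarray, k3: np.ndarray,
                 pooling_gc: str = "max") -> np.ndarray:
    """Full module-A forward by stepwise loops: softmax context, weighted map,
    max/avg descriptors, selection conv + SiLU, interaction conv, sigmoid gate."""
    h, w, c = x.shape
    logits = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            logits[i, j] = sum(wk[ch] * x[i, j, ch] for ch in range(c)) + bias
    alpha = softmax_2d_loops(logits)
    weighted = np.empty_like(x)
    for i in range(h):
        for j in range(w):
            for ch in range(c):
                weighted[i, j, ch] = alpha[i, j] * x[i, j, ch]
    f_ctx = np.empty(c)
    f_gap = np.empty(c)
    for ch in range(c):
        vals = [weighted[i, j, ch] for i in range(h) for j in range(w)]
        f_ctx[ch] = max(vals) if pooling_gc == "max" else sum(vals) / len(vals)
        f_gap[ch] = sum(x[i, j, ch] for i in range(h) for j in range(w)) / (h * w)
    f_s = silu(conv1d_2row_loops(f_ctx, f_gap, k7))
    f_att = conv1d_loops(f_s, k3)
    out = np.empty_like(x)
    for i in range(h):
        for j in range(w):
            for ch in range(c):
                out[i, j, ch] = x[i, j, ch] / (1.0 + math.exp(-f_att[ch]))
    return out
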