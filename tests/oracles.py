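"""Independent plain-scalar reference implementations used by the tests.

Everything here is deliberately written as explicit Python loops over NumPy
scalars — no use of the package's autograd ops — so it can serve as an
independent oracle for the vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def silu(x):
    return np.asarray(x, dtype=np.float64) * sigmoid(x)


def relu(x):
    return np.maximum(np.asarray(x, dtype=np.float64), 0.0)


def conv2d(x, w, b=None, stride=1, padding=0):
    """Scalar-loop 2-D cross-correlation. x: (C, H, W); w: (OC, C, KH, KW)."""
    c, h, wd = x.shape
    oc, ic, kh, kw = w.shape
    assert ic == c
    xp = np.zeros((c, h + 2 * padding, wd + 2 * padding))
    xp[:, padding:padding + h, padding:padding + wd] = x
    oh = (h + 2 * padding - kh) // stride + 1
    ow = (wd + 2 * padding - kw) // stride + 1
    out = np.zeros((oc, oh, ow))
    for o in range(oc):
        for i in range(oh):
            for j in range(ow):
                acc = 0.0
                for ci in range(c):
                    for u in range(kh):
                        for v in range(kw):
                            acc += w[o, ci, u, v] * \
                                xp[ci, i * stride + u, j * stride + v]
                out[o, i, j] = acc + (0.0 if b is None else b[o])
    return out


def bn_eval(x, gamma, beta, mean, var, eps=1e-3):
    """Per-channel eval-mode batch norm on (C, H, W)."""
    out = np.empty_like(np.asarray(x, dtype=np.float64))
    for c in range(x.shape[0]):
        out[c] = (x[c] - mean[c]) / math.sqrt(var[c] + eps) * gamma[c] + beta[c]
    return out


def se_block(x, w1, b1, w2, b2):
    """Eqs of squeeze-excitation on (C, H, W): returns (scaled x, gates)."""
    c = x.shape[0]
    z = np.array([x[ci].mean() for ci in range(c)])
    s = sigmoid(w2 @ relu(w1 @ z + b1) + b2)
    out = np.stack([s[ci] * x[ci] for ci in range(c)])
    return out, s


def cbam_channel(x, w1, w2):
    """Channel attention: sigmoid(MLP(avg) + MLP(max)), shared bias-free MLP."""
    c = x.shape[0]
    avg = np.array([x[ci].mean() for ci in range(c)])
    mx = np.array([x[ci].max() for ci in range(c)])
    m = sigmoid(w2 @ relu(w1 @ avg) + w2 @ relu(w1 @ mx))
    out = np.stack([m[ci] * x[ci] for ci in range(c)])
    return m, out


def cbam_spatial(x, w, b):
    """Spatial attention: 7x7 conv over stacked channel-avg/max maps."""
    avg = x.mean(axis=0, keepdims=True)
    mx = x.max(axis=0, keepdims=True)
    stacked = np.concatenate([avg, mx], axis=0)
    return sigmoid(conv2d(stacked, w, b, padding=w.shape[-1] // 2))


def softmax(v):
    e = np.exp(np.asarray(v, dtype=np.float64) - np.max(v))
    return e / e.sum()


def attention(q, k, v, d_k):
    """Scalar loop over query rows: softmax(q k^T / sqrt(d_k)) v."""
    t = q.shape[0]
    out = np.zeros((t, v.shape[1]))
    for i in range(t):
        scores = np.array([q[i] @ k[j] / math.sqrt(d_k) for j in range(t)])
        w = softmax(scores)
        out[i] = sum(w[j] * v[j] for j in range(t))
    return out


def depth_to_space(x, r):
    """out[c, h*r+i, w*r+j] = x[c*r^2 + i*r + j, h, w]."""
    c, h, w = x.shape
    co = c // (r * r)
    out = np.zeros((co, h * r, w * r))
    for cc in range(co):
        for hh in range(h):
            for ww in range(w):
                for i in range(r):
                    for j in range(r):
                        out[cc, hh * r + i, ww * r + j] = \
                            x[cc * r * r + i * r + j, hh, ww]
    return out


def average_precision_sweep(confs, tp_flags, n_truth):
    """Exhaustive threshold enumeration of AP = sum (R_n - R_{n-1}) P_n."""
    confs = np.asarray(confs, dtype=float)
    tp_flags = np.asarray(tp_flags, dtype=bool)
    thresholds = sorted(set(confs), reverse=True)
    ap, prev_r = 0.0, 0.0
    for th in thresholds:
        sel = confs >= th
        tp = int(tp_flags[sel].sum())
        fp = int(sel.sum() - tp)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / n_truth if n_truth else 0.0
        ap += (r - prev_r) * p
        prev_r = r
    return ap
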