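"""Independent reference implementations used only to check the package.

Everything here is deliberately written from first principles (dense linear
algebra, explicit loops, closed forms) and never calls the code under test.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg


def pearson_brute(u, v):
    """Pearson r via explicit covariance / sd computation."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    um, vm = u.mean(), v.mean()
    cov = ((u - um) * (v - vm)).sum()
    return cov / np.sqrt(((u - um) ** 2).sum() * ((v - vm) ** 2).sum())


def zscore_two_pass(col):
    """Two-pass mean/sd standardization (sample sd)."""
    col = np.asarray(col, float)
    mu = sum(col) / len(col)
    var = sum((c - mu) ** 2 for c in col) / (len(col) - 1)
    return (col - mu) / np.sqrt(var)


def affinity_brute(ms, sparsity=0.9):
    """Per-pair arccos normalized-angle affinity after row sparsification."""
    m = np.asarray(ms, float)
    n = m.shape[0]
    rows = np.zeros_like(m)
    for i in range(n):
        off = np.delete(m[i], i)
        thr = np.quantile(off, sparsity)
        for j in range(n):
            if j != i and m[i, j] >= thr:
                rows[i, j] = max(m[i, j], 0.0)
    aff = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            cos = rows[i] @ rows[j] / (
                np.linalg.norm(rows[i]) * np.linalg.norm(rows[j])
            )
            aff[i, j] = 1.0 - np.arccos(np.clip(cos, -1, 1)) / np.pi
    return aff


def diffusion_dense_oracle(w, alpha=0.5, n_components=10):
    """Dense non-symmetric eigensolve of the diffusion transition matrix.

    Right eigenvectors are normalised to unit length in the stationary
    (degree-weighted) inner product, the convention under which the trivial
    eigenvector divides out to a well-defined scale.
    """
    w = np.asarray(w, float)
    d = w.sum(axis=1)
    w1 = w / np.outer(d**alpha, d**alpha)
    d1 = w1.sum(axis=1)
    p = w1 / d1[:, None]
    lam, vec = scipy.linalg.eig(p)
    lam, vec = lam.real, vec.real
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    vec = vec / np.linalg.norm(np.sqrt(d1)[:, None] * vec, axis=0, keepdims=True)
    psi = vec / vec[:, [0]]
    lam_k = lam[1 : n_components + 1]
    comps = psi[:, 1 : n_components + 1] * (lam_k / (1 - lam_k))[None, :]
    return comps, lam_k


def pls1_power_oracle(x, y, n_components):
    """From-scratch univariate-y PLS via repeated rank-1 covariance extraction."""
    x = np.array(x, float)
    y = np.array(y, float)
    scores, weights, ev = [], [], []
    ssy = y @ y
    for _ in range(n_components):
        w = x.T @ y
        w = w / np.sqrt(w @ w)
        t = x @ w
        p = x.T @ t / (t @ t)
        c = (y @ t) / (t @ t)
        x = x - np.outer(t, p)
        y = y - t * c
        scores.append(t)
        weights.append(w)
        ev.append((t @ t) * c**2 / ssy)
    return np.array(scores).T, np.array(weights).T, np.array(ev)


def pls2_power_oracle(x, y, n_components, n_iter=2000):
    """From-scratch two-block power-iteration PLS (multivariate y)."""
    x = np.array(x, float)
    y = np.array(y, float)
    scores, weights, ev = [], [], []
    ssy = (y**2).sum()
    for _ in range(n_components):
        u = y[:, int(np.argmax((y**2).sum(axis=0)))]
        w = None
        for _ in range(n_iter):
            w = x.T @ u
            w = w / np.linalg.norm(w)
            t = x @ w
            c = y.T @ t
            c = c / np.linalg.norm(c)
            u = y @ c
        t = x @ w
        p = x.T @ t / (t @ t)
        creg = y.T @ t / (t @ t)
        x = x - np.outer(t, p)
        y = y - np.outer(t, creg)
        scores.append(t)
        weights.append(w)
        ev.append((t @ t) * (creg @ creg) / ssy)
    return np.array(scores).T, np.array(weights).T, np.array(ev)


def ols_t_by_hand(x, y, coef_index):
    """OLS t for one coefficient via explicit (X'X)^-1 linear algebra."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = x.shape[0] - x.shape[1]
    s2 = resid @ resid / df
    se = np.sqrt(s2 * xtx_inv[coef_index, coef_index])
    return beta[coef_index] / se, df


def bh_stepup_by_hand(p):
    """Literal Benjamini-Hochberg step-up rule."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def vip_by_hand(weights, ss):
    """Direct evaluation of the VIP formula."""
    w = np.asarray(weights, float)
    ss = np.asarray(ss, float)
    p, a = w.shape
    out = np.empty(p)
    for j in range(p):
        acc = 0.0
        for k in range(a):
            acc += ss[k] * (w[j, k] / np.linalg.norm(w[:, k])) ** 2
        out[j] = np.sqrt(p * acc / ss.sum())
    return out
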