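"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["zscore", "spawn_seeds", "pearson"]


def zscore(a: np.ndarray, axis: int = 0, ddof: int = 1) -> np.ndarray:
    """Standardize along ``axis`` using the sample (n-ddof) standard deviation.

    Raises ``ValueError`` if any slice has zero variance.
    """
    a = np.asarray(a, dtype=float)
    mu = a.mean(axis=axis, keepdims=True)
    sd = a.std(axis=axis, ddof=ddof, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance slice encountered during z-scoring")
    return (a - mu) / sd


def spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent child seeds (< 2**31) from a master seed."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=n)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Pearson correlation of two 1-D arrays."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("Pearson correlation undefined for a constant input")
    return float(xc @ yc / denom)
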