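"""Minimal plotting helpers (scatter with fit line, bar maps)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["scatter_with_fit", "bar_map"]


def scatter_with_fit(x, y, xlabel: str = "x", ylabel: str = "y", ax=None):
    """Scatter of two regional maps with a least-squares line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ax.scatter(x, y, s=12, alpha=0.6)
    slope, intercept = np.polyfit(x, y, 1)
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, slope * grid + intercept, color="crimson")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    return ax


def bar_map(values, labels=None, ylabel: str = "value", ax=None):
    """Bar chart of a labelled statistic vector (e.g. network-level t)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    values = np.asarray(values, float)
    pos = np.arange(len(values))
    ax.bar(pos, values)
    if labels is not None:
        ax.set_xticks(pos, labels, rotation=45, ha="right")
    ax.set_ylabel(ylabel)
    return ax
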