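"""NIPALS partial-least-squares core shared by the gene and clinical paths.

Components are extracted by maximal covariance between the predictor block X
and the response block Y, with X (and Y) deflation after each component.  For
a univariate y this reduces to the classical PLS1 recursion with no inner
iteration; for multivariate Y the two-block power iteration is run to
convergence.  Scores are mutually orthogonal, so the per-component explained
Y-variance fractions are exact R-squared increments of the response on the
cumulative score basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PLSResult", "nipals_pls", "pls_regression_coef"]


@dataclass
class PLSResult:
    """Fitted PLS model.

    x_scores: n x A; x_weights: p x A (weights w.r.t. the deflated predictor
    block, unit norm); x_loadings: p x A; y_loadings: q x A (regression
    loadings of Y on each score); explained_variance_y: A fractions of total
    response variance.  Optional downstream annotations (spin p-values per
    component, resampled predictor z-scores with FDR-adjusted p-values) are
    attached by the analysis modules.
    """

    n_components: int
    x_scores: np.ndarray
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    explained_variance_y: np.ndarray
    predictor_names: tuple[str, ...]
    response_names: tuple[str, ...]
    sample_names: tuple[str, ...]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    component_p_spin: np.ndarray | None = None
    gene_z: np.ndarray | None = None
    gene_p: np.ndarray | None = None
    gene_p_fdr: np.ndarray | None = None
    signif_genes: dict[int, list[str]] = field(default_factory=dict)

    @property
    def cumulative_r2(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_y)

    def score_map(self, component: int = 1) -> pd.Series:
        """Regional map of the given (1-based) component's X scores."""
        return pd.Series(
            self.x_scores[:, component - 1],
            index=list(self.sample_names),
            name=f"pls{component}_score",
        )


def nipals_pls(
    x: np.ndarray,
    y: np.ndarray,
    n_components: int,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Raw NIPALS on pre-standardized blocks.

    Returns (T, W, P, C, ev_y): scores n x A, unit-norm weights p x A,
    X loadings p x A, Y regression loadings q x A, and explained-variance
    fractions of Y per component.
    """
    x = np.array(x, dtype=float)
    y = np.array(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, p = x.shape
    q = y.shape[1]
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds the rank bound "
            f"min(n_samples - 1, n_predictors) = {min(n - 1, p)}"
        )
    ss_y = (y**2).sum()
    if ss_y == 0:
        raise ValueError("response block has zero variance")

    t_mat = np.empty((n, n_components))
    w_mat = np.empty((p, n_components))
    p_mat = np.empty((p, n_components))
    c_mat = np.empty((q, n_components))
    ev = np.empty(n_components)

    for a in range(n_components):
        if q == 1:
            w = x.T @ y[:, 0]
            nw = np.linalg.norm(w)
            if nw < 1e-12 * max(1.0, np.abs(x).max()):
                raise ValueError(
                    f"predictor block exhausted after {a} components "
                    "(requested more components than the data's rank supports)"
                )
            w = w / nw
            t = x @ w
        else:
            u = y[:, int(np.argmax((y**2).sum(axis=0)))]
            w = np.zeros(p)
            for _ in range(max_iter):
                w_new = x.T @ u
                nw = np.linalg.norm(w_new)
                if nw < 1e-12:
                    raise ValueError(
                        f"predictor block exhausted after {a} components"
                    )
                w_new = w_new / nw
                t = x @ w_new
                c = y.T @ t
                c = c / np.linalg.norm(c)
                u = y @ c
                if np.linalg.norm(w_new - w) < tol:
                    w = w_new
                    break
                w = w_new
            t = x @ w
        tt = t @ t
        if tt < 1e-12:
            raise ValueError(f"degenerate score at component {a + 1}")
        p_load = x.T @ t / tt
        c_reg = y.T @ t / tt
        x = x - np.outer(t, p_load)
        y = y - np.outer(t, c_reg)
        t_mat[:, a] = t
        w_mat[:, a] = w
        p_mat[:, a] = p_load
        c_mat[:, a] = c_reg
        ev[a] = tt * (c_reg @ c_reg) / ss_y
    return t_mat, w_mat, p_mat, c_mat, ev


def pls_regression_coef(
    w_mat: np.ndarray, p_mat: np.ndarray, c_mat: np.ndarray
) -> np.ndarray:
    """Regression coefficients B (p x q) in standardized space.

    B = W (P'W)^-1 C', the standard identity mapping deflated-space weights
    back to the original predictors.
    """
    pw = p_mat.T @ w_mat
    return w_mat @ np.linalg.solve(pw, c_mat.T)
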