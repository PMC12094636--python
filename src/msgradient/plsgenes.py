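"""PLS imaging transcriptomics.

Links the case-control t-map of principal-gradient scores (response, one
value per left-hemisphere region) to a region x gene expression matrix
(predictors).  Both blocks are z-scored internally across regions.  Component
explained variance is assessed against the spin null; per-gene contributions
are assessed by bootstrap resampling of regions (default) or by region
permutation, giving a z-score per gene, BH-FDR-adjusted p-values, and a
thresholded significant-gene list per component.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._pls import PLSResult, nipals_pls
from ._utils import pearson
from .groupstats import bh_fdr
from .spin import SpinPermutationSet, spin_pvalue

__all__ = [
    "pls_fit",
    "correlate_component_map",
    "gene_significance",
    "export_ranked_genes",
]

logger = logging.getLogger(__name__)


def pls_fit(x: pd.DataFrame, y: pd.Series, n_components: int = 2) -> PLSResult:
    """Fit PLS of a regional map on a region x gene expression matrix.

    ``x``: regions x genes, ``y``: per-region map sharing x's index.  Both
    are z-scored across regions internally (sample sd).
    """
    if isinstance(y, pd.Series):
        y = y.reindex(x.index)
        if y.isna().any():
            raise ValueError("y does not cover every region in X")
    else:
        y = pd.Series(np.asarray(y, float), index=x.index)
    xv = x.to_numpy(float)
    x_mean, x_sd = xv.mean(axis=0), xv.std(axis=0, ddof=1)
    dead = np.flatnonzero(x_sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance predictor column(s): {[x.columns[i] for i in dead[:5]]}"
        )
    yv = y.to_numpy(float)
    y_mean, y_sd = yv.mean(), yv.std(ddof=1)
    if y_sd == 0:
        raise ValueError("response map is constant")
    xz = (xv - x_mean) / x_sd
    yz = (yv - y_mean) / y_sd
    t_mat, w_mat, p_mat, c_mat, ev = nipals_pls(xz, yz, n_components)
    return PLSResult(
        n_components=n_components,
        x_scores=t_mat,
        x_weights=w_mat,
        x_loadings=p_mat,
        y_loadings=c_mat,
        explained_variance_y=ev,
        predictor_names=tuple(map(str, x.columns)),
        response_names=(str(y.name) if y.name else "y",),
        sample_names=tuple(map(str, x.index)),
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=np.atleast_1d(y_mean),
        y_sd=np.atleast_1d(y_sd),
    )


def correlate_component_map(
    result: PLSResult,
    y: pd.Series,
    spins: SpinPermutationSet | None = None,
) -> pd.DataFrame:
    """Pearson r of each component's score map with the response map.

    The score map is the weighted gene-expression map of that component.
    With a spin set, a two-sided spin p-value is attached per component.
    """
    if result.x_scores is None or result.x_scores.size == 0:
        raise ValueError("PLS result is not fitted")
    yv = y.reindex(list(result.sample_names)).to_numpy(float)
    if np.isnan(yv).any():
        raise ValueError("y does not cover the fitted regions")
    rows = []
    for a in range(result.n_components):
        score_map = pd.Series(result.x_scores[:, a], index=list(result.sample_names))
        r = pearson(score_map.to_numpy(), yv)
        if spins is not None:
            _, p_spin = spin_pvalue(score_map, pd.Series(yv, index=score_map.index), spins)
        else:
            p_spin = np.nan
        rows.append({"component": a + 1, "r": r, "p_spin": p_spin})
    return pd.DataFrame(rows)


def _zscore_cols(a: np.ndarray) -> np.ndarray | None:
    """Column z-score; None signals a degenerate (zero-variance) resample."""
    sd = a.std(axis=0, ddof=1)
    if np.any(sd == 0):
        return None
    return (a - a.mean(axis=0)) / sd


def gene_significance(
    x: pd.DataFrame,
    y: pd.Series,
    n_components: int = 2,
    n_resamples: int = 1000,
    method: str = "bootstrap",
    seed: int = 0,
    fdr_threshold: float = 0.001,
) -> PLSResult:
    """Per-gene contribution z-scores with BH-FDR-thresholded gene lists.

    bootstrap (default): regions are resampled with replacement, the model
    refit, each replicate's component sign aligned to the original by
    weight-vector correlation; z = original weight / bootstrap sd with
    two-sided normal p.  region_permutation: null weights from refits with y
    permuted across regions; add-one exceedance p and a moment z-score.
    Degenerate replicates are dropped and logged; more than 10% dropped is an
    error.
    """
    if n_resamples < 500:
        raise ValueError("n_resamples must be >= 500 for stable gene z-scores")
    if method not in ("bootstrap", "region_permutation"):
        raise ValueError(f"unknown method {method!r}")
    result = pls_fit(x, y, n_components)
    w_obs = result.x_weights  # genes x A
    xv = x.to_numpy(float)
    yv = y.reindex(x.index).to_numpy(float)
    n = xv.shape[0]
    rng = np.random.default_rng(seed)

    reps = np.empty((n_resamples,) + w_obs.shape)
    dropped = 0
    kept = 0
    while kept < n_resamples:
        if method == "bootstrap":
            idx = rng.integers(0, n, n)
            xb, yb = xv[idx], yv[idx]
        else:
            perm = rng.permutation(n)
            xb, yb = xv, yv[perm]
        xz = _zscore_cols(xb)
        ysd = yb.std(ddof=1)
        if xz is None or ysd == 0:
            dropped += 1
            if dropped > 0.1 * n_resamples:
                raise ValueError(
                    f"more than 10% of resamples degenerate ({dropped} dropped)"
                )
            continue
        yz = (yb - yb.mean()) / ysd
        try:
            _, w_rep, _, _, _ = nipals_pls(xz, yz, n_components)
        except ValueError:
            dropped += 1
            if dropped > 0.1 * n_resamples:
                raise ValueError(
                    f"more than 10% of resamples degenerate ({dropped} dropped)"
                )
            continue
        if method == "bootstrap":
            signs = np.sign(np.einsum("pa,pa->a", w_rep, w_obs))
            signs[signs == 0] = 1.0
            w_rep = w_rep * signs[None, :]
        reps[kept] = w_rep
        kept += 1
    if dropped:
        logger.info("dropped %d degenerate resamples", dropped)

    if method == "bootstrap":
        sd = reps.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, w_obs / sd, 0.0)
        p = 2.0 * stats.norm.sf(np.abs(z))
    else:
        exceed = (np.abs(reps) >= np.abs(w_obs)[None]).sum(axis=0)
        p = (1.0 + exceed) / (1.0 + n_resamples)
        mu, sd = reps.mean(axis=0), reps.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, (w_obs - mu) / sd, 0.0)

    p_fdr = np.column_stack(
        [bh_fdr(p[:, a]) for a in range(n_components)]
    )
    genes = np.asarray(result.predictor_names)
    signif = {
        a + 1: sorted(genes[p_fdr[:, a] < fdr_threshold].tolist())
        for a in range(n_components)
    }
    result.gene_z = z
    result.gene_p = p
    result.gene_p_fdr = p_fdr
    result.signif_genes = signif
    return result


def export_ranked_genes(result: PLSResult, component: int = 1) -> pd.DataFrame:
    """Ranked gene table for one component, sorted by descending z.

    Ties in z are broken lexicographically by gene id.
    """
    if result.gene_z is None:
        raise ValueError("gene z-scores not computed; run gene_significance first")
    a = component - 1
    table = pd.DataFrame(
        {
            "gene_id": list(result.predictor_names),
            "weight": result.x_weights[:, a],
            "z": result.gene_z[:, a],
            "p": result.gene_p[:, a],
            "p_fdr": result.gene_p_fdr[:, a],
        }
    )
    table = table.sort_values(
        ["z", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
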