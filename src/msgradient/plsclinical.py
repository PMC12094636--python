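"""Clinical phenotype PLS with VIP region importance.

Regional principal-gradient scores (predictors) are related to the PANSS
five symptom factors -- positive, negative, disorganized, excited, depressed
(the Wallwork consensus item mapping is packaged as the default) -- by
multivariate-response PLS.  Variable Importance in Projection (VIP) scores
summarise each region's contribution to the explained response variance
across components; regions with VIP > 1 are flagged as contributing, and the
mean square of VIP over regions is 1 by construction (sum VIP^2 = p).

The analysis population is patients only by default (symptom scores exist
only for them); both blocks enter z-scored.  Per-factor VIP maps come from
univariate fits per factor; the joint five-factor fit serves the total score.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from ._pls import PLSResult, nipals_pls, pls_regression_coef
from ._utils import pearson

__all__ = [
    "load_default_factor_mapping",
    "panss_five_factors",
    "fit_clinical_pls",
    "vip_scores",
    "top_regions_per_factor",
]

logger = logging.getLogger(__name__)

FACTOR_ORDER = ("positive", "negative", "disorganized", "excited", "depressed")


def load_default_factor_mapping() -> pd.DataFrame:
    """Wallwork consensus five-factor PANSS item mapping (item, factor)."""
    with resources.files("msgradient.data").joinpath(
        "wallwork_five_factor.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def panss_five_factors(
    item_scores: pd.DataFrame, mapping: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Factor scores as sums of mapped PANSS items (1-7 each).

    Unmapped items are ignored (logged); the total over *all* items is
    returned as a ``total`` column.
    """
    if mapping is None:
        mapping = load_default_factor_mapping()
    vals = item_scores.to_numpy()
    if ((vals < 1) | (vals > 7)).any():
        raise ValueError("PANSS items must be scored 1-7")
    missing = set(mapping["item"]) - set(item_scores.columns)
    if missing:
        raise ValueError(f"mapped items absent from the table: {sorted(missing)}")
    unmapped = sorted(set(item_scores.columns) - set(mapping["item"]))
    if unmapped:
        logger.info("ignoring %d unmapped PANSS items: %s", len(unmapped), unmapped)
    out = {}
    for factor in mapping["factor"].unique():
        items = mapping.loc[mapping["factor"] == factor, "item"]
        out[factor] = item_scores[list(items)].sum(axis=1)
    table = pd.DataFrame(out, index=item_scores.index)
    table["total"] = item_scores.sum(axis=1)
    return table


def _zscore_blocks(x: pd.DataFrame, y: pd.DataFrame):
    xv, yv = x.to_numpy(float), y.to_numpy(float)
    xm, xs = xv.mean(axis=0), xv.std(axis=0, ddof=1)
    ym, ys = yv.mean(axis=0), yv.std(axis=0, ddof=1)
    if np.any(xs == 0):
        bad = [x.columns[i] for i in np.flatnonzero(xs == 0)[:5]]
        raise ValueError(f"zero-variance predictor column(s): {bad}")
    if np.any(ys == 0):
        bad = [y.columns[i] for i in np.flatnonzero(ys == 0)[:5]]
        raise ValueError(f"zero-variance response column(s): {bad}")
    return (xv - xm) / xs, (yv - ym) / ys, (xm, xs, ym, ys)


def _cv_n_components(
    xz: np.ndarray, yz: np.ndarray, max_components: int, seed: int = 0
) -> int:
    """Choose the component count by 5-fold cross-validated predictive R^2."""
    n = xz.shape[0]
    kf = KFold(n_splits=min(5, n), shuffle=True, random_state=seed)
    press = np.zeros(max_components)
    total = np.zeros(max_components)
    for train, test in kf.split(xz):
        xt, yt = xz[train], yz[train]
        xm, xs = xt.mean(axis=0), xt.std(axis=0, ddof=1)
        ym, ys = yt.mean(axis=0), yt.std(axis=0, ddof=1)
        xs[xs == 0] = 1.0
        ys[ys == 0] = 1.0
        xtz, ytz = (xt - xm) / xs, (yt - ym) / ys
        a_max = min(max_components, min(len(train) - 1, xz.shape[1]))
        t_mat, w_mat, p_mat, c_mat, _ = nipals_pls(xtz, ytz, a_max)
        xte = (xz[test] - xm) / xs
        yte = (yz[test] - ym) / ys
        for a in range(max_components):
            aa = min(a + 1, a_max)
            b = pls_regression_coef(w_mat[:, :aa], p_mat[:, :aa], c_mat[:, :aa])
            resid = yte - xte @ b
            press[a] += (resid**2).sum()
            total[a] += (yte**2).sum()
    r2 = 1.0 - press / total
    return int(np.argmax(r2)) + 1


def fit_clinical_pls(
    x: pd.DataFrame,
    y: pd.DataFrame,
    n_components: int | None = None,
    seed: int = 0,
) -> PLSResult:
    """Multivariate-response PLS of factor scores on regional gradients.

    ``x``: subjects x regions; ``y``: subjects x factors, index-aligned by
    subject.  With ``n_components=None`` the count is chosen by 5-fold
    cross-validated predictive R^2, capped at 5.  The result carries
    per-factor Pearson correlations of the first X-score with each factor
    (attribute ``factor_correlations``).
    """
    y = y.loc[x.index]
    xz, yz, (xm, xs, ym, ys) = _zscore_blocks(x, y)
    rank_cap = min(x.shape[0] - 1, x.shape[1])
    if n_components is None:
        n_components = _cv_n_components(xz, yz, min(5, rank_cap), seed=seed)
    elif n_components > rank_cap:
        raise ValueError(
            f"n_components={n_components} exceeds the rank bound {rank_cap}"
        )
    t_mat, w_mat, p_mat, c_mat, ev = nipals_pls(xz, yz, n_components)
    result = PLSResult(
        n_components=n_components,
        x_scores=t_mat,
        x_weights=w_mat,
        x_loadings=p_mat,
        y_loadings=c_mat,
        explained_variance_y=ev,
        predictor_names=tuple(map(str, x.columns)),
        response_names=tuple(map(str, y.columns)),
        sample_names=tuple(map(str, x.index)),
        x_mean=xm,
        x_sd=xs,
        y_mean=ym,
        y_sd=ys,
    )
    result.factor_correlations = pd.Series(
        [pearson(t_mat[:, 0], yz[:, j]) for j in range(yz.shape[1])],
        index=list(y.columns),
        name="r_with_pls1_xscore",
    )
    return result


def vip_scores(fit: PLSResult) -> pd.DataFrame:
    """Variable Importance in Projection per predictor region.

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a ), with
    SS_a the response variance explained by component a.  ``contributing``
    flags VIP > 1; the per-factor loading sign of the first component is
    reported alongside.
    """
    ss = np.asarray(fit.explained_variance_y, float)
    if np.all(ss == 0):
        raise ValueError("no explained response variance; VIP undefined")
    w = fit.x_weights
    p = w.shape[0]
    wn = w / np.linalg.norm(w, axis=0, keepdims=True)
    vip = np.sqrt(p * (wn**2 @ ss) / ss.sum())
    out = pd.DataFrame(
        {
            "region_id": list(fit.predictor_names),
            "vip": vip,
            "contributing": vip > 1.0,
        }
    )
    c1 = fit.y_loadings[:, 0]
    for j, factor in enumerate(fit.response_names):
        out[f"sign_{factor}"] = np.sign(c1[j]).astype(int) if c1[j] != 0 else 0
    return out


def top_regions_per_factor(
    x: pd.DataFrame,
    y: pd.DataFrame,
    k: int = 5,
    n_components: int | None = None,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Top-k regions by VIP, per factor and for the joint fit.

    Each factor is fit as a univariate response for its own VIP ranking; the
    joint multi-factor fit supplies the ``total`` ranking.  Ties are broken
    by region_id.
    """
    if k > x.shape[1]:
        raise ValueError(f"k={k} exceeds the number of regions {x.shape[1]}")
    out: dict[str, pd.DataFrame] = {}
    for factor in y.columns:
        fit = fit_clinical_pls(x, y[[factor]], n_components=n_components, seed=seed)
        v = vip_scores(fit)
        v = v.sort_values(["vip", "region_id"], ascending=[False, True],
                          kind="mergesort").head(k)
        out[str(factor)] = v.reset_index(drop=True)
    joint = fit_clinical_pls(x, y, n_components=n_components, seed=seed)
    v = vip_scores(joint)
    out["total"] = (
        v.sort_values(["vip", "region_id"], ascending=[False, True], kind="mergesort")
        .head(k)
        .reset_index(drop=True)
    )
    return out
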