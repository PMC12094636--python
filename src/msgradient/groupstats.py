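"""Region-wise and network-level case-control inference.

Every region (or label-wise mean) is fit with the same ordinary-least-squares
model ``score ~ intercept + group + age + sex + age:sex + education``; the
reported t is the group coefficient's t with n - p residual df, and p-values
are Benjamini-Hochberg adjusted within the analysis family (all regions form
one family; label-level tests form their own).  Group is coded patient = 1,
control = 0, so negative t means "patient lower".
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_fdr", "design_matrix", "fit_region_glm", "aggregate_by_label"]

GROUP_CODES = {"control": 0.0, "patient": 1.0}


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.isnan(p).any():
        raise ValueError("p-values contain NaN")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def design_matrix(
    covariates: pd.DataFrame, include_interaction: bool = True
) -> tuple[np.ndarray, list[str]]:
    """[intercept, group, age, sex, age x sex, education] design.

    ``covariates`` needs columns group ({patient, control}), age, sex (0/1),
    education (numeric ordinal).
    """
    bad = set(covariates["group"]) - set(GROUP_CODES)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    group = covariates["group"].map(GROUP_CODES).to_numpy(float)
    age = covariates["age"].to_numpy(float)
    sex = covariates["sex"].to_numpy(float)
    edu = covariates["education"].to_numpy(float)
    cols = [np.ones(len(covariates)), group, age, sex]
    names = ["intercept", "group", "age", "sex"]
    if include_interaction:
        cols.append(age * sex)
        names.append("age_x_sex")
    cols.append(edu)
    names.append("education")
    x = np.column_stack(cols)
    return x, names


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify dependent columns through pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(x, pivoting=True, mode="economic")
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        dependent = [names[piv[i]] for i in range(len(names)) if diag[i] < tol]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {x.shape[1]}); "
            f"collinear columns: {dependent}"
        )


def _ols_group_t(
    y: np.ndarray, x: np.ndarray, names: list[str]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorised OLS over columns of y; returns (t_group, p, df)."""
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more subjects ({n}) than design columns ({p})")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = n - p
    s2 = (resid**2).sum(axis=0) / df
    j = names.index("group")
    se = np.sqrt(s2 * xtx_inv[j, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[j] / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return t, pvals, df


def fit_region_glm(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    include_interaction: bool = True,
) -> pd.DataFrame:
    """Per-region GLM for the group effect on gradient scores.

    ``scores``: subjects x regions, indexed by subject_id.
    ``covariates``: one row per subject with subject_id, group, age, sex,
    education.  Returns a region stat map (region_id, t_value, p_value,
    p_fdr, significant, direction).
    """
    cov = covariates.set_index("subject_id").loc[scores.index].reset_index()
    x, names = design_matrix(cov, include_interaction=include_interaction)
    _check_rank(x, names)
    y = scores.to_numpy(float)
    t, p, _ = _ols_group_t(y, x, names)
    p_fdr = bh_fdr(p)
    out = pd.DataFrame(
        {
            "region_id": scores.columns,
            "t_value": t,
            "p_value": p,
            "p_fdr": p_fdr,
            "significant": p_fdr < alpha,
            "direction": np.where(t < 0, "patient_lower", "patient_higher"),
        }
    )
    return out


def aggregate_by_label(
    scores: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    include_interaction: bool = True,
) -> pd.DataFrame:
    """Label-level GLM on per-subject mean scores within each label.

    Every region must be labeled; FDR is applied across labels (their own
    family).  The returned stat map is indexed by label.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    missing = set(scores.columns) - set(labels.index)
    if missing:
        raise ValueError(f"unlabeled regions: {sorted(missing)[:5]} ...")
    lab_for = labels.loc[list(scores.columns)]
    means = {}
    for lab in lab_for.unique():
        regions = list(lab_for.index[lab_for == lab])
        if not regions:
            raise ValueError(f"empty label category: {lab}")
        means[lab] = scores[regions].mean(axis=1)
    mean_scores = pd.DataFrame(means, index=scores.index)
    out = fit_region_glm(
        mean_scores, covariates, alpha=alpha, include_interaction=include_interaction
    )
    return out.rename(columns={"region_id": "label"})
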