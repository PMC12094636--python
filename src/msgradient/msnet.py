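"""Morphometric similarity (MS) matrices.

A subject's MS matrix is the region x region Pearson correlation of z-scored
morphometric feature vectors: features are standardized across regions, then
each pair of regional feature profiles is correlated.  The diagonal is set to
0 (self-similarity is uninformative and the downstream affinity kernel
ignores self-loops); negative similarities are retained here and handled by
the affinity kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .synthetic import FeatureTable

__all__ = [
    "MSMatrix",
    "zscore_features",
    "compute_ms_matrix",
    "subject_ms_matrices",
    "feature_subset_matrices",
]


@dataclass(frozen=True)
class MSMatrix:
    """Symmetric region x region similarity matrix for one subject."""

    subject_id: str
    matrix: np.ndarray
    region_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("MS matrix must be square")
        if len(self.region_ids) != m.shape[0]:
            raise ValueError("region_ids do not match matrix size")
        if np.abs(m - m.T).max() > 1e-12:
            raise ValueError("MS matrix must be symmetric to 1e-12")
        if np.abs(np.diag(m)).max() != 0:
            raise ValueError("MS matrix diagonal must be exactly 0")
        off = m[~np.eye(m.shape[0], dtype=bool)]
        if off.size and np.abs(off).max() > 1.0 + 1e-12:
            raise ValueError("off-diagonal entries must lie in [-1, 1]")


def zscore_features(values: np.ndarray, feature_names: Sequence[str] | None = None) -> np.ndarray:
    """Standardize each feature column across regions (sample sd, ddof=1)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a regions x features matrix")
    sd = values.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = (
            [feature_names[i] for i in bad]
            if feature_names is not None
            else [f"column {i}" for i in bad]
        )
        raise ValueError(f"zero-variance feature(s) across regions: {names}")
    return (values - values.mean(axis=0)) / sd


def compute_ms_matrix(
    standardized: np.ndarray,
    subject_id: str = "subject",
    region_ids: Sequence[str] | None = None,
) -> MSMatrix:
    """Pearson correlation between every pair of regional feature profiles."""
    standardized = np.asarray(standardized, dtype=float)
    n_regions, n_features = standardized.shape
    if n_features < 3:
        raise ValueError(
            f"need >= 3 features for a regional profile correlation, got {n_features}"
        )
    row_sd = standardized.std(axis=1)
    flat = np.flatnonzero(row_sd == 0)
    if flat.size:
        ids = (
            [region_ids[i] for i in flat]
            if region_ids is not None
            else [f"region {i}" for i in flat]
        )
        raise ValueError(f"constant feature profile in region(s): {ids}")
    m = np.corrcoef(standardized)
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    if region_ids is None:
        region_ids = tuple(f"r{i:04d}" for i in range(n_regions))
    return MSMatrix(subject_id=subject_id, matrix=m, region_ids=tuple(region_ids))


def subject_ms_matrices(
    table: FeatureTable, features: Sequence[str] | None = None
) -> list[MSMatrix]:
    """One MS matrix per subject, optionally on a feature subset."""
    if features is None:
        cols = list(range(len(table.feature_names)))
        names = table.feature_names
    else:
        names = tuple(features)
        if len(set(names)) != len(names):
            raise ValueError(f"duplicated feature name in subset: {list(names)}")
        missing = set(names) - set(table.feature_names)
        if missing:
            raise ValueError(f"unknown feature(s): {sorted(missing)}")
        if len(names) < 3:
            raise ValueError("feature subset must contain >= 3 features")
        cols = [table.feature_names.index(f) for f in names]
    out = []
    for i, sid in enumerate(table.subjects["subject_id"]):
        z = zscore_features(table.values[i][:, cols], feature_names=names)
        out.append(compute_ms_matrix(z, subject_id=sid, region_ids=table.region_ids))
    return out


def feature_subset_matrices(
    table: FeatureTable, subsets: Iterable[Sequence[str]]
) -> list[list[MSMatrix]]:
    """Per-subset lists of per-subject MS matrices (for robustness checks)."""
    return [subject_ms_matrices(table, features=subset) for subset in subsets]
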