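"""Diffusion-map gradients of MS networks.

An MS matrix is converted to a nonnegative affinity by row-wise top-decile
sparsification followed by a normalized-angle kernel, and decomposed with
anisotropic diffusion-map embedding (alpha = 0.5, diffusion-time-zero
component scaling lambda/(1-lambda)).  Individual embeddings are brought
into a common orientation by orthogonal Procrustes alignment to an iterated
group mean, after which the per-subject principal gradient scores are
directly comparable across subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .msnet import MSMatrix
from .synthetic import SphereParcellation

__all__ = [
    "GradientSet",
    "build_affinity",
    "diffusion_embedding",
    "align_gradients",
    "principal_gradient_table",
]

logger = logging.getLogger(__name__)

KERNELS = ("normalized_angle", "cosine", "identity")


@dataclass(frozen=True)
class GradientSet:
    """Regions x k embedding with eigenvalue-derived explained variance."""

    subject_id: str
    components: np.ndarray
    eigenvalues: np.ndarray
    explained_variance: np.ndarray
    region_ids: tuple[str, ...]
    aligned: bool = False
    reference_id: str | None = None

    def __post_init__(self) -> None:
        lam = self.eigenvalues
        if np.any(lam < -1e-12):
            raise ValueError("eigenvalues must be nonnegative")
        if np.any(np.diff(lam) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        ev = self.explained_variance
        if ev.sum() > 1 + 1e-9 or np.any(ev < -1e-12):
            raise ValueError("explained-variance fractions must lie in [0,1], sum <= 1")
        if self.components.shape != (len(self.region_ids), len(lam)):
            raise ValueError("components shape mismatch")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def principal(self) -> pd.Series:
        return pd.Series(self.components[:, 0], index=list(self.region_ids),
                         name=self.subject_id)


def build_affinity(
    ms: MSMatrix | np.ndarray,
    sparsity: float = 0.9,
    kernel: str = "normalized_angle",
) -> np.ndarray:
    """Row-sparsified kernel affinity of an MS matrix.

    Per row, entries below the ``sparsity`` quantile of that row's
    off-diagonal values are zeroed (any surviving negatives are clamped to 0,
    with a logged count); the kernel is then applied to pairs of sparsified
    rows.  normalized_angle(i,j) = 1 - arccos(cos_sim(row_i, row_j)) / pi.
    """
    m = ms.matrix if isinstance(ms, MSMatrix) else np.asarray(ms, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("affinity input must be square")
    if np.abs(m - m.T).max() > 1e-10:
        raise ValueError("affinity input must be symmetric")
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must lie in [0, 1)")
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {KERNELS}")

    n = m.shape[0]
    off = ~np.eye(n, dtype=bool)
    rows = np.where(off, m, np.nan)
    thr = np.nanquantile(rows, sparsity, axis=1, keepdims=True)
    sparse = np.where(off & (m >= thr), m, 0.0)
    n_neg = int((sparse < 0).sum())
    if n_neg:
        logger.info("clamping %d negative similarities to 0 before the kernel", n_neg)
        sparse = np.maximum(sparse, 0.0)

    nnz = (sparse > 0).sum(axis=1)
    weak = np.flatnonzero(nnz < 2)
    if weak.size:
        raise ValueError(
            f"rows {weak.tolist()} have < 2 nonzero entries after sparsification; "
            "lower the sparsity"
        )

    if kernel == "identity":
        aff = (sparse + sparse.T) / 2.0
    else:
        norms = np.linalg.norm(sparse, axis=1)
        cos = np.clip((sparse @ sparse.T) / np.outer(norms, norms), -1.0, 1.0)
        if kernel == "normalized_angle":
            aff = 1.0 - np.arccos(cos) / np.pi
        else:  # cosine
            aff = np.maximum(cos, 0.0)
    np.fill_diagonal(aff, 0.0)
    return aff


def diffusion_embedding(
    affinity: np.ndarray,
    alpha: float = 0.5,
    n_components: int = 10,
    subject_id: str = "subject",
    region_ids: Sequence[str] | None = None,
) -> GradientSet:
    """Anisotropic diffusion-map embedding of a nonnegative affinity matrix.

    W' = D^-alpha W D^-alpha with D the row-sum diagonal; the spectrum of the
    row-normalized transition matrix P is obtained through the conjugate
    symmetric matrix; the trivial constant eigenvector (eigenvalue 1) is
    dropped and components are scaled by lambda/(1-lambda) (the automatic
    scaling at diffusion time 0).  Explained-variance fractions are computed
    over the retained non-trivial eigenvalues.
    """
    w = np.asarray(affinity, dtype=float)
    n = w.shape[0]
    if w.ndim != 2 or w.shape[1] != n:
        raise ValueError("affinity must be square")
    if np.abs(w - w.T).max() > 1e-10:
        raise ValueError("affinity must be symmetric (symmetrize first)")
    if np.any(w < 0):
        raise ValueError("affinity must be nonnegative")
    n_comp_graph, labels = connected_components(csr_matrix(w > 0), directed=False)
    if n_comp_graph > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(
            f"affinity graph is disconnected (component sizes {sizes}); "
            "cannot embed"
        )
    if not 1 <= n_components <= n - 1:
        raise ValueError("n_components must lie in [1, n_regions - 1]")

    d = w.sum(axis=1)
    w1 = w / np.outer(d**alpha, d**alpha)
    d1 = w1.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d1)
    sym = w1 * np.outer(inv_sqrt, inv_sqrt)
    sym = (sym + sym.T) / 2.0
    lam, u = np.linalg.eigh(sym)
    order = np.argsort(lam)[::-1]
    lam, u = lam[order], u[:, order]

    v = u * inv_sqrt[:, None]  # right eigenvectors of P
    psi = v / v[:, [0]]  # trivial eigenvector normalized to 1
    k = n_components
    lam_k = lam[1 : k + 1]
    comps = psi[:, 1 : k + 1] * (lam_k / (1.0 - lam_k))[None, :]

    # pin the arbitrary eigenvector sign: largest-magnitude entry positive
    for j in range(k):
        i_max = np.argmax(np.abs(comps[:, j]))
        if comps[i_max, j] < 0:
            comps[:, j] = -comps[:, j]

    lam_k = np.maximum(lam_k, 0.0)
    explained = lam_k / lam_k.sum() if lam_k.sum() > 0 else np.zeros(k)
    if region_ids is None:
        region_ids = tuple(f"r{i:04d}" for i in range(n))
    return GradientSet(
        subject_id=subject_id,
        components=comps,
        eigenvalues=lam_k,
        explained_variance=explained,
        region_ids=tuple(region_ids),
    )


def _orient_reference(ref: np.ndarray, parcellation: SphereParcellation,
                      region_ids: Sequence[str]) -> np.ndarray:
    """Fix the reference's per-component sign: the region with the largest
    centroid-x must have a nonnegative score."""
    xs = parcellation.table.loc[list(region_ids), "x"].to_numpy(float)
    i_ref = int(np.argmax(xs))
    signs = np.where(ref[i_ref] < 0, -1.0, 1.0)
    return ref * signs[None, :]


def align_gradients(
    individual: Sequence[GradientSet],
    reference: str | GradientSet = "group_mean",
    n_iter: int = 10,
    parcellation: SphereParcellation | None = None,
) -> tuple[list[GradientSet], GradientSet]:
    """Orthogonal Procrustes alignment of individual embeddings.

    With ``reference='group_mean'`` the reference is the iterated mean of the
    aligned sets (``n_iter`` rounds); an explicit :class:`GradientSet` may be
    supplied instead.  Per-subject sign ambiguity is resolved by the rotation
    (reflections allowed).  Returns the aligned sets and the reference used.
    """
    if not individual:
        raise ValueError("no gradient sets to align")
    k = individual[0].n_components
    ids = individual[0].region_ids
    for g in individual:
        if g.n_components != k:
            raise ValueError(
                f"component-count mismatch: {g.subject_id} has {g.n_components}, "
                f"expected {k}"
            )
        if g.region_ids != ids:
            raise ValueError("all gradient sets must share the same region set")

    stack = np.stack([g.components for g in individual])

    if isinstance(reference, GradientSet):
        if reference.n_components != k or reference.region_ids != ids:
            raise ValueError("reference does not match the sets being aligned")
        ref = reference.components.copy()
        ref_id = reference.subject_id
        n_iter = 1
    elif reference == "group_mean":
        ref = stack.mean(axis=0)
        ref_id = "group_mean"
    else:
        raise ValueError("reference must be 'group_mean' or a GradientSet")

    aligned = stack
    for _ in range(n_iter):
        aligned = np.empty_like(stack)
        for i in range(stack.shape[0]):
            rot, _ = orthogonal_procrustes(stack[i], ref)
            aligned[i] = stack[i] @ rot
        if isinstance(reference, GradientSet):
            break
        ref = aligned.mean(axis=0)

    if parcellation is not None:
        oriented = _orient_reference(ref, parcellation, ids)
        signs = np.where((oriented * ref).sum(axis=0) < 0, -1.0, 1.0)
        ref = oriented
        aligned = aligned * signs[None, None, :]

    ref_set = GradientSet(
        subject_id=ref_id,
        components=ref,
        eigenvalues=np.sort(np.mean([g.eigenvalues for g in individual], axis=0))[::-1],
        explained_variance=np.mean([g.explained_variance for g in individual], axis=0),
        region_ids=ids,
        aligned=True,
        reference_id=ref_id,
    )
    out = [
        replace(g, components=aligned[i], aligned=True, reference_id=ref_id)
        for i, g in enumerate(individual)
    ]
    return out, ref_set


def principal_gradient_table(aligned: Sequence[GradientSet]) -> pd.DataFrame:
    """Stack first components into a subjects x regions table (id-sorted)."""
    unaligned = [g.subject_id for g in aligned if not g.aligned]
    if unaligned:
        raise ValueError(f"gradient sets not aligned: {unaligned}")
    rows = {g.subject_id: g.components[:, 0] for g in aligned}
    ids = aligned[0].region_ids
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(ids))
    table.index.name = "subject_id"
    return table.sort_index()
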