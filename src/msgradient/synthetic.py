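"""Synthetic inputs with known ground truth.

Every input the analysis pipeline consumes can be generated here: a spherical
parcellation (region centroids on the unit sphere with network and
cytoarchitectonic sector labels), a two-group cohort of regional morphometric
feature tables carrying a smooth latent hierarchy axis plus a planted group
effect, a spatially autocorrelated region x gene expression matrix with a
subset of genes linearly coupled to a target map, and clinical symptom-factor
scores driven by regional gradient values.  All generators are pure functions
of their parameters and an integer seed.

The latent hierarchy axis is defined from centroid geometry (the superior-
inferior coordinate, i.e. the first non-trivial spherical-harmonic coordinate
of the centroid), so the "true" gradient is known exactly and downstream
recovery is testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._utils import zscore

__all__ = [
    "FEATURE_NAMES",
    "YEO_LABELS",
    "VON_ECONOMO_LABELS",
    "SphereParcellation",
    "FeatureTable",
    "GroundTruth",
    "generate_sphere_parcellation",
    "hierarchy_axis",
    "generate_cohort",
    "generate_expression",
    "generate_clinical",
]

#: T1-derived morphometric features: gray-matter volume, cortical thickness,
#: surface area, intrinsic curvature, mean curvature, plus the curved index
#: and folding index used only for the 7-feature robustness analysis.
FEATURE_NAMES = ("GM", "CT", "SA", "IC", "MC", "CI", "FI")

YEO_LABELS = ("VN", "SMN", "DAN", "VAN", "LN", "FPN", "DMN")
VON_ECONOMO_LABELS = (
    "primary_motor",
    "association1",
    "association2",
    "primary_sensory",
    "secondary_sensory",
    "limbic",
    "insula",
)

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class SphereParcellation:
    """Spherical parcellation: unit-norm centroids with categorical labels.

    ``table`` is indexed by region_id and has columns
    ``hemisphere`` ({left, right}), ``x``, ``y``, ``z``,
    ``yeo_label`` and ``von_economo_label``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"hemisphere", "x", "y", "z", "yeo_label", "von_economo_label"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
        if t.index.duplicated().any():
            raise ValueError("region_ids must be unique")
        norms = np.linalg.norm(t[["x", "y", "z"]].to_numpy(float), axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("every centroid must have Euclidean norm 1 (±1e-9)")
        bad = set(t["hemisphere"]) - {"left", "right"}
        if bad:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad)}")

    @property
    def region_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(float)

    def ids(self, hemisphere: str | None = None) -> list[str]:
        if hemisphere is None:
            return self.region_ids
        return list(self.table.index[self.table["hemisphere"] == hemisphere])

    def centroids_of(self, hemisphere: str) -> np.ndarray:
        mask = (self.table["hemisphere"] == hemisphere).to_numpy()
        return self.centroids[mask]

    def subset(self, region_ids) -> "SphereParcellation":
        return SphereParcellation(self.table.loc[list(region_ids)].copy())


@dataclass(frozen=True)
class GroundTruth:
    """Record of what was planted by a generator (for recovery tests)."""

    seed: int
    hierarchy_axis: pd.Series | None = None
    effect_regions: tuple[str, ...] = ()
    effect_size: float = 0.0
    coupled_genes: tuple[str, ...] = ()
    coupling_coefficients: pd.Series | None = None
    clinical_loadings: pd.DataFrame | None = None

    def merged(self, other: "GroundTruth") -> "GroundTruth":
        """Combine records from successive generators (non-null wins)."""
        updates = {}
        for name in (
            "hierarchy_axis",
            "coupling_coefficients",
            "clinical_loadings",
        ):
            val = getattr(other, name)
            if val is not None:
                updates[name] = val
        if other.effect_regions:
            updates["effect_regions"] = other.effect_regions
            updates["effect_size"] = other.effect_size
        if other.coupled_genes:
            updates["coupled_genes"] = other.coupled_genes
        return replace(self, **updates)


@dataclass(frozen=True)
class FeatureTable:
    """Per-subject regions x features morphometric values with covariates.

    ``values`` has shape (n_subjects, n_regions, n_features);
    ``subjects`` has columns subject_id, group, age, sex, education and is
    positionally aligned with the first axis of ``values``.
    """

    values: np.ndarray
    subjects: pd.DataFrame
    region_ids: tuple[str, ...]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        s, r, f = self.values.shape
        if len(self.subjects) != s:
            raise ValueError("subjects table does not match values first axis")
        if len(self.region_ids) != r or len(self.feature_names) != f:
            raise ValueError("region_ids / feature_names do not match values shape")
        if np.isnan(self.values).any():
            raise ValueError("feature values contain missing entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    def subject_matrix(self, i: int) -> np.ndarray:
        return self.values[i]

    def tidy_frame(self) -> pd.DataFrame:
        """Long format: subject_id, region_id, feature, value."""
        s, r, f = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.subjects["subject_id"], self.region_ids, self.feature_names],
            names=["subject_id", "region_id", "feature"],
        )
        return pd.DataFrame({"value": self.values.reshape(-1)}, index=idx).reset_index()

    def wide_frame(self) -> pd.DataFrame:
        """Wide format: one row per subject, columns region_id|feature."""
        s, r, f = self.values.shape
        cols = [f"{rid}|{feat}" for rid in self.region_ids for feat in self.feature_names]
        out = pd.DataFrame(
            self.values.reshape(s, r * f),
            columns=cols,
            index=pd.Index(self.subjects["subject_id"], name="subject_id"),
        )
        return out


def _fibonacci_hemisphere(n: int, rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform points on the +x half of the unit sphere.

    A Fibonacci lattice on the polar cap around the +x axis restricted to
    colatitude < 90 deg; a random azimuthal offset decouples different seeds.
    """
    k = np.arange(n)
    # cos(theta) uniform in (0, 1]: strictly positive x.
    cos_t = 1.0 - (k + 0.5) / n
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = _GOLDEN_ANGLE * k + rng.uniform(0.0, 2.0 * np.pi)
    pts = np.column_stack([cos_t, sin_t * np.cos(phi), sin_t * np.sin(phi)])
    return pts


def _sector_labels(points: np.ndarray, labels: tuple[str, ...], by: str) -> list[str]:
    """Assign spatially contiguous sector labels.

    ``by='azimuth'`` slices the hemisphere into equal azimuthal wedges;
    ``by='colatitude'`` into equal-count colatitude bands (quantile bins so
    every band is populated when n >= len(labels)).
    """
    k = len(labels)
    if by == "azimuth":
        phi = np.mod(np.arctan2(points[:, 2], points[:, 1]), 2.0 * np.pi)
        bins = np.minimum((phi / (2.0 * np.pi) * k).astype(int), k - 1)
    elif by == "colatitude":
        cos_t = np.abs(points[:, 0])
        order = np.argsort(np.argsort(-cos_t))  # rank from pole outward
        bins = np.minimum((order * k) // len(points), k - 1)
    else:  # pragma: no cover
        raise ValueError(by)
    return [labels[b] for b in bins]


def generate_sphere_parcellation(
    n_left: int = 152, n_right: int = 156, seed: int = 0
) -> SphereParcellation:
    """Quasi-uniform spherical parcellation with sector labels.

    Left-hemisphere centroids have strictly negative x, right strictly
    positive (radiological x = left-right axis).  The default 152/156 split
    mirrors a bilateral 308-region parcellation whose left half is used for
    transcriptomic analyses.
    """
    if n_left < 4 or n_right < 4:
        raise ValueError(
            "need at least 4 regions per hemisphere to lay out the "
            "7-level network / cytoarchitecture sector labels"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for hemi, n, flip in (("left", n_left, -1.0), ("right", n_right, 1.0)):
        pts = _fibonacci_hemisphere(n, rng)
        pts[:, 0] *= flip
        yeo = _sector_labels(pts, YEO_LABELS, by="azimuth")
        veco = _sector_labels(pts, VON_ECONOMO_LABELS, by="colatitude")
        prefix = "lh" if hemi == "left" else "rh"
        for i in range(n):
            rows.append(
                {
                    "region_id": f"{prefix}_{i:04d}",
                    "hemisphere": hemi,
                    "x": pts[i, 0],
                    "y": pts[i, 1],
                    "z": pts[i, 2],
                    "yeo_label": yeo[i],
                    "von_economo_label": veco[i],
                }
            )
    table = pd.DataFrame(rows).set_index("region_id")
    # re-normalize to kill accumulated rounding
    c = table[["x", "y", "z"]].to_numpy()
    table[["x", "y", "z"]] = c / np.linalg.norm(c, axis=1, keepdims=True)
    return SphereParcellation(table)


def hierarchy_axis(parcellation: SphereParcellation) -> pd.Series:
    """Latent hierarchy axis g: standardized superior-inferior (z) coordinate.

    Defined from centroid geometry, not from data, so the true gradient is
    known for recovery tests.
    """
    g = zscore(parcellation.table["z"].to_numpy(float))
    return pd.Series(g, index=parcellation.table.index, name="hierarchy_axis")


def hierarchy_band_regions(
    parcellation: SphereParcellation, inner: float = 0.7
) -> list[str]:
    """Regions in the inner band of the hierarchy axis.

    The principal diffusion gradient is stationary at the poles of the
    hierarchy (the leading eigenvector flattens at the extremes), so a
    displacement planted there is second-order invisible to the
    principal-gradient score.  Recovery experiments therefore plant group
    effects among the inner ``inner`` fraction of regions by |axis value|.
    """
    if not 0 < inner <= 1:
        raise ValueError("inner must lie in (0, 1]")
    g = hierarchy_axis(parcellation).abs()
    cutoff = g.quantile(inner)
    return list(g.index[g <= cutoff])


def generate_cohort(
    parcellation: SphereParcellation,
    n_per_group: int = 100,
    n_features: int = 5,
    effect_regions: tuple[str, ...] | list[str] = (),
    effect_size: float = 0.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    age_range: tuple[float, float] = (18.0, 65.0),
) -> tuple[FeatureTable, GroundTruth]:
    """Two-group cohort of regional morphometric features.

    Region means follow ``a_f * g + b_f * g**2`` per feature, where g is the
    latent hierarchy axis; subjects add i.i.d. Gaussian noise (``noise_sd``).
    In patients, regions in ``effect_regions`` are displaced *along the
    latent axis* by an amount calibrated so the root-mean-square per-feature
    mean shift equals ``effect_size * noise_sd`` (i.e. effect_size is a
    Cohen's d at the region x feature level).  A uniform shift of a region's
    whole feature vector would be invisible to the profile-correlation
    network, so the planted effect perturbs the profile direction instead.

    Covariates: age ~ U(age_range), sex ~ Bernoulli(0.5) coded 0/1,
    education an ordinal 1-3 drawn with lower levels more probable in the
    patient group.
    """
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    if n_features < 3:
        raise ValueError("n_features must be >= 3 (profile correlation degenerate)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    effect_regions = tuple(effect_regions)
    unknown = set(effect_regions) - set(parcellation.region_ids)
    if unknown:
        raise ValueError(f"effect_regions not in parcellation: {sorted(unknown)}")
    if abs(effect_size) > 10:
        warnings.warn(
            "planted shift exceeds 10x the feature sd; recovery is trivially "
            "saturated",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    n_regions = parcellation.n_regions
    names = tuple(
        FEATURE_NAMES[i] if i < len(FEATURE_NAMES) else f"F{i + 1}"
        for i in range(n_features)
    )
    g = hierarchy_axis(parcellation).to_numpy()

    # per-feature response to the latent axis; redraw until the centred
    # linear and quadratic response directions are well separated with the
    # linear part dominant, so the planted axis is guaranteed to be the
    # leading dimension of the regional profile geometry
    def _well_conditioned(av: np.ndarray, bv: np.ndarray) -> bool:
        ac, bc = av - av.mean(), bv - bv.mean()
        cos_ab = abs(ac @ bc) / (np.linalg.norm(ac) * np.linalg.norm(bc) + 1e-12)
        return cos_ab < 0.7 and np.linalg.norm(ac) >= np.linalg.norm(bc)

    core = min(n_features, 5)  # the T1 core set used by feature-subset analyses
    for _ in range(1000):
        a = rng.uniform(0.5, 1.5, size=n_features) * rng.choice([-1.0, 1.0], n_features)
        b = rng.uniform(-0.6, 0.6, size=n_features)
        if _well_conditioned(a, b) and _well_conditioned(a[:core], b[:core]):
            break
    else:  # pragma: no cover
        raise RuntimeError("could not draw well-conditioned feature responses")
    means = g[:, None] * a[None, :] + (g**2)[:, None] * b[None, :]  # regions x feats

    # patient-group displacement along the axis in the planted regions
    means_pat = means.copy()
    if effect_regions and effect_size != 0 and noise_sd > 0:
        pos = [parcellation.region_ids.index(r) for r in effect_regions]
        for i in pos:
            slope = np.sqrt(np.mean((a + 2.0 * b * g[i]) ** 2))
            delta = effect_size * noise_sd / slope
            gi = g[i] - delta  # patients displaced downward along the axis
            means_pat[i] = gi * a + gi**2 * b

    n_total = 2 * n_per_group
    values = np.empty((n_total, n_regions, n_features))
    values[:n_per_group] = means[None] + noise_sd * rng.standard_normal(
        (n_per_group, n_regions, n_features)
    )
    values[n_per_group:] = means_pat[None] + noise_sd * rng.standard_normal(
        (n_per_group, n_regions, n_features)
    )

    subj_ids = [f"hc{i:04d}" for i in range(n_per_group)] + [
        f"scz{i:04d}" for i in range(n_per_group)
    ]
    group = ["control"] * n_per_group + ["patient"] * n_per_group
    age = rng.uniform(age_range[0], age_range[1], n_total)
    sex = rng.integers(0, 2, n_total)
    edu_probs = {"control": [0.2, 0.3, 0.5], "patient": [0.5, 0.3, 0.2]}
    education = np.array(
        [rng.choice([1, 2, 3], p=edu_probs[gr]) for gr in group], dtype=int
    )
    subjects = pd.DataFrame(
        {
            "subject_id": subj_ids,
            "group": group,
            "age": age,
            "sex": sex,
            "education": education,
        }
    )
    table = FeatureTable(
        values=values,
        subjects=subjects,
        region_ids=tuple(parcellation.region_ids),
        feature_names=names,
    )
    truth = GroundTruth(
        seed=seed,
        hierarchy_axis=hierarchy_axis(parcellation),
        effect_regions=effect_regions,
        effect_size=effect_size,
    )
    return table, truth


def _angular_distance(c: np.ndarray) -> np.ndarray:
    """Great-circle angle (radians) between unit vectors."""
    dots = np.clip(c @ c.T, -1.0, 1.0)
    return np.arccos(dots)


def generate_expression(
    parcellation: SphereParcellation,
    tmap: pd.Series,
    n_genes: int = 2000,
    n_coupled: int = 100,
    coupling: float = 0.5,
    smoothness: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Spatially autocorrelated region x gene expression (left hemisphere).

    Each gene is a Gaussian field on the left-hemisphere centroids with
    covariance exp(-theta/smoothness) in great-circle angle theta; the
    ``n_coupled`` designated genes additionally add
    ``coupling * standardized(tmap)``.
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be > 0")
    if n_coupled > n_genes:
        raise ValueError("n_coupled cannot exceed n_genes")
    left_ids = parcellation.ids("left")
    if len(tmap) != len(left_ids):
        raise ValueError(
            f"tmap length {len(tmap)} != number of left-hemisphere regions "
            f"{len(left_ids)} (transcriptomic analyses are left-only)"
        )
    tvec = tmap.reindex(left_ids).to_numpy(float) if isinstance(
        tmap, pd.Series
    ) else np.asarray(tmap, float)
    if np.isnan(tvec).any():
        raise ValueError("tmap does not cover all left-hemisphere regions")

    rng = np.random.default_rng(seed)
    theta = _angular_distance(parcellation.centroids_of("left"))
    cov = np.exp(-theta / smoothness)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(len(cov)))
    fields = chol @ rng.standard_normal((len(left_ids), n_genes))

    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    coupled_idx = np.sort(rng.choice(n_genes, size=n_coupled, replace=False))
    tz = zscore(tvec)
    fields[:, coupled_idx] += coupling * tz[:, None]

    expr = pd.DataFrame(fields, index=pd.Index(left_ids, name="region_id"),
                        columns=gene_ids)
    coupled = tuple(gene_ids[i] for i in coupled_idx)
    coeffs = pd.Series(0.0, index=gene_ids, name="coupling")
    coeffs.iloc[coupled_idx] = coupling
    truth = GroundTruth(seed=seed, coupled_genes=coupled, coupling_coefficients=coeffs)
    return expr, truth


FACTOR_NAMES = ("positive", "negative", "disorganized", "excited", "depressed")


def generate_clinical(
    gradients: pd.DataFrame,
    loadings: pd.DataFrame,
    noise_sd: float = 0.5,
    seed: int = 0,
    score_range: tuple[int, int] = (7, 49),
    round_scores: bool = True,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Symptom-factor scores driven by regional gradient values.

    ``gradients``: subjects x regions; ``loadings``: factors x regions.
    Factor score = standardized(loadings . gradient) + Gaussian noise, then
    affinely mapped into a PANSS-like integer range and clipped.
    """
    if not set(loadings.columns) <= set(gradients.columns):
        raise ValueError("loadings reference regions absent from gradients")
    if (loadings.to_numpy() != 0).sum(axis=1).min() == 0:
        raise ValueError("every factor needs a nonzero loading on >= 1 region")
    rng = np.random.default_rng(seed)
    G = gradients[loadings.columns].to_numpy(float)
    raw = G @ loadings.to_numpy(float).T  # subjects x factors
    z = zscore(raw, axis=0)
    y = z + noise_sd * rng.standard_normal(z.shape)
    lo, hi = score_range
    center, scale = (lo + hi) / 2.0, (hi - lo) / 6.0
    scores = center + y * scale
    if round_scores:
        scores = np.clip(np.rint(scores), lo, hi).astype(int)
    out = pd.DataFrame(
        scores, index=gradients.index.copy(), columns=list(loadings.index)
    )
    truth = GroundTruth(seed=seed, clinical_loadings=loadings.copy())
    return out, truth
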