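# msgradient

Morphometric-similarity network gradients for case-control neuroimaging
studies: per-subject network construction, diffusion-map gradient
extraction, covariate-adjusted group comparison with spatially-aware null
models, PLS imaging transcriptomics, and VIP-scored clinical-symptom PLS —
with a first-class synthetic-data module so the whole chain is testable
against known ground truth.

## The problem

Structural MRI yields several morphometric features per cortical region
(gray-matter volume GM, cortical thickness CT, surface area SA, intrinsic
curvature IC, mean curvature MC).  A **morphometric similarity (MS)
network** turns these into a single-subject connectome: after z-scoring each
feature across the R parcellated regions, edge (i, j) is the Pearson
correlation between region i's and region j's feature profiles, giving an
R × R matrix per subject.  A **diffusion-map embedding** of the kernelised
MS matrix orders regions along low-dimensional *gradients*; the principal
gradient is a hierarchy axis of cortical organisation.  The package asks,
on synthetic cohorts with planted effects, the questions a psychiatric
imaging study asks of patients and controls:

1. Where does the principal gradient differ between groups?  Per region,
   an OLS fit `score ~ group + age + sex + age:sex + education` with
   Benjamini–Hochberg FDR across regions, plus network-level (Yeo / von
   Economo style label) aggregation.
2. Is a map-map association stronger than expected given spatial
   autocorrelation?  A **spin test**: random 3-D rotations of the spherical
   region centroids generate autocorrelation-preserving null maps;
   p_spin = (1 + #{|r_null| ≥ |r_obs|}) / (1 + n_perm).
3. Which genes track the case-control t-map?  **PLS regression** of the
   t-vector (one value per left-hemisphere region) on a region × gene
   expression matrix; component explained variance is tested against the
   spin null, and per-gene bootstrap z-scores (weight / bootstrap sd over
   region resamples) yield FDR-thresholded gene lists, which feed a
   hypergeometric over-representation analysis against GMT gene sets.
4. Which regions carry the clinical signal?  Multivariate PLS of the five
   PANSS symptom factors (Wallwork mapping packaged) on regional gradient
   scores, summarised per region by the **Variable Importance in
   Projection**:

   VIP_j = sqrt( p · Σ_a SS_a (w_ja / ‖w_a‖)² / Σ_a SS_a ),

   where SS_a is the response variance explained by component a; regions
   with VIP > 1 are flagged, and Σ_j VIP_j² = p holds exactly.

## Worked example

```python
from msgradient import synthetic, msnet, gradients, groupstats

parc = synthetic.generate_sphere_parcellation(152, 156, seed=1)
pool = synthetic.hierarchy_band_regions(parc)
table, truth = synthetic.generate_cohort(
    parc, n_per_group=100, effect_regions=tuple(pool[:8]),
    effect_size=0.8, seed=1,
)
mats = msnet.subject_ms_matrices(table)
sets = [
    gradients.diffusion_embedding(
        gradients.build_affinity(m), subject_id=m.subject_id,
        region_ids=m.region_ids,
    )
    for m in mats
]
aligned, ref = gradients.align_gradients(sets, parcellation=parc)
scores = gradients.principal_gradient_table(aligned)
stats = groupstats.fit_region_glm(scores, table.subjects)
hit = set(stats.loc[stats.significant, "region_id"]) & set(truth.effect_regions)
print(f"explained variance of gradient 1: {sets[0].explained_variance[0]:.2f}")
print(f"significant regions: {int(stats.significant.sum())}, "
      f"planted recovered: {len(hit)}/8")
```

prints

```
explained variance of gradient 1: 0.23
significant regions: 9, planted recovered: 8/8
```

i.e. the first gradient carries about a fifth of the retained spectrum for
this subject, and the group comparison recovers all eight planted regions
(here with one extra region dragged along by the planted perturbation).

The same chain is available from the shell:

```sh
msgradient run-all --out runs/demo --seed 1
msgradient compare --run-dir runs/demo        # re-run a single stage
```

which writes per-stage CSV/JSON outputs (`synthetic/`, `msnet/`,
`gradients/`, `compare/`, `spin/`, `plsgenes/`, `plsclinical/`, `enrich/`)
plus a manifest with the config echo, stage seeds and output hashes.  A
fixed seed reproduces every CSV byte-for-byte.

## Layout

| module | role |
| --- | --- |
| `synthetic` | parcellation, cohort, expression and clinical generators with recorded ground truth |
| `msnet` | z-scoring and per-subject MS matrices |
| `gradients` | affinity kernel, diffusion embedding, Procrustes alignment |
| `groupstats` | region/label GLM, BH-FDR |
| `spin` | rotation permutations, map and PLS-component spin p-values |
| `plsgenes` | transcriptomic PLS, bootstrap gene z-scores, ranked exports |
| `plsclinical` | PANSS factors, clinical PLS, VIP scores |
| `enrich` | GMT gene sets, hypergeometric over-representation |
| `io` / `config` / `pipeline` / `cli` | text formats, validated config, orchestration |

See `docs/methods.md` for the model details, parameter defaults, and known
limitations.
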