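# Methods

This note documents the models implemented in `msgradient`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions that pin down bit-reproducibility.

## Morphometric similarity networks

For each subject, the regional feature matrix (R regions × F features;
F = 5 by default: GM, CT, SA, IC, MC, with the curved and folding indices
available as features 6–7 for robustness analyses) is z-scored per feature
across regions using the sample (n−1) standard deviation.  The MS matrix is
the Pearson correlation between every pair of regional feature profiles.
Conventions fixed here because they matter for reproducibility:

- sample (ddof = 1) standard deviations everywhere;
- the diagonal is set to 0 rather than 1 — self-similarity is
  uninformative and the affinity kernel ignores self-loops;
- negative correlations are retained in the MS matrix and handled by the
  affinity step;
- z-scoring is across all R regions (not within hemisphere).

Because z-scoring precedes correlation, the MS matrix is invariant to any
affine rescaling of a raw feature column, so heterogeneous feature units
(mm³, mm, mm², 1/mm) are immaterial.

Profile correlation has a blind spot worth knowing: each region's feature
vector is centred by its own mean before correlating, so a *uniform* shift
of all of a region's features is invisible.  Only perturbations that change
the profile's direction register in the network.  The synthetic generator's
planted effect is designed around this (below).

## Affinity and diffusion-map gradients

Each MS row is sparsified to its top decile (`sparsity = 0.9`, per-row
quantile of the off-diagonal entries); surviving negative entries are
clamped to 0 with a logged count.  The normalized-angle kernel
`1 − arccos(cos_sim(row_i, row_j))/π` maps sparsified rows to affinities in
[0, 1] (cosine and identity kernels are available).  These are the
canonical defaults of the gradient-construction lineage this package
follows.

The embedding is an anisotropic diffusion map: W′ = D^−α W D^−α with
α = 0.5, P the row-normalised W′, spectrum obtained through the conjugate
symmetric matrix.  The trivial constant eigenvector (eigenvalue 1) is
dropped and components are scaled by λ/(1−λ), the automatic scaling at
diffusion time 0.  Eigenvector normalisation: unit norm in the
degree-weighted inner product (the convention under which dividing by the
trivial eigenvector leaves a well-defined scale).  Per-component sign is
pinned by making the largest-magnitude entry positive.  Disconnected
affinities are an error (component sizes reported), as are rows left with
fewer than 2 neighbours after sparsification.

Explained-variance fractions are computed over the retained non-trivial
eigenvalues (k = 10 by default, negative eigenvalues clamped to zero in
the report).  This normalisation set is a config knob and is echoed in the
output: explained-variance percentages are only comparable across runs that
share it.  The pipeline reports both the mean of the individual subjects'
figures and the figure for an embedding of the group-mean MS matrix.

Individual embeddings are aligned by orthogonal Procrustes rotation to an
iterated group mean (10 rounds; reflections permitted, which resolves
per-subject sign ambiguity).  The reference itself is oriented so the
region with the largest centroid-x has a nonnegative score on every
component.  Only aligned sets may be stacked into the subjects × regions
principal-gradient table.

## Group comparison

Per region (or per label after averaging a subject's scores within Yeo-like
/ von Economo-like labels), OLS of the aligned principal-gradient score on
`[intercept, group, age, sex, age × sex, education]`, with the group
coefficient's t reported on n − 6 residual df.  Group is coded patient = 1,
control = 0, so t < 0 reads "patient lower".  Education enters as a single
numeric ordinal (1–3); dummy coding is deliberately not the default, as the
synthetic covariate is ordinal by construction.  BH-FDR is applied within
each analysis family separately: all regions form one family, label-level
tests their own.  Rank-deficient designs abort with the collinear columns
named.

## Spin permutations

Null maps preserve spatial autocorrelation by rigid rotation: a
Haar-uniform rotation (QR of a Gaussian matrix, sign-corrected to
det = +1) is applied to the spherical centroids and each original region
takes the value of the nearest rotated centroid by great-circle distance.
In bilateral mode the right hemisphere uses the x-flip-conjugated rotation;
mappings never cross hemispheres.  p-values are add-one: two-sided for
map-map correlations, one-sided (greater) for PLS explained variance
(which is nonnegative by construction).  The response map is what gets
spun in the PLS component test — spinning y or the rows of X gives the
same exchangeability, and y is the cheap choice; this is recorded in the
output metadata.

Two matching variants exist.  The default nearest-match assignment can map
one rotated region to several originals (the behaviour of the rotation
lineage this follows); measured on smooth fields (200 regions, 1,000
spins, 500 independent pairs) it rejects at ≈ 0.03 for α = 0.05 — mildly
conservative, because duplicated assignments overdisperse the null.  The
`exact_bijection` flag uses a Hungarian assignment instead, giving a true
permutation and measured rejection ≈ 0.06; the calibration acceptance test
exercises this variant.  A naive parametric correlation test on the same
smooth pairs rejects at 0.28–0.37 — the anticonservativeness the spin test
exists to fix.

## PLS

Components are extracted by NIPALS: for univariate y the closed one-step
recursion, for multivariate Y the two-block power iteration, both with X
(and Y) deflation.  Both blocks are z-scored internally (sample sd).
Scores are mutually orthogonal, so per-component explained response
variance is an exact R² increment; cumulative R² is non-decreasing and
≤ 1.  Note that per-component explained variance need not be decreasing,
and an exact linear relationship is only recovered in full once the number
of components reaches the predictor rank (not the number of generating
variables) — the tests assert the true property.

Gene contributions (transcriptomic path) default to bootstrap z-scores:
regions resampled with replacement, the model refit, each replicate's
component sign aligned to the original by weight-vector inner product,
z = weight / bootstrap sd, two-sided normal p, BH-FDR across genes per
component, significance at adjusted p < 0.001 (the threshold is applied to
the adjusted p; a config switch moves it to the raw p).  A region-permutation
alternative (add-one exceedance p) is provided, but note its p-values are
floored at 1/(n_resamples + 1) and cannot reach the 0.001 regime at
realistic resample counts — the reason bootstrap is the default.
Degenerate resamples (zero-variance columns) are dropped and logged; more
than 10% dropped is an error.

Caveat: with strong *long-range* autocorrelation in the predictor fields,
per-gene bootstrap scores become anticonservative conditional on a fixed
target map — the across-gene spread of gene-map correlations scales with
y′Cy (C the gene spatial covariance), which no per-gene resampling scheme
sees.  This is a property of per-gene scores in imaging transcriptomics
generally, not of this implementation; the component-level spin test is
the autocorrelation-aware statistic.  The synthetic generator's default
angular scale (below) keeps gene-level inference calibrated.

The clinical path fits the five PANSS factors (Wallwork consensus item
mapping, packaged as `data/wallwork_five_factor.csv`; factor score = sum of
mapped 1–7 items, unmapped items ignored with a log entry, total over all
items returned) on regional gradient scores, patients only by default,
both blocks z-scored.  The component count is chosen by 5-fold
cross-validated predictive R², capped at 5, unless set explicitly.
Per-factor VIP maps come from univariate fits per factor (joint-fit VIP is
used for the total score): a joint fit would give all factors the same
ranking geometry, whereas per-factor maps are expected to differ.
Σ VIP² = p is asserted as an exact identity on every fit.

## Enrichment

One-sided hypergeometric upper-tail test of a hit list against each gene
set, BH-FDR across sets.  The background is the tested universe (all genes
in the expression matrix).  Sets empty after intersection with the
background are dropped with a warning; hits outside the background are
dropped with a log entry.  GMT files are read with `gseapy.read_gmt`.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed); every downstream
claim in the test suite is a recovery or calibration statement against the
recorded ground truth.

**Parcellation.** Fibonacci lattices on each half-sphere (left x < 0,
right x > 0; 152/156 by default, mirroring a 308-region atlas whose left
half carries the transcriptomic analyses), with 7-level network labels as
azimuthal sectors and 7-level cytoarchitecture labels as colatitude bands —
spatially coherent, like real atlas labels.  With fewer than 7 regions per
hemisphere not all labels are populated.

**Cohort.** The latent hierarchy axis g is the standardized
superior-inferior centroid coordinate — defined from geometry, not data, so
the true gradient is known.  Region means follow a_f·g + b_f·g² with
per-feature coefficients (|a| ~ U(0.5, 1.5) with random sign,
b ~ U(−0.6, 0.6)), redrawn until the centred linear and quadratic response
directions are well separated with the linear part dominant (both for the
full feature set and its 5-feature core) — this guarantees the planted axis
is the leading dimension of the profile geometry rather than an accident of
the coefficient draw.  Subjects add i.i.d. Gaussian noise
(`noise_sd = 0.3` relative to a unit-sd axis; between-subject noise on the
order of a third of the between-region signal is the regime in which
5-feature profile correlations remain informative per subject).  The
planted group effect displaces affected regions *along the latent axis*,
scaled so the RMS per-feature mean shift equals `effect_size × noise_sd`
(effect_size is a Cohen's d at the region × feature level).  A plain
uniform feature shift was rejected by design: it is invisible to profile
correlation (see above).  Covariates: age ~ U(18, 65), sex ~ Bernoulli(0.5)
coded 0/1, education ordinal 1–3 with lower levels more probable in
patients (reproducing a patients-lower education imbalance); none of them
influence the features, so the GLM's covariate adjustment is exercised
against pure nuisance.

Known limitation: the principal gradient is stationary at the poles of the
hierarchy (the leading eigenvector flattens at the extremes), so an
along-axis displacement planted at an extreme region is second-order
invisible to the principal-gradient score (measured per-region d ≈ 0.2 at
|g| > 1.2 versus ≈ 0.9 mid-axis).  Recovery experiments and the pipeline's
default effect-region choice therefore draw planted regions from the inner
70% band of the axis (`hierarchy_band_regions`).  This is a sensitivity
property of principal-gradient analyses, and it means a null result in
pole regions is weak evidence of no effect.

**Expression.** Each gene is a Gaussian field on the left-hemisphere
centroids with covariance exp(−θ/θ₀) in great-circle angle θ (the simplest
stationary field on the sphere); coupled genes add
`coupling × standardized(tmap)`.  The default angular scale θ₀ = 0.1 rad
gives neighbour-scale autocorrelation at 152 regions — strong enough that
smoothness is a real feature of the fields, weak enough that gene-level
bootstrap inference stays calibrated (see the caveat above; at θ₀ ≥ 0.3
the conditional-variance inflation makes any per-gene score
anticonservative).  Defaults: 2,000 genes, 100 coupled at 0.5.

**Clinical.** Factor scores are standardized linear reads of the patients'
regional gradient scores (3 disjoint loaded regions per factor by default)
plus Gaussian noise (`noise_sd = 0.5` on the standardized scale, i.e. a
signal-dominated but clearly noisy symptom measure), affinely mapped into
a PANSS-like integer range (7–49) and clipped.  The five factors are
generated independently; real PANSS factors share a general-severity
dimension, so the real-data expectation that one PLS component correlates
with *all* factors is not reproduced here — the synthetic fit distributes
factors across components instead.

Not emulated anywhere: imaging artefacts and site effects, the
probe/donor structure of expression atlases, item-level symptom dynamics,
and any realistic effect topography (effects are planted in random regions
of the inner axis band).  Passing recovery tests therefore demonstrates
the statistical machinery under its stated assumptions, not performance on
real cohorts.

## Pipeline, formats, determinism

Stages run in a fixed order (simulate → msnet → gradients → compare →
spin-build → pls-genes → pls-clinical → enrich); expression is generated
against the *observed* case-control t-map (so coupled-gene recovery is
well defined) and clinical scores against the observed patient gradients,
which is why those generators run inside their consuming stages.  Every
stage owns a child seed spawned from the master seed, so single-stage
re-runs (`--from`, per-stage CLI commands) reproduce a full run
bit-for-bit.  All outputs are CSV/TSV + JSON; floats are written with 17
significant digits and read back with the correctly-rounded parser, so a
stage restarted from disk sees the exact float64 values the previous stage
held in memory.  MS matrices are recomputed rather than persisted by
default (`write_ms_matrices` turns persistence on).  The run manifest
echoes the config, stage seeds, package version and SHA-256 of every CSV;
no CSV embeds a timestamp, so fixed-seed runs are byte-identical.

Problem sizes used by the shipped experiments: recovery and calibration
tests run at the default study conditions (308 regions, 100 subjects per
group, 2,000 genes, 1,000 spins / bootstrap resamples) except where a
statement is per-unit and a smaller instance is statistically equivalent
(e.g. oracle equivalence on ≤ 100-region graphs, spin calibration on a
200-region hemisphere); 20 seeded replicates back each stochastic claim.
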