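"""End-to-end orchestration of the synthetic MS-gradient analysis.

Stages run in a fixed order::

    simulate -> msnet -> gradients -> compare -> spin-build
             -> pls-genes -> pls-clinical -> enrich

Each stage writes plain-text outputs into its own subdirectory of the run
directory and can be re-run in isolation (``start_from``): whatever upstream
state it needs is re-read from the run directory, or deterministically
recomputed where the artifact is cheap and not persisted (MS matrices by
default).  All randomness flows from the master seed in the config: every
stage owns an independent child seed, so partial re-runs reproduce the full
run bit-for-bit.  No output CSV embeds a timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from ._utils import spawn_seeds
from ._version import __version__
from .config import PipelineConfig
from .enrich import GeneSetCollection, hypergeometric_ora, write_gmt
from .gradients import align_gradients, build_affinity, diffusion_embedding, principal_gradient_table
from .groupstats import aggregate_by_label, fit_region_glm
from .msnet import subject_ms_matrices
from .plsclinical import fit_clinical_pls, top_regions_per_factor, vip_scores
from .plsgenes import correlate_component_map, export_ranked_genes, gene_significance
from .spin import build_spin_permutations, spin_component_significance
from .synthetic import (
    FACTOR_NAMES,
    generate_clinical,
    generate_cohort,
    generate_expression,
    generate_sphere_parcellation,
    hierarchy_band_regions,
)

__all__ = ["STAGES", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "msnet",
    "gradients",
    "compare",
    "spin-build",
    "pls-genes",
    "pls-clinical",
    "enrich",
)


class _Context:
    """Mutable bag of in-memory stage products with disk fallbacks."""

    def __init__(self, config: PipelineConfig, out_dir: Path):
        self.config = config
        self.dir = out_dir
        self.seeds = dict(zip(STAGES, spawn_seeds(config.seed, len(STAGES))))
        self.cache: dict[str, object] = {}

    # --- disk fallbacks -------------------------------------------------
    def parcellation(self):
        if "parcellation" not in self.cache:
            self.cache["parcellation"] = msio.read_parcellation(
                self.dir / "synthetic" / "parcellation.csv"
            )
        return self.cache["parcellation"]

    def features(self):
        if "features" not in self.cache:
            self.cache["features"] = msio.read_feature_table(self.dir / "synthetic")
        return self.cache["features"]

    def truth(self):
        if "truth" not in self.cache:
            self.cache["truth"] = msio.read_ground_truth(
                self.dir / "synthetic" / "ground_truth.json"
            )
        return self.cache["truth"]

    def ms_matrices(self):
        if "ms_matrices" not in self.cache:
            ms_dir = self.dir / "msnet"
            if (ms_dir / "manifest.json").exists() and any(ms_dir.glob("hc*.csv")):
                self.cache["ms_matrices"] = msio.read_ms_matrices(ms_dir)
            else:  # cheap and deterministic: recompute from features
                self.cache["ms_matrices"] = subject_ms_matrices(self.features())
        return self.cache["ms_matrices"]

    def principal(self) -> pd.DataFrame:
        if "principal" not in self.cache:
            self.cache["principal"] = msio.read_csv(
                self.dir / "gradients" / "principal_gradients.csv",
                index_col="subject_id",
            )
        return self.cache["principal"]

    def tmap_left(self) -> pd.Series:
        if "tmap_left" not in self.cache:
            stats = msio.read_csv(self.dir / "compare" / "region_stats.csv")
            parc = self.parcellation()
            t = stats.set_index("region_id")["t_value"]
            self.cache["tmap_left"] = t.loc[parc.ids("left")].rename("t_value")
        return self.cache["tmap_left"]

    def spins(self):
        if "spins" not in self.cache:
            self.cache["spins"] = msio.read_spins(self.dir / "spin")
        return self.cache["spins"]

    def expression(self) -> pd.DataFrame:
        if "expression" not in self.cache:
            self.cache["expression"] = msio.read_csv(
                self.dir / "synthetic" / "expression.csv", index_col="region_id"
            )
        return self.cache["expression"]

    def signif_genes(self) -> list[str]:
        if "signif_genes" not in self.cache:
            summary = json.loads(
                (self.dir / "plsgenes" / "summary.json").read_text()
            )
            self.cache["signif_genes"] = summary["significant_genes_union"]
        return self.cache["signif_genes"]


def _update_truth(ctx: _Context, new_truth) -> None:
    merged = ctx.truth().merged(new_truth)
    ctx.cache["truth"] = merged
    msio.write_ground_truth(merged, ctx.dir / "synthetic" / "ground_truth.json")


# --- stages -------------------------------------------------------------


def _stage_simulate(ctx: _Context) -> None:
    cfg = ctx.config.synthetic
    seed = int(ctx.seeds["simulate"])
    parc = generate_sphere_parcellation(cfg.n_left, cfg.n_right, seed=seed)
    rng = np.random.default_rng(seed)
    pool = hierarchy_band_regions(parc)
    effect_regions = tuple(
        sorted(rng.choice(pool, size=cfg.n_effect_regions, replace=False))
    )
    features, truth = generate_cohort(
        parc,
        n_per_group=cfg.n_per_group,
        n_features=cfg.n_features,
        effect_regions=effect_regions,
        effect_size=cfg.effect_size,
        noise_sd=cfg.noise_sd,
        seed=seed,
    )
    out = ctx.dir / "synthetic"
    out.mkdir(parents=True, exist_ok=True)
    msio.write_parcellation(parc, out / "parcellation.csv")
    msio.write_feature_table(features, out)
    msio.write_ground_truth(truth, out / "ground_truth.json")
    ctx.cache.update(parcellation=parc, features=features, truth=truth)


def _stage_msnet(ctx: _Context) -> None:
    matrices = subject_ms_matrices(ctx.features())
    out = ctx.dir / "msnet"
    out.mkdir(parents=True, exist_ok=True)
    if ctx.config.write_ms_matrices:
        msio.write_ms_matrices(matrices, out)
    else:
        (out / "manifest.json").write_text(
            json.dumps(
                {
                    "subjects": [m.subject_id for m in matrices],
                    "n_regions": len(matrices[0].region_ids),
                    "persisted": False,
                },
                indent=1,
            )
        )
    ctx.cache["ms_matrices"] = matrices


def _stage_gradients(ctx: _Context) -> None:
    g = ctx.config.gradients
    parc = ctx.parcellation()
    sets = []
    for ms in ctx.ms_matrices():
        aff = build_affinity(ms, sparsity=g.sparsity, kernel=g.kernel)
        sets.append(
            diffusion_embedding(
                aff,
                alpha=g.alpha,
                n_components=g.n_components,
                subject_id=ms.subject_id,
                region_ids=ms.region_ids,
            )
        )
    aligned, reference = align_gradients(sets, reference=g.align, parcellation=parc)
    principal = principal_gradient_table(aligned)
    out = ctx.dir / "gradients"
    out.mkdir(parents=True, exist_ok=True)
    msio.write_gradient_sets(aligned, out)
    msio.write_csv(principal, out / "principal_gradients.csv")

    # group-level embedding of the mean MS matrix, reported alongside the
    # mean of the individual explained-variance figures
    mean_ms = np.mean([m.matrix for m in ctx.ms_matrices()], axis=0)
    np.fill_diagonal(mean_ms, 0.0)
    group_embed = diffusion_embedding(
        build_affinity(mean_ms, sparsity=g.sparsity, kernel=g.kernel),
        alpha=g.alpha,
        n_components=g.n_components,
        subject_id="group_mean_ms",
        region_ids=sets[0].region_ids,
    )
    summary = {
        "mean_individual_explained_variance": np.mean(
            [s.explained_variance for s in sets], axis=0
        ).tolist(),
        "group_embedding_explained_variance": group_embed.explained_variance.tolist(),
        "kernel": g.kernel,
        "sparsity": g.sparsity,
        "alpha": g.alpha,
        "n_components": g.n_components,
        "explained_variance_normalization": "retained non-trivial eigenvalues",
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    ctx.cache.update(principal=principal, reference=reference)


def _stage_compare(ctx: _Context) -> None:
    st = ctx.config.stats
    parc = ctx.parcellation()
    principal = ctx.principal()
    covariates = ctx.features().subjects
    stats = fit_region_glm(
        principal,
        covariates,
        alpha=st.fdr_alpha,
        include_interaction=st.include_interaction,
    )
    yeo = aggregate_by_label(
        principal, parc.table["yeo_label"], covariates, alpha=st.fdr_alpha,
        include_interaction=st.include_interaction,
    )
    veco = aggregate_by_label(
        principal, parc.table["von_economo_label"], covariates, alpha=st.fdr_alpha,
        include_interaction=st.include_interaction,
    )
    out = ctx.dir / "compare"
    out.mkdir(parents=True, exist_ok=True)
    msio.write_csv(stats, out / "region_stats.csv", index=False)
    msio.write_csv(yeo, out / "yeo_stats.csv", index=False)
    msio.write_csv(veco, out / "von_economo_stats.csv", index=False)
    tmap = stats.set_index("region_id")["t_value"].loc[parc.ids("left")]
    ctx.cache["tmap_left"] = tmap


def _stage_spin_build(ctx: _Context) -> None:
    sp = ctx.config.spin
    spins = build_spin_permutations(
        ctx.parcellation(),
        n_perm=sp.n_perm,
        seed=int(ctx.seeds["spin-build"]),
        hemisphere_mode=sp.hemisphere_mode,
        exact_bijection=sp.exact_bijection,
    )
    msio.write_spins(spins, ctx.dir / "spin")
    ctx.cache["spins"] = spins


def _stage_pls_genes(ctx: _Context) -> None:
    cfg, pls = ctx.config.synthetic, ctx.config.pls
    seed = int(ctx.seeds["pls-genes"])
    parc = ctx.parcellation()
    tmap = ctx.tmap_left()
    expr, truth_e = generate_expression(
        parc,
        tmap,
        n_genes=cfg.n_genes,
        n_coupled=cfg.n_coupled,
        coupling=cfg.coupling,
        smoothness=cfg.smoothness,
        seed=seed,
    )
    msio.write_csv(expr, ctx.dir / "synthetic" / "expression.csv")
    _update_truth(ctx, truth_e)
    ctx.cache["expression"] = expr

    fit = gene_significance(
        expr,
        tmap,
        n_components=pls.n_components,
        n_resamples=pls.n_resamples,
        method=pls.method,
        seed=seed,
        fdr_threshold=pls.gene_fdr_threshold,
    )
    spins = ctx.spins()
    corr = correlate_component_map(fit, tmap, spins=spins)
    comp_sig = spin_component_significance(
        expr, tmap, spins, n_components=pls.n_components
    )
    fit.component_p_spin = comp_sig["p_spin"].to_numpy()

    out = ctx.dir / "plsgenes"
    out.mkdir(parents=True, exist_ok=True)
    for a in range(1, pls.n_components + 1):
        msio.write_csv(
            export_ranked_genes(fit, component=a),
            out / f"ranked_genes_pls{a}.csv",
            index=False,
        )
    maps = pd.DataFrame(
        fit.x_scores,
        index=pd.Index(list(fit.sample_names), name="region_id"),
        columns=[f"pls{a}_score" for a in range(1, pls.n_components + 1)],
    )
    msio.write_csv(maps, out / "component_maps.csv")
    union = sorted(set().union(*fit.signif_genes.values()))
    summary = {
        "explained_variance_y": fit.explained_variance_y.tolist(),
        "component_p_spin": comp_sig["p_spin"].tolist(),
        "map_correlation_r": corr["r"].tolist(),
        "map_correlation_p_spin": corr["p_spin"].tolist(),
        "n_significant_per_component": {
            str(a): len(v) for a, v in fit.signif_genes.items()
        },
        "significant_genes_union": union,
        "method": pls.method,
        "spun_map": "y",
        "p_spin_sidedness": {
            "map_correlation": "two-sided",
            "explained_variance": "one-sided greater",
        },
        "fdr_threshold_applied_to": "adjusted p",
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    ctx.cache["signif_genes"] = union


def _stage_pls_clinical(ctx: _Context) -> None:
    cfg, pls = ctx.config.synthetic, ctx.config.pls
    seed = int(ctx.seeds["pls-clinical"])
    principal = ctx.principal()
    subjects = ctx.features().subjects
    patients = subjects.loc[subjects["group"] == "patient", "subject_id"]
    x = principal.loc[sorted(patients)]

    rng = np.random.default_rng(seed)
    regions = list(principal.columns)
    chosen = rng.choice(
        len(regions), size=cfg.regions_per_factor * len(FACTOR_NAMES), replace=False
    )
    loadings = pd.DataFrame(
        0.0, index=list(FACTOR_NAMES), columns=regions
    )
    for i, factor in enumerate(FACTOR_NAMES):
        for j in chosen[i * cfg.regions_per_factor : (i + 1) * cfg.regions_per_factor]:
            loadings.loc[factor, regions[j]] = 1.0
    loadings = loadings.loc[:, (loadings != 0).any(axis=0)]

    clinical, truth_c = generate_clinical(
        x, loadings, noise_sd=cfg.clinical_noise_sd, seed=seed
    )
    msio.write_csv(clinical, ctx.dir / "synthetic" / "clinical.csv", index_label="subject_id")
    _update_truth(ctx, truth_c)

    fit = fit_clinical_pls(x, clinical, n_components=pls.clinical_components, seed=seed)
    vip = vip_scores(fit)
    top = top_regions_per_factor(
        x, clinical, k=5, n_components=pls.clinical_components, seed=seed
    )
    out = ctx.dir / "plsclinical"
    out.mkdir(parents=True, exist_ok=True)
    msio.write_csv(vip, out / "vip_joint.csv", index=False)
    for factor in clinical.columns:
        f_fit = fit_clinical_pls(
            x, clinical[[factor]], n_components=pls.clinical_components, seed=seed
        )
        msio.write_csv(vip_scores(f_fit), out / f"vip_{factor}.csv", index=False)
    (out / "top_regions.json").write_text(
        json.dumps(
            {f: t["region_id"].tolist() for f, t in top.items()},
            indent=1,
            sort_keys=True,
        )
    )
    summary = {
        "n_components": fit.n_components,
        "explained_variance_y": fit.explained_variance_y.tolist(),
        "factor_correlations_with_pls1": fit.factor_correlations.to_dict(),
        "population": "patients_only",
        "factors_z_scored": True,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))


def _stage_enrich(ctx: _Context) -> None:
    cfg = ctx.config.synthetic
    seed = int(ctx.seeds["enrich"])
    expr = ctx.expression()
    truth = ctx.truth()
    background = list(expr.columns)
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    if truth.coupled_genes:
        sets["coupled_genes"] = list(truth.coupled_genes)
    for i in range(cfg.n_random_gene_sets):
        size = min(cfg.random_gene_set_size, len(background))
        sets[f"random_set_{i:02d}"] = sorted(
            rng.choice(background, size=size, replace=False)
        )
    gmt_path = ctx.dir / "synthetic" / "genesets.gmt"
    write_gmt(sets, gmt_path)
    collection = GeneSetCollection.from_gmt(gmt_path, background)

    hits = ctx.signif_genes()
    if not hits:
        ranked = msio.read_csv(ctx.dir / "plsgenes" / "ranked_genes_pls1.csv")
        hits = (
            ranked.reindex(ranked["z"].abs().sort_values(ascending=False).index)
            .head(100)["gene_id"]
            .tolist()
        )
        logger.info("no FDR-significant genes; using top 100 |z| genes as hits")
    ora = hypergeometric_ora(hits, collection, alpha=ctx.config.stats.fdr_alpha)
    out = ctx.dir / "enrich"
    out.mkdir(parents=True, exist_ok=True)
    msio.write_csv(ora, out / "ora.csv", index=False)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "msnet": _stage_msnet,
    "gradients": _stage_gradients,
    "compare": _stage_compare,
    "spin-build": _stage_spin_build,
    "pls-genes": _stage_pls_genes,
    "pls-clinical": _stage_pls_clinical,
    "enrich": _stage_enrich,
}


def _hash_outputs(out_dir: Path) -> dict[str, str]:
    hashes = {}
    for path in sorted(out_dir.rglob("*.csv")):
        hashes[str(path.relative_to(out_dir))] = hashlib.sha256(
            path.read_bytes()
        ).hexdigest()
    return hashes


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    start_from: str | None = None,
    stop_after: str | None = None,
) -> Path:
    """Execute the pipeline (optionally a contiguous stage range).

    Writes per-stage outputs, a manifest JSON (config echo, stage seeds,
    package version, output hashes) and a human-readable log; any stage
    failure aborts with the stage name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in (start_from, stop_after):
        if name is not None and name not in STAGES:
            raise ValueError(f"unknown stage {name!r}; stages are {STAGES}")
    config.to_yaml(out_dir / "config.yaml")

    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("msgradient")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    ctx = _Context(config, out_dir)
    first = STAGES.index(start_from) if start_from else 0
    last = STAGES.index(stop_after) if stop_after else len(STAGES) - 1
    try:
        for name in STAGES[first : last + 1]:
            logger.info("stage %s starting", name)
            try:
                _STAGE_FN[name](ctx)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done", name)
        manifest = {
            "config": config.model_dump(),
            "stage_seeds": {k: int(v) for k, v in ctx.seeds.items()},
            "version": __version__,
            "output_hashes": _hash_outputs(out_dir),
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )
    finally:
        root.removeHandler(handler)
        handler.close()
    return out_dir
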