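"""Plain-text readers and writers (CSV/TSV + JSON sidecars).

Every artifact the pipeline produces or consumes round-trips through
inspectable text formats; floats are written with 17 significant digits so
reading a stage's output back reproduces the exact in-memory float64 values.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gradients import GradientSet
from .msnet import MSMatrix
from .spin import SpinPermutationSet
from .synthetic import FeatureTable, GroundTruth, SphereParcellation

__all__ = [
    "write_csv",
    "read_csv",
    "write_parcellation",
    "read_parcellation",
    "write_feature_table",
    "read_feature_table",
    "write_ground_truth",
    "read_ground_truth",
    "write_ms_matrices",
    "read_ms_matrices",
    "write_gradient_sets",
    "read_gradient_sets",
    "write_spins",
    "read_spins",
]


#: %.17g guarantees exact float64 round-trips through CSV text
FLOAT_FORMAT = "%.17g"


def write_csv(frame: pd.DataFrame, path: str | Path, **kwargs) -> None:
    frame.to_csv(path, float_format=FLOAT_FORMAT, **kwargs)


def read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    """read with the correctly-rounded float parser (exact round-trips)."""
    return pd.read_csv(path, float_precision="round_trip", **kwargs)


def write_parcellation(parc: SphereParcellation, path: str | Path) -> None:
    write_csv(parc.table, path, index_label="region_id")


def read_parcellation(path: str | Path) -> SphereParcellation:
    return SphereParcellation(read_csv(path, index_col="region_id"))


def write_feature_table(table: FeatureTable, directory: str | Path) -> None:
    """Wide CSV + tidy TSV + covariates CSV under ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_csv(table.wide_frame(), d / "features_wide.csv")
    write_csv(table.tidy_frame(), d / "features_tidy.tsv", sep="\t", index=False)
    write_csv(table.subjects, d / "covariates.csv", index=False)


def read_feature_table(directory: str | Path) -> FeatureTable:
    d = Path(directory)
    wide = read_csv(d / "features_wide.csv", index_col="subject_id")
    subjects = read_csv(d / "covariates.csv")
    pairs = [c.split("|") for c in wide.columns]
    region_ids = tuple(dict.fromkeys(p[0] for p in pairs))
    features = tuple(dict.fromkeys(p[1] for p in pairs))
    values = wide.loc[subjects["subject_id"]].to_numpy(float).reshape(
        len(subjects), len(region_ids), len(features)
    )
    return FeatureTable(
        values=values,
        subjects=subjects,
        region_ids=region_ids,
        feature_names=features,
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "seed": truth.seed,
        "effect_regions": list(truth.effect_regions),
        "effect_size": truth.effect_size,
        "coupled_genes": list(truth.coupled_genes),
        "hierarchy_axis": (
            truth.hierarchy_axis.to_dict() if truth.hierarchy_axis is not None else None
        ),
        "coupling_coefficients": (
            truth.coupling_coefficients.to_dict()
            if truth.coupling_coefficients is not None
            else None
        ),
        "clinical_loadings": (
            {
                f: truth.clinical_loadings.loc[f].to_dict()
                for f in truth.clinical_loadings.index
            }
            if truth.clinical_loadings is not None
            else None
        ),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        seed=payload["seed"],
        effect_regions=tuple(payload["effect_regions"]),
        effect_size=payload["effect_size"],
        coupled_genes=tuple(payload["coupled_genes"]),
        hierarchy_axis=(
            pd.Series(payload["hierarchy_axis"])
            if payload["hierarchy_axis"] is not None
            else None
        ),
        coupling_coefficients=(
            pd.Series(payload["coupling_coefficients"])
            if payload["coupling_coefficients"] is not None
            else None
        ),
        clinical_loadings=(
            pd.DataFrame(payload["clinical_loadings"]).T
            if payload["clinical_loadings"] is not None
            else None
        ),
    )


def write_ms_matrices(matrices: Sequence[MSMatrix], directory: str | Path) -> None:
    """One CSV per subject plus a manifest JSON."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for m in matrices:
        (pd.DataFrame(
            m.matrix, index=list(m.region_ids), columns=list(m.region_ids)
        ).pipe(write_csv, d / f"{m.subject_id}.csv", index_label="region_id"))
    manifest = {
        "subjects": [m.subject_id for m in matrices],
        "n_regions": len(matrices[0].region_ids) if matrices else 0,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_ms_matrices(directory: str | Path) -> list[MSMatrix]:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    out = []
    for sid in manifest["subjects"]:
        frame = read_csv(d / f"{sid}.csv", index_col="region_id")
        out.append(
            MSMatrix(
                subject_id=sid,
                matrix=frame.to_numpy(float),
                region_ids=tuple(frame.index),
            )
        )
    return out


def write_gradient_sets(sets: Sequence[GradientSet], directory: str | Path) -> None:
    """Long-format components CSV + JSON sidecar with spectra and flags."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    frames = []
    for g in sets:
        frame = pd.DataFrame(
            g.components,
            index=pd.Index(list(g.region_ids), name="region_id"),
            columns=[f"g{i + 1}" for i in range(g.n_components)],
        )
        frame.insert(0, "subject_id", g.subject_id)
        frames.append(frame.reset_index())
    write_csv(pd.concat(frames, ignore_index=True), d / "components.csv", index=False)
    sidecar = {
        g.subject_id: {
            "eigenvalues": g.eigenvalues.tolist(),
            "explained_variance": g.explained_variance.tolist(),
            "aligned": g.aligned,
            "reference_id": g.reference_id,
        }
        for g in sets
    }
    (d / "components.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_gradient_sets(directory: str | Path) -> list[GradientSet]:
    d = Path(directory)
    table = read_csv(d / "components.csv")
    sidecar = json.loads((d / "components.json").read_text())
    comps = [c for c in table.columns if c.startswith("g") and c[1:].isdigit()]
    out = []
    for sid, block in table.groupby("subject_id", sort=False):
        meta = sidecar[str(sid)]
        out.append(
            GradientSet(
                subject_id=str(sid),
                components=block[comps].to_numpy(float),
                eigenvalues=np.asarray(meta["eigenvalues"]),
                explained_variance=np.asarray(meta["explained_variance"]),
                region_ids=tuple(block["region_id"]),
                aligned=meta["aligned"],
                reference_id=meta["reference_id"],
            )
        )
    return out


def write_spins(spins: SpinPermutationSet, directory: str | Path) -> None:
    """Compact mapping CSV + JSON header so a null set is reusable bit-identically."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(spins.mappings, columns=list(spins.region_ids)).to_csv(
        d / "spins.csv", index=False
    )
    header = {
        "seed": spins.seed,
        "n_perm": spins.n_perm,
        "hemisphere_mode": spins.hemisphere_mode,
        "hemispheres": list(spins.hemispheres),
    }
    (d / "spins.json").write_text(json.dumps(header, indent=1))


def read_spins(directory: str | Path) -> SpinPermutationSet:
    d = Path(directory)
    header = json.loads((d / "spins.json").read_text())
    table = pd.read_csv(d / "spins.csv")
    return SpinPermutationSet(
        mappings=table.to_numpy(np.int64),
        region_ids=tuple(table.columns),
        seed=header["seed"],
        hemisphere_mode=header["hemisphere_mode"],
        hemispheres=tuple(header["hemispheres"]),
    )
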