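"""Pipeline configuration: validated, echoed verbatim into every run.

Unknown keys are rejected before any compute (pydantic ``extra='forbid'``).
All randomness flows from the single master ``seed``: each stage receives an
independent child seed derived from it, so stage re-runs and stage-skipping
reproduce identical results.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticParams(_Strict):
    n_left: int = 152
    n_right: int = 156
    n_per_group: int = 100
    n_features: int = 5
    n_effect_regions: int = 8
    effect_size: float = 0.8
    noise_sd: float = 0.3
    n_genes: int = 2000
    n_coupled: int = 100
    coupling: float = 0.5
    smoothness: float = 0.1
    clinical_noise_sd: float = 0.5
    regions_per_factor: int = 3
    n_random_gene_sets: int = 10
    random_gene_set_size: int = 100


class GradientParams(_Strict):
    sparsity: float = 0.9
    kernel: str = "normalized_angle"
    alpha: float = 0.5
    n_components: int = 10
    align: str = "group_mean"


class StatsParams(_Strict):
    fdr_alpha: float = 0.05
    include_interaction: bool = True


class SpinParams(_Strict):
    n_perm: int = 1000
    hemisphere_mode: str = "left_only"
    exact_bijection: bool = False


class PLSParams(_Strict):
    n_components: int = 2
    n_resamples: int = 1000
    method: str = "bootstrap"
    gene_fdr_threshold: float = 0.001
    clinical_components: int | None = None


class PipelineConfig(_Strict):
    seed: int = 0
    write_ms_matrices: bool = False
    synthetic: SyntheticParams = Field(default_factory=SyntheticParams)
    gradients: GradientParams = Field(default_factory=GradientParams)
    stats: StatsParams = Field(default_factory=StatsParams)
    spin: SpinParams = Field(default_factory=SpinParams)
    pls: PLSParams = Field(default_factory=PLSParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=True, default_flow_style=False)
        )
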