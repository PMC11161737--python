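"""Pipeline configuration: a single validated YAML schema.

Defaults reproduce the reference parameterisation of the workflow:
Tukey k = 1.5, differential threshold 3 (both directions), absolute
thresholds 10 / 1 FPKM, CNV calls at |log2| > 2 with 3 clusters on 10
principal components, 1500 bp promoters, FDR 0.05, FFPM cut-off 0.1.
Unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .outliers import ExtremeThresholds


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ThresholdConfig(_Strict):
    tukey_k: float = 1.5
    diff_pos: float = 3.0
    diff_neg: float = 3.0
    abs_pos: float = 10.0
    abs_neg: float = 1.0

    def to_thresholds(self) -> ExtremeThresholds:
        return ExtremeThresholds(**self.model_dump())


class CnvConfig(_Strict):
    n_clusters: int = 3
    n_components: int = 10
    seed: int = 0
    min_metanormal_cn: float = 0.1


class MethylationConfig(_Strict):
    promoter_window: int = 1500
    min_outliers: int = 2
    beta_rule_direction: str = "results"
    fdr_level: float = 0.05


class FusionConfig(_Strict):
    ffpm_cutoff: float = 0.1


class InputPaths(_Strict):
    expression: str | None = None
    annotation: str | None = None
    depth: str | None = None
    beta: str | None = None
    cpg_manifest: str | None = None
    cgi_bed: str | None = None
    fusions_a: str | None = None
    fusions_b: str | None = None
    sample_annotation: str | None = None
    druggability: str | None = None


class PipelineConfig(_Strict):
    inputs: InputPaths = InputPaths()
    thresholds: ThresholdConfig = ThresholdConfig()
    cnv: CnvConfig = CnvConfig()
    methylation: MethylationConfig = MethylationConfig()
    fusion: FusionConfig = FusionConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
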