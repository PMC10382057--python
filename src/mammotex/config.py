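"""Run configuration: schema-validated YAML, unknown keys rejected."""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class CohortSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_patients: int = Field(60, ge=10)
    effect_size: float = 0.0
    missing_label_fraction: float = Field(0.05, ge=0.0, le=1.0)


class ExclusionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_size_mm: float = 5.0
    size_window: Optional[Tuple[float, float]] = None


class ExperimentSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tasks: List[str] = ["er", "pr", "her2", "histotype"]
    contrasts: List[List[str]] = [
        ["dce"], ["sub"], ["t2"],
        ["dce", "sub"], ["dce", "t2"], ["sub", "t2"], ["dce", "sub", "t2"],
    ]
    reductions: List[str] = ["relieff", "lasso"]
    classifiers: List[str] = ["svm", "fcnn"]
    n_folds: int = 5
    n_splits: int = 25
    allow_nonstandard_folds: bool = False

    @model_validator(mode="after")
    def _check_protocol(self):
        if self.n_folds != 5 and not self.allow_nonstandard_folds:
            raise ValueError(
                "the protocol uses 5 patient-wise folds; set "
                "allow_nonstandard_folds: true to override knowingly"
            )
        return self


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "mammotex_out"
    cohort_dir: Optional[str] = None
    cohort: CohortSection = CohortSection()
    exclusions: ExclusionSection = ExclusionSection()
    experiments: ExperimentSection = ExperimentSection()

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.model_validate(doc)
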