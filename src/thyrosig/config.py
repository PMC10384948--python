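"""Pipeline configuration: a validated TOML file with one section per stage.

Unknown keys are rejected, and a loaded configuration round-trips through
``dump_config`` / ``load_config`` unchanged. A single global seed fans out
deterministically to every stage (see :func:`stage_seed`).
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from pydantic import ValidationError as PydanticValidationError

from .errors import ValidationError
from .qc_filtering import FilterConfig
from .sae import SAEConfig
from .synthetic_data import CohortSpec


class IOConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    input_dir: str = ""      # cohort directory (peak lists + compounds.tsv)
    output_dir: str = "thyrosig_out"


class SyntheticConfig(CohortSpec):
    """Cohort spec plus an on/off switch.

    The pipeline default is a desk-scale cohort (500 + 200 ions); full-size
    cohorts are available by raising the feature counts. The generator seed
    is derived from the pipeline's global seed, so the ``seed`` field here is
    ignored when run through :func:`thyrosig.pipeline.run_pipeline`.
    """

    model_config = ConfigDict(extra="forbid")

    enabled: bool = True
    n_features_pos: int = Field(default=500, ge=0)
    n_features_neg: int = Field(default=200, ge=0)


class AlignConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mz_tol_ppm: float = Field(default=10.0, gt=0)
    rt_tol_min: float = Field(default=1.0, gt=0)
    annotation_tol_ppm: float = Field(default=15.0, gt=0)


class PLSDAConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    a_max: int = Field(default=5, ge=1)
    folds: int = Field(default=10, ge=2)
    n_permutations: int = Field(default=200, ge=1)


class SelectConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    k: int = Field(default=15, ge=1)
    drop_fraction: float = Field(default=0.5, gt=0.0, lt=1.0)


class EvaluationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_repeats: int = Field(default=12, ge=1)
    test_fraction: float = Field(default=0.25, gt=0.0, lt=1.0)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    io: IOConfig = Field(default_factory=IOConfig)
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    align: AlignConfig = Field(default_factory=AlignConfig)
    filters: FilterConfig = Field(default_factory=FilterConfig)
    plsda: PLSDAConfig = Field(default_factory=PLSDAConfig)
    sae: SAEConfig = Field(default_factory=SAEConfig)
    select: SelectConfig = Field(default_factory=SelectConfig)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)

    def hash(self) -> str:
        """Digest of the analysis-relevant configuration.

        The [io] section is excluded: where results are written does not
        change what is computed, and two runs of one analysis into different
        directories must agree on their hash.
        """
        payload = self.model_dump()
        payload.pop("io", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()


_STAGES = (
    "simulate", "align", "annotate", "filter", "normalize", "select", "evaluate",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    if stage not in _STAGES:
        raise ValidationError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(global_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def load_config(path: str | Path) -> PipelineConfig:
    try:
        data = tomllib.loads(Path(path).read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ValidationError(f"invalid TOML in {path}: {exc}") from exc
    try:
        return PipelineConfig.model_validate(data)
    except PydanticValidationError as exc:
        raise ValidationError(str(exc)) from exc


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return json.dumps(value)
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise ValidationError(f"cannot serialize {type(value).__name__} to TOML")


def dump_config(config: PipelineConfig, path: str | Path | None = None) -> str:
    """Serialize a config to TOML (flat sections of scalars and lists)."""
    data = config.model_dump()
    lines: list[str] = []
    for key, value in data.items():
        if not isinstance(value, dict):
            lines.append(f"{key} = {_toml_value(value)}")
    for section, fields in data.items():
        if not isinstance(fields, dict):
            continue
        lines.append("")
        lines.append(f"[{section}]")
        for key, value in fields.items():
            if value is None:
                continue  # optional field left unset
            if isinstance(value, dict):
                for sub, subval in value.items():
                    lines.append(f"{key}.{json.dumps(sub)} = {_toml_value(subval)}")
            else:
                lines.append(f"{key} = {_toml_value(value)}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
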