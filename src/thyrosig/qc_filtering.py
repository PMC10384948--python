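"""Ion-selection cascade: adduct annotation, intensity and blank-ratio filters.

Untargeted LC-MS feature tables are dominated by background ions (solvent,
fixative, column bleed) and low-intensity noise. The cascade implemented here
reduces an aligned table to the analyzable ion set:

1. keep only ions with at least one proton-adduct compound annotation,
2. keep ions whose mean intensity over biological samples (zeros included)
   is at least ``min_mean_intensity`` (default 1e4),
3. keep ions whose sample/blank mean-intensity ratio is at least
   ``min_blank_ratio`` (default 50); an ion absent from every blank has an
   infinite ratio and is always retained,
4. optionally require the dual-software evidence flag.

Both numeric thresholds are inclusive. Every stage is recorded in a
:class:`FilterReport` whose counts satisfy conservation:
``count_in == count_out + sum(removed per stage)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .errors import ValidationError
from .feature_tables import FeatureTable, IonAnnotation


class FilterConfig(BaseModel):
    """Thresholds and switches of the ion-selection cascade."""

    model_config = ConfigDict(extra="forbid")

    min_mean_intensity: float = Field(default=1e4, gt=0)
    min_blank_ratio: float = Field(default=50.0, gt=0)
    require_adduct_annotation: bool = True
    apply_intensity_filter: bool = True
    apply_blank_ratio_filter: bool = True
    require_evidence_flag: bool = False


@dataclass
class FilterStage:
    name: str
    count_after: int
    removed_ids: list[str] = field(default_factory=list)


@dataclass
class FilterReport:
    """Machine-readable record of what each cascade stage removed."""

    count_in: int
    stages: list[FilterStage] = field(default_factory=list)

    @property
    def count_out(self) -> int:
        return self.stages[-1].count_after if self.stages else self.count_in

    def counts_after_each_stage(self) -> dict[str, int]:
        return {s.name: s.count_after for s in self.stages}

    def check_conservation(self) -> None:
        removed = [fid for s in self.stages for fid in s.removed_ids]
        if len(removed) != len(set(removed)):
            raise ValidationError("a feature id was removed twice in the report")
        if self.count_in != self.count_out + len(removed):
            raise ValidationError(
                f"report conservation violated: {self.count_in} != "
                f"{self.count_out} + {len(removed)}"
            )
        prev = self.count_in
        for stage in self.stages:
            if stage.count_after > prev:
                raise ValidationError(
                    f"stage {stage.name!r} increased the feature count"
                )
            prev = stage.count_after

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "count_in": self.count_in,
            "count_out": self.count_out,
            "stages": [
                {
                    "name": s.name,
                    "count_after": s.count_after,
                    "removed_ids": list(s.removed_ids),
                }
                for s in self.stages
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _subset(table: FeatureTable, keep: np.ndarray) -> tuple[FeatureTable, list[str]]:
    removed = [f.feature_id for f, k in zip(table.features, keep) if not k]
    return table.select_features(np.flatnonzero(keep)), removed


def mean_intensity_filter(
    table: FeatureTable, threshold: float = 1e4
) -> FeatureTable:
    """Retain features whose mean intensity over sample runs is >= threshold."""
    return _mean_intensity_step(table, threshold)[0]


def _mean_intensity_step(
    table: FeatureTable, threshold: float
) -> tuple[FeatureTable, list[str]]:
    mask = table.role_mask("sample")
    if not mask.any():
        raise ValidationError("mean_intensity_filter requires at least one sample run")
    if table.n_features == 0:
        return table, []
    means = table.intensities[:, mask].mean(axis=1)
    return _subset(table, means >= threshold)


def blank_ratio_filter(table: FeatureTable, ratio: float = 50.0) -> FeatureTable:
    """Retain features with sample-mean / blank-mean >= ratio (inclusive)."""
    return _blank_ratio_step(table, ratio)[0]


def _blank_ratio_step(
    table: FeatureTable, ratio: float
) -> tuple[FeatureTable, list[str]]:
    smask = table.role_mask("sample")
    bmask = table.role_mask("blank")
    if not bmask.any():
        raise ValidationError("blank_ratio_filter requires at least one blank run")
    if not smask.any():
        raise ValidationError("blank_ratio_filter requires at least one sample run")
    if table.n_features == 0:
        return table, []
    smean = table.intensities[:, smask].mean(axis=1)
    bmean = table.intensities[:, bmask].mean(axis=1)
    # an ion absent from every blank is maximally sample-specific: retained
    # unconditionally, however weak (the ratio is formally infinite)
    keep = (bmean <= 0) | (smean / np.where(bmean <= 0, 1.0, bmean) >= ratio)
    return _subset(table, keep)


def adduct_filter(
    table: FeatureTable, annotations: Sequence[IonAnnotation]
) -> FeatureTable:
    """Retain features carrying at least one proton-adduct annotation."""
    return _adduct_step(table, annotations)[0]


def _adduct_step(
    table: FeatureTable, annotations: Sequence[IonAnnotation]
) -> tuple[FeatureTable, list[str]]:
    annotated = {a.feature_id for a in annotations}
    keep = np.array([f.feature_id in annotated for f in table.features], dtype=bool)
    return _subset(table, keep)


def _evidence_step(table: FeatureTable) -> tuple[FeatureTable, list[str]]:
    keep = np.array([f.evidence_flag for f in table.features], dtype=bool)
    return _subset(table, keep)


def apply_cascade(
    table: FeatureTable,
    annotations: Sequence[IonAnnotation],
    config: FilterConfig | None = None,
) -> tuple[FeatureTable, FilterReport]:
    """Run the full ion-selection cascade and report per-stage bookkeeping."""
    config = config or FilterConfig()
    report = FilterReport(count_in=table.n_features)
    current = table
    if config.require_adduct_annotation:
        current, removed = _adduct_step(current, annotations)
        report.stages.append(
            FilterStage("adduct_annotation", current.n_features, removed)
        )
    if config.apply_intensity_filter:
        current, removed = _mean_intensity_step(current, config.min_mean_intensity)
        report.stages.append(
            FilterStage("mean_intensity", current.n_features, removed)
        )
    if config.apply_blank_ratio_filter:
        current, removed = _blank_ratio_step(current, config.min_blank_ratio)
        report.stages.append(FilterStage("blank_ratio", current.n_features, removed))
    if config.require_evidence_flag:
        current, removed = _evidence_step(current)
        report.stages.append(FilterStage("evidence_flag", current.n_features, removed))
    report.check_conservation()
    return current, report
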