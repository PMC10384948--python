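"""End-to-end orchestration: simulate/load -> align -> annotate -> filter ->
normalize -> select -> evaluate, with a reproducible run manifest.

The manifest records the config hash, the per-stage seeds, stage-by-stage
input/output counts and a sha256 checksum of every file written. It contains
nothing volatile, so two runs with an identical configuration produce
bit-identical outputs and manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .chemometrics import cross_validate_plsda, normalize, permutation_test
from .config import PipelineConfig, stage_seed
from .errors import ThyrosigError, ValidationError
from .evaluation import compare_models, folds_to_frame, make_splits
from .feature_tables import annotate, join_align, merge_modes
from .qc_filtering import apply_cascade
from .sae import topdown_select
from .synthetic_data import CohortSpec, generate_cohort, read_cohort


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seeds: dict[str, int]
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # file -> sha256
    status: str = "incomplete"
    failed_stage: str | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config_hash": self.config_hash,
            "version": self.version,
            "seeds": self.seeds,
            "stage_counts": self.stage_counts,
            "outputs": self.outputs,
            "status": self.status,
            "failed_stage": self.failed_stage,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage and write all exports plus the manifest."""
    out_dir = Path(config.io.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = {
        stage: stage_seed(config.seed, stage)
        for stage in ("simulate", "select", "evaluate")
    }
    manifest = RunManifest(
        config_hash=config.hash(), version=__version__, seeds=seeds
    )
    written: list[Path] = []

    def record(path: Path) -> None:
        written.append(path)

    stage = "simulate"
    try:
        if config.synthetic.enabled:
            spec = CohortSpec.model_validate(
                {
                    k: v
                    for k, v in config.synthetic.model_dump().items()
                    if k != "enabled"
                }
                | {"seed": seeds["simulate"]}
            )
            peak_lists, compounds, truth = generate_cohort(spec)
            manifest.stage_counts[stage] = {
                "runs": sum(len(v) for v in peak_lists.values()),
                "features_planted": truth.n_features,
                "expected_survivors": truth.expected_survivors,
            }
        else:
            if not config.io.input_dir:
                raise ValidationError(
                    "either [synthetic].enabled or [io].input_dir is required"
                )
            peak_lists, compounds = read_cohort(config.io.input_dir)
            manifest.stage_counts[stage] = {
                "runs": sum(len(v) for v in peak_lists.values())
            }

        stage = "align"
        tables = {}
        for mode in ("positive", "negative"):
            lists = peak_lists.get(mode, [])
            if lists and any(len(pl) for pl in lists):
                tables[mode] = join_align(
                    lists,
                    mz_tol_ppm=config.align.mz_tol_ppm,
                    rt_tol_min=config.align.rt_tol_min,
                )
        if not tables:
            raise ValidationError("no peaks in any mode")
        if len(tables) == 2:
            table = merge_modes(tables["positive"], tables["negative"])
        else:
            table = next(iter(tables.values()))
        manifest.stage_counts[stage] = {
            mode: t.n_features for mode, t in tables.items()
        } | {"merged": table.n_features}

        stage = "annotate"
        annotations = annotate(
            table.features, compounds, tol_ppm=config.align.annotation_tol_ppm
        )
        manifest.stage_counts[stage] = {
            "annotations": len(annotations),
            "annotated_features": len({a.feature_id for a in annotations}),
        }

        stage = "filter"
        filtered, report = apply_cascade(table, annotations, config.filters)
        report.to_json(out_dir / "filter_report.json")
        record(out_dir / "filter_report.json")
        filtered.write_csv(out_dir / "feature_table.csv")
        record(out_dir / "feature_table.csv")
        record(out_dir / "feature_table.samples.json")
        manifest.stage_counts[stage] = {
            "in": report.count_in,
            "out": report.count_out,
        }

        stage = "normalize"
        nm = normalize(filtered)
        manifest.stage_counts[stage] = {
            "features": nm.values.shape[0],
            "samples": nm.values.shape[1],
        }

        stage = "select"
        sae_cfg = config.sae.model_copy(update={"seed": seeds["select"]})
        signature = topdown_select(
            filtered,
            k=config.select.k,
            drop_fraction=config.select.drop_fraction,
            config=sae_cfg,
            annotations=annotations,
            compounds=compounds,
        )
        signature.write_csv(out_dir / "signature.csv")
        record(out_dir / "signature.csv")
        manifest.stage_counts[stage] = {"signature_size": len(signature.entries)}

        stage = "evaluate"
        sig_table = filtered.select_by_ids(signature.feature_ids)
        raw = sig_table.sample_matrix().T  # samples x features
        y = sig_table.class_labels("sample")
        plan = make_splits(
            y,
            n_repeats=config.evaluation.n_repeats,
            test_fraction=config.evaluation.test_fraction,
            seed=seeds["evaluate"],
        )
        plan.to_json(out_dir / "splits.json")
        record(out_dir / "splits.json")
        comparison = compare_models(raw, y, plan)
        comparison.write_csv(out_dir / "comparison.csv")
        record(out_dir / "comparison.csv")
        if "SAE" in comparison.folds:
            folds_to_frame(comparison.folds["SAE"]).to_csv(
                out_dir / "sae_folds.csv"
            )
            record(out_dir / "sae_folds.csv")
        perf = cross_validate_plsda(
            raw, y, a_max=config.plsda.a_max, folds=config.plsda.folds,
            seed=seeds["evaluate"],
        )
        perm = permutation_test(
            raw, y, n_components=min(config.plsda.a_max, 2),
            n_perm=config.plsda.n_permutations, seed=seeds["evaluate"],
            folds=min(config.plsda.folds, 5),
        )
        summary = {
            "plsda": {
                "accuracy": perf.accuracy,
                "r2": perf.r2,
                "q2": perf.q2,
                "best_a": perf.best_a,
            },
            "permutation": {
                "observed_cv_accuracy": perm.observed_statistic,
                "n_permutations": perm.n_permutations,
                "p_value": perm.p_value,
            },
            "comparison_means": {
                m: agg.mean for m, agg in comparison.aggregates.items()
            },
        }
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n"
        )
        record(out_dir / "summary.json")
        manifest.stage_counts[stage] = {
            "repeats": plan.n_repeats,
            "methods": len(comparison.aggregates),
        }
        manifest.status = "complete"
    except ThyrosigError:
        manifest.failed_stage = stage
        manifest.status = "failed"
        manifest.outputs = {p.name: _checksum(p) for p in written if p.exists()}
        manifest.to_json(out_dir / "manifest.json")
        raise

    manifest.outputs = {p.name: _checksum(p) for p in written}
    manifest.to_json(out_dir / "manifest.json")
    return manifest
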