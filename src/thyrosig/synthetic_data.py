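"""Synthetic LC-MS cohort generator with planted, bookkept ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be tested end to end without patient data:

* a two-class cohort (default 56 benign / 22 malignant) plus blank and
  pooled-QC runs, acquired in positive and negative ion mode;
* log-normal feature intensities: ``I = 10 ** (mu_f + delta_class + eps)``
  where the class effect splits the benign/malignant mean ratio symmetrically
  in log space and ``eps`` is the within-class biological noise;
* a planted set of informative ions whose benign/malignant mean-intensity
  ratios default to a realistic 0.55-7.0 spread (two of the fifteen in
  negative mode, the rest positive);
* decoy populations engineered to fail each cascade stage: ions below the
  mean-intensity threshold, blank-contaminated ions below the 50x sample/
  blank ratio, and ions with no proton-adduct match in the compound table;
* per-run m/z jitter (<=3 ppm) and RT jitter (<=0.2 min) around the true ion
  positions, so alignment is exercised realistically.

Every fate flag (annotatable / survives the intensity filter / survives the
blank-ratio filter) is recorded in :class:`GroundTruth` and verified against
the generated matrix before returning, which makes the filter-cascade
bookkeeping test an end-to-end check of alignment + filtering rather than a
tautology. All outputs are pure functions of the spec, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ValidationError
from .feature_tables import (
    CompoundRecord,
    Feature,
    FeatureTable,
    Peak,
    PeakList,
    SampleInfo,
    adduct_mz,
    monoisotopic_mass,
    write_compound_db,
    write_peak_list,
)

#: Default benign/malignant mean-intensity ratios of the 15 informative ions.
DEFAULT_BM_RATIOS = (
    7.002, 4.831, 3.067, 3.125, 0.554, 0.565, 0.573, 0.602,
    0.590, 0.686, 0.612, 0.682, 0.634, 1.731, 5.156,
)

#: Real compounds seeded into every generated compound table.
KNOWN_COMPOUNDS = (
    ("HMDB0038361", "(-)-Epigallocatechin", "C15H14O7"),
    ("HMDB0003840", "Phosphoroselenoic acid", "H3O3PSe"),
    ("SYNF0000001", "synthetic phosphate ester", "C11H3O13P3"),
)

_DETECTION_LIMIT = 100.0  # peaks below this intensity are not detected


class CohortSpec(BaseModel):
    """Everything that defines a synthetic cohort, including the seed."""

    model_config = ConfigDict(extra="forbid")

    n_benign: int = Field(default=56, ge=2)
    n_malignant: int = Field(default=22, ge=2)
    n_blanks: int = Field(default=6, ge=1)
    n_qc: int = Field(default=3, ge=0)
    n_features_pos: int = Field(default=5081, ge=0)
    n_features_neg: int = Field(default=2609, ge=0)
    n_informative: int = Field(default=15, ge=0)
    bm_ratios: list[float] = Field(default_factory=lambda: list(DEFAULT_BM_RATIOS))
    base_log10_intensity_mean: float = 4.8
    base_log10_intensity_sd: float = Field(default=0.6, gt=0)
    biological_cv: float = Field(default=0.35, gt=0)
    blank_contamination_fraction: float = Field(default=0.25, ge=0.0, le=1.0)
    below_intensity_fraction: float = Field(default=0.30, ge=0.0, le=1.0)
    annotatable_fraction: float = Field(default=0.45, ge=0.0, le=1.0)
    mz_jitter_ppm: float = Field(default=3.0, ge=0.0)
    rt_jitter_min: float = Field(default=0.2, ge=0.0)
    rt_min: float = 1.0
    rt_max: float = 24.0
    mass_min: float = 80.0
    mass_max: float = 999.0
    min_mean_intensity: float = Field(default=1e4, gt=0)
    min_blank_ratio: float = Field(default=50.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if len(self.bm_ratios) < self.n_informative:
            raise ValueError(
                "bm_ratios must provide one ratio per informative feature"
            )
        if any(r <= 0 for r in self.bm_ratios):
            raise ValueError("benign/malignant ratios must be positive")
        total = self.n_features_pos + self.n_features_neg
        if self.n_informative > max(1, int(self.annotatable_fraction * total)):
            raise ValueError(
                "n_informative exceeds the annotatable feature budget"
            )
        if self.rt_max <= self.rt_min or self.mass_max <= self.mass_min:
            raise ValueError("empty RT or mass range")
        return self


@dataclass
class ModeGroundTruth:
    """Per-mode planted truth: one row per true ion."""

    table: pd.DataFrame  # columns: mz, rt, mu, informative, ratio,
    #          annotatable, survives_intensity, survives_blank


@dataclass
class GroundTruth:
    """Planted fates and expected cascade counts for a generated cohort."""

    per_mode: dict[str, ModeGroundTruth]
    seed: int

    def _concat(self) -> pd.DataFrame:
        frames = []
        for mode, gt in self.per_mode.items():
            frame = gt.table.copy()
            frame["mode"] = mode
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)

    @property
    def n_features(self) -> int:
        return sum(len(g.table) for g in self.per_mode.values())

    def expected_counts(self) -> dict[str, int]:
        """Expected survivor count after each cascade stage (in order)."""
        t = self._concat()
        annot = t["annotatable"]
        inten = annot & t["survives_intensity"]
        blank = inten & t["survives_blank"]
        return {
            "input": len(t),
            "adduct_annotation": int(annot.sum()),
            "mean_intensity": int(inten.sum()),
            "blank_ratio": int(blank.sum()),
        }

    @property
    def expected_survivors(self) -> int:
        return self.expected_counts()["blank_ratio"]

    def informative_positions(self, mode: str) -> pd.DataFrame:
        t = self.per_mode[mode].table
        return t[t["informative"]]

    def match_informative(
        self, table: FeatureTable, mz_tol_ppm: float = 10.0, rt_tol_min: float = 0.5
    ) -> list[str]:
        """Feature ids in ``table`` that coincide with planted informative ions."""
        hits = []
        for mode, gt in self.per_mode.items():
            inf = gt.table[gt.table["informative"]]
            for _, row in inf.iterrows():
                for feat in table.features:
                    if feat.mode != mode:
                        continue
                    ppm = 1e6 * abs(feat.mz - row.mz) / row.mz
                    if ppm <= mz_tol_ppm and abs(feat.rt - row.rt) <= rt_tol_min:
                        hits.append(feat.feature_id)
                        break
        return hits


# ---------------------------------------------------------------------------
# Compound table
# ---------------------------------------------------------------------------


def generate_compound_db(
    n: int,
    mass_range: tuple[float, float] = (80.0, 999.0),
    seed: int = 0,
    min_spacing_ppm: float = 40.0,
) -> list[CompoundRecord]:
    """Random compound records with mutually spaced monoisotopic masses.

    The first records are real compounds (with formulas); the remainder get
    uniform masses rejected until every pair is separated by at least
    ``min_spacing_ppm``, so a feature planted on one compound cannot
    accidentally annotate to another at the 15 ppm tolerance.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[CompoundRecord] = []
    masses: list[float] = []
    for cid, name, formula in KNOWN_COMPOUNDS[:n]:
        m = monoisotopic_mass(formula)
        records.append(CompoundRecord(cid, name, formula, m))
        masses.append(m)
    lo, hi = mass_range
    attempts = 0
    while len(records) < n:
        m = float(rng.uniform(lo, hi))
        arr = np.asarray(masses)
        if masses and np.min(np.abs(arr - m) / arr) * 1e6 < min_spacing_ppm:
            attempts += 1
            if attempts > 200 * n:
                raise ValidationError(
                    "cannot place compounds with the requested spacing; "
                    "widen the mass range or reduce n"
                )
            continue
        i = len(records)
        records.append(
            CompoundRecord(f"SYN{i:07d}", f"synthetic compound {i}", "", m)
        )
        masses.append(m)
    return records


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _log10_noise_sd(cv: float) -> float:
    """Log10-scale SD of a log-normal with the given coefficient of variation."""
    return float(np.log10(np.e) * np.sqrt(np.log1p(cv**2)))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float,
    size: int,
) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def _allocate_informative(spec: CohortSpec) -> tuple[list[int], list[int]]:
    """Split the informative ratio indices between the two modes.

    Mirrors the reference signature layout: with the default 15-ion vector
    the first and fourteenth ions sit in negative mode, the rest positive.
    """
    k = spec.n_informative
    idx = list(range(k))
    if spec.n_features_neg == 0 or k == 0:
        return idx, []
    if spec.n_features_pos == 0:
        return [], idx
    if k >= 14:
        neg = [0, 13]
    elif k >= 2:
        neg = [0]
    else:
        neg = []
    pos = [i for i in idx if i not in neg]
    return pos, neg


def generate_cohort(
    spec: CohortSpec,
) -> tuple[dict[str, list[PeakList]], list[CompoundRecord], GroundTruth]:
    """Generate per-run peak lists, the compound table and planted truth."""
    rng = np.random.default_rng(spec.seed)
    sigma = _log10_noise_sd(spec.biological_cv)

    n_samples = spec.n_benign + spec.n_malignant
    n_runs = n_samples + spec.n_blanks + spec.n_qc
    run_ids = (
        [f"IB{i + 1:03d}" for i in range(spec.n_benign)]
        + [f"IM{i + 1:03d}" for i in range(spec.n_malignant)]
        + [f"BL{i + 1:02d}" for i in range(spec.n_blanks)]
        + [f"QC{i + 1:02d}" for i in range(spec.n_qc)]
    )
    roles = (
        ["sample"] * n_samples + ["blank"] * spec.n_blanks + ["qc"] * spec.n_qc
    )
    labels = (
        ["benign"] * spec.n_benign
        + ["malignant"] * spec.n_malignant
        + ["none"] * (spec.n_blanks + spec.n_qc)
    )

    inf_pos, inf_neg = _allocate_informative(spec)
    n_annot = {
        "positive": int(round(spec.annotatable_fraction * spec.n_features_pos)),
        "negative": int(round(spec.annotatable_fraction * spec.n_features_neg)),
    }
    n_annot["positive"] = max(n_annot["positive"], len(inf_pos))
    n_annot["negative"] = max(n_annot["negative"], len(inf_neg))
    db_size = max(1, n_annot["positive"] + n_annot["negative"] + 50)
    compounds = generate_compound_db(
        db_size, (spec.mass_min, spec.mass_max), seed=spec.seed
    )
    comp_masses = np.array([c.monoisotopic_mass for c in compounds])
    # hand compounds out without overlap between modes
    comp_cursor = 0

    peak_lists: dict[str, list[PeakList]] = {}
    per_mode_gt: dict[str, ModeGroundTruth] = {}

    for mode, n_feat, inf_idx in (
        ("positive", spec.n_features_pos, inf_pos),
        ("negative", spec.n_features_neg, inf_neg),
    ):
        if n_feat == 0:
            per_mode_gt[mode] = ModeGroundTruth(
                pd.DataFrame(
                    columns=[
                        "mz", "rt", "mu", "informative", "ratio", "annotatable",
                        "survives_intensity", "survives_blank",
                    ]
                )
            )
            peak_lists[mode] = [
                PeakList(run_id=r, role=ro, mode=mode, peaks=[],
                         class_label=lb)  # type: ignore[arg-type]
                for r, ro, lb in zip(run_ids, roles, labels)
            ]
            continue
        k_inf = len(inf_idx)
        if n_feat < k_inf:
            raise ValidationError(
                f"{mode} mode cannot host {k_inf} informative features "
                f"with only {n_feat} features"
            )

        informative = np.zeros(n_feat, dtype=bool)
        informative[:k_inf] = True
        ratios = np.ones(n_feat)
        ratios[:k_inf] = [spec.bm_ratios[i] for i in inf_idx]

        rest = np.arange(k_inf, n_feat)
        perm = rng.permutation(rest)
        n_below = min(int(round(spec.below_intensity_fraction * n_feat)), len(rest))
        below = np.zeros(n_feat, dtype=bool)
        below[perm[:n_below]] = True
        # blank contamination is modeled on intensity-passing decoys only, so
        # the contaminating blank signal always sits above the detection limit
        blank_pool = perm[n_below:]
        n_blankfail = min(
            int(round(spec.blank_contamination_fraction * n_feat)), len(blank_pool)
        )
        blankfail = np.zeros(n_feat, dtype=bool)
        blankfail[blank_pool[:n_blankfail]] = True
        # annotatable decoys are drawn across all fate groups, so the
        # intensity and blank stages each remove part of the annotated set
        annotatable = np.zeros(n_feat, dtype=bool)
        annotatable[:k_inf] = True
        n_extra_annot = min(max(0, n_annot[mode] - k_inf), len(rest))
        if n_extra_annot:
            extra = rng.choice(rest, size=n_extra_annot, replace=False)
            annotatable[extra] = True

        # base intensity level: safe zones guarantee the planted fates
        mu = np.empty(n_feat)
        lo_mean = spec.base_log10_intensity_mean
        lo_sd = spec.base_log10_intensity_sd
        pass_rows = ~below
        # zones leave margin around the 1e4 threshold (and keep even the
        # weakest ions above the detection limit in every sample run)
        mu[pass_rows] = _truncated_normal(
            rng, lo_mean, lo_sd, 4.35, 8.0, int(pass_rows.sum())
        )
        mu[below] = _truncated_normal(
            rng, lo_mean, lo_sd, 2.7, 3.45, int(below.sum())
        )

        # ion positions: annotatable ions sit on compound adduct masses
        mz = np.empty(n_feat)
        rt = rng.uniform(spec.rt_min, spec.rt_max, size=n_feat)
        annot_rows = np.flatnonzero(annotatable)
        needed = len(annot_rows)
        chosen = np.arange(comp_cursor, comp_cursor + needed)
        if chosen.size and chosen[-1] >= len(compounds):
            raise ValidationError("compound table exhausted; internal sizing bug")
        comp_cursor += needed
        for row, ci in zip(annot_rows, chosen):
            mz[row] = adduct_mz(compounds[ci].monoisotopic_mass, mode)  # type: ignore[arg-type]
        # unannotatable ions: keep >=25 ppm away from every adduct mass
        adduct_masses = np.sort(
            np.array([adduct_mz(m, mode) for m in comp_masses])  # type: ignore[arg-type]
        )
        unannot_rows = np.flatnonzero(~annotatable)
        mz_lo = max(spec.mass_min + 2.1, 67.0)
        for row in unannot_rows:
            while True:
                cand = float(rng.uniform(mz_lo, spec.mass_max))
                j = np.searchsorted(adduct_masses, cand)
                near = adduct_masses[max(0, j - 1):j + 1]
                if near.size and np.min(np.abs(near - cand) / near) * 1e6 < 25.0:
                    continue
                mz[row] = cand
                break
        # enforce alignability: any two same-mode ions closer than 30 ppm in
        # m/z must be at least 2 min apart in RT, so jittered peaks of
        # distinct ions can never fall within the 10 ppm / 1 min join window
        order = np.argsort(mz)
        mz_sorted = mz[order]
        for rank in range(1, order.size):
            b = order[rank]
            lo_rank = np.searchsorted(mz_sorted, mz_sorted[rank] / (1 + 30e-6))
            neighbors = order[lo_rank:rank]
            while neighbors.size and np.any(np.abs(rt[neighbors] - rt[b]) < 2.0):
                rt[b] = float(rng.uniform(spec.rt_min, spec.rt_max))

        # intensity matrix (features x runs)
        delta = np.zeros((n_feat, n_runs))
        half = 0.5 * np.log10(ratios)
        delta[:, :spec.n_benign] = half[:, None]
        delta[:, spec.n_benign:n_samples] = -half[:, None]
        eps = rng.normal(0.0, sigma, size=(n_feat, n_runs))
        matrix = 10.0 ** (mu[:, None] + delta + eps)
        # blanks: contamination for the blank-failing subset, silence elsewhere
        blank_cols = slice(n_samples, n_samples + spec.n_blanks)
        matrix[:, blank_cols] = 0.0
        if spec.n_blanks:
            fail_rows = np.flatnonzero(blankfail)
            if fail_rows.size:
                target = rng.uniform(2.0, 20.0, size=fail_rows.size)
                level = 10.0 ** mu[fail_rows] / target
                noise = 10.0 ** rng.normal(
                    0.0, 0.1, size=(fail_rows.size, spec.n_blanks)
                )
                matrix[fail_rows, blank_cols] = level[:, None] * noise
        matrix[matrix < _DETECTION_LIMIT] = 0.0

        # verify the planted fates against the realized matrix
        smean = matrix[:, :n_samples].mean(axis=1)
        bmat = matrix[:, blank_cols]
        bmean = bmat.mean(axis=1) if spec.n_blanks else np.zeros(n_feat)
        ok_int = smean >= spec.min_mean_intensity
        ok_blank = (bmean <= 0) | (
            smean / np.where(bmean <= 0, 1.0, bmean) >= spec.min_blank_ratio
        )
        if not np.array_equal(ok_int, ~below) or not np.array_equal(
            ok_blank, ~blankfail
        ):
            raise ValidationError(
                "generator self-check failed: realized intensities contradict "
                "the planted fates (adjust spec margins)"
            )

        per_mode_gt[mode] = ModeGroundTruth(
            pd.DataFrame(
                {
                    "mz": mz,
                    "rt": rt,
                    "mu": mu,
                    "informative": informative,
                    "ratio": ratios,
                    "annotatable": annotatable,
                    "survives_intensity": ~below,
                    "survives_blank": ~blankfail,
                }
            )
        )

        # per-run peak lists with jitter
        lists: list[PeakList] = []
        for c, (run_id, role, label) in enumerate(zip(run_ids, roles, labels)):
            detected = np.flatnonzero(matrix[:, c] >= _DETECTION_LIMIT)
            jit_mz = mz[detected] * (
                1.0
                + rng.uniform(-spec.mz_jitter_ppm, spec.mz_jitter_ppm,
                              size=detected.size) * 1e-6
            )
            jit_rt = np.clip(
                rt[detected]
                + rng.uniform(-spec.rt_jitter_min, spec.rt_jitter_min,
                              size=detected.size),
                0.0,
                None,
            )
            peaks = [
                Peak(float(m), float(t), float(v))
                for m, t, v in zip(jit_mz, jit_rt, matrix[detected, c])
            ]
            lists.append(
                PeakList(run_id=run_id, role=role, mode=mode,  # type: ignore[arg-type]
                         peaks=peaks, class_label=label)  # type: ignore[arg-type]
            )
        peak_lists[mode] = lists

    truth = GroundTruth(per_mode=per_mode_gt, seed=spec.seed)
    return peak_lists, compounds, truth


def cohort_feature_table(spec: CohortSpec) -> tuple[FeatureTable, GroundTruth]:
    """Directly build the merged, cascade-surviving feature table.

    Equivalent to generate -> align -> annotate -> filter but without the
    peak-list round trip: intended for model-level studies where only the
    surviving ions matter. The returned table contains exactly the planted
    survivors, with exact (unjittered) ion positions and intensities.
    """
    peak_lists, _, truth = generate_cohort(spec)
    tables = []
    for mode in ("positive", "negative"):
        gt = truth.per_mode[mode].table
        keep = gt["annotatable"] & gt["survives_intensity"] & gt["survives_blank"]
        rows = np.flatnonzero(keep.to_numpy())
        if rows.size == 0:
            continue
        lists = peak_lists[mode]
        n_runs = len(lists)
        # reconstruct the exact matrix from the (unjittered) ground truth
        matrix = _matrix_from_peaklists(gt, lists, rows)
        features = [
            Feature(
                f"{mode[:3]}_T{r + 1:05d}",
                mode,  # type: ignore[arg-type]
                float(gt.iloc[r]["mz"]),
                float(gt.iloc[r]["rt"]),
            )
            for r in rows
        ]
        samples = [SampleInfo(pl.run_id, pl.role, pl.class_label) for pl in lists]
        tables.append(FeatureTable(features, samples, matrix))
    if not tables:
        raise ValidationError("no surviving features; spec too aggressive")
    merged = tables[0]
    for extra in tables[1:]:
        merged = FeatureTable(
            merged.features + extra.features,
            merged.samples,
            np.vstack([merged.intensities, extra.intensities]),
        )
    return merged, truth


def _matrix_from_peaklists(
    gt: pd.DataFrame, lists: Sequence[PeakList], rows: np.ndarray
) -> np.ndarray:
    """Exact intensities of selected true ions, matched by m/z and RT."""
    true_mz = gt["mz"].to_numpy()[rows]
    true_rt = gt["rt"].to_numpy()[rows]
    order = np.argsort(true_mz)
    sorted_mz = true_mz[order]
    sorted_rt = true_rt[order]
    matrix = np.zeros((rows.size, len(lists)))
    for c, pl in enumerate(lists):
        for peak in pl.peaks:
            j = np.searchsorted(sorted_mz, peak.mz)
            best, best_cost = -1, np.inf
            for cand in range(max(0, j - 2), min(sorted_mz.size, j + 2)):
                ppm = 1e6 * abs(peak.mz - sorted_mz[cand]) / sorted_mz[cand]
                drt = abs(peak.rt - sorted_rt[cand])
                if ppm <= 10.0 and drt <= 1.0:
                    cost = ppm / 10.0 + drt
                    if cost < best_cost:
                        best, best_cost = cand, cost
            if best >= 0:
                matrix[order[best], c] += peak.intensity
    return matrix


# ---------------------------------------------------------------------------
# Frozen miniature cohort
# ---------------------------------------------------------------------------

PAPER_FIXTURE_SEED = 7823


def paper_fixture_spec() -> CohortSpec:
    """Spec of the seed-locked miniature cohort used in tests and docs."""
    return CohortSpec(
        n_features_pos=500,
        n_features_neg=200,
        seed=PAPER_FIXTURE_SEED,
    )


def paper_fixture() -> tuple[dict[str, list[PeakList]], list[CompoundRecord], GroundTruth]:
    """Seed-locked miniature cohort: 78 samples, 500+200 ions, 15 informative."""
    return generate_cohort(paper_fixture_spec())


def write_cohort(
    peak_lists: dict[str, list[PeakList]],
    compounds: Sequence[CompoundRecord],
    out_dir: str | Path,
) -> dict[str, list[str]]:
    """Write peak-list CSVs, the compound TSV and run metadata JSON."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[str]] = {"peak_lists": [], "other": []}
    runs_meta = []
    for mode, lists in peak_lists.items():
        for pl in lists:
            name = f"{pl.run_id}_{mode}.csv"
            write_peak_list(pl, out_dir / name)
            written["peak_lists"].append(name)
            runs_meta.append(
                {
                    "file": name,
                    "run_id": pl.run_id,
                    "role": pl.role,
                    "mode": mode,
                    "class_label": pl.class_label,
                }
            )
    write_compound_db(compounds, out_dir / "compounds.tsv")
    (out_dir / "runs.json").write_text(json.dumps({"runs": runs_meta}, indent=1))
    written["other"] = ["compounds.tsv", "runs.json"]
    return written


def read_cohort(in_dir: str | Path) -> tuple[dict[str, list[PeakList]], list[CompoundRecord]]:
    """Read a cohort directory written by :func:`write_cohort`."""
    import json

    from .feature_tables import read_compound_db, read_peak_list

    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "runs.json").read_text())
    peak_lists: dict[str, list[PeakList]] = {"positive": [], "negative": []}
    for run in meta["runs"]:
        pl = read_peak_list(
            in_dir / run["file"],
            run_id=run["run_id"],
            role=run["role"],
            mode=run["mode"],
            class_label=run.get("class_label", "none"),
        )
        peak_lists[run["mode"]].append(pl)
    compounds = read_compound_db(in_dir / "compounds.tsv")
    return peak_lists, compounds
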