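"""Peak-list I/O, cross-run alignment, adduct mass arithmetic and annotation.

The pipeline starts from per-run peak lists (one CSV per LC-MS injection,
columns ``mz``, ``rt_min``, ``intensity``) that an upstream peak picker has
already produced. This module turns a set of same-mode peak lists into a
features x samples intensity matrix (:class:`FeatureTable`), computes neutral
monoisotopic masses for [M+H]+ / [M-H]- adducts, and matches features against
a compound database within a ppm tolerance.

Conventions
-----------
* m/z in thomson, retention time in minutes, intensities in arbitrary
  peak-area units; an intensity of 0 means "not detected in that run".
* Only proton adducts are considered: [M+H]+ in positive mode and [M-H]- in
  negative mode. The electron mass is neglected (its effect is far below the
  15 ppm annotation tolerance at these masses).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _ptm_mass
from pyteomics.auxiliary import PyteomicsError

from .errors import DomainError, FormatError, ValidationError

#: CODATA proton mass in Da, used for [M+H]+ / [M-H]- arithmetic.
PROTON_MASS = 1.00727646

Role = Literal["sample", "blank", "qc"]
Mode = Literal["positive", "negative"]
ClassLabel = Literal["benign", "malignant", "none"]

_ROLES = ("sample", "blank", "qc")
_MODES = ("positive", "negative")
_LABELS = ("benign", "malignant", "none")


@dataclass(frozen=True)
class Peak:
    """A single detected chromatographic peak."""

    mz: float
    rt: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValidationError(f"peak m/z must be positive, got {self.mz}")
        if self.rt < 0:
            raise ValidationError(f"peak RT must be nonnegative, got {self.rt}")
        if self.intensity < 0:
            raise ValidationError(
                f"peak intensity must be nonnegative, got {self.intensity}"
            )


@dataclass
class PeakList:
    """All peaks detected in one LC-MS run, plus run metadata."""

    run_id: str
    role: Role
    mode: Mode
    peaks: list[Peak] = field(default_factory=list)
    class_label: ClassLabel = "none"

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        if self.mode not in _MODES:
            raise ValidationError(f"unknown ion mode {self.mode!r}")
        if self.class_label not in _LABELS:
            raise ValidationError(f"unknown class label {self.class_label!r}")
        if self.role in ("blank", "qc") and self.class_label != "none":
            raise ValidationError(
                f"run {self.run_id!r}: role {self.role!r} requires class_label='none'"
            )

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class SampleInfo:
    """Per-run metadata carried along a feature table column."""

    run_id: str
    role: Role
    class_label: ClassLabel = "none"


@dataclass
class Feature:
    """An aligned ion: consensus m/z and RT over its member peaks."""

    feature_id: str
    mode: Mode
    mz: float
    rt: float
    evidence_flag: bool = True


@dataclass
class FeatureTable:
    """Aligned ions x runs intensity matrix with metadata on both axes.

    ``intensities`` has shape ``(n_features, n_samples)``; zeros mark
    non-detections. Sample (column) order is stable under feature filtering.
    """

    features: list[Feature]
    samples: list[SampleInfo]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.features), len(self.samples)):
            raise ValidationError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if self.intensities.size and self.intensities.min() < 0:
            raise ValidationError("intensity matrix contains negative entries")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def role_mask(self, role: Role) -> np.ndarray:
        return np.array([s.role == role for s in self.samples], dtype=bool)

    def class_labels(self, role: Role = "sample") -> np.ndarray:
        return np.array(
            [s.class_label for s in self.samples if s.role == role], dtype=object
        )

    def sample_matrix(self) -> np.ndarray:
        """Intensities restricted to role='sample' columns (features x samples)."""
        return self.intensities[:, self.role_mask("sample")]

    def select_features(self, index: Sequence[int] | np.ndarray) -> "FeatureTable":
        index = np.asarray(index, dtype=int)
        return FeatureTable(
            features=[self.features[i] for i in index],
            samples=list(self.samples),
            intensities=self.intensities[index, :],
        )

    def select_by_ids(self, feature_ids: Iterable[str]) -> "FeatureTable":
        pos = {f.feature_id: i for i, f in enumerate(self.features)}
        try:
            index = [pos[fid] for fid in feature_ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValidationError(f"unknown feature id {exc.args[0]!r}") from exc
        return self.select_features(index)

    # -- serialization ---------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "feature_id": [f.feature_id for f in self.features],
                "mode": [f.mode for f in self.features],
                "mz": [f.mz for f in self.features],
                "rt_min": [f.rt for f in self.features],
                "evidence_flag": [f.evidence_flag for f in self.features],
            }
        )
        inten = pd.DataFrame(
            self.intensities, columns=[s.run_id for s in self.samples]
        )
        return pd.concat([meta, inten], axis=1)

    def write_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write the wide CSV plus a JSON sidecar with sample metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".samples.json")
        payload = {
            "samples": [
                {"run_id": s.run_id, "role": s.role, "class_label": s.class_label}
                for s in self.samples
            ]
        }
        sidecar.write_text(json.dumps(payload, indent=1) + "\n")


def read_feature_table(
    path: str | Path, sidecar: str | Path | None = None
) -> FeatureTable:
    """Read a wide feature-table CSV written by :meth:`FeatureTable.write_csv`."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".samples.json")
    frame = pd.read_csv(path)
    meta_cols = ["feature_id", "mode", "mz", "rt_min", "evidence_flag"]
    for col in meta_cols:
        if col not in frame.columns:
            raise FormatError(f"feature table is missing column {col!r}")
    try:
        samples_meta = json.loads(Path(sidecar).read_text())["samples"]
    except (OSError, KeyError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read sample sidecar {sidecar}: {exc}") from exc
    samples = [
        SampleInfo(m["run_id"], m["role"], m.get("class_label", "none"))
        for m in samples_meta
    ]
    run_ids = [s.run_id for s in samples]
    missing = [r for r in run_ids if r not in frame.columns]
    if missing:
        raise FormatError(f"feature table is missing run columns {missing}")
    features = [
        Feature(str(r.feature_id), r.mode, float(r.mz), float(r.rt_min), bool(r.evidence_flag))
        for r in frame[meta_cols].itertuples(index=False)
    ]
    return FeatureTable(features, samples, frame[run_ids].to_numpy(dtype=float))


@dataclass(frozen=True)
class CompoundRecord:
    """A compound-database entry with an HMDB-style identifier."""

    compound_id: str
    name: str
    formula: str
    monoisotopic_mass: float

    def __post_init__(self) -> None:
        if not self.monoisotopic_mass > 0:
            raise ValidationError(
                f"compound {self.compound_id}: monoisotopic mass must be positive"
            )
        if self.formula:
            derived = monoisotopic_mass(self.formula)
            if abs(derived - self.monoisotopic_mass) > 1e-4:
                raise ValidationError(
                    f"compound {self.compound_id}: declared mass "
                    f"{self.monoisotopic_mass} Da disagrees with formula "
                    f"{self.formula} ({derived:.6f} Da)"
                )


@dataclass(frozen=True)
class IonAnnotation:
    """A putative (feature, compound) match under a proton adduct."""

    feature_id: str
    compound_id: str
    adduct: str
    neutral_mass_obs: float
    ppm_error: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_PEAK_COLUMNS = ("mz", "rt_min", "intensity")


def read_peak_list(
    path: str | Path,
    run_id: str,
    role: Role,
    mode: Mode,
    class_label: ClassLabel = "none",
) -> PeakList:
    """Read one per-run peak list CSV (columns mz, rt_min, intensity)."""
    frame = pd.read_csv(path)
    for col in _PEAK_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    peaks: list[Peak] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        if row.intensity < 0:
            raise ValidationError(
                f"{path}: negative intensity {row.intensity} at data row {i}"
            )
        peaks.append(Peak(float(row.mz), float(row.rt_min), float(row.intensity)))
    return PeakList(run_id=run_id, role=role, mode=mode, peaks=peaks,
                    class_label=class_label)


def write_peak_list(peak_list: PeakList, path: str | Path) -> None:
    pd.DataFrame(
        {
            "mz": [p.mz for p in peak_list.peaks],
            "rt_min": [p.rt for p in peak_list.peaks],
            "intensity": [p.intensity for p in peak_list.peaks],
        }
    ).to_csv(path, index=False)


def read_compound_db(path: str | Path) -> list[CompoundRecord]:
    """Read a compound TSV: compound_id, name, formula, monoisotopic_mass.

    The mass column may be empty when a formula is given; it is then derived
    from the formula.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"formula": str})
    for col in ("compound_id", "name", "formula", "monoisotopic_mass"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records: list[CompoundRecord] = []
    for row in frame.itertuples(index=False):
        formula = "" if pd.isna(row.formula) else str(row.formula)
        if pd.isna(row.monoisotopic_mass):
            if not formula:
                raise FormatError(
                    f"{path}: compound {row.compound_id} has neither formula nor mass"
                )
            mono = monoisotopic_mass(formula)
        else:
            mono = float(row.monoisotopic_mass)
        records.append(CompoundRecord(str(row.compound_id), str(row.name), formula, mono))
    return records


def write_compound_db(records: Sequence[CompoundRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "name": [r.name for r in records],
            "formula": [r.formula for r in records],
            "monoisotopic_mass": [r.monoisotopic_mass for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Mass arithmetic
# ---------------------------------------------------------------------------


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of a molecular formula such as ``C15H14O7``."""
    if not formula or not formula.strip():
        raise FormatError("empty molecular formula")
    try:
        return float(_ptm_mass.calculate_mass(formula=formula.strip()))
    except PyteomicsError as exc:
        raise FormatError(f"cannot parse molecular formula {formula!r}: {exc}") from exc


def neutral_mass_from_mz(mz: float, mode: Mode) -> float:
    """Neutral monoisotopic mass implied by an m/z under the proton adduct."""
    if mode == "positive":
        neutral = mz - PROTON_MASS
    elif mode == "negative":
        neutral = mz + PROTON_MASS
    else:
        raise ValidationError(f"unknown ion mode {mode!r}")
    if neutral <= 0:
        raise DomainError(
            f"m/z {mz} in {mode} mode implies nonpositive neutral mass {neutral}"
        )
    return neutral


def adduct_mz(neutral_mass: float, mode: Mode) -> float:
    """Inverse of :func:`neutral_mass_from_mz`."""
    if mode == "positive":
        return neutral_mass + PROTON_MASS
    if mode == "negative":
        return neutral_mass - PROTON_MASS
    raise ValidationError(f"unknown ion mode {mode!r}")


def annotate(
    features: Sequence[Feature],
    compounds: Sequence[CompoundRecord],
    tol_ppm: float = 15.0,
) -> list[IonAnnotation]:
    """Match each feature's neutral mass against the compound database.

    Returns every (feature, compound) pair within ``tol_ppm``; a feature may
    receive zero or several annotations. Annotations are ordered by feature,
    then by increasing absolute ppm error.
    """
    if tol_ppm <= 0:
        raise ValidationError("tol_ppm must be positive")
    masses = np.array([c.monoisotopic_mass for c in compounds], dtype=float)
    order = np.argsort(masses)
    sorted_masses = masses[order]
    out: list[IonAnnotation] = []
    for feat in features:
        neutral = neutral_mass_from_mz(feat.mz, feat.mode)
        lo = neutral / (1 + tol_ppm * 1e-6)
        hi = neutral / (1 - tol_ppm * 1e-6)
        i0, i1 = np.searchsorted(sorted_masses, [lo, hi])
        hits = []
        for j in order[i0:i1]:
            ref = masses[j]
            ppm = 1e6 * (neutral - ref) / ref
            if abs(ppm) <= tol_ppm:
                hits.append((abs(ppm), ppm, compounds[j]))
        hits.sort(key=lambda h: h[0])
        adduct = "[M+H]+" if feat.mode == "positive" else "[M-H]-"
        out.extend(
            IonAnnotation(feat.feature_id, comp.compound_id, adduct, neutral, ppm)
            for _, ppm, comp in hits
        )
    return out


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def _ppm_distance(mz_a: np.ndarray, mz_b: float) -> np.ndarray:
    return 1e6 * np.abs(mz_a - mz_b) / np.maximum(mz_a, 1e-12)


def join_align(
    peak_lists: Sequence[PeakList],
    mz_tol_ppm: float = 10.0,
    rt_tol_min: float = 1.0,
    id_prefix: str = "F",
) -> FeatureTable:
    """Greedy cross-run join alignment of same-mode peak lists.

    Runs are processed in lexicographic ``run_id`` order. Within a run every
    peak is matched against the features existing before the run, using the
    combined distance ``ppm/mz_tol_ppm + |dRT|/rt_tol_min`` subject to both
    tolerances; assignments are resolved best-score-first so a run contributes
    at most one peak per feature, and unmatched peaks found new features.
    Consensus m/z and RT are intensity-weighted means over member peaks,
    updated after every run.
    """
    if not peak_lists:
        raise ValidationError("join_align requires at least one peak list")
    modes = {pl.mode for pl in peak_lists}
    if len(modes) > 1:
        raise ValidationError(f"cannot align mixed ion modes: {sorted(modes)}")
    mode = peak_lists[0].mode
    run_ids = [pl.run_id for pl in peak_lists]
    if len(set(run_ids)) != len(run_ids):
        raise ValidationError("duplicate run_id among peak lists")
    ordered = sorted(peak_lists, key=lambda pl: pl.run_id)

    feat_mz: list[float] = []       # consensus m/z
    feat_rt: list[float] = []
    members: list[list[Peak]] = []  # member peaks per feature
    columns: list[dict[int, float]] = []  # per-run {feature index: intensity}

    for pl in ordered:
        n_existing = len(feat_mz)
        mz_arr = np.array(feat_mz[:n_existing], dtype=float)
        rt_arr = np.array(feat_rt[:n_existing], dtype=float)
        candidates: list[tuple[float, int, int]] = []  # (score, peak idx, feat idx)
        if n_existing:
            for i, peak in enumerate(pl.peaks):
                ppm = _ppm_distance(mz_arr, peak.mz)
                drt = np.abs(rt_arr - peak.rt)
                ok = (ppm <= mz_tol_ppm) & (drt <= rt_tol_min)
                for j in np.flatnonzero(ok):
                    score = ppm[j] / mz_tol_ppm + drt[j] / rt_tol_min
                    candidates.append((score, i, int(j)))
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        assigned_peak: dict[int, int] = {}
        taken_feature: set[int] = set()
        for score, i, j in candidates:
            if i in assigned_peak or j in taken_feature:
                continue
            assigned_peak[i] = j
            taken_feature.add(j)
        col: dict[int, float] = {}
        for i, peak in enumerate(pl.peaks):
            if i in assigned_peak:
                j = assigned_peak[i]
            else:
                j = len(feat_mz)
                feat_mz.append(peak.mz)
                feat_rt.append(peak.rt)
                members.append([])
            members[j].append(peak)
            col[j] = col.get(j, 0.0) + peak.intensity
        columns.append(col)
        # refresh consensus after the run
        for j in set(assigned_peak.values()):
            w = np.array([p.intensity for p in members[j]])
            mzs = np.array([p.mz for p in members[j]])
            rts = np.array([p.rt for p in members[j]])
            if w.sum() > 0:
                feat_mz[j] = float(np.average(mzs, weights=w))
                feat_rt[j] = float(np.average(rts, weights=w))
            else:
                feat_mz[j] = float(mzs.mean())
                feat_rt[j] = float(rts.mean())

    n_feat = len(feat_mz)
    width = max(5, len(str(n_feat)))
    features = [
        Feature(f"{id_prefix}{i + 1:0{width}d}", mode, feat_mz[i], feat_rt[i])
        for i in range(n_feat)
    ]
    samples = [SampleInfo(pl.run_id, pl.role, pl.class_label) for pl in ordered]
    intensities = np.zeros((n_feat, len(ordered)))
    for c, col in enumerate(columns):
        for j, val in col.items():
            intensities[j, c] = val
    return FeatureTable(features, samples, intensities)


def merge_modes(pos: FeatureTable, neg: FeatureTable) -> FeatureTable:
    """Concatenate positive- and negative-mode tables over the same runs."""
    pos_ids = [s.run_id for s in pos.samples]
    neg_ids = [s.run_id for s in neg.samples]
    if set(pos_ids) != set(neg_ids):
        diff = sorted(set(pos_ids) ^ set(neg_ids))
        raise ValidationError(f"sample sets differ between modes: {diff}")
    neg_order = [neg_ids.index(r) for r in pos_ids]

    def prefixed(table: FeatureTable, tag: str) -> list[Feature]:
        return [replace(f, feature_id=f"{tag}_{f.feature_id}") for f in table.features]

    features = prefixed(pos, "pos") + prefixed(neg, "neg")
    intensities = np.vstack(
        [pos.intensities, neg.intensities[:, neg_order]]
        if neg.n_features
        else [pos.intensities, np.zeros((0, pos.n_samples))]
    )
    return FeatureTable(features, list(pos.samples), intensities)
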