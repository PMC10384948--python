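"""Repeated stratified holdout evaluation and the model-comparison harness.

"Cross-validation" here means repeated stratified Monte-Carlo splitting:
every repeat draws a random test set of ``round(test_fraction * n)`` samples
with class proportions preserved to within one sample. This matches per-fold
test sizes of 19-20 for a 56/22 cohort at test_fraction 0.25 and is the
appropriate reading of per-fold accuracies such as 16/19 and 19/20; twelve
disjoint folds of such a cohort could not produce them.

Metrics per split: global accuracy, per-class accuracy (= class recall),
AUROC as the Mann-Whitney concordance of the malignant score (ties count
0.5), and macro-averaged precision/recall/F1. Aggregation reports the mean
and sample (n-1) standard deviation over splits.

The comparison harness fits several classifiers on identical splits of the
same raw signature matrix. By default the signature is selected once, before
splitting, as the original study did; an honest mode re-selects the signature
inside every training split and documents the selection optimism of the
frozen mode.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support
from sklearn.svm import SVC

from .chemometrics import (
    BENIGN,
    MALIGNANT,
    Normalizer,
    encode_labels,
    fit_plsda,
)
from .errors import ValidationError

METRIC_NAMES = (
    "accuracy_global",
    "accuracy_benign",
    "accuracy_malignant",
    "auc",
    "precision",
    "recall",
    "f1",
)


# ---------------------------------------------------------------------------
# Split construction
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    n_repeats: int
    test_fraction: float
    stratified: bool
    seed: int
    splits: list[tuple[np.ndarray, np.ndarray]]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_repeats": self.n_repeats,
            "test_fraction": self.test_fraction,
            "stratified": self.stratified,
            "seed": self.seed,
            "splits": [
                {"train": tr.tolist(), "test": te.tolist()}
                for tr, te in self.splits
            ],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def make_splits(
    y: Sequence[str] | np.ndarray,
    n_repeats: int = 12,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> SplitPlan:
    """Stratified Monte-Carlo splits, deterministic given the seed."""
    y = np.asarray(y)
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError("test_fraction must be in (0, 1)")
    if n_repeats < 1:
        raise ValidationError("n_repeats must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        raise ValidationError("every class needs at least 2 samples")
    test_per_class = {}
    for cls, cnt in zip(classes, counts):
        t = int(np.floor(test_fraction * cnt + 0.5))  # round half up
        if t < 1 or t >= cnt:
            raise ValidationError(
                f"test_fraction={test_fraction} leaves class {cls!r} empty "
                "in train or test"
            )
        test_per_class[cls] = t
    rng = np.random.default_rng(seed)
    splits = []
    all_idx = np.arange(len(y))
    for _ in range(n_repeats):
        test_parts = []
        for cls in classes:
            members = all_idx[y == cls]
            chosen = rng.choice(members, size=test_per_class[cls], replace=False)
            test_parts.append(chosen)
        test = np.sort(np.concatenate(test_parts))
        train = np.setdiff1d(all_idx, test)
        splits.append((train, test))
    return SplitPlan(n_repeats, test_fraction, True, seed, splits)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class FoldMetrics:
    accuracy_global: float | None = None
    accuracy_benign: float | None = None
    accuracy_malignant: float | None = None
    auc: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def concordance_auc(y_true_pos: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUROC with ties counted as 0.5 concordance."""
    y_true_pos = np.asarray(y_true_pos, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true_pos.sum())
    n_neg = int((~y_true_pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC requires both classes in y_true")
    ranks = rankdata(scores)  # average ranks handle ties
    rank_sum = float(ranks[y_true_pos].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def compute_metrics(
    y_true: Sequence[str] | np.ndarray,
    y_pred: Sequence[str] | np.ndarray,
    scores: np.ndarray | None = None,
) -> FoldMetrics:
    """Per-split metrics; ``scores`` rank samples toward the malignant class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValidationError("y_true and y_pred differ in length")
    _, (neg, pos) = encode_labels(y_true)
    acc = float(np.mean(y_true == y_pred))
    acc_by = {}
    for cls in (neg, pos):
        mask = y_true == cls
        acc_by[cls] = float(np.mean(y_pred[mask] == cls))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=[neg, pos], average="macro", zero_division=0
    )
    auc = None
    if scores is not None:
        auc = concordance_auc(y_true == pos, np.asarray(scores, dtype=float))
    benign_key = neg if neg == BENIGN else neg
    return FoldMetrics(
        accuracy_global=acc,
        accuracy_benign=acc_by[benign_key],
        accuracy_malignant=acc_by[pos],
        auc=auc,
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
    )


@dataclass
class AggregateMetrics:
    """Mean, sample SD and range per metric over splits."""

    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    min: dict[str, float] = field(default_factory=dict)
    max: dict[str, float] = field(default_factory=dict)
    n_folds: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.mean)
        return pd.DataFrame(
            {
                "mean": [self.mean[m] for m in rows],
                "sd": [self.sd[m] for m in rows],
                "min": [self.min[m] for m in rows],
                "max": [self.max[m] for m in rows],
            },
            index=pd.Index(rows, name="metric"),
        )


def aggregate(folds: Sequence[FoldMetrics]) -> AggregateMetrics:
    """Arithmetic mean and sample (n-1) SD per metric; None values skipped."""
    if len(folds) < 2:
        raise ValidationError("aggregate requires at least 2 folds")
    out = AggregateMetrics(n_folds=len(folds))
    for name in METRIC_NAMES:
        vals = np.array(
            [getattr(f, name) for f in folds if getattr(f, name) is not None],
            dtype=float,
        )
        if vals.size == 0:
            continue
        out.mean[name] = float(vals.mean())
        out.sd[name] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out.min[name] = float(vals.min())
        out.max[name] = float(vals.max())
    return out


# ---------------------------------------------------------------------------
# Comparison harness
# ---------------------------------------------------------------------------


class PLSDAClassifier:
    """PLS-DA under the uniform train/predict contract (raw intensities in)."""

    def __init__(self, n_components: int = 2):
        self.n_components = n_components
        self._norm: Normalizer | None = None
        self._model = None

    def fit(self, raw_train, y_train):
        self._norm = Normalizer().fit(raw_train)
        a = min(self.n_components, raw_train.shape[1], len(y_train) - 1)
        self._model = fit_plsda(self._norm.transform(raw_train), y_train, a)
        return self

    def predict(self, raw):
        X = self._norm.transform(raw)
        return self._model.predict(X), self._model.decision_function(X)


class SklearnClassifier:
    """Adapter giving sklearn estimators the uniform contract."""

    def __init__(self, factory: Callable[[], object]):
        self.factory = factory
        self._norm: Normalizer | None = None
        self._est = None
        self._pos: str | None = None

    def fit(self, raw_train, y_train):
        self._norm = Normalizer().fit(raw_train)
        self._est = self.factory()
        self._est.fit(self._norm.transform(raw_train), y_train)
        _, (_, pos) = encode_labels(y_train)
        self._pos = pos
        return self

    def predict(self, raw):
        X = self._norm.transform(raw)
        labels = self._est.predict(X)
        if hasattr(self._est, "predict_proba"):
            classes = list(self._est.classes_)
            scores = self._est.predict_proba(X)[:, classes.index(self._pos)]
        else:
            scores = self._est.decision_function(X)
            if list(self._est.classes_)[1] != self._pos:
                scores = -scores
        return labels, scores


def default_registry(seed: int = 0, sae_config=None) -> dict[str, Callable[[], object]]:
    """Factories for the four standard classifiers, one fresh model per fold."""
    from .sae import SAEClassifier, SAEConfig

    cfg = sae_config or SAEConfig(seed=seed)
    return {
        "SAE": lambda: SAEClassifier(cfg),
        "PLS-DA": lambda: PLSDAClassifier(n_components=2),
        "SVM": lambda: SklearnClassifier(
            lambda: SVC(kernel="linear", C=1.0, random_state=seed)
        ),
        "RF": lambda: SklearnClassifier(
            lambda: RandomForestClassifier(n_estimators=500, random_state=seed)
        ),
    }


@dataclass
class ComparisonTable:
    """Per-method aggregates over a shared split plan."""

    aggregates: dict[str, AggregateMetrics]
    folds: dict[str, list[FoldMetrics]]
    plan: SplitPlan

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method, agg in self.aggregates.items():
            for metric in METRIC_NAMES:
                if metric in agg.mean:
                    rows.append(
                        {
                            "method": method,
                            "metric": metric,
                            "mean": agg.mean[metric],
                            "sd": agg.sd[metric],
                        }
                    )
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def compare_models(
    raw: np.ndarray,
    y: Sequence[str] | np.ndarray,
    plan: SplitPlan,
    registry: Mapping[str, Callable[[], object]] | None = None,
    selector: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> ComparisonTable:
    """Fit every registered method on identical splits of the raw matrix.

    ``raw`` is (n_samples, n_features): by default the frozen signature
    matrix. When ``selector`` is given (honest mode), it receives each
    training partition and returns the column indices to use for that split,
    so signature selection optimism is excluded.
    """
    raw = np.asarray(raw, dtype=float)
    y = np.asarray(y)
    if registry is None:
        registry = default_registry(seed=plan.seed)
    folds: dict[str, list[FoldMetrics]] = {m: [] for m in registry}
    for split_idx, (train, test) in enumerate(plan.splits):
        cols = np.arange(raw.shape[1])
        if selector is not None:
            cols = np.asarray(selector(raw[train], y[train]), dtype=int)
        for method, factory in registry.items():
            try:
                clf = factory().fit(raw[np.ix_(train, cols)], y[train])
                labels, scores = clf.predict(raw[np.ix_(test, cols)])
                folds[method].append(compute_metrics(y[test], labels, scores))
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                warnings.warn(
                    f"{method} failed on split {split_idx}: {exc}", stacklevel=2
                )
    aggregates = {
        m: aggregate(f) for m, f in folds.items() if len(f) >= 2
    }
    return ComparisonTable(aggregates=aggregates, folds=folds, plan=plan)


def folds_to_frame(folds: Sequence[FoldMetrics]) -> pd.DataFrame:
    return pd.DataFrame([f.as_dict() for f in folds]).rename_axis("fold")
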