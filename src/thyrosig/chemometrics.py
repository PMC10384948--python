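"""Normalization, PLS-DA with VIP scores, cross-validated R2/Q2, permutations.

The normalization pipeline applied to raw (nonnegative) intensities is, per
feature: impute zeros with half the minimum positive *training* intensity,
log10-transform, mean-center and unit-variance scale with training
parameters. Test partitions always reuse the training parameters, so
cross-validation below is leakage-free.

PLS-DA is PLS1 regression (NIPALS, one y vector) on +/-1-coded class labels
with decision threshold 0; ties resolve to the benign (majority) class.
VIP_j = sqrt(p * sum_a SS_a (w_ja/||w_a||)^2 / sum_a SS_a), where SS_a is the
y sum of squares explained by component a; mean squared VIP equals 1 by
construction.

Q2 = 1 - PRESS/SS_tot uses held-out predictions from stratified k-fold
cross-validation with per-fold renormalization. The permutation test refits
the whole CV under label permutations and uses the add-one p-value rule
p = (1 + #{null >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .feature_tables import FeatureTable

BENIGN, MALIGNANT = "benign", "malignant"


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


class Normalizer:
    """Half-minimum imputation -> log10 -> center -> scale, fit on training data.

    Operates on ``(n_samples, n_features)`` raw intensity arrays.
    """

    def __init__(self) -> None:
        self.log_offset_: np.ndarray | None = None  # half-min positive, per feature
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, raw: np.ndarray, feature_ids: Sequence[str] | None = None
            ) -> "Normalizer":
        raw = np.asarray(raw, dtype=float)
        if raw.ndim != 2:
            raise ValidationError("expected a 2-D (samples x features) array")
        if raw.size and raw.min() < 0:
            raise ValidationError("raw intensities must be nonnegative")
        pos = np.where(raw > 0, raw, np.inf)
        min_pos = pos.min(axis=0)
        dead = ~np.isfinite(min_pos)
        if dead.any():
            j = int(np.flatnonzero(dead)[0])
            name = feature_ids[j] if feature_ids is not None else f"index {j}"
            raise ValidationError(
                f"feature {name} has no positive training intensity; "
                "it should have been removed by the filter cascade"
            )
        self.log_offset_ = min_pos / 2.0
        logged = np.log10(np.where(raw > 0, raw, self.log_offset_))
        self.mean_ = logged.mean(axis=0)
        sd = logged.std(axis=0, ddof=0)
        self.sd_ = np.maximum(sd, 1e-12)  # constant features map to 0
        return self

    def transform(self, raw: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValidationError("Normalizer is not fitted")
        raw = np.asarray(raw, dtype=float)
        logged = np.log10(np.where(raw > 0, raw, self.log_offset_))
        return (logged - self.mean_) / self.sd_

    def fit_transform(self, raw: np.ndarray,
                      feature_ids: Sequence[str] | None = None) -> np.ndarray:
        return self.fit(raw, feature_ids).transform(raw)

    def inverse_log10(self, values: np.ndarray) -> np.ndarray:
        """Map normalized values back to log10 intensities."""
        if self.mean_ is None:
            raise ValidationError("Normalizer is not fitted")
        return values * self.sd_ + self.mean_


@dataclass
class NormalizedMatrix:
    """Normalized features x samples matrix with its training parameters."""

    values: np.ndarray  # (n_features, n_samples)
    feature_ids: list[str]
    sample_ids: list[str]
    class_labels: np.ndarray
    normalizer: Normalizer

    @property
    def X(self) -> np.ndarray:
        """Samples x features view, the model-fitting orientation."""
        return self.values.T


def normalize(
    table: FeatureTable, training_ids: Sequence[str] | None = None
) -> NormalizedMatrix:
    """Normalize the sample columns of a feature table.

    ``training_ids`` selects the runs whose statistics parameterize the
    transform (default: all role='sample' runs); the remaining sample columns
    are transformed with the stored training parameters.
    """
    smask = table.role_mask("sample")
    if not smask.any():
        raise ValidationError("normalize requires at least one sample run")
    sample_ids = [s.run_id for s in table.samples if s.role == "sample"]
    raw = table.intensities[:, smask].T  # samples x features
    if training_ids is None:
        train_rows = np.arange(len(sample_ids))
    else:
        missing = set(training_ids) - set(sample_ids)
        if missing:
            raise ValidationError(f"unknown training run ids: {sorted(missing)}")
        train_rows = np.array([sample_ids.index(r) for r in training_ids])
    norm = Normalizer().fit(raw[train_rows], table.feature_ids)
    values = norm.transform(raw).T
    return NormalizedMatrix(
        values=values,
        feature_ids=list(table.feature_ids),
        sample_ids=sample_ids,
        class_labels=table.class_labels("sample"),
        normalizer=norm,
    )


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


def encode_labels(y: Sequence[str] | np.ndarray) -> tuple[np.ndarray, tuple[str, str]]:
    """Encode two class labels as -1/+1. Benign maps to -1 when present."""
    y = np.asarray(y)
    classes = sorted(set(y.tolist()))
    if len(classes) != 2:
        raise ValidationError(f"PLS-DA requires exactly two classes, got {classes}")
    if BENIGN in classes and MALIGNANT in classes:
        neg, pos = BENIGN, MALIGNANT
    else:
        neg, pos = classes[0], classes[1]
    encoded = np.where(y == pos, 1.0, -1.0)
    return encoded, (neg, pos)


@dataclass
class PLSDAModel:
    """Fitted PLS1 discriminant model on +/-1-coded labels."""

    n_components: int
    weights: np.ndarray     # (p, A), unit-norm columns
    loadings: np.ndarray    # (p, A)
    scores: np.ndarray      # (n, A)
    q: np.ndarray           # (A,) y loadings
    coef_: np.ndarray       # (p,) regression vector
    x_mean_: np.ndarray
    y_mean_: float
    ss_components: np.ndarray  # (A,) y sum of squares explained per component
    classes_: tuple[str, str]  # (coded -1, coded +1)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_

    def predict(self, X: np.ndarray) -> np.ndarray:
        # threshold 0; ties resolve to the -1-coded (benign/majority) class
        raw = self.decision_function(X)
        return np.where(raw > 0, self.classes_[1], self.classes_[0])


def _as_X(X) -> np.ndarray:
    if isinstance(X, NormalizedMatrix):
        return X.X
    return np.asarray(X, dtype=float)


def fit_plsda(X, y: Sequence[str] | np.ndarray, n_components: int = 2) -> PLSDAModel:
    """Fit PLS1-DA by NIPALS with deflation after each component."""
    X = _as_X(X)
    yenc, classes = encode_labels(y)
    n, p = X.shape
    if len(yenc) != n:
        raise ValidationError("X and y have incompatible lengths")
    for cls in classes:
        if np.sum(np.asarray(y) == cls) < 2:
            raise ValidationError(f"class {cls!r} needs at least 2 training samples")
    if not 1 <= n_components <= min(p, n - 1):
        raise ValidationError(
            f"n_components={n_components} must be in [1, min(p, n-1)]"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(yenc.mean())
    Xd = X - x_mean
    yd = yenc - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    ss = np.zeros(n_components)
    a_fit = 0
    for a in range(n_components):
        w = Xd.T @ yd
        wn = np.linalg.norm(w)
        if wn < 1e-14:
            break  # X carries no remaining covariance with y
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-14:
            break
        pvec = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd = Xd - np.outer(t, pvec)
        yd = yd - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa
        ss[a] = qa * qa * tt
        a_fit = a + 1
    if a_fit == 0:
        raise ValidationError("PLS-DA found no covariance between X and y")
    W, P, T, q, ss = W[:, :a_fit], P[:, :a_fit], T[:, :a_fit], q[:a_fit], ss[:a_fit]
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSDAModel(
        n_components=a_fit,
        weights=W,
        loadings=P,
        scores=T,
        q=q,
        coef_=coef,
        x_mean_=x_mean,
        y_mean_=y_mean,
        ss_components=ss,
        classes_=classes,
    )


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection; mean squared VIP equals 1."""
    ss = model.ss_components
    total = ss.sum()
    if total <= 0:
        raise ValidationError("model explains zero y sum of squares")
    W = model.weights
    p = W.shape[0]
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (wnorm2 @ ss) / total)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class PLSDAPerformance:
    """Component-wise training fit and cross-validated prediction quality."""

    accuracy: float
    r2: float
    q2: float
    best_a: int
    accuracy_curve: np.ndarray
    r2_curve: np.ndarray
    q2_curve: np.ndarray


def _stratified_folds(y: np.ndarray, folds: int, seed: int):
    _, counts = np.unique(y, return_counts=True)
    if folds > counts.min():
        raise ValidationError(
            f"{folds}-fold CV impossible with minority class of {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cross_validate_plsda(
    raw: np.ndarray,
    y: Sequence[str] | np.ndarray,
    a_max: int = 5,
    folds: int = 10,
    seed: int = 0,
) -> PLSDAPerformance:
    """Stratified k-fold CV of PLS-DA on raw intensities.

    ``raw`` is (n_samples, n_features), nonnegative; normalization is refit
    inside every training fold so held-out samples never leak into the
    transform. Reported per component a = 1..a_max: training R2 (full-data
    fit), CV accuracy, and Q2 = 1 - PRESS/SS_tot from held-out predictions.
    The retained component count maximizes training R2, with curves exposed
    alongside.
    """
    raw = np.asarray(raw, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    yenc, _ = encode_labels(y)
    n, p = raw.shape
    a_max = min(a_max, p, n - max(2, n // folds + 1))
    a_max = max(a_max, 1)
    press = np.zeros(a_max)
    correct = np.zeros(a_max)
    for train, test in _stratified_folds(y, folds, seed):
        norm = Normalizer().fit(raw[train])
        Xtr, Xte = norm.transform(raw[train]), norm.transform(raw[test])
        model = fit_plsda(Xtr, y[train], n_components=min(a_max, len(train) - 1))
        for a in range(1, a_max + 1):
            sub = _truncate(model, a)
            pred = sub.decision_function(Xte)
            press[a - 1] += float(np.sum((yenc[test] - pred) ** 2))
            labels = sub.predict(Xte)
            correct[a - 1] += float(np.sum(labels == y[test]))
    ss_tot = float(np.sum((yenc - yenc.mean()) ** 2))
    q2_curve = 1.0 - press / ss_tot
    acc_curve = correct / n

    norm_full = Normalizer().fit(raw)
    Xfull = norm_full.transform(raw)
    model_full = fit_plsda(Xfull, y, n_components=a_max)
    r2_curve = np.zeros(a_max)
    for a in range(1, a_max + 1):
        sub = _truncate(model_full, a)
        resid = yenc - sub.decision_function(Xfull)
        r2_curve[a - 1] = 1.0 - float(np.sum(resid**2)) / ss_tot
    best_a = int(np.argmax(r2_curve)) + 1
    return PLSDAPerformance(
        accuracy=float(acc_curve[best_a - 1]),
        r2=float(r2_curve[best_a - 1]),
        q2=float(q2_curve[best_a - 1]),
        best_a=best_a,
        accuracy_curve=acc_curve,
        r2_curve=r2_curve,
        q2_curve=q2_curve,
    )


def _truncate(model: PLSDAModel, a: int) -> PLSDAModel:
    """Restrict a fitted model to its first ``a`` components."""
    a = min(a, model.n_components)
    W, P, q = model.weights[:, :a], model.loadings[:, :a], model.q[:a]
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSDAModel(
        n_components=a,
        weights=W,
        loadings=P,
        scores=model.scores[:, :a],
        q=q,
        coef_=coef,
        x_mean_=model.x_mean_,
        y_mean_=model.y_mean_,
        ss_components=model.ss_components[:a],
        classes_=model.classes_,
    )


@dataclass
class PermutationResult:
    n_permutations: int
    observed_statistic: float
    null_statistics: np.ndarray
    p_value: float


def _cv_accuracy(raw: np.ndarray, y: np.ndarray, a: int, folds: int,
                 seed: int) -> float:
    correct = 0
    for train, test in _stratified_folds(y, folds, seed):
        norm = Normalizer().fit(raw[train])
        model = fit_plsda(
            norm.transform(raw[train]), y[train],
            n_components=min(a, len(train) - 1),
        )
        correct += int(np.sum(model.predict(norm.transform(raw[test])) == y[test]))
    return correct / len(y)


def permutation_test(
    raw: np.ndarray,
    y: Sequence[str] | np.ndarray,
    n_components: int = 2,
    n_perm: int = 2000,
    seed: int = 0,
    folds: int = 10,
) -> PermutationResult:
    """Label-permutation significance of the cross-validated accuracy."""
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    raw = np.asarray(raw, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    observed = _cv_accuracy(raw, y, n_components, folds, seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        null[b] = _cv_accuracy(raw, yp, n_components, folds, seed)
    p = (1.0 + float(np.sum(null >= observed))) / (n_perm + 1.0)
    return PermutationResult(n_perm, observed, null, p)
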