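"""Supervised autoencoder (SAE): latent classification plus reconstruction.

The SAE is a small multilayer perceptron with three heads sharing an encoder:

* encoder  input(p) -> hidden (ReLU) -> latent (linear, default 2-D),
* decoder  latent -> hidden (ReLU) -> input(p) (linear),
* classifier latent -> 2 logits (linear).

Training minimizes ``class-weighted cross-entropy + lambda * MSE(x, x_hat)``
with Adam on shuffled mini-batches. The reconstruction term regularizes the
latent space so that it preserves the metabolome-wide structure instead of
collapsing onto the decision boundary, which is what makes the 2-D latent
projection interpretable for small unbalanced cohorts (tens of samples,
hundreds to thousands of ions). Class weights default to inverse class
frequency. Everything is a pure function of (data, config, seed): two runs
with the same inputs produce bitwise-identical parameters.

Feature importance is the mean input gradient of the logit difference
(malignant minus benign), keeping its sign, so an ion elevated in malignant
samples receives a positive score. Signature selection is a step-by-step
top-down elimination: fit, rank by absolute score, keep the top half (never
fewer than k), repeat until k ions remain, then refit on exactly k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .chemometrics import BENIGN, MALIGNANT, NormalizedMatrix, Normalizer
from .errors import TrainingError, ValidationError
from .feature_tables import FeatureTable, IonAnnotation


class SAEConfig(BaseModel):
    """Hyperparameters of the supervised autoencoder."""

    model_config = ConfigDict(extra="forbid")

    hidden_sizes: list[int] = Field(default_factory=lambda: [64])
    latent_dim: int = Field(default=2, ge=2)
    recon_weight: float = Field(default=0.1, ge=0.0)
    learning_rate: float = Field(default=1e-3, gt=0.0)
    epochs: int = Field(default=300, ge=1)
    batch_size: int = Field(default=16, ge=1)
    seed: int = 0
    class_weights: dict[str, float] | None = None


def _encode_classes(y: np.ndarray) -> tuple[np.ndarray, tuple[str, str]]:
    classes = sorted(set(y.tolist()))
    if len(classes) != 2:
        raise ValidationError(f"SAE requires exactly two classes, got {classes}")
    if BENIGN in classes and MALIGNANT in classes:
        classes = [BENIGN, MALIGNANT]
    return np.where(y == classes[1], 1, 0).astype(int), (classes[0], classes[1])


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class _MLP:
    """Dense stack with ReLU between layers and a linear last layer."""

    def __init__(self, dims: Sequence[int], rng: np.random.Generator):
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Return output and per-layer pre-activations (for backprop)."""
        pre: list[np.ndarray] = []
        h = x
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            a = h @ W + b
            pre.append(a)
            h = a if i == last else _relu(a)
        return h, pre

    def backward(
        self, x: np.ndarray, pre: list[np.ndarray], grad_out: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
        """Gradients of the weights/biases and of the input."""
        last = len(self.W) - 1
        acts = [x]
        for i in range(last):
            acts.append(_relu(pre[i]))
        gW = [np.zeros_like(W) for W in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        g = grad_out
        for i in range(last, -1, -1):
            gW[i] = acts[i].T @ g
            gb[i] = g.sum(axis=0)
            g = g @ self.W[i].T
            if i > 0:
                g = g * (pre[i - 1] > 0)
        return gW, gb, g

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b


@dataclass
class SAEModel:
    """Fitted supervised autoencoder."""

    config: SAEConfig
    classes_: tuple[str, str]
    encoder: _MLP
    decoder: _MLP
    clf_W: np.ndarray  # (latent_dim, 2)
    clf_b: np.ndarray  # (2,)
    loss_trace: list[float] = field(default_factory=list)
    n_features: int = 0

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValidationError(
                f"expected (n, {self.n_features}) input, got {X.shape}"
            )
        return X

    def encode(self, X: np.ndarray) -> np.ndarray:
        z, _ = self.encoder.forward(self._check_X(X))
        return z

    def logits(self, X: np.ndarray) -> np.ndarray:
        return self.encode(X) @ self.clf_W + self.clf_b

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self.logits(X))[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(
            self.predict_proba(X) > 0.5, self.classes_[1], self.classes_[0]
        )


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _as_X(X) -> np.ndarray:
    if isinstance(X, NormalizedMatrix):
        return X.X
    return np.asarray(X, dtype=float)


def fit_sae(X, y: Sequence[str] | np.ndarray, config: SAEConfig | None = None
            ) -> SAEModel:
    """Train the supervised autoencoder; deterministic given ``config.seed``."""
    config = config or SAEConfig()
    X = _as_X(X)
    y = np.asarray(y)
    yidx, classes = _encode_classes(y)
    n, p = X.shape
    counts = np.bincount(yidx, minlength=2)
    if counts.min() < 4:
        raise ValidationError("SAE training requires at least 4 samples per class")
    if config.class_weights is None:
        cw = n / (2.0 * counts)
    else:
        try:
            cw = np.array([config.class_weights[c] for c in classes], dtype=float)
        except KeyError as exc:
            raise ValidationError(f"class_weights missing class {exc.args[0]!r}")
    sample_w = cw[yidx]

    rng = np.random.default_rng(config.seed)
    enc = _MLP([p, *config.hidden_sizes, config.latent_dim], rng)
    dec = _MLP([config.latent_dim, *reversed(config.hidden_sizes), p], rng)
    clf_W = rng.normal(0.0, np.sqrt(1.0 / config.latent_dim),
                       size=(config.latent_dim, 2))
    clf_b = np.zeros(2)

    params = enc.params + dec.params + [clf_W, clf_b]
    opt = _Adam(params, config.learning_rate)
    onehot = np.eye(2)[yidx]
    lam = config.recon_weight
    trace: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, tb, wb = X[idx], onehot[idx], sample_w[idx]
            wsum = wb.sum()

            z, pre_e = enc.forward(xb)
            xhat, pre_d = dec.forward(z)
            logits = z @ clf_W + clf_b
            probs = _softmax(logits)

            logp = logits - logits.max(axis=1, keepdims=True)
            logp = logp - np.log(np.exp(logp).sum(axis=1, keepdims=True))
            ce = -(tb * logp).sum(axis=1)
            loss_ce = float((wb * ce).sum() / wsum)
            resid = xhat - xb
            loss_rec = float((resid**2).mean())
            loss = loss_ce + lam * loss_rec
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            epoch_loss += loss * len(idx)

            dlogits = (probs - tb) * (wb / wsum)[:, None]
            g_clfW = z.T @ dlogits
            g_clfb = dlogits.sum(axis=0)
            dz_clf = dlogits @ clf_W.T

            dxhat = 2.0 * lam * resid / resid.size
            gW_d, gb_d, dz_dec = dec.backward(z, pre_d, dxhat)
            gW_e, gb_e, _ = enc.backward(xb, pre_e, dz_clf + dz_dec)

            grads = gW_e + gb_e + gW_d + gb_d + [g_clfW, g_clfb]
            opt.step(params, grads)
        trace.append(epoch_loss / n)
    return SAEModel(
        config=config,
        classes_=classes,
        encoder=enc,
        decoder=dec,
        clf_W=clf_W,
        clf_b=clf_b,
        loss_trace=trace,
        n_features=p,
    )


def project_latent(model: SAEModel, X) -> np.ndarray:
    """Per-sample latent coordinates, shape (n_samples, latent_dim)."""
    return model.encode(_as_X(X))


def predict_proba(model: SAEModel, X) -> np.ndarray:
    """Malignant-class probability (softmax of the classifier logits)."""
    return model.predict_proba(_as_X(X))


def feature_scores(model: SAEModel, X) -> np.ndarray:
    """Signed importance: mean input gradient of (malignant - benign) logit."""
    X = model._check_X(_as_X(X))
    v = model.clf_W[:, 1] - model.clf_W[:, 0]  # d(logit diff)/dz
    _, pre = model.encoder.forward(X)
    g = np.broadcast_to(v, (X.shape[0], v.shape[0])).copy()
    last = len(model.encoder.W) - 1
    for i in range(last, -1, -1):
        g = g @ model.encoder.W[i].T
        if i > 0:
            g = g * (pre[i - 1] > 0)
    return g.mean(axis=0)


def save_model(model: SAEModel, path: str | Path,
               feature_ids: Sequence[str] | None = None) -> None:
    """Persist a fitted SAE as a single ``.npz`` blob with config embedded."""
    import json

    arrays: dict[str, np.ndarray] = {"clf_W": model.clf_W, "clf_b": model.clf_b}
    for tag, mlp in (("enc", model.encoder), ("dec", model.decoder)):
        for i, (W, b) in enumerate(zip(mlp.W, mlp.b)):
            arrays[f"{tag}_W{i}"] = W
            arrays[f"{tag}_b{i}"] = b
    meta = {
        "config": model.config.model_dump(),
        "classes": list(model.classes_),
        "n_features": model.n_features,
        "loss_trace": model.loss_trace,
        "feature_ids": list(feature_ids) if feature_ids else None,
    }
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_model(path: str | Path) -> SAEModel:
    """Load an SAE checkpoint written by :func:`save_model`."""
    import json

    with np.load(path, allow_pickle=False) as blob:
        meta = json.loads(str(blob["meta"]))
        config = SAEConfig.model_validate(meta["config"])
        p = int(meta["n_features"])
        rng = np.random.default_rng(0)
        enc = _MLP([p, *config.hidden_sizes, config.latent_dim], rng)
        dec = _MLP([config.latent_dim, *reversed(config.hidden_sizes), p], rng)
        for tag, mlp in (("enc", enc), ("dec", dec)):
            for i in range(len(mlp.W)):
                mlp.W[i] = blob[f"{tag}_W{i}"]
                mlp.b[i] = blob[f"{tag}_b{i}"]
        return SAEModel(
            config=config,
            classes_=tuple(meta["classes"]),
            encoder=enc,
            decoder=dec,
            clf_W=blob["clf_W"],
            clf_b=blob["clf_b"],
            loss_trace=list(meta["loss_trace"]),
            n_features=p,
        )


# ---------------------------------------------------------------------------
# Prediction-confidence curves
# ---------------------------------------------------------------------------


@dataclass
class ConfidenceCurves:
    """Class-conditional kernel densities of the predicted probability."""

    grid: np.ndarray
    density_benign: np.ndarray
    density_malignant: np.ndarray
    confidence: np.ndarray  # per sample, in [0, 1]
    bandwidths: tuple[float, float]

    def crossing_count(self) -> int:
        diff = self.density_benign - self.density_malignant
        sign = np.sign(diff[np.abs(diff) > 1e-12])
        return int(np.sum(sign[1:] != sign[:-1]))


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(s for s in (sd, iqr / 1.34) if s > 0) if max(sd, iqr) > 0 else 0.0
    return max(0.9 * spread * n ** (-0.2), 1e-3)


def _kde(points: np.ndarray, h: float, at: np.ndarray) -> np.ndarray:
    z = (at[:, None] - points[None, :]) / h
    return np.exp(-0.5 * z**2).sum(axis=1) / (len(points) * h * np.sqrt(2 * np.pi))


def confidence_curves(
    probs: np.ndarray,
    y: Sequence[str] | np.ndarray,
    grid_size: int = 201,
) -> ConfidenceCurves:
    """Gaussian KDE of predicted probabilities per true class.

    Bandwidths follow Silverman's rule per class with a floor of 1e-3. The
    curves are renormalized to unit trapezoidal mass on the [0, 1] grid.
    Per-sample confidence is d_own / (d_own + d_other) at the sample's own
    predicted probability.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y)
    yidx, classes = _encode_classes(y)
    if np.bincount(yidx, minlength=2).min() < 2:
        raise ValidationError("confidence_curves requires >=2 samples per class")
    grid = np.linspace(0.0, 1.0, grid_size)
    pts = [probs[yidx == k] for k in (0, 1)]
    hs = tuple(_silverman_bandwidth(pk) for pk in pts)
    dens_grid = []
    dens_at = []
    for pk, h in zip(pts, hs):
        on_grid = _kde(pk, h, grid)
        mass = np.trapezoid(on_grid, grid)
        scale = 1.0 / mass if mass > 0 else 1.0
        dens_grid.append(on_grid * scale)
        dens_at.append(_kde(pk, h, probs) * scale)
    d0, d1 = dens_at
    own = np.where(yidx == 0, d0, d1)
    other = np.where(yidx == 0, d1, d0)
    with np.errstate(invalid="ignore"):
        conf = np.where(own + other > 0, own / (own + other), 0.5)
    return ConfidenceCurves(grid, dens_grid[0], dens_grid[1], conf, hs)


# ---------------------------------------------------------------------------
# Effect-size summary and signature selection
# ---------------------------------------------------------------------------


def bm_ratio(table: FeatureTable, feature_id: str) -> float:
    """Benign-over-malignant ratio of mean raw intensity for one feature."""
    labels = table.class_labels("sample")
    smat = table.sample_matrix()
    try:
        row = table.feature_ids.index(feature_id)
    except ValueError:
        raise ValidationError(f"unknown feature id {feature_id!r}") from None
    for cls in (BENIGN, MALIGNANT):
        if not np.any(labels == cls):
            raise ValidationError(f"no samples of class {cls!r} in table")
    bmean = float(smat[row, labels == BENIGN].mean())
    mmean = float(smat[row, labels == MALIGNANT].mean())
    if mmean == 0:
        warnings.warn(
            f"feature {feature_id}: malignant mean intensity is zero; "
            "reporting an infinite benign/malignant ratio",
            stacklevel=2,
        )
        return float("inf")
    return bmean / mmean


@dataclass
class SignatureEntry:
    feature_id: str
    mode: str
    mz: float
    rt: float
    main_identity: str
    hmdb_id: str
    formula: str
    sae_score: float
    bm_ratio: float


@dataclass
class Signature:
    """Ranked ion signature, ordered by descending SAE score."""

    entries: list[SignatureEntry]

    @property
    def feature_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ion_mode": [e.mode for e in self.entries],
                "mz": [e.mz for e in self.entries],
                "rt_min": [e.rt for e in self.entries],
                "main_identity": [e.main_identity for e in self.entries],
                "hmdb_id": [e.hmdb_id for e in self.entries],
                "formula": [e.formula for e in self.entries],
                "sae_score": [e.sae_score for e in self.entries],
                "bm_ratio": [e.bm_ratio for e in self.entries],
            },
            index=pd.Index(self.feature_ids, name="feature_id"),
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def to_json(self) -> str:
        import json

        return json.dumps(
            [e.__dict__ for e in self.entries], indent=1, default=float
        )


def _round_seed(base: int, round_idx: int) -> int:
    return int((base * 1_000_003 + round_idx) % (2**31 - 1))


def topdown_select(
    table: FeatureTable,
    k: int = 15,
    drop_fraction: float = 0.5,
    config: SAEConfig | None = None,
    annotations: Sequence[IonAnnotation] | None = None,
    compounds: Sequence | None = None,
    progress: Callable[[int, int], None] | None = None,
) -> Signature:
    """Step-by-step top-down SAE feature elimination to a k-ion signature.

    Each round refits the SAE on the surviving ions (with a round-derived
    seed), ranks by absolute feature score and keeps the top
    ``ceil((1 - drop_fraction) * p)`` ions, never fewer than ``k``; a final
    refit on exactly ``k`` ions supplies the reported scores. The
    benign/malignant intensity ratio comes from the raw table.
    """
    config = config or SAEConfig()
    if not 0.0 < drop_fraction < 1.0:
        raise ValidationError("drop_fraction must be strictly between 0 and 1")
    if k >= table.n_features:
        raise ValidationError(
            f"k={k} must be smaller than the current feature count "
            f"{table.n_features}"
        )
    if k < 1:
        raise ValidationError("k must be >= 1")

    annot_by_feature: dict[str, str] = {}
    if annotations:
        for ann in annotations:  # first (smallest |ppm|) annotation wins
            annot_by_feature.setdefault(ann.feature_id, ann.compound_id)
    compound_lookup = {c.compound_id: c for c in compounds} if compounds else {}

    current = table
    round_idx = 0
    from .chemometrics import normalize  # local import avoids cycle at module load

    while current.n_features > k:
        nm = normalize(current)
        cfg = config.model_copy(update={"seed": _round_seed(config.seed, round_idx)})
        model = fit_sae(nm, nm.class_labels, cfg)
        scores = feature_scores(model, nm)
        keep_n = max(k, int(np.ceil((1.0 - drop_fraction) * current.n_features)))
        keep_n = min(keep_n, current.n_features - 1)  # guarantee progress
        keep_n = max(keep_n, k)
        order = np.argsort(-np.abs(scores), kind="stable")[:keep_n]
        current = current.select_features(np.sort(order))
        round_idx += 1
        if progress:
            progress(round_idx, current.n_features)

    nm = normalize(current)
    cfg = config.model_copy(update={"seed": _round_seed(config.seed, round_idx)})
    model = fit_sae(nm, nm.class_labels, cfg)
    scores = feature_scores(model, nm)

    entries = []
    for j in np.argsort(-scores, kind="stable"):
        feat = current.features[int(j)]
        hmdb = annot_by_feature.get(feat.feature_id, "")
        name, formula = "", ""
        if hmdb and hmdb in compound_lookup:
            comp = compound_lookup[hmdb]
            name, formula = comp.name, comp.formula
        entries.append(
            SignatureEntry(
                feature_id=feat.feature_id,
                mode=feat.mode,
                mz=feat.mz,
                rt=feat.rt,
                main_identity=name,
                hmdb_id=hmdb,
                formula=formula,
                sae_score=float(scores[j]),
                bm_ratio=bm_ratio(current, feat.feature_id),
            )
        )
    return Signature(entries)


# ---------------------------------------------------------------------------
# Classifier wrapper for the comparison harness
# ---------------------------------------------------------------------------


class SAEClassifier:
    """Uniform train/predict contract over raw intensities.

    Fits the normalizer on the training partition only, then trains the SAE
    on the normalized values.
    """

    def __init__(self, config: SAEConfig | None = None):
        self.config = config or SAEConfig()
        self._norm: Normalizer | None = None
        self._model: SAEModel | None = None

    def fit(self, raw_train: np.ndarray, y_train: np.ndarray) -> "SAEClassifier":
        self._norm = Normalizer().fit(raw_train)
        self._model = fit_sae(self._norm.transform(raw_train), y_train, self.config)
        return self

    def predict(self, raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        assert self._model is not None and self._norm is not None
        X = self._norm.transform(raw)
        probs = self._model.predict_proba(X)
        labels = np.where(
            probs > 0.5, self._model.classes_[1], self._model.classes_[0]
        )
        return labels, probs
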