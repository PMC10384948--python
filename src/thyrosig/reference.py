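"""Published fold-level performance of the original 78-patient FNAC cohort.

The clinical cohort behind this pipeline (56 benign / 22 malignant thyroid
nodules profiled from liquid-cytology fluid) is not publicly deposited, but
its per-fold cross-validation metrics were printed in full. They serve here
as worked-example inputs for the aggregation utilities: recomputing the mean
rows from the fold values exercises :func:`thyrosig.evaluation.aggregate`
against externally reported numbers.

``SAE_ACCURACY_FOLDS`` holds the per-split global/benign/malignant accuracy
of the supervised autoencoder over 12 repeated stratified splits;
``SAE_PERFORMANCE_FOLDS`` the matching AUC/precision/recall/F1.
``COMPARISON_FOLDS`` holds the four-split metrics of the SVM, PLS-DA and
random-forest comparators on the same 15-ion signature.
"""

from __future__ import annotations

from .evaluation import AggregateMetrics, FoldMetrics, aggregate

#: (global, benign, malignant) accuracy per split, supervised autoencoder.
SAE_ACCURACY_FOLDS: tuple[tuple[float, float, float], ...] = (
    (1.0, 1.0, 1.0),
    (0.95, 1.0, 0.667),
    (0.95, 1.0, 0.875),
    (0.842, 0.727, 1.0),
    (1.0, 1.0, 1.0),
    (0.95, 0.933, 1.0),
    (0.9, 0.933, 0.8),
    (1.0, 1.0, 1.0),
    (1.0, 1.0, 1.0),
    (1.0, 1.0, 1.0),
    (0.95, 1.0, 0.833),
    (0.947, 0.917, 1.0),
)

#: (AUC, precision, recall, F1) per split, supervised autoencoder.
SAE_PERFORMANCE_FOLDS: tuple[tuple[float, float, float, float], ...] = (
    (1.0, 1.0, 1.0, 1.0),
    (0.833, 0.972, 0.833, 0.886),
    (0.938, 0.962, 0.938, 0.947),
    (0.864, 0.864, 0.864, 0.842),
    (1.0, 1.0, 1.0, 1.0),
    (0.967, 0.917, 0.967, 0.937),
    (0.867, 0.867, 0.867, 0.867),
    (1.0, 1.0, 1.0, 1.0),
    (1.0, 1.0, 1.0, 1.0),
    (1.0, 1.0, 1.0, 1.0),
    (0.917, 0.967, 0.917, 0.937),
    (0.958, 0.938, 0.958, 0.945),
)

#: Comparator metrics over four splits: method -> metric -> fold values.
COMPARISON_FOLDS: dict[str, dict[str, tuple[float, ...]]] = {
    "SVM": {
        "auc": (0.833, 0.771, 0.938, 0.958),
        "accuracy_global": (0.895, 0.842, 0.947, 0.947),
        "precision": (0.833, 0.771, 0.938, 0.958),
        "recall": (0.933, 0.717, 0.958, 0.938),
        "f1": (0.864, 0.737, 0.945, 0.945),
    },
    "PLS-DA": {
        "auc": (0.833, 0.941, 1.0, 0.944),
        "accuracy_global": (0.895, 0.895, 1.0, 0.947),
        "precision": (0.833, 0.941, 1.0, 0.944),
        "recall": (0.933, 0.750, 1.0, 0.955),
        "f1": (0.864, 0.802, 1.0, 0.947),
    },
    "RF": {
        "auc": (1.0, 0.969, 0.887, 0.958),
        "accuracy_global": (1.0, 0.947, 0.895, 0.947),
        "precision": (1.0, 0.969, 0.887, 0.958),
        "recall": (1.0, 0.875, 0.887, 0.938),
        "f1": (1.0, 0.912, 0.887, 0.945),
    },
}


def sae_accuracy_aggregate() -> AggregateMetrics:
    """Mean/SD of the reported per-split SAE accuracies."""
    folds = [
        FoldMetrics(accuracy_global=g, accuracy_benign=b, accuracy_malignant=m)
        for g, b, m in SAE_ACCURACY_FOLDS
    ]
    return aggregate(folds)


def sae_performance_aggregate() -> AggregateMetrics:
    """Mean/SD of the reported per-split SAE AUC/precision/recall/F1."""
    folds = [
        FoldMetrics(auc=a, precision=p, recall=r, f1=f)
        for a, p, r, f in SAE_PERFORMANCE_FOLDS
    ]
    return aggregate(folds)


def comparison_aggregate(method: str) -> AggregateMetrics:
    """Mean/SD of a comparator's reported four-split metrics."""
    table = COMPARISON_FOLDS[method]
    n = len(next(iter(table.values())))
    folds = [
        FoldMetrics(**{metric: values[i] for metric, values in table.items()})
        for i in range(n)
    ]
    return aggregate(folds)
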