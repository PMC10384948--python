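"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from thyrosig.feature_tables import (
    Feature,
    FeatureTable,
    SampleInfo,
    annotate,
    join_align,
    merge_modes,
)
from thyrosig.synthetic_data import paper_fixture


@pytest.fixture(scope="session")
def fixture_cohort():
    """The seed-locked miniature cohort (peak lists, compounds, truth)."""
    return paper_fixture()


@pytest.fixture(scope="session")
def aligned_fixture(fixture_cohort):
    """Aligned + merged feature table of the miniature cohort, with annotations."""
    peak_lists, compounds, truth = fixture_cohort
    tables = {mode: join_align(pls) for mode, pls in peak_lists.items()}
    merged = merge_modes(tables["positive"], tables["negative"])
    annotations = annotate(merged.features, compounds)
    return merged, annotations, truth


def build_table(
    intensities: np.ndarray,
    roles: list[str],
    labels: list[str] | None = None,
    mode: str = "positive",
) -> FeatureTable:
    """Hand-built feature table for filter/normalization unit tests."""
    intensities = np.asarray(intensities, dtype=float)
    n_feat, n_runs = intensities.shape
    labels = labels or ["none"] * n_runs
    features = [
        Feature(f"F{i:03d}", mode, 100.0 + i, 1.0 + 0.1 * i) for i in range(n_feat)
    ]
    samples = [
        SampleInfo(f"R{c:02d}", roles[c], labels[c]) for c in range(n_runs)
    ]
    return FeatureTable(features, samples, intensities)


@pytest.fixture
def two_class_table():
    """4 features x (4 benign + 3 malignant + 2 blanks) with known means."""
    rng = np.random.default_rng(7)
    base = rng.uniform(2e4, 5e4, size=(4, 9))
    base[:, 7:] = 0.0  # blanks silent
    roles = ["sample"] * 7 + ["blank"] * 2
    labels = ["benign"] * 4 + ["malignant"] * 3 + ["none"] * 2
    return build_table(base, roles, labels)
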