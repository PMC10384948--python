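"""Supervised autoencoder: determinism, scores, confidence, selection."""

import numpy as np
import pytest

from conftest import build_table
from thyrosig.chemometrics import normalize
from thyrosig.errors import ValidationError
from thyrosig.sae import (
    SAEConfig,
    bm_ratio,
    confidence_curves,
    feature_scores,
    fit_sae,
    load_model,
    predict_proba,
    project_latent,
    save_model,
    topdown_select,
)
from thyrosig.synthetic_data import CohortSpec, cohort_feature_table


def _toy(seed=0, n=24, p=6, sep=3.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X[n // 2:, :2] += sep
    y = np.array(["benign"] * (n // 2) + ["malignant"] * (n // 2))
    return X, y


FAST = SAEConfig(hidden_sizes=[16], epochs=120, seed=0)


class TestFitSAE:
    def test_separable_toy_perfect_training_accuracy(self):
        X, y = _toy()
        model = fit_sae(X, y, FAST.model_copy(update={"recon_weight": 0.0}))
        assert np.mean(model.predict(X) == y) == 1.0

    def test_same_seed_is_bitwise_identical(self):
        X, y = _toy(1)
        m1 = fit_sae(X, y, FAST)
        m2 = fit_sae(X, y, FAST)
        for a, b in zip(m1.encoder.params, m2.encoder.params):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(m1.clf_W, m2.clf_W)
        assert m1.loss_trace == m2.loss_trace

    def test_loss_trace_decreases_on_trailing_average(self):
        X, y = _toy(2)
        model = fit_sae(X, y, FAST)
        trace = np.array(model.loss_trace)
        head = trace[:10].mean()
        tail = trace[-10:].mean()
        assert tail < head

    def test_huge_reconstruction_weight_disables_classification(self):
        X, y = _toy(3, n=32)
        strong = fit_sae(X, y, FAST.model_copy(update={"recon_weight": 0.0}))
        drowned = fit_sae(X, y, FAST.model_copy(update={"recon_weight": 1e3}))
        acc_strong = np.mean(strong.predict(X) == y)
        acc_drowned = np.mean(drowned.predict(X) == y)
        assert acc_strong == 1.0
        assert acc_drowned < acc_strong

    def test_too_few_samples_per_class_rejected(self):
        X = np.zeros((6, 3))
        y = np.array(["benign"] * 3 + ["malignant"] * 3)
        with pytest.raises(ValidationError):
            fit_sae(X, y, FAST)

    def test_checkpoint_round_trip(self, tmp_path):
        X, y = _toy(4)
        model = fit_sae(X, y, FAST)
        save_model(model, tmp_path / "sae.npz")
        back = load_model(tmp_path / "sae.npz")
        np.testing.assert_array_equal(model.predict_proba(X), back.predict_proba(X))


class TestLatentAndScores:
    def test_latent_shape_and_determinism(self):
        X, y = _toy(5)
        model = fit_sae(X, y, FAST)
        Z = project_latent(model, X)
        assert Z.shape == (X.shape[0], 2)
        # identical input rows map to identical coordinates
        Z2 = project_latent(model, X[[0, 0]])
        np.testing.assert_array_equal(Z2[0], Z2[1])
        np.testing.assert_allclose(Z2[0], Z[0], rtol=1e-12)

    def test_latent_separates_classes(self):
        X, y = _toy(6, n=40, sep=4.0)
        model = fit_sae(X, y, FAST)
        Z = project_latent(model, X)
        mu_b, mu_m = Z[:20].mean(axis=0), Z[20:].mean(axis=0)
        within = 0.5 * (Z[:20].std(axis=0).mean() + Z[20:].std(axis=0).mean())
        assert np.linalg.norm(mu_b - mu_m) > 2 * within

    def test_probabilities_complement(self):
        X, y = _toy(7)
        model = fit_sae(X, y, FAST)
        p = predict_proba(model, X)
        assert np.all((p >= 0) & (p <= 1))
        # equal logits -> probability one half
        model.clf_W[:] = 0.0
        model.clf_b[:] = 0.0
        np.testing.assert_allclose(model.predict_proba(X), 0.5)

    def test_dead_input_has_zero_score(self):
        X, y = _toy(8)
        model = fit_sae(X, y, FAST)
        model.encoder.W[0][3, :] = 0.0  # sever feature 3 from the network
        scores = feature_scores(model, X)
        assert scores[3] == 0.0

    def test_scores_match_finite_difference_gradient(self):
        """The analytic input gradient agrees with central differences."""
        X, y = _toy(9, n=20, p=5)
        model = fit_sae(X, y, FAST)
        scores = feature_scores(model, X)
        h = 1e-6

        def logit_diff(data):
            lg = model.logits(data)
            return lg[:, 1] - lg[:, 0]

        for j in range(X.shape[1]):
            up, dn = X.copy(), X.copy()
            up[:, j] += h
            dn[:, j] -= h
            fd = np.mean((logit_diff(up) - logit_diff(dn)) / (2 * h))
            assert scores[j] == pytest.approx(fd, abs=1e-5)


class TestConfidenceCurves:
    def test_separated_probabilities_give_full_confidence(self):
        probs = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        y = np.array(["benign"] * 3 + ["malignant"] * 3)
        curves = confidence_curves(probs, y)
        np.testing.assert_allclose(curves.confidence, 1.0, atol=1e-6)

    def test_densities_integrate_to_one(self):
        rng = np.random.default_rng(10)
        probs = np.clip(rng.normal([0.2] * 10 + [0.8] * 10, 0.1), 0, 1)
        y = np.array(["benign"] * 10 + ["malignant"] * 10)
        curves = confidence_curves(probs, y)
        for dens in (curves.density_benign, curves.density_malignant):
            assert np.trapezoid(dens, curves.grid) == pytest.approx(1.0, abs=1e-3)

    def test_sample_at_crossing_point_has_half_confidence(self):
        # symmetric classes around 0.5: the crossing sits at 0.5 exactly
        probs = np.array([0.3, 0.4, 0.5, 0.6, 0.7, 0.5])
        y = np.array(["benign"] * 3 + ["malignant"] * 3)
        curves = confidence_curves(probs, y)
        assert curves.confidence[2] == pytest.approx(0.5, abs=1e-9)
        assert curves.confidence[5] == pytest.approx(0.5, abs=1e-9)

    def test_overlapping_classes_yield_single_crossing(self):
        rng = np.random.default_rng(11)
        probs = np.clip(
            np.concatenate([rng.normal(0.25, 0.12, 30), rng.normal(0.75, 0.12, 30)]),
            0, 1,
        )
        y = np.array(["benign"] * 30 + ["malignant"] * 30)
        assert confidence_curves(probs, y).crossing_count() == 1


class TestBMRatio:
    def test_equal_class_means_give_one(self):
        table = build_table(
            np.array([[100.0, 100.0, 100.0, 100.0]]),
            ["sample"] * 4, ["benign", "benign", "malignant", "malignant"],
        )
        assert bm_ratio(table, "F000") == pytest.approx(1.0)

    def test_label_swap_inverts_ratio(self):
        inten = np.array([[700.2, 700.2, 100.0, 100.0]])
        t1 = build_table(inten, ["sample"] * 4,
                         ["benign", "benign", "malignant", "malignant"])
        t2 = build_table(inten, ["sample"] * 4,
                         ["malignant", "malignant", "benign", "benign"])
        r1, r2 = bm_ratio(t1, "F000"), bm_ratio(t2, "F000")
        assert r1 == pytest.approx(7.002)
        assert r2 == pytest.approx(1 / r1)

    def test_zero_malignant_mean_warns_and_returns_inf(self):
        table = build_table(
            np.array([[500.0, 500.0, 0.0, 0.0]]),
            ["sample"] * 4, ["benign", "benign", "malignant", "malignant"],
        )
        with pytest.warns(UserWarning):
            assert bm_ratio(table, "F000") == np.inf


class TestTopdownSelect:
    def test_single_round_when_one_above_k(self):
        spec = CohortSpec(
            n_benign=12, n_malignant=8, n_blanks=2, n_qc=0,
            n_features_pos=40, n_features_neg=0, n_informative=4,
            annotatable_fraction=1.0, below_intensity_fraction=0.0,
            blank_contamination_fraction=0.0, seed=21,
        )
        table, _ = cohort_feature_table(spec)
        assert table.n_features == 40
        rounds = []
        sig = topdown_select(
            table.select_features(np.arange(16)), k=15, config=FAST,
            progress=lambda r, p: rounds.append(p),
        )
        assert len(sig.entries) == 15
        assert rounds == [15]

    def test_signature_sorted_by_descending_score(self):
        spec = CohortSpec(
            n_benign=12, n_malignant=8, n_blanks=2, n_qc=0,
            n_features_pos=30, n_features_neg=0, n_informative=3,
            annotatable_fraction=1.0, below_intensity_fraction=0.0,
            blank_contamination_fraction=0.0, seed=22,
        )
        table, _ = cohort_feature_table(spec)
        sig = topdown_select(table, k=5, config=FAST)
        scores = [e.sae_score for e in sig.entries]
        assert scores == sorted(scores, reverse=True)
        assert all(e.bm_ratio > 0 for e in sig.entries)

    def test_invalid_arguments_rejected(self):
        spec = CohortSpec(
            n_benign=8, n_malignant=6, n_blanks=1, n_qc=0,
            n_features_pos=10, n_features_neg=0, n_informative=2,
            annotatable_fraction=1.0, below_intensity_fraction=0.0,
            blank_contamination_fraction=0.0, seed=23,
        )
        table, _ = cohort_feature_table(spec)
        with pytest.raises(ValidationError):
            topdown_select(table, k=10, config=FAST)  # k >= p
        with pytest.raises(ValidationError):
            topdown_select(table, k=5, drop_fraction=0.0, config=FAST)

    def test_recovers_planted_features(self):
        spec = CohortSpec(
            n_benign=28, n_malignant=14, n_blanks=3, n_qc=0,
            n_features_pos=80, n_features_neg=0, n_informative=6,
            bm_ratios=[4.0, 3.0, 2.5, 0.4, 0.35, 0.3],
            annotatable_fraction=1.0, below_intensity_fraction=0.0,
            blank_contamination_fraction=0.0, seed=24,
        )
        table, truth = cohort_feature_table(spec)
        planted = set(truth.match_informative(table))
        sig = topdown_select(table, k=6, config=SAEConfig(seed=0))
        assert len(set(sig.feature_ids) & planted) >= 5
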