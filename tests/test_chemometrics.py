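"""Normalization, PLS-DA (against independent oracles), VIP, CV, permutations."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from conftest import build_table
from thyrosig.chemometrics import (
    Normalizer,
    cross_validate_plsda,
    fit_plsda,
    normalize,
    permutation_test,
    vip_scores,
)
from thyrosig.errors import ValidationError


class TestNormalization:
    def test_training_columns_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        raw = 10 ** rng.uniform(3, 6, size=(12, 20))
        X = Normalizer().fit_transform(raw)
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(X.std(axis=0), 1.0, atol=1e-8)

    def test_round_trip_recovers_log10(self):
        rng = np.random.default_rng(1)
        raw = 10 ** rng.uniform(3, 6, size=(10, 5))
        norm = Normalizer().fit(raw)
        back = norm.inverse_log10(norm.transform(raw))
        np.testing.assert_allclose(back, np.log10(raw), atol=1e-12)

    def test_zero_imputed_with_half_min_positive(self):
        raw = np.array([[100.0], [0.0], [400.0]])
        norm = Normalizer().fit(raw)
        assert norm.log_offset_[0] == 50.0
        logged = norm.inverse_log10(norm.transform(raw))
        assert logged[1, 0] == pytest.approx(np.log10(50.0))

    def test_constant_feature_maps_to_zero(self):
        raw = np.full((6, 1), 1e4)
        X = Normalizer().fit_transform(raw)
        np.testing.assert_allclose(X, 0.0)

    def test_all_zero_feature_names_culprit(self):
        raw = np.array([[1e4, 0.0], [2e4, 0.0]])
        with pytest.raises(ValidationError, match="f_bad"):
            Normalizer().fit(raw, feature_ids=["f_ok", "f_bad"])

    def test_table_normalization_uses_training_parameters(self, two_class_table):
        train_ids = [s.run_id for s in two_class_table.samples][:5]
        nm = normalize(two_class_table, training_ids=train_ids)
        train_cols = [nm.sample_ids.index(r) for r in train_ids]
        np.testing.assert_allclose(
            nm.values[:, train_cols].mean(axis=1), 0.0, atol=1e-8
        )


class TestPLSDA:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(2)
        X = np.vstack(
            [rng.normal(-3, 0.1, size=(10, 2)), rng.normal(3, 0.1, size=(10, 2))]
        )
        y = np.array(["benign"] * 10 + ["malignant"] * 10)
        model = fit_plsda(X, y, 2)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_matches_sklearn_pls_regression_vector(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 9))
        y = np.array(["benign"] * 15 + ["malignant"] * 10)
        for a in (1, 2, 4):
            model = fit_plsda(X, y, a)
            yenc = np.where(y == "malignant", 1.0, -1.0)
            sk = PLSRegression(n_components=a, scale=False).fit(X, yenc)
            np.testing.assert_allclose(sk.coef_.ravel(), model.coef_, atol=1e-8)

    def test_single_feature_equals_univariate_least_squares(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 1))
        y = np.array(["benign"] * 10 + ["malignant"] * 10)
        model = fit_plsda(X, y, 1)
        yenc = np.where(y == "malignant", 1.0, -1.0)
        slope = np.cov(X.ravel(), yenc, bias=True)[0, 1] / np.var(X.ravel())
        assert model.coef_[0] == pytest.approx(slope)

    def test_score_orthogonality(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 12))
        y = np.array(["benign"] * 18 + ["malignant"] * 12)
        model = fit_plsda(X, y, 4)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6
        np.testing.assert_allclose(
            np.linalg.norm(model.weights, axis=0), 1.0, atol=1e-12
        )

    def test_single_class_rejected(self):
        X = np.zeros((6, 3))
        with pytest.raises(ValidationError):
            fit_plsda(X, np.array(["benign"] * 6), 1)


class TestVIP:
    def test_mean_squared_vip_is_one(self):
        rng = np.random.default_rng(6)
        for seed in range(5):
            X = rng.normal(size=(24, 11))
            y = np.array(["benign"] * 12 + ["malignant"] * 12)
            model = fit_plsda(X, y, 3)
            v = vip_scores(model)
            assert (v**2).mean() == pytest.approx(1.0, abs=1e-10)

    def test_single_component_reduces_to_scaled_weight(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 6))
        y = np.array(["benign"] * 10 + ["malignant"] * 10)
        model = fit_plsda(X, y, 1)
        v = vip_scores(model)
        np.testing.assert_allclose(
            v, np.sqrt(6) * np.abs(model.weights[:, 0]), atol=1e-12
        )

    def test_informative_features_rank_high(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 60
            y = np.array(["benign"] * 30 + ["malignant"] * 30)
            X = rng.normal(size=(n, 50))
            X[:30, :5] += 1.5  # first five features informative
            model = fit_plsda(X, y, 2)
            top10 = set(np.argsort(-vip_scores(model))[:10])
            if set(range(5)) <= top10:
                hits += 1
        assert hits >= 19  # all 5 in the VIP top 10 in >=95% of replicates


class TestCrossValidation:
    def test_pure_noise_gives_nonpositive_q2(self):
        q2 = []
        for seed in range(50):
            rng = np.random.default_rng(200 + seed)
            raw = 10 ** rng.normal(4.5, 0.5, size=(40, 10))
            y = rng.permutation(np.array(["benign"] * 28 + ["malignant"] * 12))
            perf = cross_validate_plsda(raw, y, a_max=2, folds=5, seed=seed)
            q2.append(perf.q2)
        assert np.mean(np.array(q2) <= 0) >= 0.9
        assert np.median(q2) <= 0

    def test_leakage_identity_q2_equals_r2(self):
        # duplicating every sample makes each CV test point a copy of a
        # training point, so held-out prediction equals training fit
        rng = np.random.default_rng(8)
        raw = 10 ** rng.uniform(3, 6, size=(12, 4))
        y = np.array(["benign"] * 6 + ["malignant"] * 6)
        raw2, y2 = np.vstack([raw, raw]), np.concatenate([y, y])
        perf = cross_validate_plsda(raw2, y2, a_max=1, folds=2, seed=0)
        assert perf.q2 == pytest.approx(perf.r2, abs=0.15)

    def test_strong_signal_gives_high_q2(self):
        rng = np.random.default_rng(9)
        n_b, n_m = 56, 22
        y = np.array(["benign"] * n_b + ["malignant"] * n_m)
        logI = rng.normal(4.8, 0.15, size=(n_b + n_m, 15))
        shift = np.linspace(0.15, 0.4, 15)
        logI[n_b:, :] += shift
        raw = 10**logI
        perf = cross_validate_plsda(raw, y, a_max=5, folds=10, seed=0)
        assert perf.q2 > 0.5
        assert perf.r2 >= perf.q2


class TestPermutationTest:
    def test_worst_case_p_is_one(self):
        # observed statistic below every null -> p = 1 by the add-one rule
        rng = np.random.default_rng(10)
        raw = 10 ** rng.normal(4.5, 0.3, size=(24, 5))
        y = np.array(["benign"] * 12 + ["malignant"] * 12)
        res = permutation_test(raw, y, n_components=1, n_perm=19, seed=3, folds=3)
        assert res.p_value <= 1.0
        assert res.p_value == (1 + np.sum(res.null_statistics
                                          >= res.observed_statistic)) / 20

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValidationError):
            permutation_test(np.ones((8, 2)), ["benign"] * 4 + ["malignant"] * 4,
                             n_perm=0)

    def test_strong_signal_is_significant(self):
        rng = np.random.default_rng(11)
        y = np.array(["benign"] * 56 + ["malignant"] * 22)
        logI = rng.normal(4.8, 0.15, size=(78, 15))
        logI[56:, :] += np.linspace(0.2, 0.4, 15)
        res = permutation_test(10**logI, y, n_components=2, n_perm=200,
                               seed=0, folds=5)
        assert res.p_value < 0.05
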