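"""PCA, OPLS-DA, cross-validation, correlation loadings, biomarker calls."""

import numpy as np
import pytest
from scipy import integrate, optimize
from scipy import stats as sstats

from sysmetab.chemometrics import (
    OPLSDA,
    PCAModel,
    ScalingSpec,
    critical_r,
    select_biomarkers,
)
from sysmetab.synthetic import template_bucket_map


def two_class_y(n_per=8):
    return np.array([0] * n_per + [1] * n_per)


class TestPCA:
    def test_rank_one_matrix_explains_everything(self, rng):
        X = np.outer(rng.normal(size=10), rng.normal(size=30))
        res = PCAModel(X, n_components=2, scaling=ScalingSpec(scaling="none")).fit()
        assert res.r2x[0] == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_samples_duplicate_scores(self, rng):
        X = rng.normal(size=(6, 20))
        X2 = np.vstack([X, X])
        res = PCAModel(X2, n_components=2, scaling=ScalingSpec(scaling="none")).fit()
        np.testing.assert_allclose(res.scores[:6], res.scores[6:], atol=1e-10)

    def test_matches_dense_svd_oracle_up_to_sign(self, rng):
        from sklearn.decomposition import PCA as SkPCA

        X = rng.normal(size=(10, 50))
        res = PCAModel(X, n_components=3, scaling=ScalingSpec(scaling="none")).fit()
        sk = SkPCA(n_components=3).fit(X)
        for j in range(3):
            ours, theirs = res.scores[:, j], sk.transform(X)[:, j]
            sign = np.sign(ours @ theirs)
            np.testing.assert_allclose(ours, sign * theirs, atol=1e-8)
        np.testing.assert_allclose(res.r2x, sk.explained_variance_ratio_, atol=1e-10)

    def test_zero_variance_matrix_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            PCAModel(np.ones((5, 4)), n_components=1, scaling=ScalingSpec(scaling="none")).fit()

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            PCAModel(np.eye(4), n_components=4)


class TestOPLSDA:
    def test_zero_orth_reduces_to_pls_weight_formula(self, rng):
        X = rng.normal(size=(16, 40))
        y = two_class_y()
        res = OPLSDA(X, y, n_orth=0).fit()
        Xs, _, _ = ScalingSpec().fit(X)
        yc = y - y.mean()
        t_direct = Xs @ (Xs.T @ yc)
        c = np.corrcoef(res.scores, t_direct)[0, 1]
        assert abs(c) == pytest.approx(1.0, abs=1e-10)

    def test_separated_classes_recovered_by_score_sign(self, rng):
        y = two_class_y()
        X = rng.normal(size=(16, 30)) + 5 * np.outer(y, rng.uniform(0.5, 1, 30))
        res = OPLSDA(X, y, n_orth=1).fit()
        t = res.scores
        sign = np.sign(t[y == 1].mean() - t[y == 0].mean())
        assert np.all(sign * t[y == 1] > sign * t[y == 0].max())

    def test_predictive_scores_orthogonal_to_orthogonal_scores(self, fitted_oplsda):
        res = fitted_oplsda
        for i in range(res.orth_scores.shape[1]):
            assert abs(res.scores @ res.orth_scores[:, i]) < 1e-8

    def test_sample_reordering_only_permutes_scores(self, rng):
        X = rng.normal(size=(16, 25)) + 2 * np.outer(two_class_y(), rng.uniform(0.5, 1, 25))
        y = two_class_y()
        perm = rng.permutation(16)
        res = OPLSDA(X, y, n_orth=1).fit()
        res_p = OPLSDA(X[perm], y[perm], n_orth=1).fit()
        dot = res.scores[perm] @ res_p.scores
        sign = np.sign(dot)
        np.testing.assert_allclose(res.scores[perm], sign * res_p.scores, atol=1e-8)

    def test_appended_orthogonal_noise_leaves_separation(self, rng):
        y = two_class_y()
        signal = rng.normal(size=(16, 30)) + 3 * np.outer(y, rng.uniform(0.5, 1, 30))

        def separation(X, n_orth):
            res = OPLSDA(X, y, n_orth=n_orth).fit()
            t = res.scores
            pooled = np.sqrt(0.5 * (t[y == 0].var(ddof=1) + t[y == 1].var(ddof=1)))
            return abs(t[y == 1].mean() - t[y == 0].mean()) / pooled

        base = separation(signal, 1)
        noise = np.outer(rng.normal(size=16), rng.uniform(0.5, 1, 10))
        with_noise = separation(np.hstack([signal, noise]), 2)
        assert with_noise == pytest.approx(base, rel=0.05)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            OPLSDA(rng.normal(size=(8, 5)), np.zeros(8))

    def test_excessive_orthogonal_components_rejected(self, rng):
        with pytest.raises(ValueError, match="n_orth"):
            OPLSDA(rng.normal(size=(6, 5)), two_class_y(3), n_orth=5)


class TestCrossValidation:
    def test_perfectly_predictive_matrix_gives_q2_one(self, rng):
        y = two_class_y()
        X = np.outer(y, rng.uniform(0.5, 2, 12))
        res = OPLSDA(X, y, n_orth=0, scaling=ScalingSpec(scaling="none")).fit()
        assert res.cross_validate(folds=4, seed=0) == pytest.approx(1.0, abs=1e-6)

    def test_permuted_labels_on_noise_give_nonpositive_q2(self):
        rng = np.random.default_rng(123)
        y0 = two_class_y(20)
        nonpositive = 0
        for _ in range(100):
            X = rng.normal(size=(40, 30))
            y = rng.permutation(y0)
            res = OPLSDA(X, y, n_orth=0).fit()
            if res.cross_validate(folds=7, seed=0) <= 0:
                nonpositive += 1
        assert nonpositive >= 90

    def test_q2_bounded_by_r2y(self, bucket_matrix):
        for case, ref in (("model", "control"), ("treated", "model")):
            res = OPLSDA.from_bucket_matrix(bucket_matrix, case, ref, n_orth=1).fit()
            q2 = res.cross_validate(folds=7, seed=0)
            assert q2 <= res.r2y <= 1.0

    def test_fold_without_both_classes_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        y = np.array([0, 0, 0, 0, 0, 1])
        res = OPLSDA(X, y, n_orth=0).fit()
        with pytest.raises(ValueError, match="class"):
            res.cross_validate(folds=6, seed=0)


class TestCriticalR:
    def test_published_threshold_at_n8(self):
        assert critical_r(8, 0.05) == pytest.approx(0.707, abs=5e-4)

    def test_alpha_to_one_limit(self):
        assert critical_r(8, 0.9999) < 1e-3

    def test_numeric_integration_oracle_at_n12(self):
        n = 12
        # null density of the sample correlation: f(r) prop (1-r^2)^((n-4)/2)
        norm, _ = integrate.quad(lambda r: (1 - r * r) ** ((n - 4) / 2), -1, 1)

        def upper_tail(r_star):
            v, _ = integrate.quad(lambda r: (1 - r * r) ** ((n - 4) / 2), r_star, 1)
            return 2 * v / norm

        oracle = optimize.brentq(lambda r: upper_tail(r) - 0.05, 1e-6, 1 - 1e-9)
        assert critical_r(12, 0.05) == pytest.approx(oracle, abs=1e-9)

    def test_tiny_n_rejected(self):
        with pytest.raises(ValueError):
            critical_r(2)


class TestCorrelationLoadings:
    def test_rank_one_matrix_has_unit_correlations(self, rng):
        y = two_class_y()
        X = np.outer(y, rng.uniform(0.5, 2, 10)) + 1.0
        res = OPLSDA(X, y, n_orth=0, scaling=ScalingSpec(scaling="none")).fit()
        cl = res.correlation_loadings()
        np.testing.assert_allclose(np.abs(cl.r), 1.0, atol=1e-10)

    def test_matches_naive_pearson_oracle(self, fitted_oplsda):
        res = fitted_oplsda
        cl = res.correlation_loadings()
        X = res.model.X
        t = res.scores * np.sign(res.q)  # class-oriented predictive scores
        for j in range(0, X.shape[1], 97):
            r_oracle = sstats.pearsonr(t, X[:, j]).statistic
            assert cl.r[j] == pytest.approx(r_oracle, abs=1e-12)

    def test_independent_noise_column_stays_subthreshold(self, rng):
        y = two_class_y()
        X = rng.normal(size=(16, 20)) + 4 * np.outer(y, rng.uniform(0.5, 1, 20))
        X[:, 0] = rng.normal(size=16)  # independent of the class structure
        res = OPLSDA(X, y, n_orth=0).fit()
        cl = res.correlation_loadings(threshold_n=16)
        assert abs(cl.r[0]) < cl.threshold

    def test_constant_column_warns_and_zeroes(self, rng):
        y = two_class_y()
        X = rng.normal(size=(16, 5)) + np.outer(y, np.ones(5))
        X[:, 2] = 3.14
        res = OPLSDA(X, y, n_orth=0).fit()
        with pytest.warns(UserWarning, match="constant"):
            cl = res.correlation_loadings()
        assert cl.r[2] == 0.0


class TestSelectBiomarkers:
    def test_planted_directions_recovered(self, bucket_matrix):
        res = OPLSDA.from_bucket_matrix(bucket_matrix, "treated", "model", n_orth=1).fit()
        cl = res.correlation_loadings(threshold_n=8)
        table = select_biomarkers(cl, template_bucket_map())
        directions = dict(zip(table.metabolite, table.direction))
        assert directions["Valine"] == "up"
        assert directions["Lactate"] == "up"
        assert directions["Lipids"] == "down"

    def test_model_contrast_directions(self, fitted_oplsda):
        cl = fitted_oplsda.correlation_loadings(threshold_n=8)
        table = select_biomarkers(cl, template_bucket_map())
        directions = dict(zip(table.metabolite, table.direction))
        assert directions["Valine"] == "down"
        assert directions["Lipids"] == "up"

    def test_no_bucket_passing_gives_empty_table(self, fitted_oplsda):
        cl = fitted_oplsda.correlation_loadings(threshold_n=8)
        cl.threshold = 1.1  # nothing can pass
        assert select_biomarkers(cl, template_bucket_map()).empty
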