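"""classifiers: fitting against sample-moment oracles, score formulas against
literal re-implementations, sklearn cross-checks, and decision invariances."""

import numpy as np
import pytest
from scipy import stats
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)

from puv_fcd import classifiers as clf
from puv_fcd.classifiers import ClassifierModel, FeatureScaler

from conftest import fit_all_kinds, random_gaussian_data


def random_model(rng, kind, d=3):
    """A ClassifierModel with random parameters (not fitted from data)."""
    mk_cov = lambda: (lambda a: a @ a.T + d * np.eye(d))(rng.standard_normal((d, d)))
    p = rng.uniform(0.2, 0.8)
    return ClassifierModel(
        kind=kind,
        means=rng.standard_normal((2, d)) * 2,
        priors=np.array([p, 1 - p]),
        nb_sds=rng.uniform(0.5, 2.0, size=(2, d)),
        pooled_cov=mk_cov(),
        class_covs=np.stack([mk_cov(), mk_cov()]),
    )


# ---------------------------------------------------------------------------
# Fitting

class TestFit:
    def test_sample_moments_recovered_exactly(self, rng):
        X, y = random_gaussian_data(rng, n=200, d=3)
        pos, neg = X[y == 1], X[y == 0]
        n = len(X)
        for kind in clf.KINDS:
            m = clf.fit(kind, X, y, ridge=0.0)
            np.testing.assert_allclose(m.means[0], pos.mean(axis=0))
            np.testing.assert_allclose(m.means[1], neg.mean(axis=0))
            np.testing.assert_allclose(
                m.priors, [len(pos) / n, len(neg) / n])
        nb = clf.fit("NB", X, y, ridge=0.0)
        np.testing.assert_allclose(nb.nb_sds[0], pos.std(axis=0, ddof=1))
        lda = clf.fit("LDA", X, y, ridge=0.0)
        s1 = np.cov(pos, rowvar=False)
        s2 = np.cov(neg, rowvar=False)
        pooled = ((len(pos) - 1) * s1 + (len(neg) - 1) * s2) / (n - 2)
        np.testing.assert_allclose(lda.pooled_cov, pooled)
        qda = clf.fit("QDA", X, y, ridge=0.0)
        np.testing.assert_allclose(qda.class_covs[0], np.atleast_2d(s1))

    def test_explicit_priors_respected(self, rng):
        X, y = random_gaussian_data(rng, n=100)
        m = clf.fit("LDA", X, y, priors=(0.5, 0.5))
        np.testing.assert_array_equal(m.priors, [0.5, 0.5])

    def test_single_class_errors(self, rng):
        X = rng.standard_normal((20, 2))
        with pytest.raises(ValueError, match="both classes"):
            clf.fit("NB", X, np.ones(20, dtype=int))

    def test_zero_variance_feature_named(self, rng):
        X = rng.standard_normal((30, 3))
        X[:, 1] = 5.0
        y = (np.arange(30) < 10).astype(int)
        with pytest.raises(ValueError, match="Fd3"):
            clf.fit("LDA", X, y, feature_names=("Fd1", "Fd3", "Fd4"))

    def test_too_few_samples(self, rng):
        X = rng.standard_normal((3, 3))
        with pytest.raises(ValueError, match="more samples than features"):
            clf.fit("QDA", X, np.array([1, 0, 1]))

    def test_unknown_kind(self, rng):
        X, y = random_gaussian_data(rng, n=50)
        with pytest.raises(ValueError, match="unknown classifier kind"):
            clf.fit("SVM", X, y)

    def test_json_round_trip(self, tmp_path, rng):
        models, X, _ = fit_all_kinds(rng, n=120)
        for kind, m in models.items():
            p = tmp_path / f"{kind}.json"
            m.to_json(p)
            back = ClassifierModel.from_json(p)
            np.testing.assert_allclose(
                clf.score(back, X[:20]), clf.score(m, X[:20]), atol=1e-12)


# ---------------------------------------------------------------------------
# Score formulas against literal oracles

class TestScoreOracles:
    def test_nb_matches_density_product(self, rng):
        m = random_model(rng, "NB")
        X = rng.standard_normal((50, 3)) * 2
        like = []
        for i in range(2):
            pdf = np.prod(stats.norm.pdf(X, m.means[i], m.nb_sds[i]), axis=1)
            like.append(pdf * m.priors[i])
        np.testing.assert_allclose(clf.nb_score(m, X),
                                   np.log(like[0]) - np.log(like[1]), atol=1e-9)

    def test_lda_matches_discriminant_formula(self, rng):
        m = random_model(rng, "LDA")
        X = rng.standard_normal((50, 3)) * 2
        inv = np.linalg.inv(m.pooled_cov)
        g = [X @ inv @ m.means[i] - 0.5 * m.means[i] @ inv @ m.means[i]
             + np.log(m.priors[i]) for i in range(2)]
        np.testing.assert_allclose(clf.lda_score(m, X), g[0] - g[1], atol=1e-9)

    def test_qda_full_matches_log_gaussian(self, rng):
        m = random_model(rng, "QDA")
        X = rng.standard_normal((50, 3)) * 2
        logpost = [stats.multivariate_normal.logpdf(X, m.means[i], m.class_covs[i])
                   + np.log(m.priors[i]) for i in range(2)]
        got = clf.qda_score(m, X, variant="full")
        # both omit only the shared -d/2 log(2 pi) constant, which cancels
        np.testing.assert_allclose(got, logpost[0] - logpost[1], atol=1e-9)

    def test_qda_printed_matches_linear_terms(self, rng):
        m = random_model(rng, "QDA")
        X = rng.standard_normal((50, 3)) * 2
        g = []
        for i in range(2):
            inv = np.linalg.inv(m.class_covs[i])
            g.append(X @ inv @ m.means[i] - 0.5 * m.means[i] @ inv @ m.means[i]
                     + np.log(m.priors[i]))
        np.testing.assert_allclose(clf.qda_score(m, X, variant="printed"),
                                   g[0] - g[1], atol=1e-9)

    def test_mda_matches_mahalanobis_difference(self, rng):
        m = random_model(rng, "MDA")
        X = rng.standard_normal((50, 3)) * 2
        inv = np.linalg.inv(m.pooled_cov)
        d = [np.einsum("nd,de,ne->n", X - m.means[i], inv, X - m.means[i])
             for i in range(2)]
        np.testing.assert_allclose(clf.mda_score(m, X), d[1] - d[0], atol=1e-9)

    def test_kind_mismatch_rejected(self, rng):
        m = random_model(rng, "NB")
        with pytest.raises(ValueError, match="expected a LDA model"):
            clf.lda_score(m, np.zeros((1, 3)))


class TestLabelBasics:
    def test_class_mean_is_labeled_its_class(self, rng):
        m = random_model(rng, "MDA")
        assert clf.mda_label(m, m.means[0:1])[0] == 1
        assert clf.mda_label(m, m.means[1:2])[0] == 0

    def test_mda_tie_resolves_negative(self):
        m = ClassifierModel(kind="MDA", means=np.array([[1.0], [-1.0]]),
                            priors=np.array([0.5, 0.5]),
                            pooled_cov=np.eye(1))
        assert clf.mda_label(m, np.array([[0.0]]))[0] == 0

    def test_lda_equal_setup_is_nearest_mean(self, rng):
        m = ClassifierModel(kind="LDA", means=np.array([[2.0, 0.0], [-2.0, 0.0]]),
                            priors=np.array([0.5, 0.5]), pooled_cov=np.eye(2))
        X = rng.standard_normal((100, 2)) * 3
        nearest = (np.linalg.norm(X - m.means[0], axis=1)
                   < np.linalg.norm(X - m.means[1], axis=1))
        np.testing.assert_array_equal(clf.lda_label(m, X).astype(bool), nearest)

    def test_nb_prior_dominance(self):
        base = dict(means=np.zeros((2, 1)), nb_sds=np.ones((2, 1)))
        tilted = ClassifierModel(kind="NB", priors=np.array([0.9, 0.1]), **base)
        x = np.array([[0.3]])
        assert clf.nb_label(tilted, x)[0] == 1   # identical likelihoods: prior wins

    def test_mda_ignores_priors(self, rng):
        m = random_model(rng, "MDA")
        skew = ClassifierModel(kind="MDA", means=m.means,
                               priors=np.array([0.99, 0.01]),
                               pooled_cov=m.pooled_cov)
        X = rng.standard_normal((200, 3))
        np.testing.assert_array_equal(clf.mda_label(m, X), clf.mda_label(skew, X))


# ---------------------------------------------------------------------------
# Identities and invariances

class TestIdentities:
    def test_mda_equals_lda_at_equal_priors(self, rng):
        X, y = random_gaussian_data(rng, n=300)
        lda = clf.fit("LDA", X, y, priors=(0.5, 0.5))
        mda = clf.fit("MDA", X, y)
        pts = rng.standard_normal((500, 3)) * 3
        np.testing.assert_allclose(clf.mda_score(mda, pts),
                                   2.0 * clf.lda_score(lda, pts), atol=1e-9)
        np.testing.assert_array_equal(clf.mda_label(mda, pts),
                                      clf.lda_label(lda, pts))

    def test_full_qda_equals_lda_at_equal_covariances(self, rng):
        lda = random_model(rng, "LDA")
        qda = ClassifierModel(kind="QDA", means=lda.means, priors=lda.priors,
                              class_covs=np.stack([lda.pooled_cov] * 2))
        pts = rng.standard_normal((500, 3)) * 3
        np.testing.assert_allclose(clf.qda_score(qda, pts, "full"),
                                   clf.lda_score(lda, pts), atol=1e-9)

    def test_labels_affine_invariant(self, rng):
        X, y = random_gaussian_data(rng, n=400, d=3)
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        b = rng.standard_normal(3)
        pts = rng.standard_normal((300, 3)) * 3
        for kind in clf.KINDS:
            m0 = clf.fit(kind, X, y, ridge=0.0)
            m1 = clf.fit(kind, X @ A.T + b, y, ridge=0.0)
            if kind == "NB":
                continue  # NB's diagonal model is only scale-invariant
            np.testing.assert_array_equal(
                clf.predict_label(m0, pts),
                clf.predict_label(m1, pts @ A.T + b))

    def test_nb_labels_scaling_invariant(self, rng):
        X, y = random_gaussian_data(rng, n=400, d=3)
        scale = np.array([0.1, 3.0, 20.0])
        m0 = clf.fit("NB", X, y, ridge=0.0)
        m1 = clf.fit("NB", X * scale, y, ridge=0.0)
        pts = rng.standard_normal((300, 3)) * 3
        np.testing.assert_array_equal(clf.nb_label(m0, pts),
                                      clf.nb_label(m1, pts * scale))


# ---------------------------------------------------------------------------
# sklearn cross-checks (independent implementations)

class TestSklearnAgreement:
    def test_lda_decision_close_to_sklearn(self, rng):
        X, y = random_gaussian_data(rng, n=2000, d=3, sep=3.0)
        ours = clf.fit("LDA", X, y, ridge=0.0)
        sk = LinearDiscriminantAnalysis(solver="svd").fit(X, y)
        pts, _ = random_gaussian_data(rng, n=2000, d=3, sep=3.0)
        agree = (clf.lda_label(ours, pts) == sk.predict(pts)).mean()
        assert agree >= 0.99   # denominators differ (n-2 vs n); boundary only

    def test_qda_decision_close_to_sklearn(self, rng):
        X, y = random_gaussian_data(rng, n=2000, d=3, sep=3.0)
        ours = clf.fit("QDA", X, y, ridge=0.0)
        sk = QuadraticDiscriminantAnalysis(store_covariance=True).fit(X, y)
        pts, _ = random_gaussian_data(rng, n=2000, d=3, sep=3.0)
        agree = (clf.qda_label(ours, pts) == sk.predict(pts)).mean()
        assert agree >= 0.99


# ---------------------------------------------------------------------------
# Subsampling and scaling

class TestSubsample:
    def test_caps_negatives(self, rng):
        X = rng.standard_normal((1000, 2))
        y = np.zeros(1000, dtype=int)
        y[:20] = 1
        Xs, ys = clf.subsample_negatives(X, y, rng, neg_per_pos=10)
        assert (ys == 1).sum() == 20 and (ys == 0).sum() == 200

    def test_noop_below_cap(self, rng):
        X = rng.standard_normal((50, 2))
        y = (np.arange(50) < 25).astype(int)
        Xs, ys = clf.subsample_negatives(X, y, rng, neg_per_pos=10)
        np.testing.assert_array_equal(Xs, X)

    def test_keeps_all_positives(self, rng):
        X = np.arange(300, dtype=float).reshape(-1, 1)
        y = (X[:, 0] % 29 == 0).astype(int)
        Xs, ys = clf.subsample_negatives(X, y, rng, neg_per_pos=5)
        assert set(X[y == 1, 0]) <= set(Xs[:, 0])

    def test_deterministic_per_seed(self):
        X = np.arange(500, dtype=float).reshape(-1, 1)
        y = (X[:, 0] < 10).astype(int)
        a, _ = clf.subsample_negatives(X, y, np.random.default_rng(1), 10)
        b, _ = clf.subsample_negatives(X, y, np.random.default_rng(1), 10)
        np.testing.assert_array_equal(a, b)


class TestScaler:
    def test_zero_mean_unit_sd(self, rng):
        X = rng.standard_normal((200, 3)) * np.array([1.0, 10.0, 0.1]) + 5
        Z = FeatureScaler().fit(X).transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)

    def test_constant_feature_passthrough(self, rng):
        X = np.column_stack([rng.standard_normal(50), np.full(50, 3.0)])
        Z = FeatureScaler().fit(X).transform(X)
        np.testing.assert_allclose(Z[:, 1], 0.0)
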