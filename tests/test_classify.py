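import numpy as np
import pytest
from sklearn.svm import SVC

from chaolle.classify import (GRBFParams, GRBFSVC, cross_validated_accuracy,
                              grbf_gram, grbf_kernel, median_heuristic_sigma,
                              paired_feature_ttest, split_70_25_5,
                              train_smsvm)


def _two_gaussians(n=100, sep=2.5, seed=0, d=2):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n, d)), rng.normal(sep, 1, (n, d))])
    y = np.r_[np.zeros(n, dtype=int), np.ones(n, dtype=int)]
    return X, y


class TestKernel:
    def test_tau2_is_standard_rbf(self):
        x, z = np.array([0.3, -1.0]), np.array([1.2, 0.4])
        sigma = 0.8
        expected = np.exp(-np.sum((x - z) ** 2) / (2 * sigma ** 2))
        assert grbf_kernel(x, z, GRBFParams(sigma, 2.0)) == pytest.approx(expected)

    def test_self_similarity_is_one(self):
        x = np.array([1.0, 2.0, 3.0])
        for tau in (0.5, 1.0, 2.0):
            assert grbf_kernel(x, x, GRBFParams(1.7, tau)) == 1.0

    def test_laplacian_case_value(self):
        assert grbf_kernel([0.0], [1.0], GRBFParams(1.0, 1.0)) == \
            pytest.approx(np.exp(-0.5))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GRBFParams(sigma=0.0)
        with pytest.raises(ValueError, match="tau"):
            GRBFParams(sigma=1.0, tau=3.0)
        with pytest.raises(ValueError, match="tau"):
            GRBFParams(sigma=1.0, tau=-1.0)

    @pytest.mark.parametrize("tau", [0.5, 1.0, 1.5, 2.0])
    def test_gram_symmetric_unit_diagonal(self, tau):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (30, 3))
        K = grbf_gram(X, X, GRBFParams(1.3, tau, center=0.7))
        np.testing.assert_allclose(K, K.T, atol=1e-14)
        np.testing.assert_allclose(np.diag(K), 1.0)
        # Mercer check: PSD up to numerical noise
        assert np.linalg.eigvalsh(K).min() > -1e-10


class TestGRBFSVC:
    def test_separable_toy_perfect_training_accuracy(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        model = GRBFSVC(C=10.0, sigma=1.0).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            GRBFSVC().fit(np.zeros((4, 1)), np.zeros(4))

    def test_decision_values_match_reference_rbf_at_tau2(self):
        X, y = _two_gaussians(40)
        sigma = 1.3
        ours = GRBFSVC(C=1.0, sigma=sigma, tau=2.0).fit(X, y)
        ref = SVC(C=1.0, kernel="rbf", gamma=1 / (2 * sigma ** 2)).fit(X, y)
        Xt = _two_gaussians(25, seed=9)[0]
        np.testing.assert_allclose(ours.decision_function(Xt),
                                   ref.decision_function(Xt), atol=1e-6)

    def test_generalization_on_planted_gaussians(self):
        X, y = _two_gaussians(100)
        Xt, yt = _two_gaussians(100, seed=3)
        sigma = median_heuristic_sigma(X)
        model = train_smsvm(X, y, C=1.0, params=GRBFParams(sigma, 2.0))
        assert np.mean(model.predict(Xt) == yt) > 0.9

    def test_dual_coefficients_within_box(self):
        X, y = _two_gaussians(50, sep=1.0)
        C = 0.7
        model = GRBFSVC(C=C, sigma=1.0).fit(X, y)
        assert np.all(np.abs(model.dual_coef_) <= C + 1e-12)

    def test_sklearn_get_set_params_roundtrip(self):
        m = GRBFSVC(C=2.0, sigma=0.5, tau=1.5)
        params = m.get_params()
        m2 = GRBFSVC().set_params(**params)
        assert m2.get_params() == params


class TestSplit:
    def test_100_rows_exact_70_25_5(self):
        y = np.r_[np.zeros(50), np.ones(50)]
        tr, te, va = split_70_25_5(y, seed=0)
        assert (len(tr), len(te), len(va)) == (70, 25, 5)

    def test_40_rows_largest_remainder(self):
        y = np.r_[np.zeros(20), np.ones(20)]
        tr, te, va = split_70_25_5(y, seed=0)
        assert (len(tr), len(te), len(va)) == (28, 10, 2)

    def test_deterministic_and_partition(self):
        y = np.r_[np.zeros(31), np.ones(44)]
        a = split_70_25_5(y, seed=7)
        b = split_70_25_5(y, seed=7)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa, pb)
        allidx = np.concatenate(a)
        assert len(allidx) == 75
        assert len(np.unique(allidx)) == 75

    def test_stratified_by_label(self):
        y = np.r_[np.zeros(60), np.ones(40)]
        tr, te, va = split_70_25_5(y, seed=1)
        assert np.sum(y[tr] == 0) == 42 and np.sum(y[tr] == 1) == 28

    def test_too_small_inputs_raise(self):
        with pytest.raises(ValueError, match="20 rows"):
            split_70_25_5(np.zeros(10))
        with pytest.raises(ValueError, match="fewer than 3"):
            split_70_25_5(np.r_[np.zeros(19), np.ones(2)])


class TestPairedTTest:
    def test_identical_arrays_degenerate(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_feature_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_constant_shift_degenerate(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero-variance"):
            paired_feature_ttest(a + 1.0, a)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 30), rng.normal(0.3, 1, 30)
        from scipy import stats
        t, p = paired_feature_ttest(a, b)
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(t_ref) and p == pytest.approx(p_ref)

    def test_power_for_half_sigma_shift(self):
        # a 0.5 sd paired shift: power ~0.59 at n=20 and ~0.93 at n=50
        # (both frozen from brute-force simulation)
        def power(n):
            hits = 0
            for seed in range(100):
                rng = np.random.default_rng(seed)
                b = rng.normal(0, 1, n)
                a = b + rng.normal(0.5, 1, n)
                hits += paired_feature_ttest(a, b)[1] < 0.05
            return hits
        assert 40 <= power(20) <= 75
        assert power(50) >= 85


class TestCrossValidatedAccuracy:
    def test_separable_is_perfect(self):
        X, y = _two_gaussians(50, sep=8.0)
        acc = cross_validated_accuracy(X, y, k=5, seed=0)
        assert acc == 1.0

    def test_reproducible(self):
        X, y = _two_gaussians(60, sep=1.0)
        assert cross_validated_accuracy(X, y, seed=4) == \
            cross_validated_accuracy(X, y, seed=4)

    def test_null_labels_near_chance(self):
        X, _ = _two_gaussians(100, sep=0.0)
        in_range = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, len(X))
            if len(np.unique(y)) < 2:
                continue
            acc = cross_validated_accuracy(X, y, k=5, seed=seed)
            in_range += 0.4 <= acc <= 0.6
        assert in_range >= 8

    def test_invalid_k_raises(self):
        X, y = _two_gaussians(20)
        with pytest.raises(ValueError):
            cross_validated_accuracy(X, y, k=1)
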