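import numpy as np
import pytest

from nirselect.pls import (
    RankError,
    cross_validate,
    galtier_verdict,
    pca_kaiser,
    pls_fit,
    set_accuracy,
)


class TestPlsFit:
    def test_exact_recovery_rank_one_signal(self):
        # X carries a single latent direction and y is linear in it, so one
        # component reproduces the response exactly
        rng = np.random.default_rng(0)
        t_lat = rng.normal(size=20)
        X = np.outer(t_lat, rng.normal(size=6))
        y = 2.0 * t_lat + 1.0
        model = pls_fit(X, y, 1)
        assert np.sqrt(np.mean((model.predict(X) - y) ** 2)) < 1e-8

    def test_full_rank_equals_least_squares(self):
        # 8x3 toy: at A = rank(X), PLS reproduces the normal-equations fit
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        model = pls_fit(X, y, 3)
        Xd = np.column_stack([np.ones(8), X])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        assert np.allclose(model.predict(X), Xd @ beta, atol=1e-8)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 8))
        y = rng.normal(size=15)
        perm = rng.permutation(15)
        b1 = pls_fit(X, y, 3).coef
        b2 = pls_fit(X[perm], y[perm], 3).coef
        assert np.allclose(b1, b2, atol=1e-10)

    def test_training_rmse_monotone_in_components(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 10))
        y = X @ rng.normal(size=10) + 0.3 * rng.normal(size=25)
        rmse = []
        for A in range(1, 8):
            m = pls_fit(X, y, A)
            rmse.append(np.sqrt(np.mean((m.predict(X) - y) ** 2)))
        assert all(a >= b - 1e-12 for a, b in zip(rmse, rmse[1:]))

    def test_rank_deficiency_names_achievable_rank(self):
        X = np.zeros((10, 4))
        X[:, 0] = np.arange(10)
        y = np.arange(10, dtype=float)
        with pytest.raises(RankError, match="rank"):
            pls_fit(X, y, 3)

    def test_matches_independent_pls_implementation(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 12))
        y = X @ rng.normal(size=12) + rng.normal(size=30)
        ours = pls_fit(X, y, 4)
        ref = PLSRegression(n_components=4, scale=False).fit(X, y)
        assert np.allclose(ours.coef, ref.coef_.ravel(), atol=1e-8)
        assert np.allclose(ours.predict(X), ref.predict(X).ravel(), atol=1e-8)


class TestCrossValidate:
    def test_constant_response(self):
        X = np.random.default_rng(0).normal(size=(12, 4))
        m = cross_validate(X, np.full(12, 3.0), 2, folds=4, seed=0)
        assert m.rmsecv == 0.0

    def test_noiseless_linear_generalizes(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 1))
        y = X[:, 0] * 1.5 + 2.0
        m = cross_validate(X, y, 1, folds=5, seed=0)
        assert m.rmsecv < 1e-6

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 8))
        y = (np.arange(30) % 5 + 1).astype(float)
        a = cross_validate(X, y, 3, folds=10, seed=7)
        b = cross_validate(X, y, 3, folds=10, seed=7)
        assert a.rmsecv == b.rmsecv and a.r2 == b.r2

    def test_rmsep_on_validation_set(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        y = X[:, 1] * 2.0
        m = cross_validate(X, y, 5, folds=5, seed=0, X_val=X[:5], y_val=y[:5])
        assert m.rmsep == pytest.approx(0.0, abs=1e-8)


class TestPcaKaiser:
    def test_independent_columns_eigenvalues_near_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5000, 8))
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        _, eig, k = pca_kaiser(X)
        assert np.all(np.abs(eig - 1.0) < 0.1)

    def test_matches_exact_eigendecomposition_with_duplicate_column(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 4))
        X = np.column_stack([X, X[:, 0]])  # duplicated column
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        _, eig, k = pca_kaiser(Xs)
        ref = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
        assert np.allclose(eig, ref, atol=1e-8)
        assert eig[0] >= 2.0 - 1e-8  # duplicate pair carries eigenvalue >= 2
        assert k == int(np.sum(ref >= 1.0))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pca_kaiser(np.zeros((2, 3)))


class TestGaltierRule:
    @pytest.mark.parametrize(
        "candidate,y_pre,y_dev,expected",
        [
            (1, 1.782, 0.553, "suspicious"),
            (1, 0.380, 0.438, "uncredited"),
            (2, 2.084, 0.059, "ok"),
            (3, 3.000, 0.000, "ok"),
            (2, 2.635, 0.450, "suspicious"),   # deviation exactly at the limit
            (5, 5.653, 0.462, "suspicious"),   # above the code range, noisy
            (1, 1.629, 0.445, "ok"),           # just under the deviation limit
        ],
    )
    def test_flags(self, candidate, y_pre, y_dev, expected):
        v = galtier_verdict(candidate, y_pre, y_dev)
        assert v.flag == expected

    def test_negative_deviation_rejected(self):
        with pytest.raises(ValueError):
            galtier_verdict(1, 1.0, -0.1)

    def test_set_accuracy_all_correct(self):
        verdicts = [galtier_verdict(c, float(c), 0.01) for c in (1, 2, 3, 4, 5)]
        assert set_accuracy(verdicts, np.array([1, 2, 3, 4, 5])) == 100.00

    def test_set_accuracy_counts_flags_and_mismatches(self):
        verdicts = [
            galtier_verdict(1, 1.0, 0.01),
            galtier_verdict(2, 2.0, 0.60),  # suspicious
            galtier_verdict(3, 3.0, 0.01),
        ]
        assert set_accuracy(verdicts, np.array([1, 2, 2])) == pytest.approx(33.33)
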