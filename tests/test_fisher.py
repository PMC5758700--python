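import numpy as np
import pytest

from nirselect.fisher import (
    FisherModel,
    FitError,
    fisher_classify,
    fisher_fit,
    loo_cross_validate,
    resubstitution,
    stepwise_select,
    wilks_lambda,
)


def five_class_data(seed: int = 0, n_per_class: int = 8, p_noise: int = 6, sd: float = 0.3):
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(1, 6), n_per_class)
    n = labels.size
    centers = rng.normal(scale=2.0, size=(5, 3))
    X_sig = centers[labels - 1] + sd * rng.normal(size=(n, 3))
    X = np.column_stack([X_sig, rng.normal(size=(n, p_noise))])
    return X, labels


class TestStepwise:
    def test_perfect_separator_enters_first(self):
        rng = np.random.default_rng(0)
        labels = np.repeat(np.arange(1, 6), 6)
        X = rng.normal(size=(30, 8))
        X[:, 5] = labels * 10.0 + 0.01 * rng.normal(size=30)  # dominant separator
        retained, trace = stepwise_select(X, labels)
        assert retained[0] == 5
        assert trace.rows[0]["action"] == "enter"

    def test_infinite_entry_threshold_empty(self):
        X, labels = five_class_data()
        with pytest.warns(UserWarning, match="f_enter"):
            retained, _ = stepwise_select(X, labels, f_enter=np.inf)
        assert retained.size == 0

    def test_wilks_lambda_non_increasing_along_entries(self):
        X, labels = five_class_data(1)
        _, trace = stepwise_select(X, labels)
        lams = [r["wilks_lambda"] for r in trace.rows if r["action"] == "enter"]
        assert all(a >= b - 1e-12 for a, b in zip(lams, lams[1:]))

    def test_lambda_definition_on_univariate_anova(self):
        # det ratio reduces to SSW/SST in one dimension
        rng = np.random.default_rng(2)
        labels = np.repeat([1, 2], 10)
        x = rng.normal(size=20) + (labels == 2) * 3.0
        ssw = sum(((x[labels == c] - x[labels == c].mean()) ** 2).sum() for c in (1, 2))
        sst = ((x - x.mean()) ** 2).sum()
        assert wilks_lambda(x[:, None], labels) == pytest.approx(ssw / sst)

    def test_wavenumber_mapping(self):
        X, labels = five_class_data(3)
        wn = 4000.0 + 10.0 * np.arange(X.shape[1])
        retained, trace = stepwise_select(X, labels, wavenumbers=wn)
        assert set(retained) <= set(wn)


class TestFisherFit:
    def test_two_class_boundary_at_zero(self):
        x = np.concatenate([np.full(10, -1.0), np.full(10, 1.0)])
        x += 0.01 * np.random.default_rng(0).normal(size=20)
        labels = np.repeat([1, 2], 10)
        model = fisher_fit(x[:, None], labels)
        assert fisher_classify(model, np.array([[-0.2]]))[0] == 1
        assert fisher_classify(model, np.array([[0.2]]))[0] == 2

    def test_argmax_score_equals_mahalanobis_argmin(self):
        rng = np.random.default_rng(1)
        X, labels = five_class_data(1, p_noise=1)
        model = fisher_fit(X, labels)
        pts = rng.normal(scale=2.0, size=(200, X.shape[1]))
        pred = fisher_classify(model, pts)
        Winv = np.linalg.inv(model.pooled_cov)
        d2 = np.array(
            [[(q - m) @ Winv @ (q - m) for m in model.centroids] for q in pts]
        )
        oracle = np.asarray(model.classes)[np.argmin(d2, axis=1)]
        assert np.array_equal(pred, oracle)

    def test_feature_shift_invariance(self):
        X, labels = five_class_data(2)
        model_a = fisher_fit(X, labels)
        model_b = fisher_fit(X + 7.5, labels)
        pts = np.random.default_rng(3).normal(size=(50, X.shape[1]))
        assert np.array_equal(
            fisher_classify(model_a, pts), fisher_classify(model_b, pts + 7.5)
        )

    def test_centroids_classified_to_own_class(self):
        X, labels = five_class_data(4)
        model = fisher_fit(X, labels)
        assert np.array_equal(fisher_classify(model, model.centroids), model.classes)

    def test_tie_breaks_to_lower_code(self):
        model = fisher_fit(
            np.array([[-1.1], [-0.9], [0.9], [1.1]]), np.array([1, 1, 2, 2])
        )
        assert fisher_classify(model, np.array([[0.0]]))[0] == 1

    def test_small_class_rejected(self):
        with pytest.raises(FitError):
            fisher_fit(np.zeros((3, 2)), np.array([1, 1, 2]))

    def test_wrong_dimension_rejected(self):
        X, labels = five_class_data(5)
        model = fisher_fit(X, labels)
        with pytest.raises(FitError):
            model.scores(np.zeros((1, X.shape[1] + 1)))


class TestValidation:
    def test_noise_free_separation_gives_perfect_loo(self):
        X, labels = five_class_data(6, sd=0.01, p_noise=0)
        acc, conf = loo_cross_validate(X, labels)
        assert acc == 100.00

    def test_confusion_rows_sum_to_class_counts(self):
        X, labels = five_class_data(7, sd=1.5)
        _, conf = loo_cross_validate(X, labels)
        for c in np.unique(labels):
            assert conf.loc[c].sum() == np.sum(labels == c)

    def test_resubstitution_not_worse_than_loo(self):
        X, labels = five_class_data(8, sd=1.0)
        r, _ = resubstitution(X, labels)
        l, _ = loo_cross_validate(X, labels)
        assert r >= l

    def test_too_small_for_loo(self):
        with pytest.raises(FitError):
            loo_cross_validate(np.zeros((6, 2)), np.array([1, 1, 2, 2, 3, 3]))


def test_model_json_round_trip(tmp_path):
    X, labels = five_class_data(9)
    wn = 4000.0 + 3.857 * np.arange(X.shape[1])
    model = fisher_fit(X, labels, wavenumbers=wn)
    model.to_json(tmp_path / "m.json")
    back = FisherModel.from_json(tmp_path / "m.json")
    pts = np.random.default_rng(10).normal(size=(40, X.shape[1]))
    assert np.array_equal(fisher_classify(model, pts), fisher_classify(back, pts))
    assert back.wavenumbers == model.wavenumbers
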