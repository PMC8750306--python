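"""PCA, PLS-DA (with independent oracles), VIP, outliers, SVM, metrics, LCO."""

import numpy as np
import pytest

from meatspec.discriminant import (
    ConfusionMatrix,
    SVMSpec,
    evaluate_on_split,
    fit_pca,
    fit_plsda,
    leave_class_out,
    metrics,
    outlier_flags,
    tune_svm,
    vip_scores,
)
from meatspec.errors import ConfigError, FitError, ValidationError


class TestPCA:
    def test_line_in_3d_fully_explained_by_pc1(self, rng):
        t = rng.normal(size=40)
        X = np.outer(t, [1.0, -2.0, 0.5]) + np.array([3.0, 1.0, -1.0])
        model = fit_pca(X, 1)
        np.testing.assert_allclose(model.explained_variance_fraction[0], 1.0, atol=1e-9)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(15, 6))
        model = fit_pca(X, 6)
        np.testing.assert_allclose(model.reconstruct(model.scores), X, atol=1e-9)

    def test_scores_orthogonal(self, rng):
        X = rng.normal(size=(30, 8))
        model = fit_pca(X, 4)
        G = model.scores.T @ model.scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)

    def test_components_beyond_rank_error(self, rng):
        t = rng.normal(size=20)
        X = np.outer(t, np.ones(5))
        with pytest.raises(FitError):
            fit_pca(X, 2)


def _simpls(X, Y, a_max):
    """Independent SIMPLS oracle (de Jong) for cross-checking predictions."""
    X = np.asarray(X, float)
    Y = np.atleast_2d(np.asarray(Y, float))
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xm, Y - ym
    S = X0.T @ Y0
    R = np.zeros((X.shape[1], a_max))
    V = np.zeros((X.shape[1], a_max))
    Q = np.zeros((Y.shape[1], a_max))
    for a in range(a_max):
        _, _, c = np.linalg.svd(S.T, full_matrices=False)
        r = c[0]
        t = X0 @ r
        t -= t.mean()
        nt = np.linalg.norm(t)
        t /= nt
        r /= nt
        p = X0.T @ t
        q = Y0.T @ t
        v = p.copy()
        for j in range(a):
            v -= V[:, j] * (V[:, j] @ p)
        v /= np.linalg.norm(v)
        S -= np.outer(v, v @ S)
        R[:, a], V[:, a], Q[:, a] = r, v, q
    B = R @ Q.T
    return lambda Xn: (np.atleast_2d(Xn) - xm) @ B + ym


class TestPLSDA:
    def test_separable_two_class_selects_one_lv(self, rng):
        x = np.concatenate([rng.uniform(-2, -1, 20), rng.uniform(1, 2, 20)])
        X = np.column_stack([x, rng.normal(size=40)])
        labels = ["neg"] * 20 + ["pos"] * 20
        model = fit_plsda(X, labels, max_lv=2, cv_scheme="kfold", cv_params={"k": 5}, seed=0)
        assert model.n_lv == 1
        assert model.cv_error_curve[0] == 0.0
        assert np.all(model.predict(X) == np.asarray(labels, dtype=object))

    def test_full_rank_equals_indicator_least_squares(self, rng):
        # at maximal rank PLS2 reproduces the ordinary least-squares fit
        for trial in range(5):
            X = rng.normal(size=(20, 8))
            labels = [f"c{i % 4}" for i in range(20)]
            model = fit_plsda(X, labels, max_lv=8, cv_scheme="kfold", cv_params={"k": 4}, seed=trial)
            from meatspec.discriminant import _coef_for_lv, indicator_matrix

            B = _coef_for_lv(model.x_weights, model.x_loadings, model.y_loadings, 8)
            Y = indicator_matrix(labels, model.classes)
            Xc = X - X.mean(axis=0)
            B_ls = np.linalg.lstsq(Xc, Y - Y.mean(axis=0), rcond=None)[0]
            np.testing.assert_allclose(
                Xc @ B, Xc @ B_ls, atol=1e-8
            )

    def test_nipals_matches_simpls_on_two_class_instances(self, rng):
        # with a 2-class indicator (rank-1 response) NIPALS and SIMPLS agree
        X = rng.normal(size=(16, 10))
        labels = ["a"] * 8 + ["b"] * 8
        model = fit_plsda(X, labels, max_lv=3, cv_scheme="kfold", cv_params={"k": 4}, seed=0)
        from meatspec.discriminant import _coef_for_lv, indicator_matrix

        Y = indicator_matrix(labels, model.classes)
        oracle = _simpls(X, Y, model.n_lv)
        B = _coef_for_lv(model.x_weights, model.x_loadings, model.y_loadings, model.n_lv)
        ours = (X - X.mean(axis=0)) @ B + Y.mean(axis=0)
        np.testing.assert_allclose(ours, oracle(X), atol=1e-8)

    def test_label_permutation_gives_chance_error(self, rng):
        X = rng.normal(size=(80, 12))
        labels = list(rng.permutation(["a", "b", "c", "d"] * 20))
        model = fit_plsda(X, labels, max_lv=3, cv_scheme="kfold", cv_params={"k": 5}, seed=0)
        # 4 balanced random classes → error ≈ 0.75; allow generous binomial slack
        assert abs(min(model.cv_error_curve) - 0.75) < 0.18

    def test_max_lv_exceeding_rows_error(self, rng):
        with pytest.raises(ConfigError):
            fit_plsda(rng.normal(size=(5, 3)), ["a", "b", "a", "b", "a"], max_lv=5)


class TestVIP:
    def test_sum_of_squares_identity(self, rng):
        X = rng.normal(size=(30, 15))
        labels = ["a", "b", "c"] * 10
        model = fit_plsda(X, labels, max_lv=4, cv_scheme="kfold", cv_params={"k": 5}, seed=0)
        v = vip_scores(model)
        np.testing.assert_allclose((v**2).sum(), 15.0, atol=1e-6)

    def test_informative_variable_scores_above_one(self, rng):
        signal = np.concatenate([np.zeros(25), np.ones(25)])
        X = rng.normal(scale=1.0, size=(50, 20))
        X[:, 0] = signal * 4 + rng.normal(scale=0.1, size=50)
        labels = ["a"] * 25 + ["b"] * 25
        model = fit_plsda(X, labels, max_lv=2, cv_scheme="kfold", cv_params={"k": 5}, seed=0)
        v = vip_scores(model)
        assert v[0] > 1.0
        assert v[0] == v.max()

    def test_uniform_weights_give_unit_vip(self, rng):
        t = np.concatenate([-np.ones(10), np.ones(10)]) + rng.normal(0, 0.01, 20)
        X = np.outer(t, np.ones(6))
        labels = ["a"] * 10 + ["b"] * 10
        model = fit_plsda(X, labels, max_lv=1, cv_scheme="kfold", cv_params={"k": 4}, seed=0)
        np.testing.assert_allclose(vip_scores(model), 1.0, atol=1e-9)


class TestOutlierFlags:
    def test_training_mean_row_not_flagged(self, rng):
        X = rng.normal(size=(60, 10))
        model = fit_pca(X, 3)
        fl = outlier_flags(model, X.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(fl.t2, 0.0, atol=1e-12)
        assert not fl.flags[0]

    def test_huge_orthogonal_residual_flagged_by_q(self, rng):
        X = rng.normal(size=(60, 10))
        model = fit_pca(X, 3)
        resid_dir = np.zeros(10)
        # direction orthogonal to the retained components
        basis = model.loadings
        v = rng.normal(size=10)
        v -= basis.T @ (basis @ v)
        v /= np.linalg.norm(v)
        row = model.mean + 100.0 * v
        fl = outlier_flags(model, row[None, :], rule="either")
        assert fl.q[0] > fl.q_limit
        assert fl.flags[0]

    def test_in_model_data_flagged_at_alpha_rate_by_t2(self):
        rng = np.random.default_rng(77)
        X = rng.normal(size=(2000, 5))
        model = fit_pca(X[:1000], 3)
        fl = outlier_flags(model, X[1000:], alpha=0.05, rule="either")
        t2_rate = np.mean(fl.t2 > fl.t2_limit)
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(t2_rate - 0.05) < 3 * se + 0.01


class TestSVM:
    def test_separable_toy_reaches_perfect_cv(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, size=(20, 2)), rng.normal(3, 0.3, size=(20, 2))])
        labels = ["a"] * 20 + ["b"] * 20
        spec, acc = tune_svm(
            X, labels, cv_scheme="kfold", cv_params={"k": 4},
            Cs=(1.0, 10.0), gammas=(0.1, 1.0), seed=0,
        )
        assert acc == 1.0

    def test_label_permutation_near_chance(self, rng):
        X = rng.normal(size=(60, 4))
        labels = list(rng.permutation(["a", "b"] * 30))
        _, acc = tune_svm(
            X, labels, kernels=("quadratic",), cv_scheme="kfold",
            cv_params={"k": 4}, Cs=(1.0,), seed=1,
        )
        assert abs(acc - 0.5) < 0.2

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(40, 3))
        labels = ["a", "b"] * 20
        a = tune_svm(X, labels, cv_scheme="kfold", cv_params={"k": 4}, Cs=(1.0, 10.0), seed=5)
        b = tune_svm(X, labels, cv_scheme="kfold", cv_params={"k": 4}, Cs=(1.0, 10.0), seed=5)
        assert a == b

    def test_single_class_errors(self, rng):
        with pytest.raises(ValidationError):
            tune_svm(rng.normal(size=(10, 2)), ["a"] * 10)


class TestMetrics:
    def test_hand_built_confusion_counts(self):
        cm = ConfusionMatrix(("x", "y"), np.array([[8, 2], [5, 15]]))
        out = metrics(cm)
        np.testing.assert_allclose(out.loc["x", "sensitivity"], 0.800)
        np.testing.assert_allclose(out.loc["x", "specificity"], 0.750)
        np.testing.assert_allclose(out.loc["x", "accuracy"], 23 / 30, atol=5e-5)
        np.testing.assert_allclose(out.loc["x", "error"], 7 / 30, atol=5e-5)

    def test_perfect_predictions(self):
        cm = ConfusionMatrix.from_labels(["a", "b", "a"], ["a", "b", "a"])
        out = metrics(cm)
        np.testing.assert_allclose(out[["sensitivity", "specificity", "accuracy"]], 1.0)
        np.testing.assert_allclose(out["error"], 0.0)

    def test_error_plus_accuracy_is_one(self, rng):
        y_true = list(rng.choice(["a", "b", "c"], size=50))
        y_pred = list(rng.choice(["a", "b", "c"], size=50))
        out = metrics(ConfusionMatrix.from_labels(y_true, y_pred))
        np.testing.assert_allclose(out["accuracy"] + out["error"], 1.0)

    def test_degenerate_sensitivity_warns_nan(self):
        cm = ConfusionMatrix.from_labels(["a", "a"], ["a", "b"], classes=["a", "b"])
        with pytest.warns(UserWarning, match="sensitivity"):
            out = metrics(cm)
        assert np.isnan(out.loc["b", "sensitivity"])

    def test_counts_balance(self, rng):
        y_true = list(rng.choice(["a", "b", "c", "d"], size=40))
        y_pred = list(rng.choice(["a", "b", "c", "d"], size=40))
        cm = ConfusionMatrix.from_labels(y_true, y_pred)
        for counts in cm.per_class_counts().values():
            assert sum(counts.values()) == 40


class TestLeaveClassOut:
    @pytest.fixture
    def geometry(self, rng):
        # four clusters: 'mid' sits halfway between 'left' and 'right';
        # 'far' is distant from all three
        centers = {"left": (-4, 0), "right": (4, 0), "mid": (0, 0), "far": (0, 40)}
        X, labels, groups = [], [], []
        for name, c in centers.items():
            for g in range(8):
                for _ in range(3):
                    X.append(rng.normal(c, 0.4))
                    labels.append(name)
                    groups.append(f"{name}{g}")
        return np.asarray(X), labels, groups

    def test_allocations_conserved(self, geometry):
        X, labels, groups = geometry
        table = leave_class_out(X, labels, groups, cv_scheme="kfold", cv_params={"k": 4}, seed=0)
        for _, row in table.iterrows():
            allocated = sum(row[f"to_{c}"] for c in ("left", "right", "mid", "far"))
            assert allocated + row["unassigned"] == row["n_spectra"]

    def test_midway_class_splits_between_neighbours(self, geometry):
        X, labels, groups = geometry
        table = leave_class_out(X, labels, groups, cv_scheme="kfold", cv_params={"k": 4}, seed=0)
        row = table.set_index("left_out").loc["mid"]
        assert row["to_far"] <= 0.05 * row["n_spectra"]
        assert row["to_left"] + row["to_right"] + row["unassigned"] >= 0.9 * row["n_spectra"]

    def test_deterministic(self, geometry):
        X, labels, groups = geometry
        a = leave_class_out(X, labels, groups, cv_scheme="kfold", cv_params={"k": 4}, seed=3)
        b = leave_class_out(X, labels, groups, cv_scheme="kfold", cv_params={"k": 4}, seed=3)
        assert a.equals(b)


class TestEvaluateOnSplit:
    def test_perfect_classifier_and_recomputable_metrics(self, rng):
        # two tight, well-separated classes with grouped replicates
        X, labels, groups = [], [], []
        for name, c in (("a", -5.0), ("b", 5.0)):
            for g in range(10):
                base = rng.normal(c, 0.2)
                for _ in range(3):
                    X.append([base + rng.normal(0, 0.05), rng.normal()])
                    labels.append(name)
                    groups.append(f"{name}{g}")
        X = np.asarray(X)
        train_rows = np.arange(0, 24).tolist() + np.arange(30, 54).tolist()
        test_rows = np.arange(24, 30).tolist() + np.arange(54, 60).tolist()
        blocks = evaluate_on_split(
            X, labels, groups, np.asarray(train_rows), np.asarray(test_rows),
            method="plsda", max_lv=2, cv_scheme="kfold", cv_params={"k": 4}, seed=0,
        )
        for name, block in blocks.items():
            np.testing.assert_allclose(block.metrics["accuracy"], 1.0)
            recomputed = metrics(block.confusion)
            assert recomputed.equals(block.metrics) or np.allclose(
                recomputed.to_numpy(dtype=float), block.metrics.to_numpy(dtype=float)
            )
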