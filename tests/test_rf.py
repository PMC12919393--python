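import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilpte import rf
from soilpte.rf import (RFError, Standardizer, build_feature_matrix, evaluate,
                        one_hot, oob_error_curve, partial_dependence,
                        permutation_importance, split_data, train_rf,
                        winsorize, zscore)


class TestWinsorize:
    def test_constant_vector_unchanged(self):
        v = np.full(10, 3.0)
        np.testing.assert_array_equal(winsorize(v), v)

    def test_1_to_100_clipped_to_interpolated_percentiles(self):
        v = np.arange(1.0, 101.0)
        out = winsorize(v)
        assert out.min() == pytest.approx(5.95)
        assert out.max() == pytest.approx(95.05)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_near_idempotent_with_fixed_interior(self, values):
        """Re-winsorizing leaves interior points untouched; the clip bounds
        themselves can drift by at most one inter-percentile gap (linear
        interpolation makes exact idempotence unattainable on distinct
        values)."""
        once = winsorize(values)
        twice = winsorize(once)
        lo, hi = np.percentile(once, [5, 95])
        interior = (once > lo) & (once < hi)
        np.testing.assert_array_equal(twice[interior], once[interior])
        assert twice.min() >= once.min() - 1e-12
        assert twice.max() <= once.max() + 1e-12

    def test_order_preserving_on_the_interior(self):
        v = np.array([0.0, 10.0, 20.0, 30.0, 100.0])
        out = winsorize(v)
        assert (np.diff(out) >= 0).all()

    def test_empty_rejected(self):
        with pytest.raises(RFError):
            winsorize([])


class TestZScore:
    def test_unit_spacing(self):
        np.testing.assert_allclose(zscore([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_output_standardized(self):
        rng = np.random.default_rng(0)
        out = zscore(rng.normal(5, 3, 200))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_transform_of_training_mean_is_zero(self):
        st_ = Standardizer().fit([2.0, 4.0, 9.0])
        assert st_.transform([5.0])[0] == pytest.approx(0.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(RFError):
            zscore([1.0, 1.0, 1.0])


class TestOneHot:
    def test_five_levels_give_four_columns(self):
        cats = ["CM", "AG", "RD", "FT", "RS"] * 2
        out = one_hot(cats, "CM")
        assert out.shape == (10, 4)
        assert "CM" not in out.columns

    def test_reference_rows_are_all_zero(self):
        enc = rf.OneHotEncoder("CM").fit(["CM", "AG", "RD"])
        out = enc.transform(["CM", "CM"])
        assert out.shape == (2, 2)
        assert (out.to_numpy() == 0).all()

    def test_row_sums_at_most_one(self):
        cats = ["a", "b", "c", "a", "b"]
        out = one_hot(cats, "a")
        assert (out.sum(axis=1) <= 1).all()

    def test_unseen_level_at_transform_rejected(self):
        enc = rf.OneHotEncoder("a").fit(["a", "b"])
        with pytest.raises(RFError, match="unseen"):
            enc.transform(["a", "z"])


class TestSplit:
    def test_study_size_split(self):
        tr, te = split_data(120, 0.7, seed=1)
        assert len(tr) == 84 and len(te) == 36

    def test_reproducible_and_partitioning(self):
        a = split_data(50, seed=9)
        b = split_data(50, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        union = np.concatenate(a)
        assert sorted(union) == list(range(50))
        assert len(np.intersect1d(a[0], a[1])) == 0

    def test_too_small_rejected(self):
        with pytest.raises(RFError):
            split_data(1)


@pytest.fixture(scope="module")
def smooth_problem():
    rng = np.random.default_rng(7)
    X = rng.uniform(-2, 2, (500, 2))
    y = np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2
    return X, y


@pytest.fixture(scope="module")
def linear_model():
    rng = np.random.default_rng(11)
    X = rng.uniform(-3, 3, (400, 3))  # the third column is pure noise
    y = 2.0 * X[:, 0] + 1.0 * X[:, 1]
    features = pd.DataFrame(X, columns=["x1", "x2", "noise"])
    return train_rf(features, y, n_trees=100, seed=11), features, y


class TestTrainAndEvaluate:
    def test_noise_free_smooth_target_is_learnable(self, smooth_problem):
        X, y = smooth_problem
        tr, te = split_data(len(y), 0.7, seed=2)
        model = train_rf(X[tr], y[tr], n_trees=100, seed=2)
        metrics = evaluate(model, X[te], y[te], y[tr].mean())
        assert metrics["R2"] >= 0.9

    def test_ensemble_is_exact_mean_of_trees(self, smooth_problem):
        X, y = smooth_problem
        model = train_rf(X[:100], y[:100], n_trees=40, seed=3)
        per_tree = model.per_tree_predictions(X[100:140])
        np.testing.assert_allclose(model.predict(X[100:140]),
                                   per_tree.mean(axis=0), atol=1e-12)

    def test_same_seed_identical_predictions(self, smooth_problem):
        X, y = smooth_problem
        a = train_rf(X[:200], y[:200], n_trees=30, seed=5).predict(X[200:250])
        b = train_rf(X[:200], y[:200], n_trees=30, seed=5).predict(X[200:250])
        np.testing.assert_array_equal(a, b)

    def test_nan_rejected(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(RFError):
            train_rf(X, np.ones(10))

    def test_perfect_predictions_metrics(self):
        class Perfect:
            feature_names = ["x0"]

            def predict(self, X):
                return np.asarray(X, float)[:, 0]

        X = np.array([[1.0], [2.0], [4.0]])
        m = evaluate(Perfect(), X, X[:, 0], train_target_mean=2.0)
        assert m["R2"] == 1.0 and m["Q2"] == 1.0 and m["RMSE"] == 0.0

    def test_predicting_test_mean_gives_zero_r2(self):
        class Mean:
            feature_names = ["x0"]

            def predict(self, X):
                return np.full(len(X), 13.0)

        m = evaluate(Mean(), np.zeros((2, 1)), np.array([12.0, 14.0]), 13.0)
        assert m["R2"] == pytest.approx(0.0)

    def test_q2_hand_arithmetic(self):
        # train mean 10, y = {12, 14}, yhat = {11, 15}: Q2 = 1 - 2/20
        class Fixed:
            feature_names = ["x0"]

            def predict(self, X):
                return np.array([11.0, 15.0])

        m = evaluate(Fixed(), np.zeros((2, 1)), np.array([12.0, 14.0]), 10.0)
        assert m["Q2"] == pytest.approx(0.9)
        assert m["RMSE"] == pytest.approx(1.0)

    def test_zero_variance_test_target_rejected(self):
        class Any:
            feature_names = ["x0"]

            def predict(self, X):
                return np.zeros(len(X))

        with pytest.raises(RFError):
            evaluate(Any(), np.zeros((2, 1)), np.array([3.0, 3.0]), 1.0)


class TestImportanceAndPD:
    def test_noise_feature_has_negligible_importance(self, linear_model):
        model, _, _ = linear_model
        imp = permutation_importance(model, n_repeats=3, seed=1)
        assert imp["noise"] <= 0.1 * imp.max()
        assert imp.idxmax() == "x1"

    def test_informative_feature_has_positive_importance(self, linear_model):
        model, _, _ = linear_model
        imp = permutation_importance(model, n_repeats=3, seed=2)
        assert imp["x1"] > 0 and imp["x2"] > 0

    def test_importance_reported_for_every_column(self, linear_model):
        model, _, _ = linear_model
        imp = permutation_importance(model, n_repeats=2, seed=3)
        assert list(imp.index) == ["x1", "x2", "noise"]

    def test_pd_slope_matches_additive_coefficient(self, linear_model):
        model, features, _ = linear_model
        grid, curve = partial_dependence(model, features, "x1",
                                         grid=np.linspace(-2, 2, 9))
        slope = np.polyfit(grid, curve, 1)[0]
        assert slope == pytest.approx(2.0, rel=0.1)

    def test_pd_of_ignored_feature_is_flat(self, linear_model):
        model, features, _ = linear_model
        _, curve = partial_dependence(model, features, "noise",
                                      grid=np.linspace(-2, 2, 9))
        assert np.ptp(curve) < 0.2 * np.ptp(model.y_train)

    def test_pd_matches_hand_computed_mean(self, linear_model):
        model, features, _ = linear_model
        five = features.iloc[:5]
        grid, curve = partial_dependence(model, five, "x1", grid=[0.7])
        manual = five.copy()
        manual["x1"] = 0.7
        assert curve[0] == pytest.approx(model.predict(manual).mean())

    def test_empty_grid_rejected(self, linear_model):
        model, features, _ = linear_model
        with pytest.raises(RFError):
            partial_dependence(model, features, "x1", grid=[])


class TestOOBCurve:
    def test_curve_length_and_stabilization(self):
        rng = np.random.default_rng(13)
        X = rng.uniform(-2, 2, (200, 2))
        y = X[:, 0] ** 2 + rng.normal(0, 0.1, 200)
        model = train_rf(X, y, n_trees=100, seed=13)
        curve = oob_error_curve(model)
        assert len(curve) == 100
        head = np.nanmax(curve[:30]) - np.nanmin(curve[:30])
        tail = np.nanmax(curve[-30:]) - np.nanmin(curve[-30:])
        assert tail < head

    def test_single_tree_model(self):
        rng = np.random.default_rng(14)
        X = rng.uniform(0, 1, (50, 2))
        model = train_rf(X, X[:, 0], n_trees=1, seed=14)
        assert len(oob_error_curve(model)) == 1


class TestFeatureMatrix:
    def test_columns_and_standardization(self, noisy_k4, base_solution_k4):
        ds = noisy_k4[0]
        X, state = build_feature_matrix(ds, base_solution_k4.G)
        for col in ("pH", "EC_uScm", "x", "y"):
            assert X[col].mean() == pytest.approx(0.0, abs=1e-9)
        assert "land_use=AG" in X.columns and "land_use=CM" not in X.columns
        assert {"F1", "F2", "F3", "F4"} <= set(X.columns)
        assert not X.isna().any().any()

    def test_g_row_mismatch_rejected(self, noisy_k4):
        ds = noisy_k4[0]
        with pytest.raises(RFError):
            build_feature_matrix(ds, np.ones((5, 4)))
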