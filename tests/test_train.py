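"""Training protocol: undersampling, importance, selection, CV, bundles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import f1_score
from sklearn.model_selection import ShuffleSplit, cross_val_score
from sklearn.model_selection import ParameterGrid, StratifiedKFold

from trophomode.config import MODES
from trophomode.profiles import apply_scaler, fit_scaler
from trophomode.train import (
    DEFAULT_HYPERPARAMS,
    HYPERPARAM_GRID,
    TrophicModelBundle,
    _sub_seed,
    cross_validate,
    culture_accuracy,
    encode_labels,
    evaluate_f1,
    grid_search,
    learning_curve,
    make_classifier,
    permutation_importance,
    select_features,
    train_bundle,
    undersample,
)


def toy_dataset(n_per_class=30, n_features=8, seed=0, separation=3.0, noise_sd=0.0):
    """Three-class data: exact one-hot class indicators plus noise columns.

    The first three features carry the class signal exactly (``separation``
    for the own class, 0 otherwise, optionally blurred by ``noise_sd``); the
    remaining features are pure Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for k, mode in enumerate(MODES):
        block = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
        block[:, :3] = rng.normal(0.0, noise_sd, size=(n_per_class, 3)) if noise_sd else 0.0
        block[:, k] += separation
        rows.append(block)
        labels += [mode] * n_per_class
    X = pd.DataFrame(
        np.vstack(rows), columns=[f"PF{i:05d}" for i in range(1, n_features + 1)]
    )
    return X, pd.Series(labels)


class TestUndersample:
    def test_counts_match_protocol(self, full_training):
        matrix, labels, _ = full_training
        Xu, yu = undersample(matrix, labels, 100, seed=3)
        counts = yu.value_counts().to_dict()
        assert counts == {"phototrophy": 100, "mixotrophy": 85, "heterotrophy": 44}

    def test_full_count_is_identity_on_phototrophs(self, small_training):
        matrix, labels, _ = small_training
        n_photo = int((labels == "phototrophy").sum())
        Xu, yu = undersample(matrix, labels, n_photo, seed=0)
        assert set(yu.index) == set(labels.index)

    def test_deterministic_under_seed(self, small_training):
        matrix, labels, _ = small_training
        a = undersample(matrix, labels, 10, seed=5)[1]
        b = undersample(matrix, labels, 10, seed=5)[1]
        pd.testing.assert_series_equal(a, b)

    def test_oversized_request_errors(self, small_training):
        matrix, labels, _ = small_training
        with pytest.raises(ValueError, match="exceeds"):
            undersample(matrix, labels, 10_000, seed=0)


class TestEvaluateF1:
    def test_all_correct(self):
        y = ["phototrophy", "mixotrophy", "heterotrophy"] * 3
        rep = evaluate_f1(y, y)
        assert (rep.per_class["f1"] == 1.0).all()
        assert rep.weighted_f1 == 1.0

    def test_hand_confusion_arithmetic(self):
        # phototrophy: TP=8, FP=2, FN=2 -> precision = recall = 0.8 -> F1 = 0.8
        y_true = ["phototrophy"] * 10 + ["mixotrophy"] * 10
        y_pred = (
            ["phototrophy"] * 8 + ["mixotrophy"] * 2
            + ["phototrophy"] * 2 + ["mixotrophy"] * 8
        )
        rep = evaluate_f1(y_true, y_pred)
        assert rep.per_class.loc["phototrophy", "f1"] == pytest.approx(0.8)
        assert rep.confusion.loc["phototrophy", "phototrophy"] == 8
        assert rep.confusion.loc["phototrophy", "mixotrophy"] == 2

    def test_single_class_all_predicted(self):
        y = ["heterotrophy"] * 5
        assert evaluate_f1(y, y).weighted_f1 == 1.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            evaluate_f1([], [])


class TestCultureAccuracy:
    def test_expected_mode_sets(self):
        table = pd.DataFrame(
            {
                "culture_id": ["a", "a", "b", "c"],
                "expected_modes": [
                    "phototrophy", "phototrophy",
                    "mixotrophy|heterotrophy", "heterotrophy",
                ],
                "predicted_mode": [
                    "phototrophy", "mixotrophy", "heterotrophy", "phototrophy",
                ],
            }
        )
        rep_acc, cult_acc = culture_accuracy(table)
        assert rep_acc == pytest.approx(2 / 4)
        assert cult_acc == pytest.approx(1 / 3)  # only culture b fully correct


class TestPermutationImportance:
    def test_constant_feature_scores_zero_every_split(self):
        X, y = toy_dataset(n_per_class=20, seed=1)
        X["PF_const"] = 0.5
        imp = permutation_importance(X, y, n_splits=4, seed=2)
        split_cols = [c for c in imp.columns if c.startswith("split_")]
        assert (imp.loc["PF_const", split_cols] == 0).all()

    def test_planted_signal_positive_noise_near_zero(self):
        rng = np.random.default_rng(0)
        n = 300
        y = pd.Series([MODES[i % 3] for i in range(n)])
        signal = encode_labels(y) + rng.normal(0, 0.4, n)
        X = pd.DataFrame({"PF_sig": signal})
        for j in range(10):
            X[f"PF_noise{j}"] = rng.normal(0, 1, n)
        imp = permutation_importance(X, y, n_splits=6, seed=4)
        assert imp.loc["PF_sig", "mean_importance"] > 0
        noise_means = imp.drop("PF_sig")["mean_importance"]
        assert (noise_means.abs() < 0.05).all()

    def test_matches_naive_per_feature_loop(self):
        """Chunked batch prediction equals an independently coded per-feature
        shuffle loop using the same fitted models and shuffle stream."""
        X, y = toy_dataset(n_per_class=15, n_features=5, seed=3, separation=1.5, noise_sd=1.0)
        seed = 11
        imp = permutation_importance(X, y, n_splits=3, seed=seed)

        yc = encode_labels(y)
        Xa = X.to_numpy()
        naive = np.zeros((X.shape[1], 3))
        splitter = ShuffleSplit(n_splits=3, test_size=0.30, random_state=_sub_seed(seed, "splits"))
        for s, (tr, te) in enumerate(splitter.split(Xa, yc)):
            clf = make_classifier(seed=_sub_seed(seed, f"fit_{s}"))
            clf.fit(Xa[tr], yc[tr])
            base = f1_score(yc[te], clf.predict(Xa[te]), average="weighted", zero_division=0)
            rng = np.random.default_rng(_sub_seed(seed, f"shuffle_{s}"))
            used = sorted(
                int(k[1:]) for k in clf.get_booster().get_score(importance_type="weight")
            )
            for j in used:
                Xs = Xa[te].copy()
                rng.shuffle(Xs[:, j])
                f1s = f1_score(yc[te], clf.predict(Xs), average="weighted", zero_division=0)
                naive[j, s] = (base - f1s) / base
        split_cols = [f"split_{s}" for s in range(3)]
        np.testing.assert_allclose(imp[split_cols].to_numpy(), naive, atol=1e-12)

    def test_single_class_errors(self):
        X = pd.DataFrame({"f": np.arange(10.0)})
        y = pd.Series(["phototrophy"] * 10)
        with pytest.raises(ValueError):
            permutation_importance(X, y, seed=0)


class TestSelectFeatures:
    def test_positive_in_at_least_one_dataset_retains(self):
        imps = {
            1: pd.Series({"PFX": -0.01}),
            2: pd.Series({"PFX": +0.002}),
            3: pd.Series({"PFX": -0.03}),
            4: pd.Series({"PFX": 0.0}),
        }
        assert select_features(imps) == ["PFX"]

    def test_never_positive_drops(self):
        imps = {1: pd.Series({"PFX": -0.01, "PFY": 0.0})}
        assert select_features(imps) == []

    def test_monotone_in_datasets(self):
        base = {1: pd.Series({"PFX": 0.01, "PFY": -0.5})}
        more = dict(base)
        more[2] = pd.Series({"PFX": -0.9, "PFY": -0.9})
        assert set(select_features(base)) <= set(select_features(more)) | {"PFX"}
        assert "PFX" in select_features(more)


class TestGridSearch:
    def test_singleton_grid_returns_it(self):
        X, y = toy_dataset(n_per_class=15, seed=5)
        grid = {"n_estimators": [20], "max_depth": [3]}
        best, results = grid_search(X, y, grid, k=3, seed=0)
        assert best == {"n_estimators": 20, "max_depth": 3}
        assert len(results) == 1

    def test_full_grid_has_324_combinations(self):
        assert len(list(ParameterGrid(HYPERPARAM_GRID))) == 324

    def test_agrees_with_independent_exhaustive_loop(self):
        X, y = toy_dataset(n_per_class=18, seed=6, separation=1.0, noise_sd=1.0)
        grid = {"n_estimators": [10, 30], "max_depth": [2, 4]}
        k, seed = 3, 9
        best, _ = grid_search(X, y, grid, k=k, seed=seed)

        # independent brute force: same folds, same estimator construction
        yc = encode_labels(y)
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=_sub_seed(seed, "gridcv"))
        scores = []
        combos = list(ParameterGrid(grid))
        for combo in combos:
            clf = make_classifier(seed=_sub_seed(seed, "gridfit"))
            clf.set_params(**combo)
            s = cross_val_score(clf, X.to_numpy(), yc, cv=cv, scoring="f1_weighted")
            scores.append(s.mean())
        expected = combos[int(np.argmax(scores))]
        assert best == expected

    def test_small_class_errors(self):
        X, y = toy_dataset(n_per_class=3, seed=0)
        with pytest.raises(ValueError, match="class"):
            grid_search(X, y, {"n_estimators": [10]}, k=5, seed=0)


class TestCrossValidate:
    def test_separable_data_perfect_f1(self):
        X, y = toy_dataset(n_per_class=30, seed=7, separation=8.0)
        res = cross_validate(X, y, n_splits=3, seed=1)
        assert (res.per_split["weighted"] == 1.0).all()

    def test_shuffled_labels_near_chance(self):
        X, y = toy_dataset(n_per_class=40, seed=8, separation=5.0)
        rng = np.random.default_rng(0)
        y_shuf = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        res = cross_validate(X, y_shuf, n_splits=3, seed=2)
        # balanced 3-class baseline weighted F1 is ~1/3
        assert res.weighted_mean < 0.55

    def test_learning_curve_improves_on_separable_data(self):
        X, y = toy_dataset(n_per_class=40, seed=9, separation=2.0, noise_sd=1.0)
        lc = learning_curve(X, y, fractions=(0.25, 1.0), n_splits=3, seed=3)
        means = lc.groupby("fraction")["weighted_f1"].mean()
        assert means.loc[1.0] >= means.loc[0.25] - 0.05


class TestBundle:
    def test_probabilities_on_simplex_and_roundtrip(self, tmp_path, small_training):
        matrix, labels, truth = small_training
        bundle = train_bundle(matrix, labels, features=truth["signal_pfams"], seed=5)
        proba = bundle.predict_proba(matrix.iloc[:10])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

        bundle.save(tmp_path / "bundle")
        loaded = TrophicModelBundle.load(tmp_path / "bundle")
        assert loaded.features == bundle.features
        assert loaded.hyperparams == DEFAULT_HYPERPARAMS
        pd.testing.assert_frame_equal(
            loaded.predict_proba(matrix.iloc[:10]), proba, atol=1e-12
        )

    def test_corrupt_bundle_errors(self, tmp_path):
        (tmp_path / "bundle").mkdir()
        with pytest.raises(FileNotFoundError, match="corrupt"):
            TrophicModelBundle.load(tmp_path / "bundle")
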