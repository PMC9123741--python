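import numpy as np
import pandas as pd
import pytest

from conftest import oracle_auc_pair_count, oracle_average_precision
from xtclass import learn
from xtclass.imbalance import ResampleConfig
from xtclass.learn import (
    SplitConfig,
    XyloseTransportModel,
    average_precision,
    calibrate_threshold,
    deserialize,
    evaluate_scores,
    fit,
    predict,
    rfecv,
    roc_auc,
    serialize,
    split,
)
from xtclass.seqio import XtclassError


def _informative_data(seed, n=120, n_features=10, n_pos=30):
    """Features 0 and 1 jointly determine the label; the rest are noise."""
    rng = np.random.default_rng(seed)
    y = np.array([1] * n_pos + [0] * (n - n_pos))
    X = rng.normal(0, 1, size=(n, n_features))
    X[:, 0] += 3.0 * y
    if n_features > 1:
        X[:, 1] -= 3.0 * y
    cols = [f"f{i}" for i in range(n_features)]
    return pd.DataFrame(X, columns=cols, index=[f"s{i}" for i in range(n)]), y


class TestSplit:
    def test_balanced_small(self):
        X = pd.DataFrame(np.arange(20).reshape(10, 2),
                         index=[f"s{i}" for i in range(10)])
        y = pd.Series([1] * 5 + [0] * 5, index=X.index)
        Xtr, ytr, Xte, yte = split(X, y, SplitConfig(train_fraction=0.7, seed=0))
        assert set(Xtr.index).isdisjoint(Xte.index)
        assert ytr.sum() in (3, 4)
        assert (ytr == 0).sum() in (3, 4)

    def test_same_seed_identical(self):
        X, y = _informative_data(1)
        a = split(X, pd.Series(y, index=X.index), SplitConfig(seed=5))
        b = split(X, pd.Series(y, index=X.index), SplitConfig(seed=5))
        assert list(a[0].index) == list(b[0].index)

    def test_paper_class_counts_partition(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(396, 3)),
                         index=[f"s{i}" for i in range(396)])
        y = pd.Series([1] * 25 + [0] * 371, index=X.index)
        Xtr, ytr, Xte, yte = split(X, y, SplitConfig(train_fraction=0.7, seed=1))
        assert ytr.sum() in (17, 18)
        assert ytr.sum() + yte.sum() == 25

    def test_single_sample_class_rejected(self):
        X = pd.DataFrame(np.zeros((4, 1)), index=list("abcd"))
        y = pd.Series([1, 0, 0, 0], index=X.index)
        with pytest.raises(XtclassError):
            split(X, y, SplitConfig())


class TestMetrics:
    def test_perfect_predictions(self):
        y = [1, 1, 0, 0]
        m = evaluate_scores(y, [0.9, 0.8, 0.2, 0.1])
        assert (m.precision, m.recall, m.mcc, m.roc_auc) == (1, 1, 1, 1)
        assert m.average_precision == 1.0

    def test_all_negative_predictor_flagged(self):
        m = evaluate_scores([1, 0, 0], [0.1, 0.2, 0.3])
        assert m.recall == 0.0
        assert m.precision == 0.0 and not m.precision_defined

    def test_hand_example_auc_matches_pair_counting(self):
        y = [1, 1, 0, 1, 0, 0]
        s = [0.9, 0.8, 0.7, 0.4, 0.3, 0.2]
        assert roc_auc(np.array(y), np.array(s)) == pytest.approx(
            oracle_auc_pair_count(y, s)
        )

    def test_random_scores_match_oracles(self):
        rng = np.random.default_rng(2)
        for trial in range(10):
            n = int(rng.integers(6, 20))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.random(n), 2)  # induce ties
            assert roc_auc(y, s) == pytest.approx(
                oracle_auc_pair_count(y.tolist(), s.tolist()), abs=1e-12
            )
            assert average_precision(y, s) == pytest.approx(
                oracle_average_precision(y.tolist(), s.tolist()), abs=1e-12
            )

    def test_sklearn_cross_check(self):
        from sklearn.metrics import (
            average_precision_score,
            matthews_corrcoef,
            roc_auc_score,
        )

        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        s = rng.random(50)
        m = evaluate_scores(y, s, threshold=0.5)
        assert m.roc_auc == pytest.approx(roc_auc_score(y, s))
        assert m.average_precision == pytest.approx(
            average_precision_score(y, s)
        )
        assert m.mcc == pytest.approx(
            matthews_corrcoef(y, (s >= 0.5).astype(int))
        )

    def test_single_class_auc_absent(self):
        m = evaluate_scores([1, 1], [0.9, 0.8])
        assert m.roc_auc is None

    def test_confusion_sums_to_n(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, size=30)
        s = rng.random(30)
        m = evaluate_scores(y, s, threshold=0.4)
        assert m.tp + m.fp + m.tn + m.fn == 30


class TestRfecv:
    def test_single_feature_selected(self):
        X, y = _informative_data(5, n_features=1)
        res = rfecv(X, y, folds=3, seed=0)
        assert res.selected_features == ["f0"]

    def test_large_step_single_round(self):
        X, y = _informative_data(6, n_features=4)
        res = rfecv(X, y, step=10, folds=3, seed=0)
        assert res.curve["n_features"].tolist() == [4, 1]

    def test_informative_features_recovered(self):
        hits = 0
        for seed in range(5):
            X, y = _informative_data(100 + seed)
            res = rfecv(X, y, step=1, folds=4, seed=seed)
            if {"f0", "f1"} & set(res.selected_features):
                hits += 1
        assert hits >= 4

    def test_resampling_confined_to_fold_training(self, monkeypatch):
        X, y = _informative_data(7)
        calls = []
        import xtclass.learn as learn_mod
        original = learn_mod.resample

        def spy(Xa, ya, cfg, logger=None):
            calls.append(np.asarray(Xa))
            return original(Xa, ya, cfg, logger)

        monkeypatch.setattr(learn_mod, "resample", spy)
        rfecv(X, y, folds=4, seed=0,
              resample_cfg=ResampleConfig(seed=0, k_smote=3))
        original_rows = {tuple(np.round(r, 12)) for r in X.to_numpy()}
        # folds resample strictly fewer rows; only the final refit may
        # see the full training split, and no call sees synthetic rows
        assert sum(Xa.shape[0] < len(X) for Xa in calls) >= 4
        for Xa in calls:
            for row in Xa:
                assert tuple(np.round(row, 12)) in original_rows

    def test_min_features_floor(self):
        X, y = _informative_data(8)
        res = rfecv(X, y, step=0.5, folds=3, min_features=4, seed=0)
        assert res.n_selected >= 4


class TestFitPredict:
    def test_separable_training_recovered(self):
        X, y = _informative_data(9, n_features=3)
        bundle = fit(X, y, seed=0)
        probs = bundle.probabilities(X)
        assert (((probs >= 0.5).astype(int)) == y).all()

    def test_refit_identical(self):
        X, y = _informative_data(10)
        b1 = fit(X, y, seed=3, resample_cfg=ResampleConfig(seed=3, k_smote=3))
        b2 = fit(X, y, seed=3, resample_cfg=ResampleConfig(seed=3, k_smote=3))
        assert (b1.probabilities(X) == b2.probabilities(X)).all()

    def test_importances_sum_to_one(self):
        X, y = _informative_data(11)
        bundle = fit(X, y, seed=0)
        table = pd.DataFrame(bundle.metadata["importance_table"])
        assert table["importance"].sum() == pytest.approx(1.0)

    def test_predict_columns_and_near_miss(self):
        X, y = _informative_data(12, n_features=2)
        bundle = fit(X, y, seed=0)
        bundle = calibrate_threshold(bundle, mode="fixed", value=0.98)
        out = predict(bundle, X)
        assert list(out.columns) == ["probability", "predicted", "near_miss"]
        border = (out.probability >= 0.93) & (out.probability < 0.98)
        assert (out.near_miss == border).all()
        assert (out.predicted == (out.probability >= 0.98).astype(int)).all()

    def test_probability_at_threshold_is_positive(self):
        X, y = _informative_data(13, n_features=2)
        bundle = fit(X, y, seed=0)
        probs = bundle.probabilities(X)
        thr = float(probs.max())
        bundle = calibrate_threshold(bundle, mode="fixed", value=min(thr, 0.99))
        out = predict(bundle, X)
        assert out.predicted.iloc[int(np.argmax(probs))] == 1

    def test_missing_feature_named(self):
        X, y = _informative_data(14, n_features=3)
        bundle = fit(X, y, seed=0)
        with pytest.raises(XtclassError, match="f2"):
            predict(bundle, X[["f0", "f1"]])

    def test_row_shuffle_permutes_output(self):
        X, y = _informative_data(15, n_features=3)
        bundle = fit(X, y, seed=0)
        out1 = predict(bundle, X)
        shuffled = X.sample(frac=1.0, random_state=1)
        out2 = predict(bundle, shuffled)
        assert (out2.loc[out1.index, "probability"] == out1.probability).all()


class TestCalibration:
    def test_fixed_098_classifies_boundary(self):
        probs = np.array([0.99, 0.979])
        cls = (probs >= 0.98).astype(int)
        assert cls.tolist() == [1, 0]

    def test_extreme_thresholds(self):
        y = [1, 0, 1]
        s = [0.6, 0.4, 0.2]
        assert evaluate_scores(y, s, threshold=0.0).tp + \
            evaluate_scores(y, s, threshold=0.0).fp == 3
        m = evaluate_scores(y, s, threshold=1.0 + 1e-9)
        assert m.tp + m.fp == 0

    def test_raising_threshold_never_increases_positives(self):
        rng = np.random.default_rng(16)
        s = rng.random(50)
        y = rng.integers(0, 2, size=50)
        counts = [
            evaluate_scores(y, s, threshold=t).tp
            + evaluate_scores(y, s, threshold=t).fp
            for t in sorted(np.unique(s))
        ]
        assert counts == sorted(counts, reverse=True)

    def test_precision_floor_mode(self):
        X, y = _informative_data(17, n_features=2)
        bundle = fit(X, y, seed=0)
        out = calibrate_threshold(
            bundle, X, y, mode="precision_floor", value=0.9
        )
        probs = bundle.probabilities(X)
        pred = probs >= out.threshold
        assert (pred & (y == 1)).sum() / pred.sum() >= 0.9

    def test_unattainable_floor_reports_best(self):
        X, y = _informative_data(18, n_features=1)
        # scramble labels so perfect precision is impossible
        rng = np.random.default_rng(0)
        y_bad = rng.integers(0, 2, size=len(y))
        y_bad[:2] = [0, 1]
        bundle = fit(X, y_bad, seed=0)
        with pytest.raises(XtclassError, match="best achievable"):
            calibrate_threshold(
                bundle, X, y_bad, mode="precision_floor", value=1.1
            )


class TestSerialization:
    def test_roundtrip_bitwise(self, tmp_path):
        X, y = _informative_data(19)
        bundle = fit(X, y, seed=2)
        path = tmp_path / "model.json"
        serialize(bundle, path)
        back = deserialize(path)
        assert (back.probabilities(X) == bundle.probabilities(X)).all()
        assert back.selected_features == bundle.selected_features

    def test_metadata_preserved(self, tmp_path):
        X, y = _informative_data(20)
        bundle = fit(X, y, seed=7, metadata={"note": "m"})
        serialize(bundle, tmp_path / "m.json")
        back = deserialize(tmp_path / "m.json")
        assert back.metadata["seed"] == 7
        assert back.metadata["note"] == "m"
        assert back.metadata["config_hash"] == bundle.metadata["config_hash"]

    def test_missing_threshold_rejected(self, tmp_path):
        X, y = _informative_data(21)
        bundle = fit(X, y, seed=0)
        path = tmp_path / "m.json"
        serialize(bundle, path)
        import json

        doc = json.loads(path.read_text())
        del doc["threshold"]
        path.write_text(json.dumps(doc))
        with pytest.raises(XtclassError):
            deserialize(path)


class TestModelResults:
    def test_fit_evaluate_summary(self):
        X, y = _informative_data(22)
        model = XyloseTransportModel(
            X, y, rfecv_step=0.5, rfecv_folds=3, seed=0,
            resample_cfg=ResampleConfig(seed=0, k_smote=3),
        )
        res = model.fit()
        metrics = res.evaluate(X, y)
        assert metrics.roc_auc > 0.9
        text = res.summary()
        assert "threshold" in text and "importance" in text
        strict = res.calibrate(mode="fixed", value=0.98)
        assert strict.bundle.threshold == 0.98
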