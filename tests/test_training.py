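"""Training recipe, per-class metrics and the evaluation protocol."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from raecg.datasets import BeatDataset
from raecg.io import TARGET_CLASSES
from raecg.model import RACNN
from raecg.training import (
    EvalReport,
    RACNNClassifier,
    TrainConfig,
    TrainingError,
    compute_metrics,
    confusion_matrix,
    evaluate,
    train,
)


class TestLearningRateSchedule:
    @pytest.mark.parametrize("epoch,lr", [
        (1, 1e-3), (20, 1e-3), (21, 1e-4), (25, 1e-4),
        (40, 1e-4), (41, 1e-5), (45, 1e-5), (60, 1e-5), (61, 1e-6),
    ])
    def test_tenfold_decay_every_twenty_epochs(self, epoch, lr):
        assert TrainConfig().lr_at(epoch) == pytest.approx(lr)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)


class TestComputeMetrics:
    def test_perfect_predictions_give_all_hundreds(self):
        m = compute_metrics(np.diag([10, 5, 7, 3]))
        assert m["acc"] == 100.0
        for c in TARGET_CLASSES:
            assert m["per_class"][c] == {"Sen": 100.0, "Ppr": 100.0, "F1": 100.0}

    def test_all_normal_predictor_has_zero_minority_sensitivity(self):
        cm = confusion_matrix(["N", "S", "V", "F"], ["N", "N", "N", "N"])
        with pytest.warns(UserWarning):
            m = compute_metrics(cm)
        assert m["per_class"]["S"]["Sen"] == 0.0
        assert m["per_class"]["V"]["Sen"] == 0.0

    def test_hand_computed_confusion_example(self):
        cm = np.array([[8, 1, 1, 0], [2, 6, 0, 0], [0, 0, 9, 1], [0, 0, 1, 3]])
        m = compute_metrics(cm)
        assert m["per_class"]["N"]["Sen"] == pytest.approx(80.0)
        assert m["per_class"]["N"]["Ppr"] == pytest.approx(80.0)
        assert m["acc"] == pytest.approx(100.0 * 26 / 32)

    def test_f1_is_harmonic_mean_of_sen_and_ppr(self):
        # recomputed from published sensitivity/precision pairs
        f1 = lambda s, p: 2 * s * p / (s + p)
        assert f1(83.06, 82.48) == pytest.approx(82.77, abs=0.01)
        assert f1(93.46, 90.04) == pytest.approx(91.72, abs=0.01)
        assert f1(98.87, 98.64) == pytest.approx(98.75, abs=0.01)

    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_f1_of_equal_rates_is_the_rate(self, p):
        cmlike = 2 * p * p / (p + p)
        assert cmlike == pytest.approx(p)

    @given(st.lists(st.tuples(st.sampled_from(TARGET_CLASSES),
                              st.sampled_from(TARGET_CLASSES)),
                    min_size=1, max_size=60))
    def test_agrees_with_per_sample_recount_oracle(self, pairs):
        y_true = [t for t, _ in pairs]
        y_pred = [p for _, p in pairs]
        cm = confusion_matrix(y_true, y_pred)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = compute_metrics(cm)
        # independent recount straight from the sample lists
        for i, c in enumerate(TARGET_CLASSES):
            tp = sum(1 for t, p in pairs if t == c and p == c)
            fn = sum(1 for t, p in pairs if t == c and p != c)
            fp = sum(1 for t, p in pairs if t != c and p == c)
            sen = 100.0 * tp / (tp + fn) if tp + fn else 0.0
            ppr = 100.0 * tp / (tp + fp) if tp + fp else 0.0
            assert m["per_class"][c]["Sen"] == pytest.approx(sen)
            assert m["per_class"][c]["Ppr"] == pytest.approx(ppr)
            if m["per_class"][c]["Sen"] > 0 and m["per_class"][c]["Ppr"] > 0:
                f = m["per_class"][c]["F1"]
                assert min(sen, ppr) - 1e-9 <= f <= max(sen, ppr) + 1e-9
        acc = 100.0 * sum(1 for t, p in pairs if t == p) / len(pairs)
        assert m["acc"] == pytest.approx(acc)

    def test_counts_are_consistent_with_margins(self):
        rng = np.random.default_rng(0)
        cm = rng.integers(0, 30, (4, 4))
        m = compute_metrics(cm)
        for i, c in enumerate(TARGET_CLASSES):
            k = m["counts"][c]
            assert k["TP"] + k["FN"] == cm[i].sum()
            assert k["TP"] + k["FP"] == cm[:, i].sum()
        assert sum(m["counts"][c]["TP"] for c in TARGET_CLASSES) == np.trace(cm)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([[1, 0, 0, 0], [0, -1, 0, 0],
                                      [0, 0, 1, 0], [0, 0, 0, 1]]))


class TestEvalReport:
    def test_report_exports(self):
        rep = EvalReport(confusion=np.diag([5, 5, 5, 5]))
        assert "Acc 100.0%" in rep.to_text()
        assert '"acc": 100.0' in rep.to_json()
        assert rep.confusion_csv().splitlines()[0] == ",N,S,V,F"

    def test_row_sums_equal_true_class_counts(self):
        y_true = ["N"] * 6 + ["S"] * 3 + ["V"] * 2 + ["F"]
        y_pred = ["N"] * 5 + ["S"] + ["S"] * 3 + ["V", "N"] + ["F"]
        rep = EvalReport(confusion=confusion_matrix(y_true, y_pred))
        assert rep.confusion.sum(axis=1).tolist() == [6, 3, 2, 1]


class TestTrainAndEvaluate:
    def test_overfits_separable_images_within_five_epochs(self, separable_images):
        """Sanity oracle: a tiny network variant must reach >= 95% training
        accuracy on 200 trivially separable images in 5 epochs."""
        X, y = separable_images
        clf = RACNNClassifier(input_size=32, epochs=5, seed=0)
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.95
        assert clf.loss_history_[-1] < clf.loss_history_[0]

    def test_empty_dataset_rejected(self):
        model = RACNN(input_size=32, seed=0)
        ds = BeatDataset(images=np.zeros((0, 3, 32, 32), dtype=np.float32),
                         labels=np.array([], dtype="U1"), partition="DS1")
        with pytest.raises(TrainingError, match="empty"):
            train(model, ds, TrainConfig(epochs=1))

    def test_evaluate_refuses_augmented_test_data(self):
        model = RACNN(input_size=32, seed=0)
        ds = BeatDataset(images=np.zeros((4, 3, 32, 32), dtype=np.float32),
                         labels=np.array(["N", "S", "V", "F"]),
                         partition="DS2", augmented=True)
        with pytest.raises(ValueError, match="augment"):
            evaluate(model, ds)

    def test_evaluate_produces_one_prediction_per_beat(self):
        model = RACNN(input_size=32, seed=0)
        rng = np.random.default_rng(0)
        ds = BeatDataset(images=rng.random((10, 3, 32, 32)).astype(np.float32),
                         labels=np.array(list("NSVF") + list("NNNNNN")),
                         partition="DS2")
        rep = evaluate(model, ds)
        assert rep.confusion.sum() == 10

    def test_estimator_follows_sklearn_protocol(self, separable_images):
        from sklearn.base import clone
        X, y = separable_images
        clf = RACNNClassifier(input_size=32, epochs=1, seed=1)
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()
        clf.fit(X[:40], y[:40])
        assert set(clf.classes_) == set("NSVF")
        proba = clf.predict_proba(X[:8])
        assert proba.shape == (8, 4)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-5)
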