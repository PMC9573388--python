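import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import precision_score, recall_score

from ecgfusion.network import ModelConfig, ParallelCrossNetwork
from ecgfusion.train_eval import (
    AAMI_CLASSES,
    ConfusionMatrix,
    Dataset,
    TrainConfig,
    compute_metrics,
    evaluate,
    kfold_cv,
    split_dataset,
    sweep_learning_rates,
    train,
)

MICRO_CFG = ModelConfig(seq_len=20, image_shape=(12, 12), lstm_units=(2, 4, 4),
                        conv_filters=(2, 4, 4), dense_units=16)


def toy_dataset(counts, seq_len=8, img=4, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(counts)), counts)
    n = labels.size
    return Dataset(rng.standard_normal((n, seq_len)),
                   rng.random((n, img, img)), labels)


class TestSplit:
    def test_per_class_fractions_within_one_sample(self):
        ds = toy_dataset([100, 10, 20, 5])
        tr, te = split_dataset(ds, 0.8, seed=0)
        assert tr.class_counts() == {"NB": 80, "SVEB": 8, "VEB": 16, "FB": 4}
        assert te.class_counts() == {"NB": 20, "SVEB": 2, "VEB": 4, "FB": 1}

    def test_same_seed_reproduces_membership(self):
        ds = toy_dataset([50, 10, 10, 10])
        a = split_dataset(ds, 0.8, seed=42)
        b = split_dataset(ds, 0.8, seed=42)
        np.testing.assert_array_equal(a[0].beats, b[0].beats)
        np.testing.assert_array_equal(a[1].labels, b[1].labels)

    def test_disjoint_and_exhaustive(self):
        ds = toy_dataset([40, 8, 8, 8])
        tr, te = split_dataset(ds, 0.75, seed=1)
        assert len(tr) + len(te) == len(ds)

    def test_full_train_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(toy_dataset([10, 10, 10, 10]), 1.0)

    def test_singleton_class_rejected_by_name(self):
        with pytest.raises(ValueError, match="FB"):
            split_dataset(toy_dataset([10, 10, 10, 1]), 0.8)


class TestConfusionAndMetrics:
    def test_diagonal_matrix_gives_perfect_metrics(self):
        cm = ConfusionMatrix(np.diag([10, 5, 3, 2]))
        m = compute_metrics(cm)
        assert (m.per_class.values == 100.0).all()
        assert (m.macro == 100.0).all()

    def test_hand_computed_one_vs_rest_example(self):
        # class 0: TP=90, FP=10, FN=30, TN=870 (total 1000)
        counts = np.array([
            [90, 10, 10, 10],
            [5, 400, 0, 0],
            [5, 0, 300, 0],
            [0, 0, 0, 170],
        ])
        cm = ConfusionMatrix(counts)
        tp, fp, tn, fn = cm.one_vs_rest(0)
        assert (tp, fp, tn, fn) == (90, 10, 870, 30)
        m = compute_metrics(cm).per_class.loc["NB"]
        assert m["ACC"] == pytest.approx(96.00)
        assert m["PPV"] == pytest.approx(90.00)
        assert m["SE"] == pytest.approx(75.00)
        assert m["F1"] == pytest.approx(81.82, abs=0.005)

    def test_macro_is_mean_of_per_class(self, rng):
        cm = ConfusionMatrix(rng.integers(0, 50, (4, 4)))
        m = compute_metrics(cm)
        pd.testing.assert_series_equal(m.macro, m.per_class.mean(axis=0))

    def test_agreement_with_sklearn_precision_recall(self, rng):
        y_true = rng.integers(0, 4, 500)
        y_pred = rng.integers(0, 4, 500)
        counts = np.zeros((4, 4), int)
        np.add.at(counts, (y_true, y_pred), 1)
        m = compute_metrics(ConfusionMatrix(counts))
        ppv = precision_score(y_true, y_pred, average=None, zero_division=0)
        se = recall_score(y_true, y_pred, average=None, zero_division=0)
        np.testing.assert_allclose(m.per_class["PPV"].values, 100 * ppv, atol=1e-9)
        np.testing.assert_allclose(m.per_class["SE"].values, 100 * se, atol=1e-9)

    def test_permutation_equivariance_under_relabeling(self, rng):
        counts = rng.integers(0, 50, (4, 4))
        perm = np.array([2, 0, 3, 1])
        m1 = compute_metrics(ConfusionMatrix(counts)).per_class.values
        m2 = compute_metrics(
            ConfusionMatrix(counts[np.ix_(perm, perm)])
        ).per_class.values
        np.testing.assert_allclose(m2, m1[perm])

    def test_zero_denominator_reported_as_zero_with_flag(self):
        # nothing predicted as FB and no true FB -> PPV/SE undefined
        counts = np.diag([5, 5, 5, 0])
        m = compute_metrics(ConfusionMatrix(counts))
        assert m.per_class.loc["FB", "PPV"] == 0.0
        assert ("FB", "PPV") in m.undefined and ("FB", "SE") in m.undefined

    def test_tp_sums_and_totals(self, rng):
        counts = rng.integers(0, 30, (4, 4))
        cm = ConfusionMatrix(counts)
        tps = [cm.one_vs_rest(i)[0] for i in range(4)]
        assert sum(tps) == np.trace(counts)
        assert sum(cm.one_vs_rest(i)[0] + cm.one_vs_rest(i)[3]
                   for i in range(4)) == cm.total


class TestEvaluate:
    def test_confusion_total_equals_test_size(self, micro_dataset):
        model = ParallelCrossNetwork(MICRO_CFG, seed=0)
        cm = evaluate(model, micro_dataset)
        assert cm.total == len(micro_dataset)

    def test_row_sums_are_true_class_counts(self, micro_dataset):
        model = ParallelCrossNetwork(MICRO_CFG, seed=0)
        cm = evaluate(model, micro_dataset)
        counts = micro_dataset.class_counts()
        for i, name in enumerate(AAMI_CLASSES):
            assert cm.counts[i].sum() == counts[name]

    def test_empty_test_set_rejected(self):
        model = ParallelCrossNetwork(MICRO_CFG, seed=0)
        with pytest.raises(ValueError):
            evaluate(model, toy_dataset([0, 0, 0, 0]))


class TestTraining:
    def test_one_epoch_smoke_records_one_history_row(self, micro_dataset):
        ds = micro_dataset.subset(np.arange(64))
        model = ParallelCrossNetwork(MICRO_CFG, seed=0)
        hist = train(model, ds, TrainConfig(batch_size=32, epochs=1,
                                            learning_rate=5e-4, seed=0))
        assert len(hist) == 1
        assert {"epoch", "loss", "accuracy"} <= set(hist.columns)

    def test_memorization_loss_decreases(self, micro_dataset):
        ds = micro_dataset.subset(np.arange(50))
        model = ParallelCrossNetwork(MICRO_CFG, seed=1)
        hist = train(model, ds, TrainConfig(batch_size=50, epochs=8,
                                            learning_rate=5e-4, seed=1))
        assert hist["loss"].iloc[-1] < hist["loss"].iloc[0]

    def test_shape_mismatch_raises(self, micro_dataset):
        model = ParallelCrossNetwork(
            ModelConfig(seq_len=30, image_shape=(12, 12), lstm_units=(2, 4, 4),
                        conv_filters=(2, 4, 4)), seed=0)
        with pytest.raises(ValueError, match="do not match"):
            train(model, micro_dataset, TrainConfig(epochs=1))

    def test_lr_sweep_emits_one_history_per_rate(self, micro_dataset):
        tr, te = split_dataset(micro_dataset, 0.8, seed=0)
        results = sweep_learning_rates(
            lambda: ParallelCrossNetwork(MICRO_CFG, seed=0), tr, te,
            TrainConfig(batch_size=32, epochs=1, seed=0))
        assert set(results) == {5e-4, 1e-4, 5e-5}
        for res in results.values():
            assert len(res["history"]) == 1
            assert res["confusion"].total == len(te)


class TestKFold:
    def test_folds_partition_dataset_exactly(self, micro_dataset):
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=0)
        seen = np.concatenate([
            te for _, te in skf.split(micro_dataset.beats, micro_dataset.labels)
        ])
        assert sorted(seen) == list(range(len(micro_dataset)))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="FB"):
            kfold_cv(toy_dataset([20, 20, 20, 3]), k=5)

    def test_average_row_is_column_mean_and_separable_data_scores_high(
        self, separable_dataset
    ):
        cfg = ModelConfig(seq_len=50, image_shape=(28, 28),
                          lstm_units=(4, 8, 8), conv_filters=(4, 8, 8),
                          dense_units=32)
        table = kfold_cv(
            separable_dataset, k=2,
            model_factory=lambda: ParallelCrossNetwork(cfg, seed=0),
            cfg=TrainConfig(batch_size=8, epochs=40, learning_rate=5e-4, seed=0),
        )
        folds = table.drop(index="Average")
        np.testing.assert_allclose(table.loc["Average"].values,
                                   folds.mean(axis=0).values)
        # separable-by-construction data -> near-perfect fold metrics
        assert table.loc["Average"].mean() > 90.0
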