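"""Trial classifiers: scaling, architectures, training protocol, lr selection."""

import numpy as np
import pandas as pd
import pytest

from gazefeit.models import (
    ArchConfig,
    BaselineScaler,
    TrainConfig,
    build_network,
    featurize_baseline,
    predict_trials,
    select_learning_rate,
    train,
)


def separable_baseline_data(n_participants=10, trials_each=12, gap=4.0, seed=0):
    """Two well-separated 3-feature clusters, one per class, participant-grouped."""
    rng = np.random.default_rng(seed)
    X, y, pids = [], [], []
    for i in range(n_participants):
        label = i % 2
        center = np.array([0.0, 0.0, 0.0]) + label * gap
        X.append(center + rng.normal(0, 0.5, (trials_each, 3)))
        y.extend([label] * trials_each)
        pids.extend([f"p{i:02d}"] * trials_each)
    return np.vstack(X).astype(np.float32), np.array(y), np.array(pids)


QUICK = TrainConfig(max_epochs=60, early_stop_patience=15, lr_grid=(1e-2,), seed=0)


class TestScaler:
    def test_training_statistics_give_standard_moments(self):
        rng = np.random.default_rng(1)
        X = rng.normal(5, 3, (200, 3))
        Z = BaselineScaler().fit(X).transform(X)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-6)
        assert np.allclose(Z.std(axis=0), 1, atol=1e-5)

    def test_row_at_training_mean_maps_to_zero(self):
        X = np.array([[1.0, 2.0, 3.0], [3.0, 6.0, 9.0]])
        scaler = BaselineScaler().fit(X)
        assert np.allclose(scaler.transform(np.array([[2.0, 4.0, 6.0]])), 0)

    def test_constant_feature_guarded(self):
        X = np.array([[1.0, 5.0, 2.0], [2.0, 5.0, 3.0], [3.0, 5.0, 4.0]])
        Z = BaselineScaler().fit(X).transform(X)
        assert (Z[:, 1] == 0).all()

    def test_featurize_uses_canonical_columns(self):
        df = pd.DataFrame(
            {"fix_anywhere": [400, 500], "n_saccades": [40, 50], "scan_path_length": [0.05, 0.1],
             "fix_eyes": [1, 2]}
        )
        scaler = BaselineScaler().fit(df[["fix_anywhere", "n_saccades", "scan_path_length"]].to_numpy())
        assert featurize_baseline(df, scaler).shape == (2, 3)


class TestArchitectures:
    def test_baseline_network_layout(self):
        net = build_network(ArchConfig(kind="baseline"), np.random.default_rng(0))
        out = net.forward(np.zeros((4, 3), dtype=np.float32))
        assert out.shape == (4, 2)

    def test_cnn_parameter_count_is_small(self):
        net = build_network(ArchConfig(kind="cnn"), np.random.default_rng(0))
        assert 1_000 < net.n_parameters() < 50_000
        out = net.forward(np.zeros((2, 2, 34, 34), dtype=np.float32))
        assert out.shape == (2, 2)

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError):
            ArchConfig(kind="lstm")


class TestTraining:
    def test_separable_data_reaches_high_training_accuracy(self):
        X, y, pids = separable_baseline_data()
        model = train(X, y, pids, ArchConfig(kind="baseline"), QUICK)
        assert (predict_trials(model, X) == y).mean() > 0.95

    def test_seeded_training_is_reproducible(self):
        X, y, pids = separable_baseline_data(seed=3)
        a = train(X, y, pids, ArchConfig(kind="baseline"), QUICK)
        b = train(X, y, pids, ArchConfig(kind="baseline"), QUICK)
        assert np.array_equal(predict_trials(a, X), predict_trials(b, X))
        assert a.log["val_loss"] == b.log["val_loss"]

    def test_early_stopping_bounds_and_best_restore(self):
        X, y, pids = separable_baseline_data(seed=4)
        cfg = TrainConfig(max_epochs=300, early_stop_patience=15, lr_grid=(1e-2,), seed=1)
        model = train(X, y, pids, ArchConfig(kind="baseline"), cfg)
        assert model.log["epochs_trained"] <= 300
        assert model.log["best_val_loss"] == pytest.approx(min(model.log["val_loss"]))

    def test_label_shuffled_data_stays_near_majority_rate(self):
        X, y, pids = separable_baseline_data(n_participants=12, seed=5)
        rng = np.random.default_rng(6)
        # Shuffle labels at participant level so trials stay internally consistent.
        perm = dict(zip(sorted(set(pids)), rng.permutation([i % 2 for i in range(12)])))
        y_null = np.array([perm[p] for p in pids])
        model = train(X, y_null, pids, ArchConfig(kind="baseline"), QUICK)
        acc = (predict_trials(model, X) == y_null).mean()
        assert acc < 0.85  # no memorization of noise at this capacity

    def test_single_class_rejected(self):
        X, y, pids = separable_baseline_data()
        with pytest.raises(ValueError, match="single class"):
            train(X, np.zeros_like(y), pids, ArchConfig(kind="baseline"), QUICK)

    def test_cnn_learns_blob_position(self):
        rng = np.random.default_rng(7)
        X = np.zeros((48, 2, 34, 34), dtype=np.float32)
        y = np.tile([0, 1], 24)
        pids = np.repeat([f"p{i}" for i in range(8)], 6)
        y = np.repeat([i % 2 for i in range(8)], 6)
        for i in range(48):
            r = 8 if y[i] == 0 else 24
            X[i, 1, r - 3 : r + 3, 14:20] = 1.0
            X[i] += rng.normal(0, 0.05, (2, 34, 34))
        cfg = TrainConfig(max_epochs=30, early_stop_patience=10, lr_grid=(1e-2,), seed=0)
        model = train(X, y, pids, ArchConfig(kind="cnn"), cfg)
        assert (predict_trials(model, X) == y).mean() > 0.9

    def test_predict_shape_mismatch_rejected(self):
        X, y, pids = separable_baseline_data()
        model = train(X, y, pids, ArchConfig(kind="baseline"), QUICK)
        with pytest.raises(ValueError, match="shape"):
            predict_trials(model, np.zeros((3, 5), dtype=np.float32))


class TestLearningRateSelection:
    def test_singleton_grid_short_circuits(self):
        X, y, pids = separable_baseline_data(n_participants=4, trials_each=4)
        cfg = TrainConfig(max_epochs=20, early_stop_patience=5, lr_grid=(3e-3,), seed=0)
        assert select_learning_rate(X, y, pids, ArchConfig(kind="baseline"), cfg) == 3e-3

    def test_workable_rate_beats_vanishing_rate(self):
        # With a handful of epochs, lr=1e-6 cannot move the weights; 1e-2 can.
        X, y, pids = separable_baseline_data(n_participants=6, trials_each=8, seed=8)
        cfg = TrainConfig(max_epochs=25, early_stop_patience=8, lr_grid=(1e-2, 1e-6), seed=0)
        assert select_learning_rate(X, y, pids, ArchConfig(kind="baseline"), cfg) == 1e-2

    def test_tie_goes_to_smallest_rate(self):
        # Trivially separable data: both rates reach perfect inner accuracy.
        X, y, pids = separable_baseline_data(n_participants=6, trials_each=8, gap=20.0, seed=9)
        cfg = TrainConfig(max_epochs=40, early_stop_patience=10, lr_grid=(1e-2, 5e-3), seed=0)
        assert select_learning_rate(X, y, pids, ArchConfig(kind="baseline"), cfg) == 5e-3

    def test_inner_fold_cap_limits_folds(self):
        X, y, pids = separable_baseline_data(n_participants=8, trials_each=4, seed=10)
        cfg = TrainConfig(max_epochs=15, early_stop_patience=5, lr_grid=(1e-2, 1e-3),
                          seed=0, inner_fold_cap=3)
        lr = select_learning_rate(X, y, pids, ArchConfig(kind="baseline"), cfg)
        assert lr in (1e-2, 1e-3)
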