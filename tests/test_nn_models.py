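"""Architecture contracts (shapes, parameter counts), inference semantics,
training-loop behaviour and the hyperparameter search."""

import numpy as np
import pytest

from kicksense.nn import (
    CNN_SPACE,
    TrainConfig,
    build_cnn,
    build_convlstm,
    build_lstm,
    hyperparameter_search,
    train_model,
)
from kicksense.nn.models import load_model, save_model


@pytest.fixture(scope="module")
def cnn():
    return build_cnn(seed=0)


@pytest.fixture(scope="module")
def lstm():
    return build_lstm(seed=0)


@pytest.fixture(scope="module")
def convlstm():
    return build_convlstm(seed=0)


class TestArchitectureTables:
    def test_cnn_shapes_and_parameter_counts(self, cnn):
        rows = [(r.layer_type, r.output_shape, r.n_params) for r in cnn.layer_table]
        assert rows == [
            ("1D Convolution", (398, 256), 4864),
            ("Max-pooling", (199, 256), 0),
            ("1D Convolution", (197, 128), 98432),
            ("Dropout", (197, 128), 0),
            ("Max-pooling", (98, 128), 0),
            ("1D Convolution", (96, 16), 6160),
            ("Dropout", (96, 16), 0),
            ("Max-pooling", (48, 16), 0),
            ("Fully-connected", (768,), 0),
            ("Dropout", (768,), 0),
            ("Dense", (3,), 2307),
        ]
        assert cnn.total_params == 4864 + 98432 + 6160 + 2307

    def test_lstm_parameter_counts(self, lstm):
        rows = [(r.layer_type, r.output_shape, r.n_params) for r in lstm.layer_table]
        assert rows == [
            ("LSTM", (64,), 18432),
            ("BatchNorm", (64,), 256),
            ("Dense", (3,), 195),
        ]
        # double-bias recurrent convention: 4U(D+U) + 2*4U
        assert 4 * 64 * (6 + 64) + 2 * 4 * 64 == 18432

    def test_convlstm_parameter_counts(self, convlstm):
        rows = [(r.layer_type, r.output_shape, r.n_params)
                for r in convlstm.layer_table]
        assert rows == [
            ("convLSTM2D", (1, 48, 128), 206336),
            ("Dropout", (1, 48, 128), 0),
            ("Fully-connected", (6144,), 0),
            ("Dense", (3,), 18435),
        ]
        assert 4 * 128 * (1 * 3 * (6 + 128) + 1) == 206336

    def test_convlstm_rejects_indivisible_segmentation(self):
        with pytest.raises(ValueError, match="divisible"):
            build_convlstm(num_segments=7)

    def test_printed_hyperparameter_defaults(self, cnn, lstm, convlstm):
        assert cnn.learning_rate == pytest.approx(0.09996)
        assert lstm.learning_rate == pytest.approx(0.06955)
        assert lstm.clipvalue == pytest.approx(0.19517)
        assert convlstm.learning_rate == pytest.approx(0.09403)


class TestInference:
    @pytest.mark.parametrize("arch", ["cnn", "lstm", "convlstm"])
    def test_probabilities_sum_to_one(self, arch, cnn, lstm, convlstm, rng):
        spec = {"cnn": cnn, "lstm": lstm, "convlstm": convlstm}[arch]
        x = rng.normal(size=(4, 400, 6)) * 0.3
        p = spec.predict_proba(x)
        assert p.shape == (4, 3)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_wrong_shape_is_an_error(self, cnn, rng):
        with pytest.raises(ValueError, match="expected input"):
            cnn.predict_proba(rng.normal(size=(2, 399, 6)))

    def test_duplicated_inputs_give_identical_rows(self, cnn, rng):
        w = rng.normal(size=(400, 6)) * 0.3
        p = cnn.predict_proba(np.stack([w, w]))
        np.testing.assert_array_equal(p[0], p[1])

    def test_single_window_convenience(self, lstm, rng):
        p = lstm.predict_proba(rng.normal(size=(400, 6)) * 0.3)
        assert p.shape == (3,)

    def test_save_load_roundtrip(self, tmp_path, cnn, rng):
        x = rng.normal(size=(3, 400, 6)) * 0.3
        save_model(cnn, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        np.testing.assert_allclose(back.predict_proba(x), cnn.predict_proba(x),
                                   atol=1e-7)


def _tiny_dataset(rng, n=90):
    """Trivially separable windows: class determined by a constant offset."""
    X = 0.05 * rng.normal(size=(n, 400, 6))
    y = np.array(["shot", "pass", "null"] * (n // 3))
    X[y == "shot", :, 0] += 0.8
    X[y == "pass", :, 3] += 0.8
    return X, y


class TestTrainingLoop:
    def test_undersampling_balances_classes(self, rng):
        from kicksense.svm import undersample

        labels = np.array(["null"] * 40 + ["pass"] * 25 + ["shot"] * 10)
        keep = undersample(labels, rng)
        _, counts = np.unique(labels[keep], return_counts=True)
        assert np.all(counts == 10)

    def test_single_class_training_set_raises(self, rng):
        X = rng.normal(size=(10, 400, 6))
        y = ["null"] * 10
        spec = build_cnn(seed=0)
        with pytest.raises(ValueError, match="single class"):
            train_model(spec, X, y, X, y, TrainConfig(max_epochs=1))

    def test_schedule_validation(self):
        with pytest.raises(ValueError, match="patience"):
            TrainConfig(early_stop_patience=10, lr_patience=20)
        with pytest.raises(ValueError, match="positive"):
            TrainConfig(batch_size=0)

    def test_two_lr_reductions_compound_to_four_percent(self):
        assert TrainConfig().lr_factor**2 == pytest.approx(0.04)

    def test_same_seed_same_history_and_weights(self, rng):
        X, y = _tiny_dataset(rng)
        runs = []
        for _ in range(2):
            spec = build_cnn(filters=(8, 8, 8), seed=3).astype(np.float32)
            hist = train_model(spec, X, y, X, y,
                              TrainConfig(max_epochs=3, seed=7))
            runs.append((hist, spec.get_weights()))
        assert runs[0][0] == runs[1][0]
        for wa, wb in zip(runs[0][1], runs[1][1]):
            for k in wa:
                np.testing.assert_array_equal(wa[k], wb[k])

    def test_small_cnn_fits_trivial_data(self, rng):
        X, y = _tiny_dataset(rng)
        spec = build_cnn(filters=(8, 8, 8), dropouts=(0.0, 0.0, 0.0),
                         learning_rate=0.05, seed=3).astype(np.float32)
        hist = train_model(spec, X, y, X, y, TrainConfig(max_epochs=10, seed=7))
        assert hist["best_val_f1"] > 0.95

    def test_lr_schedule_reduces_on_stagnation(self, rng):
        X, y = _tiny_dataset(rng, n=30)
        spec = build_cnn(filters=(4, 4, 4), learning_rate=0.0, seed=3)
        spec = spec.astype(np.float32)
        hist = train_model(
            spec, X, y, X, y,
            TrainConfig(max_epochs=8, lr_patience=3, early_stop_patience=7, seed=7),
        )
        # zero LR -> no improvement ever -> reduction after 3 stagnant epochs
        assert hist["lr"][0] == 0.0
        assert len(hist["val_f1"]) <= 8


class TestHyperparameterSearch:
    def test_empty_space_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            hyperparameter_search({}, 3, lambda c, f: 0.0)

    def test_budget_one_returns_single_sampled_config(self):
        calls = []

        def objective(cfg, fold):
            calls.append((cfg, fold))
            return 0.5

        best, trials = hyperparameter_search(CNN_SPACE, 1, objective, n_folds=2)
        assert len(trials) == 1 and best == trials[0].config
        assert {f for _, f in calls} == {0, 1}

    def test_cnn_space_matches_published_ranges(self):
        assert CNN_SPACE["filter1"][1] == (64, 128, 256, 512)
        assert CNN_SPACE["filter2"][1] == (16, 32, 64, 128, 256)
        assert CNN_SPACE["poolsize"][1] == (2, 3, 4, 5)
        assert CNN_SPACE["kernelsize"][1] == (2, 3, 4)
        assert CNN_SPACE["dropout1"] == ("loguniform", (0.01, 1.0))
        assert CNN_SPACE["learning_rate"] == ("loguniform", (0.001, 0.1))

    def test_search_finds_the_better_region(self):
        space = {"x": ("loguniform", (0.001, 1.0))}

        def objective(cfg, fold):
            return -abs(np.log10(cfg["x"]) + 1.5)  # optimum near x = 0.03

        best, trials = hyperparameter_search(space, 20, objective, n_folds=1,
                                             seed=3, prune=False)
        assert best["x"] == max((t.config["x"] for t in trials),
                                key=lambda v: -abs(np.log10(v) + 1.5))

    def test_pruned_trials_skip_remaining_folds(self):
        scores = iter([0.9, 0.1, 0.8])

        def objective(cfg, fold):
            return next(scores) if fold == 0 else 0.9

        _, trials = hyperparameter_search(
            {"x": ("categorical", (1, 2))}, 3, objective, n_folds=2, seed=0
        )
        assert trials[1].pruned and len(trials[1].fold_scores) == 1
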