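"""Dataset assembly, early stopping, model selection and regularization modes."""

import warnings

import numpy as np
import pytest

from diffcnn import nn, training
from diffcnn.models import (DeepModelSpec, HeadSpec, ModelGraph,
                            ShallowCNNSpec, build_deep_cnn, build_shallow_cnn)
from diffcnn.training import (SearchSpace, SequenceDataset, TrainingConfig,
                              augment_reverse_complement, build_serial_model,
                              build_transfer_model, classification_heads,
                              make_serial_graph, random_search, split_folds,
                              train_final_on_all, train_parallel_multitask,
                              train_with_early_stopping)


def _fake_examples(counts: dict[int, int], L=8):
    y = np.concatenate([np.full(n, c) for c, n in counts.items()])
    rng = np.random.default_rng(0)
    X = np.zeros((len(y), 4, L))
    X[np.arange(len(y)), rng.integers(0, 4, len(y)), 0] = 1.0
    y_reg = rng.random((len(y), 2))
    return X, y, y_reg


class TestAugmentation:
    def test_target_doubles_and_larger_classes_untouched(self):
        X, y, yr = _fake_examples({0: 100, 1: 300, 2: 250})
        Xa, ya, _ = augment_reverse_complement(X, y, yr, target_class=0)
        counts = {c: (ya == c).sum() for c in (0, 1, 2)}
        assert counts == {0: 200, 1: 300, 2: 250}

    def test_classes_below_doubled_target_fully_duplicated(self):
        X, y, yr = _fake_examples({0: 100, 1: 150, 2: 250})
        Xa, ya, _ = augment_reverse_complement(X, y, yr, target_class=0)
        counts = {c: (ya == c).sum() for c in (0, 1, 2)}
        assert counts == {0: 200, 1: 300, 2: 250}

    def test_empty_target_class_is_a_no_op(self):
        X, y, yr = _fake_examples({1: 10})
        Xa, ya, _ = augment_reverse_complement(X, y, yr, target_class=0)
        assert len(ya) == 10

    def test_duplicates_are_reverse_complements(self):
        X, y, yr = _fake_examples({0: 3})
        Xa, ya, yra = augment_reverse_complement(X, y, yr, target_class=0)
        np.testing.assert_array_equal(Xa[3:], X[:, ::-1, ::-1])
        np.testing.assert_array_equal(yra[3:], yr)


class TestSplitFolds:
    def test_partition_sizes_and_disjointness(self):
        y = np.repeat(np.arange(7), 100)
        cfg = TrainingConfig(seed=1)
        test_idx, folds = split_folds(y, cfg)
        assert len(test_idx) == 140
        all_idx = np.concatenate([test_idx] + folds)
        assert len(np.unique(all_idx)) == 700 == len(all_idx)
        for f in folds:
            assert 180 <= len(f) <= 195

    def test_stratification(self):
        y = np.repeat(np.arange(3), 60)
        test_idx, folds = split_folds(y, TrainingConfig(seed=0))
        for c in range(3):
            assert (y[test_idx] == c).sum() == 12

    def test_deterministic_under_seed(self):
        y = np.repeat(np.arange(3), 30)
        a = split_folds(y, TrainingConfig(seed=9))
        b = split_folds(y, TrainingConfig(seed=9))
        np.testing.assert_array_equal(a[0], b[0])
        for fa, fb in zip(a[1], b[1]):
            np.testing.assert_array_equal(fa, fb)


def _toy_graph(seed=0, L=200):
    spec = ShallowCNNSpec(n_filters=4, filter_width=4, fc_sizes=(8,),
                          dropout=0.0, input_length=L)
    return build_shallow_cnn(
        spec, [HeadSpec("cls", "classification", ("a", "b"))],
        rng=np.random.default_rng(seed))


def _separable_data(n=60, L=200, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = np.zeros((n, 4, L), dtype=np.float32)
    X[y == 0, 0, :] = 1.0  # poly-A vs poly-T
    X[y == 1, 3, :] = 1.0
    return X, y


class TestEarlyStopping:
    def test_no_improvement_stops_after_patience(self):
        # learning rate 0: the validation loss can never improve after the
        # first epoch, so training must stop at epoch 1 + patience
        X, y = _separable_data()
        g = _toy_graph()
        cfg = TrainingConfig(learning_rate=0.0, patience=2, max_epochs=50,
                             batch_size=16, seed=0)
        g, best_epoch, _ = train_with_early_stopping(g, "cls", X[:40], y[:40],
                                                     X[40:], y[40:], cfg)
        assert best_epoch == 1

    def test_monotone_improvement_runs_to_max_epochs(self):
        X, y = _separable_data()
        g = _toy_graph()
        cfg = TrainingConfig(learning_rate=1e-2, patience=50, max_epochs=4,
                             batch_size=16, seed=0)
        _, best_epoch, train_loss = train_with_early_stopping(
            g, "cls", X[:40], y[:40], X[40:], y[40:], cfg)
        assert best_epoch <= 4
        assert np.isfinite(train_loss)

    def test_separable_data_reduces_training_loss(self):
        X, y = _separable_data()
        g = _toy_graph()
        init_loss = nn.cross_entropy_grad(g.predict_logits(X, "cls"), y)[0]
        cfg = TrainingConfig(learning_rate=1e-2, patience=10, max_epochs=15,
                             batch_size=16, seed=0)
        g, _, stop_loss = train_with_early_stopping(g, "cls", X[:40], y[:40],
                                                    X[40:], y[40:], cfg)
        assert stop_loss < init_loss

    def test_best_weights_are_restored(self):
        X, y = _separable_data()
        g = _toy_graph()
        cfg = TrainingConfig(learning_rate=0.0, patience=1, max_epochs=10,
                             batch_size=16, seed=0)
        before = [p.data.copy() for p in g.parameters()]
        g, _, _ = train_with_early_stopping(g, "cls", X[:40], y[:40],
                                            X[40:], y[40:], cfg)
        for p, b in zip(g.parameters(), before):
            np.testing.assert_array_equal(p.data, b)  # lr 0: epoch-1 weights

    def test_bitwise_reproducible_under_seed(self):
        X, y = _separable_data()
        cfg = TrainingConfig(learning_rate=1e-2, patience=3, max_epochs=5,
                             batch_size=16, seed=4)
        ga, _, _ = train_with_early_stopping(_toy_graph(1), "cls", X[:40],
                                             y[:40], X[40:], y[40:], cfg)
        gb, _, _ = train_with_early_stopping(_toy_graph(1), "cls", X[:40],
                                             y[:40], X[40:], y[40:], cfg)
        for pa, pb in zip(ga.parameters(), gb.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)


class TestFinalTraining:
    def test_infinite_criterion_stops_after_first_epoch(self):
        X, y = _separable_data()
        g = _toy_graph()
        cfg = TrainingConfig(learning_rate=1e-3, max_epochs=50, batch_size=16,
                             seed=0)
        counted = []
        orig = training._epoch

        def counting(*args, **kw):
            counted.append(1)
            return orig(*args, **kw)

        training._epoch = counting
        try:
            train_final_on_all(g, "cls", X, y, criterion=np.inf, config=cfg)
        finally:
            training._epoch = orig
        assert len(counted) == 1

    def test_unreachable_criterion_warns_at_max_epochs(self):
        X, y = _separable_data()
        g = _toy_graph()
        cfg = TrainingConfig(learning_rate=1e-3, max_epochs=2, batch_size=16,
                             seed=0)
        with pytest.warns(UserWarning, match="not reached"):
            train_final_on_all(g, "cls", X, y, criterion=1e-9, config=cfg)

    def test_final_loss_meets_reachable_criterion(self):
        X, y = _separable_data()
        g = _toy_graph()
        cfg = TrainingConfig(learning_rate=1e-2, max_epochs=40, batch_size=16,
                             seed=0)
        init_loss = nn.cross_entropy_grad(g.predict_logits(X, "cls"), y)[0]
        criterion = 0.8 * init_loss
        g = train_final_on_all(g, "cls", X, y, criterion, cfg)
        final = nn.cross_entropy_grad(g.predict_logits(X, "cls"), y)[0]
        assert final <= criterion * 1.5  # epoch-mean criterion, end-state check is loose


@pytest.fixture(scope="module")
def seq_dataset(small_dataset):
    return SequenceDataset.from_synthetic(small_dataset)


class TestRandomSearch:
    CFG = TrainingConfig(max_epochs=2, patience=1, batch_size=32, seed=0)
    HEAD = None  # set per test from dataset class names

    def test_single_trial_wins_and_is_deterministic(self, seq_dataset):
        head = HeadSpec("cls", "classification", tuple(seq_dataset.class_names))
        space = SearchSpace({"n_filters": [4], "filter_width": [6],
                             "fc_sizes": [(8,)], "dropout": [0.0],
                             "input_length": [210]}, n_trials=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t1, g1, test1 = random_search(space, seq_dataset, head, self.CFG)
            t2, g2, test2 = random_search(space, seq_dataset, head, self.CFG)
        assert t1.description["trial"] == 0
        np.testing.assert_array_equal(test1, test2)
        for pa, pb in zip(g1.parameters(), g2.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_deep_family_derives_input_length_from_rf(self, seq_dataset):
        head = HeadSpec("cls", "classification", tuple(seq_dataset.class_names))
        space = SearchSpace({"n_pool_blocks": [1], "n_dil_blocks": [1],
                             "channels": [4], "kernel_widths": [3],
                             "pool_width": [2], "bottleneck": ["off"],
                             "bottleneck_ratio": [0.5], "dropout": [0.0],
                             "dilation_base": [1], "dilation_growth": [2.0],
                             "max_dilation": [4]}, n_trials=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trial, g, _ = random_search(space, seq_dataset, head, self.CFG,
                                        family="deep")
        # RF of this spec is 8, far below the 200 nt floor
        assert g.input_length == 200

    def test_empty_choice_list_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace({"n_filters": []})


class TestTransfer:
    def test_conv_frozen_and_input_length_inherited(self, seq_dataset):
        reg_head = HeadSpec("regression", "regression",
                            tuple(seq_dataset.replicate_names))
        spec = ShallowCNNSpec(n_filters=4, filter_width=6, fc_sizes=(8,),
                              dropout=0.0, input_length=220)
        gr = build_shallow_cnn(spec, [reg_head], rng=np.random.default_rng(0))
        X = seq_dataset.encode(220)
        cfg = TrainingConfig(max_epochs=2, patience=1, batch_size=32, seed=0)
        gr, _, _ = train_with_early_stopping(gr, "regression", X[:150],
                                             seq_dataset.y_reg[:150], X[150:],
                                             seq_dataset.y_reg[150:], cfg)
        w_before = gr.trunk.layers[0].w.data.copy()
        head = HeadSpec("cls", "classification", tuple(seq_dataset.class_names))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, gt, _ = build_transfer_model(gr, seq_dataset, head, cfg,
                                            fc_size_choices=[(8,)],
                                            dropout_choices=[0.0])
        np.testing.assert_array_equal(gt.trunk.layers[0].w.data, w_before)
        assert gt.input_length == 220
        assert not gt.trunk.layers[0].w.trainable

    def test_requires_shallow_regression_model(self, seq_dataset):
        spec = DeepModelSpec(n_pool_blocks=1, n_dil_blocks=0, channels=4,
                             kernel_widths=3, pool_width=2, bottleneck="off",
                             dropout=0.0, input_length=200)
        g = build_deep_cnn(spec, [HeadSpec("regression", "regression", ("r",))],
                           rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            build_transfer_model(g, seq_dataset,
                                 HeadSpec("cls", "classification", ("a", "b")),
                                 TrainingConfig())


def _identity_regression_graph(n_out=2, L=200):
    """A fixed graph whose 'regression' output is the per-channel mean of
    the first n_out one-hot rows — perfectly known, no training involved."""
    conv = nn.Conv1d(4, n_out, 1, rng=np.random.default_rng(0))
    conv.w.data[...] = 0.0
    for j in range(n_out):
        conv.w.data[j, j, 0] = 1.0
    conv.b.data[...] = 0.0
    trunk = nn.Sequential([conv])
    head = HeadSpec("regression", "regression", tuple(f"r{i}" for i in range(n_out)))
    spec = ShallowCNNSpec(n_filters=n_out, filter_width=1, fc_sizes=(),
                          dropout=0.0, input_length=L)
    return ModelGraph(trunk, {"regression": (head, nn.Sequential([nn.GlobalAvgPool()]))},
                      spec, family="deep")


class TestSerial:
    def test_classifier_learns_replicate_comparison(self):
        # down label defined exactly as output_0 < output_1 of the frozen
        # trunk; the dense classifier must recover it almost perfectly
        rng = np.random.default_rng(0)
        base = _identity_regression_graph()
        n, L = 240, 200
        X = np.zeros((n, 4, L), dtype=np.float32)
        frac = rng.random(n)
        for i in range(n):
            k = int(frac[i] * L)
            X[i, 0, :k] = 1.0
            X[i, 1, k:] = 1.0
        y = (frac < 0.5).astype(int)  # class 0 iff channel-A mean < channel-C mean
        head = HeadSpec("down", "classification", ("down", "non"))
        sg = make_serial_graph(base, head, (8,), np.random.default_rng(1))
        cfg = TrainingConfig(learning_rate=3e-2, max_epochs=60, patience=60,
                             batch_size=32, seed=0)
        sg, _, _ = train_with_early_stopping(sg, "down", X[:180], 1 - y[:180],
                                             X[180:], 1 - y[180:], cfg)
        pred = sg.predict_logits(X[180:], "down").argmax(axis=1)
        truth = 1 - y[180:]
        recall = (pred[truth == 0] == 0).mean()
        assert recall >= 0.95

    def test_trunk_weights_frozen_during_training(self):
        base = _identity_regression_graph()
        before = [p.data.copy() for p in base.parameters()]
        X = np.random.default_rng(0).random((40, 4, 200)).astype(np.float32)
        y = np.random.default_rng(1).integers(0, 2, 40)
        head = HeadSpec("down", "classification", ("a", "b"))
        sg = make_serial_graph(base, head, (8,), np.random.default_rng(2))
        cfg = TrainingConfig(learning_rate=1e-2, max_epochs=3, patience=3,
                             batch_size=16, seed=0)
        train_with_early_stopping(sg, "down", X[:30], y[:30], X[30:], y[30:], cfg)
        for p, b in zip(base.parameters(), before):
            np.testing.assert_array_equal(p.data, b)

    def test_identical_trunk_outputs_give_identical_logits(self):
        base = _identity_regression_graph()
        head = HeadSpec("down", "classification", ("a", "b"))
        sg = make_serial_graph(base, head, (8,), np.random.default_rng(0))
        x = np.zeros((2, 4, 200), dtype=np.float32)
        x[0, 0, :50] = 1.0
        x[1, 0, 100:150] = 1.0  # different position, same channel means
        out = sg.predict_logits(x, "down")
        np.testing.assert_allclose(out[0], out[1], atol=1e-6)

    def test_selection_over_hidden_sizes(self, seq_dataset):
        spec = DeepModelSpec(n_pool_blocks=1, n_dil_blocks=0, channels=4,
                             kernel_widths=3, pool_width=2, bottleneck="off",
                             dropout=0.0, input_length=200)
        gr = build_deep_cnn(spec, [HeadSpec("regression", "regression",
                                            tuple(seq_dataset.replicate_names))],
                            rng=np.random.default_rng(0))
        head = HeadSpec("cls", "classification", tuple(seq_dataset.class_names))
        cfg = TrainingConfig(max_epochs=2, patience=1, batch_size=32, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trial, sg, _ = build_serial_model(gr, seq_dataset, head, cfg,
                                              hidden_choices=[(4,), (8,)])
        assert trial.description["hidden"] in ((4,), (8,))


class TestParallel:
    def test_head_class_sets(self, seq_dataset):
        heads2 = classification_heads(seq_dataset.class_names, "2task")
        assert [h.name for h in heads2] == ["down"]
        assert heads2[0].names == ("down_t0", "down_t1", "down_t2",
                                   "non_differential")
        heads3 = classification_heads(seq_dataset.class_names, "3task")
        assert heads3[1].names == ("up_t0", "up_t1", "up_t2",
                                   "non_differential")
        with pytest.raises(ValueError):
            classification_heads(seq_dataset.class_names, "4task")

    def test_early_stopping_never_consults_regression_loss(self, seq_dataset,
                                                           monkeypatch):
        spec = DeepModelSpec(n_pool_blocks=1, n_dil_blocks=0, channels=4,
                             kernel_widths=3, pool_width=2, bottleneck="off",
                             dropout=0.0, input_length=200)
        seen = []
        orig = training.evaluate_loss

        def spy(graph, head, X, y, batch_size=256):
            seen.append(head)
            return orig(graph, head, X, y, batch_size)

        monkeypatch.setattr(training, "evaluate_loss", spy)
        cfg = TrainingConfig(max_epochs=2, patience=1, batch_size=32, seed=0)
        graph, _ = train_parallel_multitask(spec, seq_dataset, cfg, mode="3task")
        assert "regression" not in seen
        assert set(seen) == {"down", "up"}
        assert set(graph.heads) == {"regression", "down", "up"}

    def test_shared_trunk_updated_by_all_tasks(self, seq_dataset):
        spec = DeepModelSpec(n_pool_blocks=1, n_dil_blocks=0, channels=4,
                             kernel_widths=3, pool_width=2, bottleneck="off",
                             dropout=0.0, input_length=200)
        cfg = TrainingConfig(max_epochs=1, patience=1, batch_size=32, seed=0)
        graph, _ = train_parallel_multitask(spec, seq_dataset, cfg, mode="2task")
        # the down head sees only down/non-differential examples: C = 4
        assert graph.head_spec("down").size == 4
        assert graph.head_spec("regression").size == len(
            seq_dataset.replicate_names)
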