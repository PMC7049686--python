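"""Attribution methods against exactly solvable oracles."""

import numpy as np
import pytest

from diffcnn.attribution import (AttributionTrack, MutationMap,
                                 attribute_dataset, completeness_check,
                                 completeness_report, ensemble_attribution,
                                 gradient_times_input, importance_from_map,
                                 integrated_gradients, mutation_map,
                                 rank_features, strongest_window)
from diffcnn.genomics import one_hot_encode
from diffcnn.models import DeepModelSpec, HeadSpec, build_deep_cnn

from helpers import LinearGraph, brute_force_window_max

L = 40


@pytest.fixture(scope="module")
def linear_graph():
    rng = np.random.default_rng(7)
    return LinearGraph(rng.normal(size=(3, 4, L)), rng.normal(size=3))


@pytest.fixture(scope="module")
def onehot_x():
    rng = np.random.default_rng(8)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=L))
    return one_hot_encode(seq, L)


class TestMutationMap:
    def test_reference_base_effects_are_zero(self, linear_graph, onehot_x):
        mm = mutation_map(linear_graph, onehot_x, "out", 1)
        ref = onehot_x.argmax(axis=0)
        for i in range(L):
            assert mm.effects[i, ref[i]] == 0.0

    def test_closed_form_on_linear_graph(self, linear_graph, onehot_x):
        c = 2
        mm = mutation_map(linear_graph, onehot_x, "out", c)
        w = linear_graph.w[c]
        ref = onehot_x.argmax(axis=0)
        for i in range(L):
            for b in range(4):
                expected = 0.0 if b == ref[i] else w[b, i] - w[ref[i], i]
                assert mm.effects[i, b] == pytest.approx(expected, abs=1e-9)

    def test_padded_columns_are_skipped(self, linear_graph):
        x = one_hot_encode("ACGT" * 5, L)  # 20 nt centred in 40
        mm = mutation_map(linear_graph, x, "out", 0)
        pad = np.nonzero(x.sum(axis=0) == 0)[0]
        assert len(pad) == 20
        np.testing.assert_array_equal(mm.effects[pad], 0.0)

    def test_number_of_evaluations_is_three_per_base(self, linear_graph, onehot_x):
        calls = []
        orig = linear_graph.predict_logits

        def counting(X, head, batch_size=256):
            calls.append(len(X))
            return orig(X, head)

        linear_graph.predict_logits = counting
        try:
            mutation_map(linear_graph, onehot_x, "out", 0)
        finally:
            linear_graph.predict_logits = orig
        assert sum(calls) == 1 + 3 * L  # reference pass + 3L substitutions

    def test_unknown_class_rejected(self, linear_graph, onehot_x):
        with pytest.raises(ValueError):
            mutation_map(linear_graph, onehot_x, "out", 17)


class TestImportance:
    def test_sign_convention_example(self):
        mm = MutationMap(np.array([[0.0, -2.0, -3.0, -1.0]]), 0.0)
        track = importance_from_map(mm)
        assert track.scores[0] == pytest.approx(6.0)

    def test_zero_map_gives_zero_track(self):
        track = importance_from_map(MutationMap(np.zeros((5, 4)), 0.0))
        np.testing.assert_array_equal(track.scores, 0.0)

    def test_closed_form_on_linear_graph(self, linear_graph, onehot_x):
        c = 0
        track = importance_from_map(mutation_map(linear_graph, onehot_x, "out", c))
        w = linear_graph.w[c]
        ref = onehot_x.argmax(axis=0)
        for i in range(L):
            expected = 3 * w[ref[i], i] - sum(w[b, i] for b in range(4)
                                              if b != ref[i])
            assert track.scores[i] == pytest.approx(expected, abs=1e-9)


class TestIntegratedGradients:
    def test_exact_for_linear_model_any_steps(self, linear_graph, onehot_x):
        w = linear_graph.w[1]
        for steps in (1, 3, 64):
            track = integrated_gradients(linear_graph, onehot_x, "out", 1,
                                         steps=steps)
            expected = (w * onehot_x).sum(axis=0)
            np.testing.assert_allclose(track.scores, expected, atol=1e-10)

    def test_exact_with_nonzero_references(self, linear_graph, onehot_x, rng):
        refs = rng.random((4, 4, L))
        track = integrated_gradients(linear_graph, onehot_x, "out", 2,
                                     steps=16, references=refs)
        w = linear_graph.w[2]
        expected = np.mean([(w * (onehot_x - r)).sum(axis=0) for r in refs],
                           axis=0)
        np.testing.assert_allclose(track.scores, expected, atol=1e-10)

    def test_gradient_times_input_is_single_step_zero_reference(
            self, linear_graph, onehot_x):
        gxi = gradient_times_input(linear_graph, onehot_x, "out", 0)
        ig1 = integrated_gradients(linear_graph, onehot_x, "out", 0, steps=1)
        np.testing.assert_array_equal(gxi.scores, ig1.scores)

    def test_gxi_equals_ig1_on_a_real_network(self):
        spec = DeepModelSpec(n_pool_blocks=1, n_dil_blocks=1, channels=8,
                             kernel_widths=5, pool_width=2, bottleneck="relu",
                             bottleneck_ratio=0.5, dropout=0.0, input_length=200)
        g = build_deep_cnn(spec, [HeadSpec("cls", "classification", ("a", "b"))],
                           rng=np.random.default_rng(0))
        x = one_hot_encode("ACGT" * 50, 200)
        gxi = gradient_times_input(g, x, "cls", 1)
        ig1 = integrated_gradients(g, x, "cls", 1, steps=1)
        np.testing.assert_allclose(gxi.scores, ig1.scores, atol=1e-7)

    def test_gxi_zero_input_gives_zero_track(self, linear_graph):
        track = gradient_times_input(linear_graph, np.zeros((4, L)), "out", 0)
        np.testing.assert_array_equal(track.scores, 0.0)

    def test_gxi_closed_form(self, linear_graph, onehot_x):
        track = gradient_times_input(linear_graph, onehot_x, "out", 1)
        ref = onehot_x.argmax(axis=0)
        for i in range(L):
            assert track.scores[i] == pytest.approx(linear_graph.w[1][ref[i], i])

    def test_reference_length_mismatch_rejected(self, linear_graph, onehot_x):
        with pytest.raises(ValueError):
            integrated_gradients(linear_graph, onehot_x, "out", 0, steps=4,
                                 references=np.zeros((1, 4, L + 5)))


class TestCompleteness:
    def test_zero_deviation_for_affine_model(self, linear_graph, onehot_x):
        for steps in (1, 7, 33):
            dev = completeness_check(linear_graph, onehot_x, "out", 0, steps)
            assert dev < 1e-10

    def test_degenerate_denominator_flagged(self, onehot_x):
        g = LinearGraph(np.zeros((2, 4, L)), np.zeros(2))  # f identically 0
        assert np.isnan(completeness_check(g, onehot_x, "out", 0, 4))

    def test_mean_deviation_non_increasing_in_steps_on_trained_net(self):
        spec = DeepModelSpec(n_pool_blocks=1, n_dil_blocks=1, channels=8,
                             kernel_widths=5, pool_width=2, bottleneck="relu",
                             bottleneck_ratio=0.5, dropout=0.0, input_length=200)
        g = build_deep_cnn(spec, [HeadSpec("cls", "classification", ("a", "b"))],
                           rng=np.random.default_rng(3))
        rng = np.random.default_rng(4)
        X = np.stack([one_hot_encode("".join("ACGT"[i] for i in
                                             rng.integers(0, 4, 200)), 200)
                      for _ in range(10)])
        report = completeness_report(g, X, "cls", 0, step_counts=(4, 32, 128))
        assert report[128]["mean"] <= report[4]["mean"] + 1e-3
        assert report[128]["max"] < 0.05


class TestStrongestWindow:
    def test_block_of_mass_leftmost_tie_break(self):
        scores = np.zeros(100)
        scores[50:59] = 1.0  # all mass inside any window starting 34..50
        call = strongest_window(AttributionTrack(scores, "r"), window=25)
        assert (call.start, call.end) == (34, 59)
        assert call.score == pytest.approx(9.0)

    def test_uniform_track_starts_at_zero(self):
        call = strongest_window(AttributionTrack(np.ones(60), "r"), window=25)
        assert call.start == 0

    def test_matches_exhaustive_search_on_random_tracks(self, rng):
        for _ in range(500):
            n = int(rng.integers(25, 120))
            scores = rng.normal(size=n)
            call = strongest_window(AttributionTrack(scores, "r"), window=25)
            start, best = brute_force_window_max(scores, 25)
            assert call.start == start
            assert call.score == pytest.approx(best, rel=1e-9)

    def test_track_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            strongest_window(AttributionTrack(np.ones(10), "r"), window=25)


class TestRanking:
    def _tracks(self, scores_by_id):
        return [AttributionTrack(np.full(30, v), rid)
                for rid, v in scores_by_id.items()]

    def test_descending_order(self):
        calls = rank_features(self._tracks({"r1": 3.0, "r2": 1.0, "r3": 2.0}),
                              window=25)
        assert [c.region_id for c in calls] == ["r1", "r3", "r2"]
        assert [c.rank for c in calls] == [1, 2, 3]

    def test_permutation_invariance(self):
        tracks = self._tracks({"r1": 3.0, "r2": 1.0, "r3": 2.0})
        a = rank_features(tracks, window=25)
        b = rank_features(tracks[::-1], window=25)
        assert [c.region_id for c in a] == [c.region_id for c in b]

    def test_ties_break_by_region_identifier(self):
        calls = rank_features(self._tracks({"zz": 1.0, "aa": 1.0}), window=25)
        assert [c.region_id for c in calls] == ["aa", "zz"]


class TestEnsemble:
    def test_identical_graphs_equal_single_model(self, linear_graph, onehot_x):
        single = gradient_times_input(linear_graph, onehot_x, "out", 0)
        ens = ensemble_attribution([linear_graph, linear_graph], onehot_x,
                                   "out", 0, method="gradient_x_input")
        np.testing.assert_allclose(ens.scores, single.scores, atol=1e-12)

    def test_opposite_models_cancel(self, onehot_x, rng):
        w = rng.normal(size=(2, 4, L))
        g1, g2 = LinearGraph(w), LinearGraph(-w)
        ens = ensemble_attribution([g1, g2], onehot_x, "out", 0,
                                   method="gradient_x_input")
        np.testing.assert_allclose(ens.scores, 0.0, atol=1e-12)

    def test_all_three_modes_run(self, linear_graph, rng):
        X = np.stack([one_hot_encode("".join("ACGT"[i] for i in
                                             rng.integers(0, 4, L)), L)
                      for _ in range(4)])
        ids = [f"r{i}" for i in range(4)]
        graphs = [linear_graph, linear_graph]
        for mode, kw in [("all_data", {}), ("ensemble", {}),
                         ("held_out", {"fold_of": np.array([0, 1, 0, 1])})]:
            tracks = attribute_dataset(graphs, X, ids, "out", 0,
                                       method="gradient_x_input", mode=mode, **kw)
            assert len(tracks) == 4
        with pytest.raises(ValueError):
            attribute_dataset(graphs, X, ids, "out", 0, mode="held_out")
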