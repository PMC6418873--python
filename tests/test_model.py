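import numpy as np
import pytest

from dticnn import model as M
from dticnn.errors import DomainError, TrainingError


class TestShapePropagation:
    def test_reference_input_shape(self):
        model = M.build_model((58, 70, 58), M.TrainingConfig(epochs=1, seed=0))
        assert model.architecture.hidden_spatial == [(29, 35, 29), (15, 18, 15), (8, 9, 8)]
        assert model.architecture.linear_in == 8 * 9 * 8 * 128 == 73728
        linear = model.layers[-1]
        assert linear.W.size + linear.b.size == 73728 * 2 + 2 == 147458

    def test_conv1_parameter_count(self):
        model = M.build_model((8, 8, 8), M.TrainingConfig(epochs=1, seed=0))
        conv1 = model.layers[0]
        assert conv1.W.size + conv1.b.size == 27 * 1 * 32 + 32 == 896

    def test_channel_counts(self):
        model = M.build_model((16, 16, 16), M.TrainingConfig(epochs=1, seed=0))
        convs = [l for l in model.layers if type(l).__name__ == "Conv3dSame"]
        assert [c.c_out for c in convs] == [32, 64, 128]

    @pytest.mark.parametrize(
        "shape,expected",
        [
            ((16, 16, 16), [(8, 8, 8), (4, 4, 4), (2, 2, 2)]),
            ((24, 28, 24), [(12, 14, 12), (6, 7, 6), (3, 4, 3)]),
            ((9, 11, 13), [(5, 6, 7), (3, 3, 4), (2, 2, 2)]),
        ],
    )
    def test_hand_calculated_shapes(self, shape, expected):
        model = M.build_model(shape, M.TrainingConfig(epochs=1, seed=0))
        assert model.architecture.hidden_spatial == expected

    def test_too_small_input_rejected(self):
        with pytest.raises(DomainError):
            M.build_model((4, 16, 16), M.TrainingConfig(epochs=1, seed=0))

    def test_two_pool_variant(self):
        model = M.build_model((8, 8, 8), M.TrainingConfig(epochs=1, seed=0), n_pools=2)
        assert model.architecture.hidden_spatial == [(4, 4, 4), (2, 2, 2), (2, 2, 2)]


class TestForward:
    def test_probabilities_normalize(self):
        model = M.build_model((8, 8, 8), M.TrainingConfig(epochs=1, seed=0))
        x = np.random.default_rng(0).normal(size=(7, 8, 8, 8, 1)).astype(np.float32)
        probs = M.forward(model, x)
        assert probs.shape == (7, 2)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_batch_independent(self):
        model = M.build_model((8, 8, 8), M.TrainingConfig(epochs=1, seed=0))
        rng = np.random.default_rng(1)
        batch = rng.normal(size=(45, 8, 8, 8, 1)).astype(np.float32)
        alone = M.forward(model, batch[:1], training=False)
        inside = M.forward(model, batch, training=False)[:1]
        # float32 GEMM blocking differs with batch size; equality up to
        # rounding noise only
        np.testing.assert_allclose(alone, inside, atol=1e-6)

    def test_zero_linear_weights_give_uniform(self):
        model = M.build_model((8, 8, 8), M.TrainingConfig(epochs=1, seed=0))
        model.layers[-1].W[...] = 0
        model.layers[-1].b[...] = 0
        x = np.random.default_rng(2).normal(size=(3, 8, 8, 8, 1)).astype(np.float32)
        np.testing.assert_allclose(M.forward(model, x), 0.5, atol=1e-7)

    def test_shape_mismatch_rejected(self):
        model = M.build_model((8, 8, 8), M.TrainingConfig(epochs=1, seed=0))
        with pytest.raises(DomainError):
            M.forward(model, np.zeros((2, 9, 8, 8, 1), np.float32))


class TestCost:
    def test_perfect_prediction_zero(self):
        assert M.cross_entropy_cost([(1.0, 0.0)], [(1, 0)]) == 0.0

    def test_uniform_prediction_ln2(self):
        assert M.cross_entropy_cost([(0.5, 0.5)], [(0, 1)]) == pytest.approx(np.log(2))

    def test_hand_summed_batch(self):
        preds = [(0.9, 0.1), (0.2, 0.8), (0.6, 0.4)]
        labels = [(1, 0), (0, 1), (0, 1)]
        expected = -(np.log(0.9) + np.log(0.8) + np.log(0.4))
        assert M.cross_entropy_cost(preds, labels) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(DomainError):
            M.cross_entropy_cost([(0.5, 0.5)], [(1, 0), (0, 1)])

    def test_nonnegative(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet([1, 1], size=20)
        y = np.eye(2)[rng.integers(0, 2, 20)]
        assert M.cross_entropy_cost(p, y) >= 0


class TestTraining:
    def test_separable_reaches_perfect_validation(self, trained_tiny_model):
        _, history, _ = trained_tiny_model
        assert max(history.val_accuracy) == 1.0

    def test_deterministic(self, separable_store):
        store = separable_store
        labels = store.labels.astype(np.float32)

        def run():
            cfg = M.TrainingConfig(epochs=3, seed=9, batch_size=8)
            model = M.build_model(store.target_shape, cfg)
            _, h = M.train(model, store.volumes[:16], labels[:16],
                           store.volumes[16:], labels[16:], cfg)
            return h

        h1, h2 = run(), run()
        assert h1.train_cost == h2.train_cost
        assert h1.val_accuracy == h2.val_accuracy

    def test_cost_decreases_on_separable(self, trained_tiny_model):
        _, history, _ = trained_tiny_model
        costs = history.train_cost
        # non-increasing after the first epoch within 5% tolerance
        for earlier, later in zip(costs[1:], costs[2:]):
            assert later <= earlier * 1.05 + 1e-6

    def test_history_lengths(self, trained_tiny_model):
        _, history, _ = trained_tiny_model
        assert len(history.train_cost) == len(history.val_accuracy) == 5

    def test_empty_sets_rejected(self):
        cfg = M.TrainingConfig(epochs=1, seed=0)
        model = M.build_model((8, 8, 8), cfg)
        with pytest.raises(DomainError):
            M.train(model, np.zeros((0, 8, 8, 8)), np.zeros((0, 2)),
                    np.zeros((1, 8, 8, 8)), np.zeros((1, 2)), cfg)

    def test_divergence_reported(self, separable_store):
        store = separable_store
        cfg = M.TrainingConfig(epochs=2, seed=0, batch_size=8)
        model = M.build_model(store.target_shape, cfg)
        labels = store.labels.astype(np.float32)
        model.layers[-1].W[...] = np.inf  # non-finite cost must abort with context
        with pytest.raises(TrainingError, match="epoch 0"):
            M.train(model, store.volumes[:16], labels[:16],
                    store.volumes[16:], labels[16:], cfg)


class TestFeatureMaps:
    def test_layer_counts(self, trained_tiny_model):
        model, _, store = trained_tiny_model
        vol = store.volumes[0]
        assert len(M.extract_feature_maps(model, vol, 1)) == 32
        assert len(M.extract_feature_maps(model, vol, 2)) == 64
        assert len(M.extract_feature_maps(model, vol, 3)) == 128

    def test_layer1_spatial_shape(self, trained_tiny_model):
        model, _, store = trained_tiny_model
        maps = M.extract_feature_maps(model, store.volumes[0], 1)
        assert maps[0].shape == (6, 6, 6)  # 12 -> ceil(12/2)

    def test_invalid_layer_rejected(self, trained_tiny_model):
        model, _, store = trained_tiny_model
        with pytest.raises(DomainError):
            M.extract_feature_maps(model, store.volumes[0], 4)

    def test_deterministic_across_identical_models(self, separable_store):
        store = separable_store

        def build():
            cfg = M.TrainingConfig(epochs=1, seed=5, batch_size=8)
            return M.build_model(store.target_shape, cfg)

        m1, m2 = build(), build()
        f1 = M.extract_feature_maps(m1, store.volumes[0], 1)
        f2 = M.extract_feature_maps(m2, store.volumes[0], 1)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)


class TestCheckpoint:
    def test_round_trip(self, trained_tiny_model, tmp_path):
        model, _, store = trained_tiny_model
        path = tmp_path / "model.npz"
        M.save_checkpoint(model, path)
        back = M.load_checkpoint(path)
        x = store.volumes[:3]
        np.testing.assert_array_equal(M.forward(back, x[..., None]), M.forward(model, x[..., None]))
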