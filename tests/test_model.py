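import numpy as np
import pytest

from pulsecast import CbanetModel, ModelConfig
from pulsecast.errors import ConfigError, ValidationError

SMALL = ModelConfig(conv1_channels=4, conv2_channels=8, lstm_hidden=4, lstm_layers=2, heads=2)


@pytest.fixture
def small_model():
    return CbanetModel(SMALL, seed=0)


class TestShapeContract:
    @pytest.mark.parametrize("T", [3, 10, 700])
    def test_full_chain_shapes(self, T):
        cfg = ModelConfig(conv1_channels=8, conv2_channels=16, lstm_hidden=8, heads=2)
        m = CbanetModel(cfg, seed=1)
        x = np.random.default_rng(T).standard_normal((T, 7))
        h1 = m.lfe_forward(x)
        assert h1.shape == (T, 16)
        h2 = m.trn_forward(h1.data)
        assert h2.shape == (T, 16)  # 2h = 16
        z = m.gra_forward(h2.data)
        assert z.shape == (T, 16)
        y = m.readout(z.data)
        assert y.shape == (T, 1)
        assert m.forward(x).shape == (T, 1)

    def test_batched_input(self, small_model):
        x = np.zeros((3, 12, 7))
        assert small_model.forward(x).shape == (3, 12, 1)

    def test_channel_mismatch_rejected(self, small_model):
        with pytest.raises(ValidationError):
            small_model.lfe_forward(np.zeros((10, 5)))

    def test_head_divisibility_enforced(self):
        with pytest.raises(ConfigError):
            ModelConfig(lstm_hidden=4, heads=3)

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(kernel=4)


class TestLfe:
    def test_output_nonnegative(self, small_model):
        x = np.random.default_rng(0).standard_normal((20, 7))
        assert np.all(small_model.lfe_forward(x).data >= 0.0)

    def test_zero_input_zero_bias_gives_zero(self, small_model):
        small_model.params["conv1_b"].data[:] = 0.0
        small_model.params["conv2_b"].data[:] = 0.0
        out = small_model.lfe_forward(np.zeros((15, 7)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_shift_equivariance_in_interior(self, small_model):
        rng = np.random.default_rng(3)
        T, k = 40, 7
        x = rng.standard_normal((T, 7))
        shifted = np.roll(x, k, axis=0)
        a = small_model.lfe_forward(x).data
        b = small_model.lfe_forward(shifted).data
        # compare away from both edges (2 conv layers -> halo of 2 samples)
        margin = 4
        np.testing.assert_allclose(
            a[margin : T - k - margin], b[margin + k : T - margin], atol=1e-10
        )


class TestTrn:
    def test_width_is_twice_hidden(self):
        m = CbanetModel(ModelConfig(lstm_hidden=64), seed=0)
        out = m.trn_forward(np.zeros((4, 64)))
        assert out.shape == (4, 128)

    def test_single_step_sequence(self, small_model):
        out = small_model.trn_forward(np.zeros((1, 8)))
        assert out.shape == (1, 8)
        assert np.all(np.isfinite(out.data))

    def test_time_reversal_swaps_direction_halves(self):
        # with the backward params copied onto the forward ones, reversing
        # the input in time swaps the two h-sized halves of the output
        cfg = ModelConfig(conv1_channels=4, conv2_channels=8, lstm_hidden=4, lstm_layers=1, heads=2)
        m = CbanetModel(cfg, seed=5)
        for name in ("Wx", "Wh", "b"):
            m.params[f"lstm0_bwd_{name}"].data = m.params[f"lstm0_fwd_{name}"].data.copy()
        x = np.random.default_rng(0).standard_normal((5, 8))
        h = m.trn_forward(x).data
        h_rev = m.trn_forward(x[::-1].copy()).data
        np.testing.assert_allclose(h[:, :4], h_rev[::-1, 4:], atol=1e-12)
        np.testing.assert_allclose(h[:, 4:], h_rev[::-1, :4], atol=1e-12)


class TestGra:
    def test_attention_rows_stochastic_across_seeds(self):
        for seed in range(100):
            m = CbanetModel(SMALL, seed=seed)
            x = np.random.default_rng(seed).standard_normal((6, 8))
            m.gra_forward(x)
            alpha = m.last_attention
            assert np.all(alpha >= 0.0) and np.all(alpha <= 1.0)
            np.testing.assert_allclose(alpha.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_step_attention_is_one(self, small_model):
        small_model.gra_forward(np.random.default_rng(0).standard_normal((1, 8)))
        np.testing.assert_array_equal(small_model.last_attention, 1.0)

    def test_zero_keys_give_uniform_attention(self, small_model):
        small_model.params["Wk"].data[:] = 0.0
        x = np.random.default_rng(1).standard_normal((9, 8))
        small_model.gra_forward(x)
        np.testing.assert_allclose(small_model.last_attention, 1.0 / 9.0, atol=1e-12)


class TestReadout:
    def test_zero_weights_constant_bias(self, small_model):
        small_model.params["out_W"].data[:] = 0.0
        small_model.params["out_b"].data[:] = 0.5
        out = small_model.readout(np.random.default_rng(0).standard_normal((7, 8)))
        np.testing.assert_allclose(out.data, 0.5)

    def test_identical_rows_identical_outputs(self, small_model):
        row = np.random.default_rng(2).standard_normal(8)
        out = small_model.readout(np.stack([row, row])).data
        np.testing.assert_array_equal(out[0], out[1])


class TestFullModel:
    def test_inference_deterministic(self, small_model):
        x = np.random.default_rng(4).standard_normal((25, 7))
        a = small_model.predict(x)
        b = small_model.predict(x)
        np.testing.assert_array_equal(a, b)

    def test_parameter_count_grows_with_hidden_size(self):
        n_small = CbanetModel(ModelConfig(lstm_hidden=16), seed=0).n_parameters()
        n_large = CbanetModel(ModelConfig(lstm_hidden=32), seed=0).n_parameters()
        assert 0 < n_small < n_large

    def test_gradient_reaches_every_parameter(self, small_model):
        from pulsecast.train_eval import LossConfig, _composite_terms

        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 16, 7))
        y = rng.standard_normal((2, 16))
        pred = small_model.forward(x)
        loss, _ = _composite_terms(pred.reshape(2, 16), y, LossConfig.mse_only())
        small_model.zero_grad()
        loss.backward()
        for name, p in small_model.params.items():
            assert p.grad is not None and np.any(p.grad != 0.0), f"dead parameter {name}"

    def test_checkpoint_round_trip(self, small_model, tmp_path):
        x = np.random.default_rng(5).standard_normal((12, 7))
        path = tmp_path / "model.npz"
        small_model.save(path)
        restored = CbanetModel.load(path)
        np.testing.assert_allclose(restored.predict(x), small_model.predict(x), atol=1e-6)
        assert restored.config == small_model.config

    def test_overfits_single_repeated_batch(self):
        from pulsecast import TrainConfig, WindowSpec, train
        from pulsecast.train_eval import LossConfig

        rng = np.random.default_rng(0)
        x = np.repeat(rng.standard_normal((1, 40, 7)), 4, axis=0)
        y = np.repeat(rng.standard_normal((1, 40)) * 0.5, 4, axis=0)
        m = CbanetModel(
            ModelConfig(conv1_channels=8, conv2_channels=16, lstm_hidden=8, lstm_layers=1, heads=2),
            seed=0,
        )
        hist = train(
            m,
            x,
            y,
            TrainConfig(
                epochs=500,
                batch_size=4,
                learning_rate=5e-3,
                seed=0,
                window=WindowSpec(40, 40),
                loss=LossConfig.mse_only(),
            ),
        )
        assert hist[-1]["total"] < 0.01 * hist[0]["total"]
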