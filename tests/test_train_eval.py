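import numpy as np
import pytest

from pulsecast import (
    CbanetModel,
    EvalReport,
    LossConfig,
    ModelConfig,
    PairedRecord,
    TrainConfig,
    WindowSpec,
    bland_altman,
    composite_loss,
    delta_metrics,
    evaluate_pipeline,
    fit_normalizer,
    kfold_split,
    mae,
    mse_loss,
    r2,
    rmse,
    train,
)
from pulsecast.errors import ValidationError
from pulsecast.features import build_feature_matrix
from pulsecast.synthgen import SynthConfig, gen_components


class TestMseLoss:
    def test_perfect_prediction(self):
        assert mse_loss([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_worked_example(self):
        assert mse_loss([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]) == pytest.approx(2.0 / 3.0)

    def test_constant_offset_closed_form(self):
        y = np.random.default_rng(0).standard_normal(50)
        assert mse_loss(y + 0.7, y) == pytest.approx(0.49)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            mse_loss([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCompositeLoss:
    def test_perfect_prediction_zeroes_every_term(self):
        y = np.sin(np.linspace(0, 6, 64))
        total, terms = composite_loss(y, y, LossConfig(0.1, 0.01, 0.1))
        assert total == pytest.approx(0.0, abs=1e-12)
        assert terms["mse"] == terms["delta"] == terms["psd"] == 0.0
        assert terms["rho"] == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_weights_reduce_to_mse(self):
        rng = np.random.default_rng(1)
        p, y = rng.standard_normal(64), rng.standard_normal(64)
        total, _ = composite_loss(p, y, LossConfig.mse_only())
        assert total == mse_loss(p, y)

    def test_anticorrelated_rho_term_is_two(self):
        y = np.sin(np.linspace(0, 6 * np.pi, 128))  # zero-mean
        _, terms = composite_loss(-y, y, LossConfig(0.0, 0.0, 1.0))
        assert terms["rho"] == pytest.approx(2.0, abs=1e-9)

    def test_zero_variance_defines_rho_zero_with_warning(self):
        y = np.full(32, 2.0)
        with pytest.warns(UserWarning):
            _, terms = composite_loss(np.full(32, 1.0), y, LossConfig(0.0, 0.0, 1.0))
        assert terms["rho"] == 1.0

    def test_terms_nonnegative(self):
        rng = np.random.default_rng(2)
        _, terms = composite_loss(
            rng.standard_normal(64), rng.standard_normal(64), LossConfig(0.1, 0.01, 0.1)
        )
        assert terms["mse"] >= 0 and terms["delta"] >= 0 and terms["psd"] >= 0
        assert 0.0 <= terms["rho"] <= 2.0


class TestMetrics:
    def test_perfect_prediction(self):
        y = [1.0, 2.0, 3.0]
        assert rmse(y, y) == 0.0
        assert mae(y, y) == 0.0
        assert r2(y, y) == 1.0

    def test_worked_example(self):
        y, y_hat = [1.0, 2.0, 3.0], [2.0, 2.0, 2.0]
        assert rmse(y, y_hat) == pytest.approx(0.8165, abs=1e-4)
        assert mae(y, y_hat) == pytest.approx(0.6667, abs=1e-4)
        assert r2(y, y_hat) == pytest.approx(0.0, abs=1e-12)

    def test_mean_predictor_r2_zero(self):
        y = np.random.default_rng(0).standard_normal(100)
        assert r2(y, np.full(100, y.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_target_rejected(self):
        with pytest.raises(ValidationError):
            r2(np.full(10, 1.0), np.arange(10.0))

    def test_eval_report_invariants(self):
        with pytest.raises(ValidationError):
            EvalReport(rmse=0.5, mae=0.9, r2=0.5)  # mae cannot exceed rmse
        with pytest.raises(ValidationError):
            EvalReport(rmse=1.0, mae=0.5, r2=1.5)


class TestDeltaMetrics:
    def test_identical_reports_zero_delta(self):
        rep = EvalReport(rmse=1.0, mae=0.8, r2=0.5)
        d = delta_metrics(rep, rep)
        assert d.d_rmse_pct == d.d_mae_pct == d.d_r2 == 0.0

    def test_zero_raw_error_rejected(self):
        with pytest.raises(ValidationError):
            delta_metrics(EvalReport(0.0, 0.0, 1.0), EvalReport(1.0, 0.5, 0.0))


class TestBlandAltman:
    def test_perfect_agreement(self):
        y = np.arange(10.0)
        ba = bland_altman(y, y)
        assert ba.bias == ba.sd == ba.loa_low == ba.loa_high == 0.0

    def test_loa_spread_is_392_sd(self):
        rng = np.random.default_rng(3)
        ref, pred = rng.standard_normal(200), rng.standard_normal(200)
        ba = bland_altman(ref, pred)
        assert ba.loa_low <= ba.bias <= ba.loa_high
        assert ba.loa_high - ba.loa_low == pytest.approx(2 * 1.96 * ba.sd)
        np.testing.assert_allclose(ba.diffs, pred - ref)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            bland_altman([1.0], [2.0])


class TestKfold:
    def test_ten_windows_five_folds(self):
        splits = kfold_split(10, 5)
        tests = [list(te) for _, te in splits]
        assert tests == [[0, 1], [2, 3], [4, 5], [6, 7], [8, 9]]

    def test_partition_property(self):
        for n in (10, 11, 23):
            splits = kfold_split(n, 5)
            all_test = np.concatenate([te for _, te in splits])
            assert sorted(all_test) == list(range(n))
            sizes = [len(te) for _, te in splits]
            assert max(sizes) - min(sizes) <= 1
            for tr, te in splits:
                assert not set(tr) & set(te)
                assert len(tr) + len(te) == n

    def test_too_few_windows(self):
        with pytest.raises(ValidationError):
            kfold_split(3, 5)


class TestTrain:
    def _data(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((6, 30, 7))
        y = x[:, :, 0] * 0.5
        return x, y

    def _cfg(self, **kw):
        base = dict(
            epochs=3,
            batch_size=4,
            learning_rate=1e-3,
            seed=1,
            window=WindowSpec(30, 30),
            loss=LossConfig.mse_only(),
        )
        base.update(kw)
        return TrainConfig(**base)

    def _model(self):
        return CbanetModel(
            ModelConfig(conv1_channels=4, conv2_channels=8, lstm_hidden=4, lstm_layers=1, heads=2),
            seed=1,
        )

    def test_same_seed_identical_history(self):
        x, y = self._data()
        h1 = train(self._model(), x, y, self._cfg())
        h2 = train(self._model(), x, y, self._cfg())
        assert h1 == h2

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError):
            train(self._model(), np.zeros((0, 30, 7)), np.zeros((0, 30)), self._cfg())

    def test_history_has_loss_breakdown(self):
        x, y = self._data()
        hist = train(self._model(), x, y, self._cfg(loss=LossConfig(0.1, 0.01, 0.1)))
        assert len(hist) == 3
        assert {"mse", "delta", "psd", "rho", "total", "epoch"} <= set(hist[0])


class _OracleModel:
    """Stub predictor returning the raw (channel-0) input unchanged."""

    def predict(self, window):
        return window[:, 0]


class _MeanModel:
    """Stub predictor always outputting the normalized training mean (0)."""

    def predict(self, window):
        return np.zeros(window.shape[0])


class TestEvaluatePipeline:
    @pytest.fixture
    def record_and_norm(self):
        comps = gen_components(SynthConfig(duration_s=30.0, seed=11, spike_rate_hz=0.0))
        source = comps["source"]
        # target IS the source: an identity mapping an oracle can match
        record = PairedRecord(source=source, target=source)
        fm = build_feature_matrix(source)
        norm = fit_normalizer(fm.values, source.samples)
        return record, norm

    def test_oracle_model_scores_perfectly(self, record_and_norm):
        record, norm = record_and_norm
        report, ba, fused = evaluate_pipeline(
            _OracleModel(), record, norm, WindowSpec(200, 50)
        )
        assert report.rmse < 1e-9
        assert report.r2 == pytest.approx(1.0)
        assert abs(ba.bias) < 1e-9

    def test_mean_model_r2_near_zero(self, record_and_norm):
        record, norm = record_and_norm
        report, _, _ = evaluate_pipeline(_MeanModel(), record, norm, WindowSpec(200, 50))
        assert abs(report.r2) < 0.15

    def test_metrics_on_physical_scale(self, record_and_norm):
        record, norm = record_and_norm
        scaled = PairedRecord(
            source=record.source,
            target=record.target.with_samples(record.target.samples),
        )
        report, _, fused = evaluate_pipeline(
            _OracleModel(), scaled, norm, WindowSpec(200, 50)
        )
        sl = fused.covered_slice
        np.testing.assert_allclose(
            fused.values[sl], record.target.samples[sl], atol=1e-9
        )
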