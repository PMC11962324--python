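"""Transformer forecaster: windowing arithmetic, training mechanics, causal
masking, autoregressive consistency, and state-match scoring."""

import numpy as np
import pandas as pd
import pytest

from moodcast.forecaster import (
    ForecasterConfig,
    PosteriorForecaster,
    forecast,
    forecast_batch,
    make_windows,
    one_step_predictions,
    state_match_curve,
    train_forecaster,
)


def _cycle_sequence(T: int, K: int = 3) -> np.ndarray:
    return np.eye(K)[np.arange(T) % K]


def _small_config(**kw) -> ForecasterConfig:
    base = dict(
        embed_dim=16, n_heads=2, n_layers=2, ff_dim=32, dropout=0.0,
        enc_len=9, dec_len=6, epochs=30, patience=30, lr=3e-3, val_fraction=0.0, seed=0,
    )
    base.update(kw)
    return ForecasterConfig(**base)


class TestMakeWindows:
    @pytest.mark.parametrize("T,expected", [(51, 1), (60, 10), (49, 0), (50, 0)])
    def test_window_counts(self, T, expected):
        seqs = [np.random.default_rng(0).dirichlet(np.ones(3), size=T)]
        X_enc, X_dec, Y, skipped = make_windows(seqs, 30, 20)
        assert len(X_enc) == expected
        assert skipped == (1 if expected == 0 else 0)

    def test_target_is_decoder_shifted_one_day(self):
        seq = np.arange(60, dtype=float)[:, None] @ np.ones((1, 2)) / 100
        X_enc, X_dec, Y, _ = make_windows([seq], 30, 20)
        np.testing.assert_array_equal(X_enc[0], seq[:30])
        np.testing.assert_array_equal(X_dec[0], seq[30:50])
        np.testing.assert_array_equal(Y[0], seq[31:51])


class TestTraining:
    def test_overfit_single_instance(self):
        """Capacity sanity: one window, no dropout, many epochs -> tiny loss."""
        seq = _cycle_sequence(16)
        windows = make_windows([seq], 9, 6)
        cfg = _small_config(epochs=400, lr=5e-3, input_noise=0.0)
        model, history = train_forecaster(windows[:3], cfg)
        assert history["train_loss"].iloc[-1] < 1e-3

    def test_seeded_determinism_identical_weights(self):
        rng = np.random.default_rng(0)
        seqs = [rng.dirichlet(np.ones(3), size=30) for _ in range(3)]
        windows = make_windows(seqs, 9, 6)
        cfg = _small_config(epochs=3, dropout=0.2, val_fraction=0.2)
        m1, h1 = train_forecaster(windows[:3], cfg)
        m2, h2 = train_forecaster(windows[:3], cfg)
        for a, b in zip(m1.state_arrays(), m2.state_arrays()):
            np.testing.assert_array_equal(a, b)
        pd.testing.assert_frame_equal(h1, h2)

    def test_causal_mask_probe(self):
        """Perturbing the decoder input at position t changes outputs only at
        positions >= t (eval mode, dropout off)."""
        rng = np.random.default_rng(1)
        cfg = _small_config()
        model = PosteriorForecaster(3, cfg)
        model.set_training(False)
        enc = rng.dirichlet(np.ones(3), size=(1, 9))
        dec = rng.dirichlet(np.ones(3), size=(1, 6))
        base = model.forward(enc, dec).data
        for t in range(6):
            perturbed = dec.copy()
            perturbed[0, t] = perturbed[0, t][::-1]
            out = model.forward(enc, perturbed).data
            if t > 0:
                np.testing.assert_allclose(out[0, :t], base[0, :t], atol=1e-10)
            assert np.abs(out[0, t:] - base[0, t:]).max() > 1e-8

    def test_nan_loss_aborts_with_diagnostics(self):
        seq = _cycle_sequence(20)
        X_enc, X_dec, Y, _ = make_windows([seq], 9, 6)
        X_enc = X_enc.copy()
        X_enc[0, 0, 0] = np.nan  # poisoned input propagates to the loss
        with pytest.raises(RuntimeError, match="non-finite"):
            train_forecaster((X_enc, X_dec, Y), _small_config(epochs=2))

    def test_empty_windows_rejected(self):
        with pytest.raises(ValueError):
            train_forecaster((np.empty((0, 9, 3)), np.empty((0, 6, 3)), np.empty((0, 6, 3))), _small_config())


class TestForecast:
    @pytest.fixture(scope="class")
    def cycle_model(self):
        seq = _cycle_sequence(40)
        windows = make_windows([seq], 9, 6)
        cfg = _small_config(epochs=300, lr=5e-3, input_noise=0.0)
        model, _ = train_forecaster(windows[:3], cfg)
        return model, seq

    def test_simplex_contract(self, cycle_model):
        model, seq = cycle_model
        res = forecast(model, seq[-9:], 5)
        assert np.all(res.simplex >= 0)
        np.testing.assert_allclose(res.simplex.sum(axis=1), 1.0, atol=1e-8)
        assert res.raw.shape == res.simplex.shape

    def test_prefix_consistency(self, cycle_model):
        model, seq = cycle_model
        one = forecast(model, seq[-9:], 1)
        five = forecast(model, seq[-9:], 5)
        np.testing.assert_allclose(one.simplex[0], five.simplex[0], atol=1e-12)

    def test_overfit_cycle_reproduced_seven_days(self, cycle_model):
        model, seq = cycle_model
        res = forecast(model, seq[-9:], 7)
        predicted = res.simplex.argmax(axis=1)
        expected = np.arange(len(seq), len(seq) + 7) % 3
        np.testing.assert_array_equal(predicted, expected)

    def test_short_context_rejected(self, cycle_model):
        model, seq = cycle_model
        with pytest.raises(ValueError):
            forecast(model, seq[-5:], 3)

    def test_batch_matches_single(self, cycle_model):
        model, seq = cycle_model
        contexts = np.stack([seq[0:9], seq[3:12]])
        simplex, raw = forecast_batch(model, contexts, 4)
        single = forecast(model, seq[3:12], 4)
        np.testing.assert_allclose(simplex[1], single.simplex, atol=1e-12)

    def test_one_step_predictions_alignment(self, cycle_model):
        """Row j holds the forecast made at day j for day j+1."""
        model, seq = cycle_model
        preds = one_step_predictions(model, seq)
        assert np.isnan(preds[: model.config.enc_len]).all()
        days = np.flatnonzero(~np.isnan(preds).any(axis=1))
        assert (preds[days].argmax(axis=1) == (days + 1) % 3).all()


class TestStateMatchCurve:
    def test_identical_predictions_perfect(self):
        rng = np.random.default_rng(2)
        truth = [rng.dirichlet(np.ones(3), size=8) for _ in range(5)]
        df = state_match_curve(truth, truth, range(8))
        np.testing.assert_array_equal(df["accuracy"], 1.0)

    def test_uniform_random_predictions_near_chance(self):
        rng = np.random.default_rng(3)
        K = 7
        n = 1500
        truth = [rng.dirichlet(np.ones(K), size=8) for _ in range(n)]
        preds = [rng.dirichlet(np.ones(K), size=8) for _ in range(n)]
        df = state_match_curve(preds, truth, range(8))
        np.testing.assert_allclose(df["accuracy"], 1 / K, atol=0.03)

    def test_hand_built_mismatch(self):
        truth = [np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], float)] * 3
        preds = [truth[0].copy() for _ in range(3)]
        preds[0] = preds[0].copy()
        preds[0][1] = [1, 0, 0]  # one mismatch at horizon 1
        df = state_match_curve(preds, truth, range(3))
        np.testing.assert_allclose(df["accuracy"], [1.0, 2 / 3, 1.0])

    def test_misaligned_shapes_rejected(self):
        a = [np.ones((8, 3)) / 3]
        b = [np.ones((8, 4)) / 4]
        with pytest.raises(ValueError):
            state_match_curve(a, b, range(8))
        with pytest.raises(ValueError):
            state_match_curve(a, a + a, range(8))


def test_checkpoint_round_trip(tmp_path):
    seq = _cycle_sequence(20)
    windows = make_windows([seq], 9, 6)
    model, _ = train_forecaster(windows[:3], _small_config(epochs=2))
    path = tmp_path / "model.pkl"
    model.save(path)
    loaded = PosteriorForecaster.load(path)
    a = forecast(model, seq[-9:], 3).simplex
    b = forecast(loaded, seq[-9:], 3).simplex
    np.testing.assert_array_equal(a, b)
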