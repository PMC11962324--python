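"""Encoder-decoder transformer forecasting hidden-state posterior sequences.

The model is trained self-supervised: sliding windows of posterior sequences
are split into an encoder context and a decoder segment, and the decoder is
trained (teacher-forced, causally masked) to output the segment shifted one
day ahead. At inference the decoder is seeded with the final observed day and
rolls forward autoregressively; raw outputs are projected to the probability
simplex by softmax.

Default hyperparameters (embedding 32, 4 heads, 3 encoder and 3 decoder
layers, feed-forward 128, dropout 0.3, learning rate 1e-3, 30-day encoder /
20-day decoder windows, 80 epochs with early stopping) are small enough to
train on a single CPU.
"""

from __future__ import annotations

import copy
import json
import logging
import pickle
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from moodcast.nn.autodiff import Tensor, no_grad
from moodcast.nn.layers import (
    Adam,
    Dropout,
    FeedForward,
    LayerNorm,
    Linear,
    Module,
    MultiHeadAttention,
    causal_mask,
    sinusoidal_encoding,
)

logger = logging.getLogger(__name__)


@dataclass
class ForecasterConfig:
    embed_dim: int = 32
    n_heads: int = 4
    n_layers: int = 3
    ff_dim: int = 128
    dropout: float = 0.3
    lr: float = 1e-3
    loss: str = "mse"  # or "mae"
    epochs: int = 80
    patience: int = 10
    enc_len: int = 30
    dec_len: int = 20
    batch_size: int = 32
    val_fraction: float = 0.1
    #: Maximum per-day mixing weight toward the uniform simplex applied to
    #: decoder inputs during training. Autoregressive inference re-feeds the
    #: model's own (softer) outputs, so training on softened inputs closes the
    #: train/inference input-distribution gap; 0 disables the augmentation.
    input_noise: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.loss not in ("mse", "mae"):
            raise ValueError("loss must be 'mse' or 'mae'")
        if self.enc_len < 1 or self.dec_len < 1:
            raise ValueError("enc_len and dec_len must be >= 1")


@dataclass
class ForecastResult:
    """Per-horizon forecasts: simplex-projected vectors and raw logits."""

    simplex: np.ndarray  # (N, K)
    raw: np.ndarray  # (N, K)


class _EncoderLayer(Module):
    def __init__(self, cfg: ForecasterConfig, rng: np.random.Generator):
        self.attn = MultiHeadAttention(cfg.embed_dim, cfg.n_heads, rng)
        self.norm1 = LayerNorm(cfg.embed_dim)
        self.ff = FeedForward(cfg.embed_dim, cfg.ff_dim, rng)
        self.norm2 = LayerNorm(cfg.embed_dim)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        x = self.norm1(x + self.drop(self.attn(x, x, x), rng))
        return self.norm2(x + self.drop(self.ff(x), rng))


class _DecoderLayer(Module):
    def __init__(self, cfg: ForecasterConfig, rng: np.random.Generator):
        self.self_attn = MultiHeadAttention(cfg.embed_dim, cfg.n_heads, rng)
        self.norm1 = LayerNorm(cfg.embed_dim)
        self.cross_attn = MultiHeadAttention(cfg.embed_dim, cfg.n_heads, rng)
        self.norm2 = LayerNorm(cfg.embed_dim)
        self.ff = FeedForward(cfg.embed_dim, cfg.ff_dim, rng)
        self.norm3 = LayerNorm(cfg.embed_dim)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, x: Tensor, memory: Tensor, mask: np.ndarray, rng: np.random.Generator) -> Tensor:
        x = self.norm1(x + self.drop(self.self_attn(x, x, x, mask=mask), rng))
        x = self.norm2(x + self.drop(self.cross_attn(x, memory, memory), rng))
        return self.norm3(x + self.drop(self.ff(x), rng))


class PosteriorForecaster(Module):
    """Encoder-decoder transformer over K-dimensional posterior vectors."""

    def __init__(self, n_states: int, config: ForecasterConfig):
        config.validate()
        self.config = config
        self.n_states = n_states
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        self.input_proj = Linear(n_states, config.embed_dim, rng)
        self.enc_layers = [_EncoderLayer(config, rng) for _ in range(config.n_layers)]
        self.dec_layers = [_DecoderLayer(config, rng) for _ in range(config.n_layers)]
        self.out_proj = Linear(config.embed_dim, n_states, rng)
        self.out_proj.W.data *= 0.1  # start close to the persistence forecast
        self.in_drop = Dropout(config.dropout)
        self._pe_cache = sinusoidal_encoding(1024, config.embed_dim)
        self.training = True

    def _embed(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        T = x.shape[1]
        pe = self._pe_cache[:T]
        return self.in_drop(self.input_proj(x) + Tensor(pe), rng)

    def encode(self, enc_x: Tensor, rng: np.random.Generator) -> Tensor:
        h = self._embed(enc_x, rng)
        for layer in self.enc_layers:
            h = layer(h, rng)
        return h

    def decode(self, dec_x: Tensor, memory: Tensor, rng: np.random.Generator) -> Tensor:
        mask = causal_mask(dec_x.shape[1])
        h = self._embed(dec_x, rng)
        for layer in self.dec_layers:
            h = layer(h, memory, mask, rng)
        return h

    def forward(self, enc_x, dec_x, rng: np.random.Generator | None = None, return_hidden: bool = False):
        """Raw output logits (B, T_dec, K); the decoder output at position t
        predicts the posterior one day after decoder input t."""
        if rng is None:
            rng = np.random.default_rng(0)  # unused when dropout is off (eval)
        enc_x = enc_x if isinstance(enc_x, Tensor) else Tensor(enc_x)
        dec_x = dec_x if isinstance(dec_x, Tensor) else Tensor(dec_x)
        memory = self.encode(enc_x, rng)
        hidden = self.decode(dec_x, memory, rng)
        logits = self._output_logits(dec_x.data, hidden)
        if return_hidden:
            return logits, hidden
        return logits

    def _output_logits(self, dec_x_data: np.ndarray, hidden: Tensor) -> Tensor:
        """Residual persistence bias: a tempered copy of the decoder input's
        log-probabilities is added to the output logits, so the untrained
        model already leans toward persistence forecasting and training
        learns the departure from it. The 0.5 temper and the clip floor keep
        the initial softmax away from saturation (where MSE gradients
        vanish)."""
        skip = 0.5 * np.log(np.clip(dec_x_data, 1e-2, None))
        return self.out_proj(hidden) + Tensor(skip)

    # -- persistence ----------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump({"config": asdict(self.config), "n_states": self.n_states, "state": self.state_arrays()}, fh)
        path.with_suffix(".json").write_text(json.dumps({"config": asdict(self.config), "n_states": self.n_states}))

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorForecaster":
        with open(path, "rb") as fh:
            doc = pickle.load(fh)
        model = cls(doc["n_states"], ForecasterConfig(**doc["config"]))
        model.load_state_arrays(doc["state"])
        model.set_training(False)
        return model


def make_windows(
    sequences: list[np.ndarray], enc_len: int, dec_len: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Sliding stride-1 training windows from posterior sequences.

    Each instance spans enc_len + dec_len + 1 days: the first enc_len feed the
    encoder, the next dec_len feed the decoder, and the target Y is the
    decoder segment shifted one day ahead. Sequences shorter than the span
    are skipped and counted.
    """
    span = enc_len + dec_len + 1
    X_enc, X_dec, Y = [], [], []
    skipped = 0
    for seq in sequences:
        seq = np.asarray(seq, dtype=float)
        T = len(seq)
        if T < span:
            skipped += 1
            continue
        for start in range(T - span + 1):
            X_enc.append(seq[start : start + enc_len])
            X_dec.append(seq[start + enc_len : start + enc_len + dec_len])
            Y.append(seq[start + enc_len + 1 : start + span])
    if skipped:
        logger.info("make_windows: skipped %d sequences shorter than %d days", skipped, span)
    if not X_enc:
        K = sequences[0].shape[1] if sequences else 0
        empty = np.empty((0, 0, K))
        return empty, empty, empty, skipped
    return np.stack(X_enc), np.stack(X_dec), np.stack(Y), skipped


def _loss_tensor(logits: Tensor, target: np.ndarray, kind: str) -> Tensor:
    pred = logits.softmax(axis=-1)
    diff = pred - Tensor(target)
    if kind == "mse":
        return (diff * diff).mean()
    return diff.abs().mean()


def train_forecaster(
    windows: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: ForecasterConfig,
    n_states: int | None = None,
) -> tuple[PosteriorForecaster, pd.DataFrame]:
    """Train with teacher forcing, Adam, dropout, and early stopping.

    A window-level validation split (``config.val_fraction``) drives early
    stopping with the configured patience; the best-validation weights are
    restored. With too few windows for a validation split, training loss is
    monitored instead. Deterministic given data, config, and seed.
    """
    config.validate()
    X_enc, X_dec, Y = windows[:3]
    n = len(X_enc)
    if n < 1:
        raise ValueError("need at least one training instance")
    if n_states is None:
        n_states = X_enc.shape[2]

    root = np.random.SeedSequence(config.seed)
    model_seed, split_seed, train_seed = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in root.spawn(3))
    model = PosteriorForecaster(n_states, ForecasterConfig(**{**asdict(config), "seed": model_seed}))
    rng = np.random.default_rng(train_seed)

    n_val = int(round(n * config.val_fraction))
    order = np.random.default_rng(split_seed).permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        train_idx, val_idx = order, order[:0]

    optimizer = Adam(model.parameters(), lr=config.lr)
    history = []
    best_monitor = np.inf
    best_state = None
    patience_left = config.patience

    for epoch in range(config.epochs):
        model.set_training(True)
        perm = rng.permutation(len(train_idx))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(train_idx), config.batch_size):
            idx = train_idx[perm[start : start + config.batch_size]]
            x_dec = X_dec[idx]
            if config.input_noise > 0:
                K = x_dec.shape[-1]
                eps = rng.uniform(0, config.input_noise, size=x_dec.shape[:-1] + (1,))
                x_dec = (1 - eps) * x_dec + eps / K
            logits = model.forward(X_enc[idx], x_dec, rng=rng)
            loss = _loss_tensor(logits, Y[idx], config.loss)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"lr={config.lr}, batch={len(idx)}, loss={float(loss.data)}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        train_loss = epoch_loss / max(n_batches, 1)

        model.set_training(False)
        if len(val_idx):
            with no_grad():
                val_logits = model.forward(X_enc[val_idx], X_dec[val_idx])
                val_loss = float(_loss_tensor(val_logits, Y[val_idx], config.loss).data)
            monitor = val_loss
        else:
            val_loss = np.nan
            monitor = train_loss
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})

        if monitor < best_monitor - 1e-12:
            best_monitor = monitor
            best_state = copy.deepcopy(model.state_arrays())
            patience_left = config.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                logger.info("early stopping at epoch %d", epoch)
                break

    if best_state is not None:
        model.load_state_arrays(best_state)
    model.set_training(False)
    return model, pd.DataFrame(history)


def forecast(model: PosteriorForecaster, context: np.ndarray, horizon: int) -> ForecastResult:
    """Autoregressive multi-day forecast from the last ``enc_len`` observed days."""
    out = forecast_batch(model, context[None, :, :], horizon)
    return ForecastResult(simplex=out[0][0], raw=out[1][0])


def forecast_batch(model: PosteriorForecaster, contexts: np.ndarray, horizon: int) -> tuple[np.ndarray, np.ndarray]:
    """Batched autoregressive forecasting.

    ``contexts``: (B, enc_len, K). The decoder is seeded with the final
    observed day; each simplex-projected prediction is appended and re-fed.
    Returns (simplex (B, N, K), raw (B, N, K)).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    contexts = np.asarray(contexts, dtype=float)
    if contexts.ndim != 3 or contexts.shape[1] != model.config.enc_len:
        raise ValueError(f"context must be (B, enc_len={model.config.enc_len}, K)")
    model.set_training(False)
    B, _, K = contexts.shape
    with no_grad():
        memory = model.encode(Tensor(contexts), np.random.default_rng(0))
        dec_seq = contexts[:, -1:, :]
        raw_steps = []
        simplex_steps = []
        for _ in range(horizon):
            hidden = model.decode(Tensor(dec_seq), memory, np.random.default_rng(0))
            logits = model._output_logits(dec_seq, hidden)
            last = logits.data[:, -1, :]
            raw_steps.append(last)
            shifted = last - last.max(axis=-1, keepdims=True)
            e = np.exp(shifted)
            probs = e / e.sum(axis=-1, keepdims=True)
            simplex_steps.append(probs)
            dec_seq = np.concatenate([dec_seq, probs[:, None, :]], axis=1)
    return np.stack(simplex_steps, axis=1), np.stack(raw_steps, axis=1)


def one_step_predictions(model: PosteriorForecaster, seq: np.ndarray) -> np.ndarray:
    """Teacher-forced decoder outputs along a posterior sequence.

    Returns a (T, K) array whose row j is the forecast made at day j for day
    j+1 (the decoder output at the position whose input is day j, computed
    from data through day j only). The first enc_len days, which lack a full
    encoder context, are NaN. Windows are tiled with stride dec_len so each
    position is decoded exactly once.
    """
    cfg = model.config
    seq = np.asarray(seq, dtype=float)
    T, K = seq.shape
    out = np.full((T, K), np.nan)
    if T < cfg.enc_len + 1:
        return out
    model.set_training(False)
    enc_batch, dec_batch, targets = [], [], []
    t0 = cfg.enc_len  # first day at which a forecast is made
    while t0 < T:
        block = min(cfg.dec_len, T - t0)
        enc_batch.append(seq[t0 - cfg.enc_len : t0])
        dec_batch.append(_pad_to(seq[t0 : t0 + block], cfg.dec_len))
        targets.append((t0, block))
        t0 += block
    with no_grad():
        logits = model.forward(np.stack(enc_batch), np.stack(dec_batch)).data
    for i, (start, block) in enumerate(targets):
        raw = logits[i, :block, :]
        shifted = raw - raw.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        out[start : start + block] = e / e.sum(axis=-1, keepdims=True)
    return out


def _pad_to(arr: np.ndarray, length: int) -> np.ndarray:
    if len(arr) == length:
        return arr
    pad = np.repeat(arr[-1:], length - len(arr), axis=0)
    return np.concatenate([arr, pad], axis=0)


def state_match_curve(
    predicted: list[np.ndarray], truth: list[np.ndarray], horizons: range | list[int] = range(8)
) -> pd.DataFrame:
    """Fraction of days where argmax(prediction) equals argmax(true posterior),
    per forecast horizon.

    ``predicted`` and ``truth`` are aligned lists of (H+1, K) arrays, one per
    anchor, whose row h is the horizon-h prediction/truth (horizon 0 being
    the same-day reconstruction).
    """
    horizons = list(horizons)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal lengths")
    hits = np.zeros(len(horizons))
    counts = np.zeros(len(horizons))
    for pred, true in zip(predicted, truth):
        pred = np.asarray(pred)
        true = np.asarray(true)
        if pred.shape != true.shape:
            raise ValueError("misaligned prediction/truth shapes")
        if len(pred) < len(horizons):
            raise ValueError("instance shorter than requested horizons")
        for j, h in enumerate(horizons):
            hits[j] += np.argmax(pred[h]) == np.argmax(true[h])
            counts[j] += 1
    return pd.DataFrame({"horizon": horizons, "accuracy": hits / np.maximum(counts, 1), "n": counts.astype(int)})
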