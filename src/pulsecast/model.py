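"""CBAnet: local convolutional features, bidirectional recurrence, global
self-attention, and a pointwise linear readout.

The network maps a window of the T x 7 composite feature matrix to a T x 1
waveform prediction through three subnets composed in sequence:

* **LFE** (local feature extraction): two stride-1 1-D convolutions with
  kernel 3 and zero "same" padding (7 -> 32 -> 64 channels), each followed
  by ReLU.  No subsampling, so temporal resolution and phase are preserved.
* **TRN** (temporal representation): stacked bidirectional LSTMs; at each
  step the forward and backward hidden states are concatenated, giving a
  T x 2h representation that carries order information.
* **GRA** (global reweighting and alignment): multi-head scaled-dot-product
  self-attention over the full window, no causal mask, heads concatenated
  and projected back to 2h.  Because the recurrent subnet precedes it, no
  positional encoding is added.
* **readout**: one affine map shared across time steps, 2h -> 1.

Weights live in plain float64 numpy arrays (see :mod:`pulsecast.autodiff`);
a forward pass with fixed weights is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, lstm_layer, softmax, tensor, unfold1d
from .errors import ConfigError, ValidationError

__all__ = ["ModelConfig", "CbanetModel"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``lstm_hidden`` is the per-direction hidden size h; the bidirectional
    representation has width 2h, which the head count must divide.
    """

    in_channels: int = 7
    conv1_channels: int = 32
    conv2_channels: int = 64
    kernel: int = 3
    lstm_hidden: int = 64
    lstm_layers: int = 2
    heads: int = 4
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.kernel % 2 != 1 or self.kernel < 1:
            raise ConfigError(f"kernel must be odd and positive, got {self.kernel}")
        if (2 * self.lstm_hidden) % self.heads != 0:
            raise ConfigError(
                f"heads={self.heads} must divide 2h={2 * self.lstm_hidden}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError(f"dropout must be in [0, 1), got {self.dropout}")
        for name in ("in_channels", "conv1_channels", "conv2_channels", "lstm_hidden", "lstm_layers", "heads"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")

    @property
    def d_model(self) -> int:
        return 2 * self.lstm_hidden

    @property
    def d_head(self) -> int:
        return self.d_model // self.heads


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def _orthogonal_gates(rng: np.random.Generator, h: int) -> np.ndarray:
    """(h, 4h) recurrent matrix with one orthogonal block per gate."""
    blocks = []
    for _ in range(4):
        a = rng.standard_normal((h, h))
        q, r = np.linalg.qr(a)
        blocks.append(q * np.sign(np.diag(r)))
    return np.concatenate(blocks, axis=1)


class CbanetModel:
    """The composed network with all parameters and forward passes."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        P: dict[str, Tensor] = {}

        k, c_in, c1, c2 = cfg.kernel, cfg.in_channels, cfg.conv1_channels, cfg.conv2_channels
        P["conv1_W"] = Tensor(_uniform(rng, (k * c_in, c1), k * c_in), requires_grad=True)
        P["conv1_b"] = Tensor(_uniform(rng, (c1,), k * c_in), requires_grad=True)
        P["conv2_W"] = Tensor(_uniform(rng, (k * c1, c2), k * c1), requires_grad=True)
        P["conv2_b"] = Tensor(_uniform(rng, (c2,), k * c1), requires_grad=True)

        h = cfg.lstm_hidden
        d_in = c2
        for layer in range(cfg.lstm_layers):
            for direction in ("fwd", "bwd"):
                pre = f"lstm{layer}_{direction}"
                P[f"{pre}_Wx"] = Tensor(_uniform(rng, (d_in, 4 * h), h), requires_grad=True)
                P[f"{pre}_Wh"] = Tensor(_orthogonal_gates(rng, h), requires_grad=True)
                b = _uniform(rng, (4 * h,), h)
                b[h : 2 * h] += 1.0  # forget-gate bias offset aids early memory
                P[f"{pre}_b"] = Tensor(b, requires_grad=True)
            d_in = 2 * h

        d = cfg.d_model
        for name in ("Wq", "Wk", "Wv", "Wo"):
            P[name] = Tensor(_uniform(rng, (d, d), d), requires_grad=True)
        P["out_W"] = Tensor(_uniform(rng, (d, 1), d), requires_grad=True)
        P["out_b"] = Tensor(_uniform(rng, (1,), d), requires_grad=True)

        self.params = P
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))
        self.training = False
        self.last_attention: np.ndarray | None = None

    # -- utilities ---------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    @staticmethod
    def _as_batch(x) -> tuple[Tensor, bool]:
        t = tensor(x)
        if t.ndim == 2:
            return t.reshape(1, *t.shape), True
        if t.ndim == 3:
            return t, False
        raise ValidationError(f"expected (T, C) or (B, T, C) input, got shape {t.shape}")

    def _dropout(self, x: Tensor) -> Tensor:
        p = self.config.dropout
        if not self.training or p == 0.0:
            return x
        mask = (self._dropout_rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(mask)

    # -- subnets -----------------------------------------------------------
    def lfe_forward(self, x) -> Tensor:
        """Two same-length conv+ReLU stages: (.., T, 7) -> (.., T, 64)."""
        xb, squeeze = self._as_batch(x)
        if xb.shape[-1] != self.config.in_channels:
            raise ValidationError(
                f"expected {self.config.in_channels} input channels, got {xb.shape[-1]}"
            )
        if xb.shape[-2] < self.config.kernel:
            raise ValidationError(
                f"window length {xb.shape[-2]} shorter than kernel {self.config.kernel}"
            )
        k = self.config.kernel
        u1 = (unfold1d(xb, k) @ self.params["conv1_W"] + self.params["conv1_b"]).relu()
        h = (unfold1d(u1, k) @ self.params["conv2_W"] + self.params["conv2_b"]).relu()
        return h.reshape(*h.shape[1:]) if squeeze else h

    def trn_forward(self, h_lfe) -> Tensor:
        """Stacked bidirectional LSTM: (.., T, 64) -> (.., T, 2h)."""
        xb, squeeze = self._as_batch(h_lfe)
        out = xb
        for layer in range(self.config.lstm_layers):
            fwd = lstm_layer(
                out,
                self.params[f"lstm{layer}_fwd_Wx"],
                self.params[f"lstm{layer}_fwd_Wh"],
                self.params[f"lstm{layer}_fwd_b"],
                reverse=False,
            )
            bwd = lstm_layer(
                out,
                self.params[f"lstm{layer}_bwd_Wx"],
                self.params[f"lstm{layer}_bwd_Wh"],
                self.params[f"lstm{layer}_bwd_b"],
                reverse=True,
            )
            out = concat([fwd, bwd], axis=-1)
        return out.reshape(*out.shape[1:]) if squeeze else out

    def gra_forward(self, h_trn) -> Tensor:
        """Multi-head self-attention over the full window: (.., T, 2h) -> same."""
        xb, squeeze = self._as_batch(h_trn)
        cfg = self.config
        B, T, d = xb.shape
        if d != cfg.d_model:
            raise ValidationError(f"expected width {cfg.d_model}, got {d}")
        nh, dk = cfg.heads, cfg.d_head

        def split_heads(t: Tensor) -> Tensor:
            # (B, T, d) -> (B, heads, T, dk)
            return t.reshape(B, T, nh, dk).swapaxes(1, 2)

        q = split_heads(xb @ self.params["Wq"])
        k = split_heads(xb @ self.params["Wk"])
        v = split_heads(xb @ self.params["Wv"])
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dk))
        alpha = softmax(scores, axis=-1)
        self.last_attention = np.array(alpha.data)
        ctx = alpha @ v  # (B, heads, T, dk)
        merged = ctx.swapaxes(1, 2).reshape(B, T, d)
        # standard residual form of the attention block: the reweighted
        # context is a correction on top of the recurrent representation;
        # without the residual, near-uniform initial attention collapses the
        # whole window to its average and erases temporal structure
        out = xb + merged @ self.params["Wo"]
        return out.reshape(*out.shape[1:]) if squeeze else out

    def readout(self, z) -> Tensor:
        """Time-shared affine map: (.., T, 2h) -> (.., T, 1)."""
        zb, squeeze = self._as_batch(z)
        out = zb @ self.params["out_W"] + self.params["out_b"]
        return out.reshape(*out.shape[1:]) if squeeze else out

    def forward(self, x) -> Tensor:
        """Full composition readout(GRA(TRN(LFE(x))))."""
        h = self._dropout(self.lfe_forward(x))
        h = self._dropout(self.trn_forward(h))
        z = self.gra_forward(h)
        return self.readout(z)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference on a single (T, C) window; returns a (T,) array."""
        was_training = self.training
        self.training = False
        try:
            out = self.forward(np.asarray(x, dtype=np.float64))
        finally:
            self.training = was_training
        return np.asarray(out.data).reshape(-1)

    # -- persistence --------------------------------------------------------
    FORMAT_VERSION = 1

    def save(self, path: str | Path) -> None:
        """Versioned checkpoint: config as JSON plus all weight arrays."""
        path = Path(path)
        arrays = {name: p.data for name, p in self.params.items()}
        np.savez(
            path,
            __meta__=np.frombuffer(
                json.dumps(
                    {"format_version": self.FORMAT_VERSION, "config": asdict(self.config)}
                ).encode(),
                dtype=np.uint8,
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "CbanetModel":
        path = Path(path)
        if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
            path = path.with_suffix(path.suffix + ".npz")
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format_version") != cls.FORMAT_VERSION:
                raise ConfigError(
                    f"unsupported checkpoint version {meta.get('format_version')}"
                )
            model = cls(ModelConfig(**meta["config"]))
            for name in model.params:
                model.params[name].data = np.array(data[name], dtype=np.float64)
        return model
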