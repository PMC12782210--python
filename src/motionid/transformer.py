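"""Dual-stream temporal/frequency attention network for raw IMU windows.

The architecture follows the transformer-based feature extractor used in
mobile behavioral biometrics ("SwipeFormer"-style), adapted to end-to-end
classification: two parallel streams each apply a 1-D convolutional embedding
followed by self-attention encoder layers, one over the raw per-sample
6-channel window (yaw, pitch, roll, accelerometer X/Y/Z) and one over the
per-channel discrete-Fourier-transform magnitude spectra of the same window.
The two mean-pooled stream embeddings are concatenated and passed through a
multilayer perceptron with a single sigmoid output scoring the target-user
class.  Training minimizes binary cross-entropy with Adam; everything is
seeded and single-threaded, so runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Adam, Tensor, concat

__all__ = ["DualStreamClassifier"]


def _positional_encoding(length: int, dim: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc


def _im2col(x: np.ndarray, kernel: int) -> np.ndarray:
    """Edge-padded sliding patches: (B, T, C) -> (B, T, kernel * C)."""
    pad = kernel // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)), mode="edge")
    view = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=1)
    # view: (B, T, C, kernel) -> (B, T, kernel * C)
    return np.ascontiguousarray(view.transpose(0, 1, 3, 2)).reshape(
        x.shape[0], x.shape[1], kernel * x.shape[2]
    )


class DualStreamClassifier:
    """Temporal + frequency self-attention classifier on raw window sequences."""

    def __init__(self, config):
        # `config` is a models.TransformerConfig; duck-typed to avoid a cycle.
        self.cfg = config
        self.params: dict[str, Tensor] = {}
        self.loss_history: list[float] = []
        self._channel_mean: np.ndarray | None = None
        self._channel_std: np.ndarray | None = None
        self._freq_mean: np.ndarray | None = None
        self._freq_std: np.ndarray | None = None
        self._rng = np.random.default_rng(
            np.random.SeedSequence((config.seed & 0x7FFFFFFF, 31))
        )
        self._init_params()

    # -- parameters --------------------------------------------------------

    def _add(self, name: str, shape: tuple[int, ...], scale: float) -> None:
        self.params[name] = Tensor(
            self._rng.normal(0.0, scale, shape), requires_grad=True
        )

    def _add_zeros(self, name: str, shape: tuple[int, ...]) -> None:
        self.params[name] = Tensor(np.zeros(shape), requires_grad=True)

    def _add_ones(self, name: str, shape: tuple[int, ...]) -> None:
        self.params[name] = Tensor(np.ones(shape), requires_grad=True)

    def _init_params(self) -> None:
        cfg = self.cfg
        e = cfg.embedding_dim
        kin = cfg.conv_kernel * cfg.channels
        for stream in ("time", "freq"):
            self._add(f"{stream}.conv.W", (kin, e), np.sqrt(2.0 / kin))
            self._add_zeros(f"{stream}.conv.b", (e,))
            for layer in range(cfg.encoder_layers):
                p = f"{stream}.enc{layer}"
                for w in ("Wq", "Wk", "Wv", "Wo"):
                    self._add(f"{p}.{w}", (e, e), np.sqrt(1.0 / e))
                self._add(f"{p}.W1", (e, 2 * e), np.sqrt(2.0 / e))
                self._add_zeros(f"{p}.b1", (2 * e,))
                self._add(f"{p}.W2", (2 * e, e), np.sqrt(1.0 / e))
                self._add_zeros(f"{p}.b2", (e,))
                self._add_ones(f"{p}.ln1.g", (e,))
                self._add_zeros(f"{p}.ln1.b", (e,))
                self._add_ones(f"{p}.ln2.g", (e,))
                self._add_zeros(f"{p}.ln2.b", (e,))
        widths = [2 * e] + list(cfg.mlp_hidden_sizes) + [1]
        for j, (win, wout) in enumerate(zip(widths[:-1], widths[1:])):
            self._add(f"mlp.W{j}", (win, wout), np.sqrt(2.0 / win))
            self._add_zeros(f"mlp.b{j}", (wout,))

    # -- forward graph -----------------------------------------------------

    def _encode_stream(self, x: np.ndarray, stream: str) -> Tensor:
        """(B, T, C) constant input -> pooled (B, E) embedding."""
        cfg = self.cfg
        e = cfg.embedding_dim
        heads = cfg.attention_heads
        dh = e // heads
        patches = Tensor(_im2col(x, cfg.conv_kernel))
        h = (
            patches @ self.params[f"{stream}.conv.W"]
            + self.params[f"{stream}.conv.b"]
        ).relu()
        h = h + Tensor(_positional_encoding(x.shape[1], e))
        batch = x.shape[0]
        length = x.shape[1]
        for layer in range(cfg.encoder_layers):
            p = f"{stream}.enc{layer}"
            q = (h @ self.params[f"{p}.Wq"]).reshape(batch, length, heads, dh)
            k = (h @ self.params[f"{p}.Wk"]).reshape(batch, length, heads, dh)
            v = (h @ self.params[f"{p}.Wv"]).reshape(batch, length, heads, dh)
            q = q.transpose((0, 2, 1, 3))
            k = k.transpose((0, 2, 3, 1))
            v = v.transpose((0, 2, 1, 3))
            att = ((q @ k) * (1.0 / np.sqrt(dh))).softmax(axis=-1)
            ctx = (att @ v).transpose((0, 2, 1, 3)).reshape(batch, length, e)
            h = (h + ctx @ self.params[f"{p}.Wo"]).layer_norm(
                self.params[f"{p}.ln1.g"], self.params[f"{p}.ln1.b"]
            )
            ff = (
                (h @ self.params[f"{p}.W1"] + self.params[f"{p}.b1"]).relu()
                @ self.params[f"{p}.W2"]
                + self.params[f"{p}.b2"]
            )
            h = (h + ff).layer_norm(
                self.params[f"{p}.ln2.g"], self.params[f"{p}.ln2.b"]
            )
        return h.mean(axis=1)

    def _logits(self, time_input: np.ndarray, freq_input: np.ndarray) -> Tensor:
        z = concat(
            [
                self._encode_stream(time_input, "time"),
                self._encode_stream(freq_input, "freq"),
            ],
            axis=-1,
        )
        n_mlp = len(self.cfg.mlp_hidden_sizes) + 1
        for j in range(n_mlp):
            z = z @ self.params[f"mlp.W{j}"] + self.params[f"mlp.b{j}"]
            if j < n_mlp - 1:
                z = z.relu()
        return z.reshape(z.shape[0])

    # -- input preparation -------------------------------------------------

    @staticmethod
    def _spectra(x: np.ndarray) -> np.ndarray:
        """Per-channel rFFT magnitude spectra: (B, T, C) -> (B, T//2+1, C)."""
        return np.abs(np.fft.rfft(x, axis=1))

    def _prepare(self, x: np.ndarray, fit: bool) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        if x.ndim != 3 or x.shape[1] != self.cfg.sequence_length or x.shape[2] != self.cfg.channels:
            raise ValueError(
                f"expected sequences of shape (n, {self.cfg.sequence_length}, "
                f"{self.cfg.channels}), got {x.shape}"
            )
        f = self._spectra(x)
        if fit:
            self._channel_mean = x.mean(axis=(0, 1))
            self._channel_std = x.std(axis=(0, 1)) + 1e-8
            self._freq_mean = f.mean(axis=(0, 1))
            self._freq_std = f.std(axis=(0, 1)) + 1e-8
        if self._channel_mean is None:
            raise RuntimeError("predict called before fit")
        xt = (x - self._channel_mean) / self._channel_std
        ft = (f - self._freq_mean) / self._freq_std
        return xt, ft

    # -- training / inference ---------------------------------------------

    def fit(self, sequences: np.ndarray, y: np.ndarray) -> "DualStreamClassifier":
        cfg = self.cfg
        y = np.asarray(y, dtype=float)
        xt, ft = self._prepare(sequences, fit=True)
        n = len(y)
        opt = Adam(self.params, lr=cfg.learning_rate)
        for _ in range(cfg.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits = self._logits(xt[idx], ft[idx])
                yb = Tensor(y[idx])
                # BCE(z, y) = y * softplus(-z) + (1 - y) * softplus(z)
                loss = (
                    yb * (-logits).softplus() + (1.0 - yb) * logits.softplus()
                ).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            self.loss_history.append(epoch_loss / n)
        return self

    def predict_scores(self, sequences: np.ndarray) -> np.ndarray:
        xt, ft = self._prepare(sequences, fit=False)
        scores = []
        for start in range(0, len(xt), self.cfg.batch_size):
            z = self._logits(
                xt[start : start + self.cfg.batch_size],
                ft[start : start + self.cfg.batch_size],
            )
            scores.append(1.0 / (1.0 + np.exp(-np.clip(z.data, -500, 500))))
        return np.concatenate(scores)
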