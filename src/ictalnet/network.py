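"""Trainable realization of the hybrid CNN-LSTM.

A vectorized numpy implementation (im2col GEMM convolutions, batched LSTM,
manual backpropagation, Adam) of the architecture whose arithmetic is spelled
out naively in :mod:`ictalnet.reference`:

    input (1, T) → [conv(k) → ReLU → maxpool(p)] x 3 → dropout(P)
                 → time-major reshape → LSTM(H) → dropout(P)
                 → dense softmax (n_classes)

Training minimizes categorical cross-entropy.  Dropout (inverted scaling) is
active only during training; inference is deterministic and runs in float64
so that :meth:`CNNLSTMClassifier.predict_proba` agrees with
:func:`ictalnet.reference.reference_forward` on exported parameters to tight
tolerance.  Training arithmetic is float32.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .reference import ConvLayerSpec, DenseSpec, LSTMWeights, ModelParams

__all__ = ["ModelConfig", "CNNLSTMClassifier", "build_trainable_model", "count_parameters"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    The network always has exactly three conv+pool blocks (the fixed depth of
    the architecture) and one LSTM layer.  ``dropout_p`` applies at two
    sites — after the pooling stack and after the LSTM — each of which can be
    disabled.  ``epochs`` is a maximum: training stops early once the mean
    epoch cross-entropy drops below ``early_stop_loss``.

    Default pool size is 4 per block: with 4096-sample inputs this hands the
    LSTM a 62-step sequence, short enough for gradients to propagate through
    unrolled time (pools of 2 would give 508 steps).
    """

    conv_channels: tuple[int, int, int] = (16, 32, 32)
    kernel_sizes: tuple[int, int, int] = (5, 5, 5)
    pool_sizes: tuple[int, int, int] = (4, 4, 4)
    lstm_hidden: int = 64
    dropout_p: float = 0.5
    dropout_after_cnn: bool = True
    dropout_after_lstm: bool = True
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    loss: str = "cross_entropy"
    early_stop_loss: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conv_channels", "kernel_sizes", "pool_sizes"):
            v = tuple(getattr(self, name))
            object.__setattr__(self, name, v)
            if len(v) != 3:
                raise ValueError(f"{name} must list exactly 3 blocks, got {v}")
            if any(x < 1 for x in v):
                raise ValueError(f"{name} entries must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must satisfy 0 <= P < 1")
        if self.lstm_hidden < 1:
            raise ValueError("lstm_hidden must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss != "cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")


def count_parameters(cfg: ModelConfig, n_classes: int) -> int:
    """Closed-form trainable-parameter count of the architecture."""
    total = 0
    c_in = 1
    for c_out, k in zip(cfg.conv_channels, cfg.kernel_sizes):
        total += c_in * c_out * k + c_out
        c_in = c_out
    h = cfg.lstm_hidden
    total += 4 * (h * (h + c_in) + h)
    total += h * n_classes + n_classes
    return total


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CNNLSTMClassifier:
    """Trainable hybrid CNN-LSTM classifier for fixed-length 1-D segments.

    Parameters are seeded at construction: two models built from the same
    config have bit-identical initial weights.
    """

    def __init__(self, cfg: ModelConfig, n_classes: int):
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        self.cfg = cfg
        self.n_classes = int(n_classes)
        self._rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, np.ndarray] = {}
        self._init_weights()
        self._opt_state: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._opt_t = 0
        self.history_: dict[str, list[float] | int] = {"loss": [], "epochs_run": 0}

    # ------------------------------------------------------------------ setup
    def _init_weights(self) -> None:
        rng = self._rng
        cfg = self.cfg
        c_in = 1
        for l, (c_out, k) in enumerate(zip(cfg.conv_channels, cfg.kernel_sizes)):
            std = np.sqrt(2.0 / (c_in * k))  # He init for ReLU
            self.params[f"convW{l}"] = rng.normal(0.0, std, (c_out, c_in, k)).astype(np.float32)
            self.params[f"convb{l}"] = np.zeros(c_out, dtype=np.float32)
            c_in = c_out
        h = cfg.lstm_hidden
        concat = h + c_in
        lim = np.sqrt(6.0 / (concat + h))
        self.params["lstmW"] = rng.uniform(-lim, lim, (4 * h, concat)).astype(np.float32)
        b = np.zeros(4 * h, dtype=np.float32)
        b[:h] = 1.0  # forget-gate bias at 1: remember by default early in training
        self.params["lstmb"] = b
        lim = np.sqrt(6.0 / (h + self.n_classes))
        self.params["denseW"] = rng.uniform(-lim, lim, (self.n_classes, h)).astype(np.float32)
        self.params["denseb"] = np.zeros(self.n_classes, dtype=np.float32)

    def count_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # ---------------------------------------------------------------- forward
    def _forward(
        self,
        X: np.ndarray,
        train: bool,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        """Forward pass; returns (probs, cache or None)."""
        cfg = self.cfg
        B = X.shape[0]
        A = X[:, None, :].astype(dtype)  # (B, 1, T)
        cache: dict = {"conv": []} if train else None
        for l, (k, p) in enumerate(zip(cfg.kernel_sizes, cfg.pool_sizes)):
            W = self.params[f"convW{l}"].astype(dtype, copy=False)
            b = self.params[f"convb{l}"].astype(dtype, copy=False)
            c_out, c_in, _ = W.shape
            L_out = A.shape[2] - k + 1
            if L_out < 1:
                raise ValueError(f"conv block {l + 1}: input length {A.shape[2]} < kernel {k}")
            win = sliding_window_view(A, k, axis=2)  # (B, Cin, L_out, k)
            col = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B * L_out, c_in * k)
            U = (col @ W.reshape(c_out, c_in * k).T + b).reshape(B, L_out, c_out)
            U = U.transpose(0, 2, 1)  # (B, Cout, L_out)
            relu_mask = U > 0
            act = np.where(relu_mask, U, 0.0)
            L_p = L_out // p
            if L_p < 1:
                raise ValueError(f"conv block {l + 1}: length {L_out} < pool size {p}")
            Rwin = act[:, :, : L_p * p].reshape(B, c_out, L_p, p)
            arg = Rwin.argmax(axis=3)
            pooled = np.take_along_axis(Rwin, arg[..., None], axis=3)[..., 0]
            if train:
                cache["conv"].append(
                    {"col": col, "relu_mask": relu_mask, "arg": arg, "shape_in": A.shape, "L_out": L_out}
                )
            A = pooled

        if train and cfg.dropout_after_cnn and cfg.dropout_p > 0:
            keep = 1.0 - cfg.dropout_p
            mask = (rng.random(A.shape) < keep).astype(dtype) / keep
            A = A * mask
            cache["cnn_drop_mask"] = mask

        S = np.ascontiguousarray(A.transpose(0, 2, 1))  # (B, T_seq, C)
        T_seq, C = S.shape[1], S.shape[2]
        H = cfg.lstm_hidden
        Wl = self.params["lstmW"].astype(dtype, copy=False)
        bl = self.params["lstmb"].astype(dtype, copy=False)
        Wh, Wx = Wl[:, :H], Wl[:, H:]
        Xp = (S.reshape(B * T_seq, C) @ Wx.T + bl).reshape(B, T_seq, 4 * H)
        h = np.zeros((B, H), dtype=dtype)
        c = np.zeros((B, H), dtype=dtype)
        if train:
            F = np.empty((T_seq, B, H), dtype=dtype)
            I = np.empty_like(F)
            O = np.empty_like(F)
            G = np.empty_like(F)  # candidate C~
            Cs = np.empty_like(F)
            Hs = np.empty_like(F)
        for t in range(T_seq):
            g = Xp[:, t] + h @ Wh.T
            f_t = _sigmoid(g[:, :H])
            i_t = _sigmoid(g[:, H : 2 * H])
            o_t = _sigmoid(g[:, 2 * H : 3 * H])
            g_t = np.tanh(g[:, 3 * H :])
            c = f_t * c + i_t * g_t
            h = o_t * np.tanh(c)
            if train:
                F[t], I[t], O[t], G[t], Cs[t], Hs[t] = f_t, i_t, o_t, g_t, c, h
        if train:
            cache["lstm"] = {"S": S, "F": F, "I": I, "O": O, "G": G, "Cs": Cs, "Hs": Hs}

        h_top = h
        if train and cfg.dropout_after_lstm and cfg.dropout_p > 0:
            keep = 1.0 - cfg.dropout_p
            mask = (rng.random(h_top.shape) < keep).astype(dtype) / keep
            h_top = h_top * mask
            cache["lstm_drop_mask"] = mask
        if train:
            cache["h_top"] = h_top

        Wd = self.params["denseW"].astype(dtype, copy=False)
        bd = self.params["denseb"].astype(dtype, copy=False)
        probs = _softmax(h_top @ Wd.T + bd)
        return probs, cache

    # --------------------------------------------------------------- backward
    def _backward(self, probs: np.ndarray, y: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        cfg = self.cfg
        B = probs.shape[0]
        H = cfg.lstm_hidden
        grads: dict[str, np.ndarray] = {}

        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        h_top = cache["h_top"]
        grads["denseW"] = dlogits.T @ h_top
        grads["denseb"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params["denseW"].astype(dlogits.dtype, copy=False)
        if "lstm_drop_mask" in cache:
            dh = dh * cache["lstm_drop_mask"]

        ls = cache["lstm"]
        S, F, I, O, G, Cs, Hs = ls["S"], ls["F"], ls["I"], ls["O"], ls["G"], ls["Cs"], ls["Hs"]
        T_seq, C = S.shape[1], S.shape[2]
        Wl = self.params["lstmW"].astype(dh.dtype, copy=False)
        Wh, Wx = Wl[:, :H], Wl[:, H:]
        dG_all = np.empty((T_seq, B, 4 * H), dtype=dh.dtype)
        dc = np.zeros_like(dh)
        for t in range(T_seq - 1, -1, -1):
            tc = np.tanh(Cs[t])
            do = dh * tc
            dc = dc + dh * O[t] * (1.0 - tc * tc)
            c_prev = Cs[t - 1] if t > 0 else np.zeros_like(dc)
            df = dc * c_prev
            di = dc * G[t]
            dg = dc * I[t]
            blk = dG_all[t]
            blk[:, :H] = df * F[t] * (1.0 - F[t])
            blk[:, H : 2 * H] = di * I[t] * (1.0 - I[t])
            blk[:, 2 * H : 3 * H] = do * O[t] * (1.0 - O[t])
            blk[:, 3 * H :] = dg * (1.0 - G[t] * G[t])
            dh = blk @ Wh
            dc = dc * F[t]
        dG_bt = np.ascontiguousarray(dG_all.transpose(1, 0, 2)).reshape(B * T_seq, 4 * H)
        Hprev = np.empty((B, T_seq, H), dtype=dh.dtype)
        Hprev[:, 0] = 0.0
        if T_seq > 1:
            Hprev[:, 1:] = Hs[:-1].transpose(1, 0, 2)
        Z = np.concatenate([Hprev, S], axis=2).reshape(B * T_seq, H + C)
        grads["lstmW"] = dG_bt.T @ Z
        grads["lstmb"] = dG_bt.sum(axis=0)
        dS = (dG_bt @ Wx).reshape(B, T_seq, C)

        dA = np.ascontiguousarray(dS.transpose(0, 2, 1))  # (B, C, T_seq)
        if "cnn_drop_mask" in cache:
            dA = dA * cache["cnn_drop_mask"]

        for l in range(2, -1, -1):
            cc = cache["conv"][l]
            W = self.params[f"convW{l}"].astype(dA.dtype, copy=False)
            c_out, c_in, k = W.shape
            p = cfg.pool_sizes[l]
            L_out = cc["L_out"]
            L_p = dA.shape[2]
            # unpool: route gradient to the argmax positions
            dR = np.zeros((dA.shape[0], c_out, L_p, p), dtype=dA.dtype)
            np.put_along_axis(dR, cc["arg"][..., None], dA[..., None], axis=3)
            dAct = np.zeros((dA.shape[0], c_out, L_out), dtype=dA.dtype)
            dAct[:, :, : L_p * p] = dR.reshape(dA.shape[0], c_out, L_p * p)
            dU = dAct * cc["relu_mask"]
            dU_mat = np.ascontiguousarray(dU.transpose(0, 2, 1)).reshape(-1, c_out)
            grads[f"convW{l}"] = (dU_mat.T @ cc["col"]).reshape(c_out, c_in, k)
            grads[f"convb{l}"] = dU.sum(axis=(0, 2))
            if l > 0:
                dcol = (dU_mat @ W.reshape(c_out, c_in * k)).reshape(dA.shape[0], L_out, c_in, k)
                dX = np.zeros(cc["shape_in"], dtype=dA.dtype)
                for kk in range(k):
                    dX[:, :, kk : kk + L_out] += dcol[:, :, :, kk].transpose(0, 2, 1)
                dA = dX
        return grads

    # ------------------------------------------------------------------ train
    def _apply_gradients(self, grads: dict[str, np.ndarray]) -> None:
        cfg = self.cfg
        if cfg.optimizer == "sgd":
            for name, g in grads.items():
                self.params[name] -= (cfg.learning_rate * g).astype(self.params[name].dtype)
            return
        self._opt_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for name, g in grads.items():
            if name not in self._opt_state:
                self._opt_state[name] = (np.zeros_like(g), np.zeros_like(g))
            m, v = self._opt_state[name]
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self._opt_t)
            vhat = v / (1 - b2**self._opt_t)
            self.params[name] -= (cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)).astype(
                self.params[name].dtype
            )

    def fit(self, segments: np.ndarray, labels: Sequence[int]) -> "CNNLSTMClassifier":
        """Train with mini-batch categorical cross-entropy.

        Raises ``RuntimeError`` on non-finite loss (training divergence).
        """
        X = np.asarray(segments, dtype=np.float32)
        y = np.asarray(labels, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("segments must be (n, length) aligned with labels")
        if y.min() < 0 or y.max() >= self.n_classes:
            raise ValueError(f"labels must lie in 0..{self.n_classes - 1}")
        cfg = self.cfg
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xFEED]))
        n = X.shape[0]
        losses: list[float] = self.history_["loss"]  # type: ignore[assignment]
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                probs, cache = self._forward(X[idx], train=True, rng=rng)
                batch_loss = -np.mean(np.log(np.clip(probs[np.arange(idx.size), y[idx]], 1e-12, None)))
                if not np.isfinite(batch_loss):
                    raise RuntimeError(f"non-finite training loss at epoch {epoch + 1}")
                epoch_loss += float(batch_loss) * idx.size
                grads = self._backward(probs, y[idx], cache)
                self._apply_gradients(grads)
            epoch_loss /= n
            losses.append(epoch_loss)
            self.history_["epochs_run"] = epoch + 1
            if epoch_loss < cfg.early_stop_loss:
                break
        return self

    def predict_proba(self, segments: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Deterministic inference-mode class probabilities (dropout off, float64)."""
        X = np.asarray(segments, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        chunks = [
            self._forward(X[s : s + batch_size], train=False, dtype=np.float64)[0]
            for s in range(0, X.shape[0], batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    def predict(self, segments: np.ndarray) -> np.ndarray:
        return self.predict_proba(segments).argmax(axis=1)

    def get_params(self) -> ModelParams:
        """Export weights as the reference-forward layer specs (float64)."""
        cfg = self.cfg
        blocks = []
        for l, p in enumerate(cfg.pool_sizes):
            blocks.append(
                ConvLayerSpec(
                    kernels=self.params[f"convW{l}"].astype(np.float64),
                    biases=self.params[f"convb{l}"].astype(np.float64),
                    activation="relu",
                    pool_size=int(p),
                    pool_stride=int(p),
                )
            )
        H = cfg.lstm_hidden
        Wl = self.params["lstmW"].astype(np.float64)
        bl = self.params["lstmb"].astype(np.float64)
        lstm = LSTMWeights(
            W_f=Wl[:H], W_i=Wl[H : 2 * H], W_o=Wl[2 * H : 3 * H], W_C=Wl[3 * H :],
            b_f=bl[:H], b_i=bl[H : 2 * H], b_o=bl[2 * H : 3 * H], b_C=bl[3 * H :],
        )
        dense = DenseSpec(
            weights=self.params["denseW"].astype(np.float64),
            biases=self.params["denseb"].astype(np.float64),
        )
        return ModelParams(conv_blocks=blocks, lstm=lstm, dense=dense)


def build_trainable_model(cfg: ModelConfig, n_classes: int) -> CNNLSTMClassifier:
    """Construct a seeded trainable model (fit / predict_proba / get_params)."""
    return CNNLSTMClassifier(cfg, n_classes)
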