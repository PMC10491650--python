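"""Reference forward semantics of the hybrid CNN-LSTM.

This module spells out, layer by layer and with no vectorization tricks, the
exact arithmetic of the network:

* 1-D convolution blocks: for output channel ``m`` of layer ``l``,
  ``u_m^l = sum_{n in p} corr(x_n, H_mn^l) + b_m^l`` (cross-correlation,
  valid positions, stride 1), then ``x_m^l = f(u_m^l)``, then an affine
  max-pool ``a_m^l * down(x_m^l) + b_m^l(pool)``.
* LSTM cell on the concatenation ``z = [h_{t-1}, x_t]``::

      f_t = sigma(W_f z + b_f)        i_t = sigma(W_i z + b_i)
      C~_t = tanh(W_C z + b_C)        C_t = f_t * C_{t-1} + i_t * C~_t
      o_t = sigma(W_o z + b_o)        h_t = o_t * tanh(C_t)

* dense softmax head: ``softmax(w h_T + b)``.

It exists as an executable specification: the vectorized trainable model in
:mod:`ictalnet.network` must agree with it on exported parameters, which pins
down the whole architecture wiring (channel ordering, pooled-time-step to
LSTM-input reshape, gate layout).  Dropout is inference-disabled here by
construction; the forward pass is pure and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ConvLayerSpec",
    "LSTMWeights",
    "LSTMStepTrace",
    "DenseSpec",
    "ModelParams",
    "ForwardTrace",
    "conv1d_forward",
    "maxpool1d",
    "lstm_step",
    "lstm_forward",
    "dense_softmax",
    "reference_forward",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "relu": lambda u: np.maximum(u, 0.0),
    "identity": lambda u: u,
    "tanh": np.tanh,
    "sigmoid": _sigmoid,
}


@dataclass
class ConvLayerSpec:
    """One convolution + max-pool block.

    ``kernels`` has shape ``(out_channels, in_channels, kernel_len)``;
    ``input_channels`` is the optional channel selection ``p`` (default: all
    input channels feed every output channel).  ``pool_scale`` / ``pool_bias``
    are the per-channel affine applied after pooling (plain max-pooling when
    left at 1 and 0).
    """

    kernels: np.ndarray
    biases: np.ndarray
    activation: str = "relu"
    input_channels: tuple[int, ...] | None = None
    pool_size: int = 1
    pool_stride: int | None = None
    pool_scale: np.ndarray | float = 1.0
    pool_bias: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float)
        if self.kernels.ndim != 3 or self.kernels.shape[2] < 1:
            raise ValueError("kernels must have shape (out, in, k) with k >= 1")
        if self.biases.shape != (self.kernels.shape[0],):
            raise ValueError("one bias per output channel required")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")


@dataclass
class LSTMWeights:
    """Gate matrices over the concatenation [h_{t-1}, x_t] and their offsets."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_o: np.ndarray
    W_C: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_o: np.ndarray
    b_C: np.ndarray

    def __post_init__(self) -> None:
        mats = {"W_f": self.W_f, "W_i": self.W_i, "W_o": self.W_o, "W_C": self.W_C}
        for name, m in mats.items():
            arr = np.asarray(m, dtype=float)
            setattr(self, name, arr)
            if arr.shape != np.asarray(self.W_f).shape:
                raise ValueError(f"gate matrix {name} shape {arr.shape} != W_f shape {self.W_f.shape}")
        hidden = self.W_f.shape[0]
        for name in ("b_f", "b_i", "b_o", "b_C"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (hidden,):
                raise ValueError(f"offset {name} must have the hidden dimension {hidden}")

    @property
    def hidden_size(self) -> int:
        return int(self.W_f.shape[0])

    @property
    def input_size(self) -> int:
        return int(self.W_f.shape[1] - self.W_f.shape[0])


@dataclass
class LSTMStepTrace:
    """All intermediate vectors of one LSTM step."""

    f: np.ndarray
    i: np.ndarray
    o: np.ndarray
    c_tilde: np.ndarray
    c: np.ndarray
    h: np.ndarray


@dataclass
class DenseSpec:
    """Fully-connected softmax head: weights (n_classes, in_dim), biases (n_classes,)."""

    weights: np.ndarray
    biases: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float)
        if self.weights.ndim != 2 or self.biases.shape != (self.weights.shape[0],):
            raise ValueError("dense weights must be (n_classes, in_dim) with matching biases")


@dataclass
class ModelParams:
    """Complete parameter set of the hybrid network (3 conv blocks, LSTM, dense)."""

    conv_blocks: list[ConvLayerSpec]
    lstm: LSTMWeights
    dense: DenseSpec


@dataclass
class ForwardTrace:
    """Per-layer pre-activations and outputs collected during a forward pass."""

    conv_preact: list[np.ndarray] = field(default_factory=list)
    conv_out: list[np.ndarray] = field(default_factory=list)
    pool_out: list[np.ndarray] = field(default_factory=list)
    lstm_steps: list[LSTMStepTrace] = field(default_factory=list)
    dense_preact: np.ndarray | None = None


def conv1d_forward(x: np.ndarray, spec: ConvLayerSpec) -> tuple[np.ndarray, np.ndarray]:
    """Valid cross-correlation plus bias, then the activation.

    Returns ``(outputs x_m^l, pre-activations u_m^l)``, each of shape
    ``(out_channels, time - k + 1)``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n_out, n_in, k = spec.kernels.shape
    if x.shape[0] != n_in:
        raise ValueError(f"input has {x.shape[0]} channels, kernels expect {n_in}")
    if x.shape[1] < k:
        raise ValueError(f"input length {x.shape[1]} shorter than kernel length {k}")
    selected = spec.input_channels if spec.input_channels is not None else tuple(range(n_in))
    t_out = x.shape[1] - k + 1
    u = np.empty((n_out, t_out))
    for m in range(n_out):
        acc = np.full(t_out, spec.biases[m])
        for n in selected:
            acc = acc + np.correlate(x[n], spec.kernels[m, n], mode="valid")
        u[m] = acc
    return ACTIVATIONS[spec.activation](u), u


def maxpool1d(
    x: np.ndarray,
    pool_size: int,
    pool_stride: int | None = None,
    pool_scale: np.ndarray | float = 1.0,
    pool_bias: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Per-channel windowed max with an affine offset: ``a * max(window) + b``.

    Non-overlapping windows when the stride equals the pool size (the
    default); a trailing partial window is dropped.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    stride = pool_stride if pool_stride is not None else pool_size
    if stride < 1:
        raise ValueError("pool_stride must be >= 1")
    t = x.shape[1]
    if pool_size > t:
        raise ValueError(f"pool_size {pool_size} exceeds time length {t}")
    starts = range(0, t - pool_size + 1, stride)
    pooled = np.stack([x[:, s : s + pool_size].max(axis=1) for s in starts], axis=1)
    scale = np.asarray(pool_scale, dtype=float).reshape(-1, 1) if np.ndim(pool_scale) else pool_scale
    bias = np.asarray(pool_bias, dtype=float).reshape(-1, 1) if np.ndim(pool_bias) else pool_bias
    return scale * pooled + bias


def lstm_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, w: LSTMWeights
) -> LSTMStepTrace:
    """One LSTM cell update on ``z = [h_prev, x_t]``; see the module docstring."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    hidden, concat = w.W_f.shape
    if h_prev.shape != (hidden,):
        raise ValueError(f"h_prev has shape {h_prev.shape}, W_f expects hidden size {hidden}")
    if c_prev.shape != (hidden,):
        raise ValueError(f"c_prev has shape {c_prev.shape}, W_f expects hidden size {hidden}")
    if x_t.shape != (concat - hidden,):
        raise ValueError(f"x_t has shape {x_t.shape}, W_f expects input size {concat - hidden}")
    z = np.concatenate([h_prev, x_t])
    f = _sigmoid(w.W_f @ z + w.b_f)
    i = _sigmoid(w.W_i @ z + w.b_i)
    c_tilde = np.tanh(w.W_C @ z + w.b_C)
    c = f * c_prev + i * c_tilde
    o = _sigmoid(w.W_o @ z + w.b_o)
    h = o * np.tanh(c)
    return LSTMStepTrace(f=f, i=i, o=o, c_tilde=c_tilde, c=c, h=h)


def lstm_forward(
    sequence: np.ndarray,
    w: LSTMWeights,
    h0: np.ndarray | None = None,
    c0: np.ndarray | None = None,
    return_trace: bool = False,
) -> np.ndarray | tuple[np.ndarray, list[LSTMStepTrace]]:
    """Fold :func:`lstm_step` over a (time, features) sequence; return h_T."""
    seq = np.atleast_2d(np.asarray(sequence, dtype=float))
    if seq.shape[0] == 0:
        raise ValueError("lstm_forward requires a non-empty sequence")
    h = np.zeros(w.hidden_size) if h0 is None else np.asarray(h0, dtype=float)
    c = np.zeros(w.hidden_size) if c0 is None else np.asarray(c0, dtype=float)
    traces: list[LSTMStepTrace] = []
    for t in range(seq.shape[0]):
        step = lstm_step(seq[t], h, c, w)
        h, c = step.h, step.c
        if return_trace:
            traces.append(step)
    return (h, traces) if return_trace else h


def dense_softmax(h: np.ndarray, spec: DenseSpec) -> np.ndarray:
    """Affine map then numerically stable softmax (max-subtracted)."""
    h = np.asarray(h, dtype=float)
    if h.shape != (spec.weights.shape[1],):
        raise ValueError(f"input of shape {h.shape} does not match dense weights {spec.weights.shape}")
    u = spec.weights @ h + spec.biases
    u = u - u.max()
    e = np.exp(u)
    return e / e.sum()


def reference_forward(
    segment: np.ndarray,
    params: ModelParams,
    return_trace: bool = False,
) -> np.ndarray | tuple[np.ndarray, ForwardTrace]:
    """Full deterministic forward pass of one normalized segment.

    conv/pool block x3 → (dropout is a no-op at inference) → the pooled
    (channels, time) map is transposed time-major so each pooled time step
    becomes one LSTM input vector → LSTM → dense softmax.
    """
    x = np.atleast_2d(np.asarray(segment, dtype=float))
    trace = ForwardTrace()
    for idx, block in enumerate(params.conv_blocks):
        try:
            out, u = conv1d_forward(x, block)
            x = maxpool1d(out, block.pool_size, block.pool_stride, block.pool_scale, block.pool_bias)
        except ValueError as exc:
            raise ValueError(f"conv block {idx + 1}: {exc}") from exc
        trace.conv_preact.append(u)
        trace.conv_out.append(out)
        trace.pool_out.append(x)
    sequence = x.T  # (pooled time steps, channels)
    try:
        h, steps = lstm_forward(sequence, params.lstm, return_trace=True)
    except ValueError as exc:
        raise ValueError(f"lstm: {exc}") from exc
    trace.lstm_steps = steps
    try:
        probs = dense_softmax(h, params.dense)
    except ValueError as exc:
        raise ValueError(f"dense: {exc}") from exc
    trace.dense_preact = params.dense.weights @ h + params.dense.biases
    return (probs, trace) if return_trace else probs
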