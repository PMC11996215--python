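"""Reference single-step recurrent cell arithmetic.

These functions spell out the gate equations one time step at a time, with
optional bias terms (the bias-free form is the textbook one; training adds
biases by default).  The batched training layers in
:mod:`pcgseg.models.nets` must agree with these to machine precision — the
unit tests hold them to hand-unrolled evaluations.

GRU update for input x_t and previous hidden state h_{t-1}:

    z_t = sigmoid(W_z x_t + U_z h_{t-1})          (update gate)
    r_t = sigmoid(W_r x_t + U_r h_{t-1})          (reset gate)
    h~_t = tanh(W_h x_t + r_t * (U_h h_{t-1}))    (candidate state)
    h_t = (1 - z_t) * h~_t + z_t * h_{t-1}

LSTM update with separate cell state c_t:

    i, f, o = sigmoid(W x_t + U h_{t-1} + b)      (input/forget/output gates)
    g = tanh(W_g x_t + U_g h_{t-1} + b_g)         (candidate)
    c_t = f * c_{t-1} + i * g
    h_t = o * tanh(c_t)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def sigmoid(a: np.ndarray) -> np.ndarray:
    # overflow-safe piecewise logistic
    out = np.empty_like(a, dtype=float)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


@dataclass(frozen=True)
class GruCellParams:
    """Weight matrices of one GRU cell, shaped (hidden, input) and (hidden, hidden)."""

    w_zx: np.ndarray
    w_rx: np.ndarray
    w_hx: np.ndarray
    u_zh: np.ndarray
    u_rh: np.ndarray
    u_hh: np.ndarray
    b_z: np.ndarray | None = None
    b_r: np.ndarray | None = None
    b_h: np.ndarray | None = None

    def __post_init__(self) -> None:
        h, d = self.w_zx.shape
        for name in ("w_rx", "w_hx"):
            if getattr(self, name).shape != (h, d):
                raise ValueError(f"{name} must have shape {(h, d)}")
        for name in ("u_zh", "u_rh", "u_hh"):
            if getattr(self, name).shape != (h, h):
                raise ValueError(f"{name} must have shape {(h, h)}")
        for name in ("b_z", "b_r", "b_h"):
            b = getattr(self, name)
            if b is not None and b.shape != (h,):
                raise ValueError(f"{name} must have shape {(h,)}")

    @property
    def hidden_size(self) -> int:
        return self.w_zx.shape[0]

    @property
    def input_size(self) -> int:
        return self.w_zx.shape[1]


@dataclass(frozen=True)
class LstmCellParams:
    """Gate parameter blocks of one LSTM cell.

    ``w_*`` are (hidden, input), ``u_*`` are (hidden, hidden); the four
    blocks are the input gate (i), forget gate (f), output gate (o) and the
    candidate (g).
    """

    w_i: np.ndarray
    w_f: np.ndarray
    w_o: np.ndarray
    w_g: np.ndarray
    u_i: np.ndarray
    u_f: np.ndarray
    u_o: np.ndarray
    u_g: np.ndarray
    b_i: np.ndarray | None = None
    b_f: np.ndarray | None = None
    b_o: np.ndarray | None = None
    b_g: np.ndarray | None = None

    def __post_init__(self) -> None:
        h, d = self.w_i.shape
        for name in ("w_f", "w_o", "w_g"):
            if getattr(self, name).shape != (h, d):
                raise ValueError(f"{name} must have shape {(h, d)}")
        for name in ("u_i", "u_f", "u_o", "u_g"):
            if getattr(self, name).shape != (h, h):
                raise ValueError(f"{name} must have shape {(h, h)}")
        for name in ("b_i", "b_f", "b_o", "b_g"):
            b = getattr(self, name)
            if b is not None and b.shape != (h,):
                raise ValueError(f"{name} must have shape {(h,)}")

    @property
    def hidden_size(self) -> int:
        return self.w_i.shape[0]


def _bias(b: np.ndarray | None, h: int) -> np.ndarray:
    return np.zeros(h) if b is None else b


def gru_step(params: GruCellParams, x_t: np.ndarray, h_prev: np.ndarray) -> np.ndarray:
    """One GRU time step; returns the new hidden state h_t."""
    x_t = np.atleast_1d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_1d(np.asarray(h_prev, dtype=float))
    h = params.hidden_size
    if x_t.shape != (params.input_size,) or h_prev.shape != (h,):
        raise ValueError(
            f"expected x_t of shape {(params.input_size,)} and h_prev of shape {(h,)}"
        )
    z = sigmoid(params.w_zx @ x_t + params.u_zh @ h_prev + _bias(params.b_z, h))
    r = sigmoid(params.w_rx @ x_t + params.u_rh @ h_prev + _bias(params.b_r, h))
    h_cand = np.tanh(
        params.w_hx @ x_t + r * (params.u_hh @ h_prev) + _bias(params.b_h, h)
    )
    return (1.0 - z) * h_cand + z * h_prev


def lstm_step(
    params: LstmCellParams,
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM time step; returns ``(h_t, c_t)``."""
    x_t = np.atleast_1d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_1d(np.asarray(h_prev, dtype=float))
    c_prev = np.atleast_1d(np.asarray(c_prev, dtype=float))
    h = params.hidden_size
    i = sigmoid(params.w_i @ x_t + params.u_i @ h_prev + _bias(params.b_i, h))
    f = sigmoid(params.w_f @ x_t + params.u_f @ h_prev + _bias(params.b_f, h))
    o = sigmoid(params.w_o @ x_t + params.u_o @ h_prev + _bias(params.b_o, h))
    g = np.tanh(params.w_g @ x_t + params.u_g @ h_prev + _bias(params.b_g, h))
    c_t = f * c_prev + i * g
    return o * np.tanh(c_t), c_t


def bigru_forward(
    fwd: GruCellParams, bwd: GruCellParams, x: np.ndarray
) -> np.ndarray:
    """Bidirectional GRU over a sequence; concatenated states per step.

    ``x`` is (T, input).  One cell runs start-to-end, the other end-to-start,
    and the output at step t is the concatenation [h_fwd_t, h_bwd_t], giving
    width 2 * hidden.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if fwd.input_size != bwd.input_size:
        raise ValueError("forward and backward cells must share input size")
    T = x.shape[0]
    hf = np.zeros(fwd.hidden_size)
    hb = np.zeros(bwd.hidden_size)
    out_f = np.empty((T, fwd.hidden_size))
    out_b = np.empty((T, bwd.hidden_size))
    for t in range(T):
        hf = gru_step(fwd, x[t], hf)
        out_f[t] = hf
    for t in range(T - 1, -1, -1):
        hb = gru_step(bwd, x[t], hb)
        out_b[t] = hb
    return np.concatenate([out_f, out_b], axis=1)


def softmax(scores: np.ndarray, axis: int = -1) -> np.ndarray:
    """Overflow-safe softmax: exp(x_i) / sum_j exp(x_j)."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("softmax input must be finite")
    shifted = scores - np.max(scores, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=axis, keepdims=True)
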