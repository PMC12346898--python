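"""Single-layer LSTM with full backpropagation through time.

Input is a (batch, time, features) sequence; the layer exposes the final
hidden state, which summarises the whole sequence for classification.
Gate order in the stacked weight matrices is (input, forget, cell, output);
the forget-gate bias starts at 1 so early training does not erase memory.
"""

from __future__ import annotations

import numpy as np

from .layers import Layer, Param

__all__ = ["LSTM"]


def _sigmoid(x):
    # split by sign to avoid overflow in exp
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTM(Layer):
    def __init__(self, d_in, d_hidden, *, rng):
        self.d_in = d_in
        self.h = d_hidden
        s_in = 1.0 / np.sqrt(d_in)
        s_h = 1.0 / np.sqrt(d_hidden)
        self.wx = Param(rng.uniform(-s_in, s_in, (4 * d_hidden, d_in)), "lstm.wx")
        self.wh = Param(rng.uniform(-s_h, s_h, (4 * d_hidden, d_hidden)), "lstm.wh")
        b = np.zeros(4 * d_hidden)
        b[d_hidden : 2 * d_hidden] = 1.0  # forget gate
        self.b = Param(b, "lstm.b")
        self._cache = None

    def forward(self, x, train=False):
        n, t, _ = x.shape
        hdim = self.h
        h = np.zeros((n, hdim), dtype=np.float32)
        c = np.zeros((n, hdim), dtype=np.float32)
        steps = []
        for k in range(t):
            z = x[:, k] @ self.wx.value.T + h @ self.wh.value.T + self.b.value
            i = _sigmoid(z[:, :hdim])
            f = _sigmoid(z[:, hdim : 2 * hdim])
            g = np.tanh(z[:, 2 * hdim : 3 * hdim])
            o = _sigmoid(z[:, 3 * hdim :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            if train:
                steps.append((x[:, k], h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
        if train:
            self._cache = (steps, x.shape)
        return h

    def backward(self, dh_last):
        steps, x_shape = self._cache
        self._cache = None
        n, t, d = x_shape
        hdim = self.h
        dx = np.zeros(x_shape, dtype=np.float32)
        dh = np.ascontiguousarray(dh_last, dtype=np.float32)
        dc = np.zeros((n, hdim), dtype=np.float32)
        for k in range(t - 1, -1, -1):
            xk, h_prev, c_prev, i, f, g, o, tanh_c = steps[k]
            do = dh * tanh_c
            dct = dc + dh * o * (1 - tanh_c**2)
            di = dct * g
            df = dct * c_prev
            dg = dct * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.wx.grad += dz.T @ xk
            self.wh.grad += dz.T @ h_prev
            self.b.grad += dz.sum(axis=0)
            dx[:, k] = dz @ self.wx.value
            dh = dz @ self.wh.value
            dc = dct * f
        return dx

    def params(self):
        return [self.wx, self.wh, self.b]
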