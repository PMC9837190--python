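"""Decoder architectures for windowed population firing-rate input.

Both models map a (batch, 60, n_units) firing-rate window to a
(batch, n_characters, 3) score matrix; softmax over the last axis gives
each character's probability distribution over {YES, NO, DNK}.
"""
from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .layers import (LSTM, BatchNorm, Conv2d, Linear, Module,
                     max_pool2d, softmax)


class LSTMDecoder(Module):
    """Two stacked LSTM layers (128 units each by default) followed by two
    fully-connected layers with batch normalisation and leaky-ReLU."""

    def __init__(self, n_units: int, n_characters: int = 4, hidden: int = 128,
                 num_layers: int = 2, fc_hidden: int = 128, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_characters = n_characters
        self.lstm = LSTM(n_units, hidden, num_layers, rng)
        self.fc1 = Linear(hidden, fc_hidden, rng)
        self.bn = BatchNorm(fc_hidden, ndim=2)
        self.fc2 = Linear(fc_hidden, n_characters * 3, rng)

    def __call__(self, x: np.ndarray) -> Tensor:
        h = self.lstm(x)
        z = self.bn(self.fc1(h)).leaky_relu()
        return self.fc2(z).reshape(x.shape[0], self.n_characters, 3)


class CNNDecoder(Module):
    """Convolutional decoder: the 60 x n_units window is treated as a
    one-channel image passed through 3x3 convolutions (batch norm +
    leaky-ReLU in between), one max-pool, then two fully-connected layers."""

    def __init__(self, n_units: int, n_characters: int = 4,
                 channels=(16, 32, 64), kernel: int = 3, fc_hidden: int = 128,
                 window: int = 60, seed: int = 0, pool_each: bool = True,
                 pools=None):
        rng = np.random.default_rng(seed)
        self.n_characters = n_characters
        self.convs: list[Conv2d] = []
        self.bns: list[BatchNorm] = []
        self.pools: list[tuple[int, int]] = []
        c_prev = 1
        h, w = window, n_units
        for li, c in enumerate(channels):
            self.convs.append(Conv2d(c_prev, c, kernel, rng))
            self.bns.append(BatchNorm(c, ndim=4))
            # pooling after each block keeps the activation maps small;
            # explicit per-block ``pools`` (e.g. time-only (2, 1)) override
            # the default; with pool_each=False only the last block pools
            if pools is not None:
                pool = pools[li]
            elif pool_each or li == len(channels) - 1:
                pool = (2 if h >= 2 else 1, 2 if w >= 2 else 1)
            else:
                pool = (1, 1)
            pool = (min(pool[0], max(h, 1)), min(pool[1], max(w, 1)))
            h, w = h // pool[0], w // pool[1]
            self.pools.append(pool)
            c_prev = c
        self.fc1 = Linear(c_prev * h * w, fc_hidden, rng)
        self.bn_fc = BatchNorm(fc_hidden, ndim=2)
        self.fc2 = Linear(fc_hidden, n_characters * 3, rng)

    def __call__(self, x: np.ndarray) -> Tensor:
        batch, window, n_units = x.shape
        t = Tensor(x.reshape(batch, 1, window, n_units))
        for conv, bn, pool in zip(self.convs, self.bns, self.pools):
            t = bn(conv(t)).leaky_relu()
            if pool != (1, 1):
                t = max_pool2d(t, pool)
        t = t.reshape(batch, -1)
        z = self.bn_fc(self.fc1(t)).leaky_relu()
        return self.fc2(z).reshape(batch, self.n_characters, 3)


def predict_proba(model: Module, x: np.ndarray, batch_size: int = 512
                  ) -> np.ndarray:
    """Per-character label probabilities, shape (n, n_characters, 3)."""
    model.eval()
    out = []
    for start in range(0, x.shape[0], batch_size):
        logits = model(x[start:start + batch_size])
        out.append(softmax(logits.data))
    return np.concatenate(out, axis=0)
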