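"""Neural-network building blocks on the autograd engine.

Layers follow the decoder architectures used for spike-window
classification: stacked LSTMs, 3x3 convolutions with batch
normalisation and leaky-ReLU, max pooling, and fully-connected heads.
Weight initialisation conventions: convolutions draw from a Gaussian
with mean 0 and standard deviation 0.1; fully-connected and recurrent
weights draw from the usual symmetric uniform with bound 1/sqrt(fan).
"""
from __future__ import annotations

import numpy as np

from .autograd import Tensor

DTYPE = np.float32


class Module:
    training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def _batchnorms(self) -> list["BatchNorm"]:
        found: list["BatchNorm"] = []
        for v in self.__dict__.values():
            if isinstance(v, BatchNorm):
                found.append(v)
            elif isinstance(v, Module):
                found.extend(v._batchnorms())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        found.extend(item._batchnorms())
        return found

    def state_dict(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.parameters()]
        for bn in self._batchnorms():
            state.append(bn.running_mean.copy())
            state.append(bn.running_var.copy())
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, d in zip(params, state):
            p.data = d.copy()
        it = iter(state[len(params):])
        for bn in self._batchnorms():
            bn.running_mean = next(it).copy()
            bn.running_var = next(it).copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=DTYPE):
        bound = 1.0 / np.sqrt(n_in)
        self.weight = Tensor(
            rng.uniform(-bound, bound, (n_in, n_out)).astype(dtype),
            requires_grad=True)
        self.bias = Tensor(
            rng.uniform(-bound, bound, (n_out,)).astype(dtype),
            requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight).add(self.bias)


class LSTM(Module):
    """Stacked LSTM; consumes a raw (batch, time, features) array and
    returns the top layer's final hidden state."""

    def __init__(self, n_in: int, hidden: int, num_layers: int,
                 rng: np.random.Generator, dtype=DTYPE):
        self.hidden = hidden
        self.num_layers = num_layers
        self.w_x: list[Tensor] = []
        self.w_h: list[Tensor] = []
        self.b: list[Tensor] = []
        bound = 1.0 / np.sqrt(hidden)
        for layer in range(num_layers):
            fan_in = n_in if layer == 0 else hidden
            self.w_x.append(Tensor(
                rng.uniform(-bound, bound, (fan_in, 4 * hidden)).astype(dtype),
                requires_grad=True))
            self.w_h.append(Tensor(
                rng.uniform(-bound, bound, (hidden, 4 * hidden)).astype(dtype),
                requires_grad=True))
            bias = rng.uniform(-bound, bound, (4 * hidden,)).astype(dtype)
            bias[hidden:2 * hidden] += 1.0  # forget-gate bias
            self.b.append(Tensor(bias, requires_grad=True))

    def __call__(self, x: np.ndarray) -> Tensor:
        batch, steps, _ = x.shape
        h_dim = self.hidden
        layer_inputs: list[Tensor] = [Tensor(x[:, t, :]) for t in range(steps)]
        for layer in range(self.num_layers):
            w_x, w_h, b = self.w_x[layer], self.w_h[layer], self.b[layer]
            h = Tensor(np.zeros((batch, h_dim), dtype=x.dtype))
            c = Tensor(np.zeros((batch, h_dim), dtype=x.dtype))
            outputs: list[Tensor] = []
            for t in range(steps):
                gates = layer_inputs[t].matmul(w_x).add(h.matmul(w_h)).add(b)
                i = gates.narrow(1, 0, h_dim).sigmoid()
                f = gates.narrow(1, h_dim, h_dim).sigmoid()
                g = gates.narrow(1, 2 * h_dim, h_dim).tanh()
                o = gates.narrow(1, 3 * h_dim, h_dim).sigmoid()
                c = f.mul(c).add(i.mul(g))
                h = o.mul(c.tanh())
                outputs.append(h)
            layer_inputs = outputs
        return layer_inputs[-1]


class BatchNorm(Module):
    """Batch normalisation over the batch (and spatial) axes.

    ``ndim=2`` normalises (B, F) features; ``ndim=4`` normalises
    (B, C, H, W) per channel.
    """

    def __init__(self, n_features: int, ndim: int = 2, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=DTYPE):
        self.ndim = ndim
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(n_features, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(n_features, dtype=np.float64)
        self.running_var = np.ones(n_features, dtype=np.float64)

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0,) if self.ndim == 2 else (0, 2, 3)
        shape = (1, -1) if self.ndim == 2 else (1, -1, 1, 1)
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mu = self.running_mean.astype(x.data.dtype)
            var = self.running_var.astype(x.data.dtype)
        std = np.sqrt(var + self.eps)
        xhat = (x.data - mu.reshape(shape)) / std.reshape(shape)
        out_data = self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)
        gamma, beta = self.gamma, self.beta
        training = self.training
        n = x.data.size / x.data.shape[1] if self.ndim == 4 else x.data.shape[0]

        def bwd(g):
            gamma._accum(np.sum(g * xhat, axis=axes))
            beta._accum(np.sum(g, axis=axes))
            if training:
                gmean = np.mean(g, axis=axes).reshape(shape)
                gx_mean = np.mean(g * xhat, axis=axes).reshape(shape)
                dx = (gamma.data.reshape(shape) / std.reshape(shape)) * (
                    g - gmean - xhat * gx_mean)
            else:
                dx = g * (gamma.data.reshape(shape) / std.reshape(shape))
            x._accum(dx.astype(x.data.dtype))

        return Tensor._make(out_data.astype(x.data.dtype), (x,), bwd)


class Conv2d(Module):
    """Convolution with 'same' zero padding, stride 1 (im2col).

    ``kernel`` may be an int (square) or an (kh, kw) tuple — e.g. (3, 1)
    for a purely temporal filter that never mixes the unit axis."""

    def __init__(self, c_in: int, c_out: int, kernel,
                 rng: np.random.Generator, init_sd: float = 0.1, dtype=DTYPE):
        if isinstance(kernel, int):
            kernel = (kernel, kernel)
        self.kernel = kernel
        self.pad = (kernel[0] // 2, kernel[1] // 2)
        self.weight = Tensor(
            rng.normal(0.0, init_sd,
                       (c_out, c_in, kernel[0], kernel[1])).astype(dtype),
            requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        kh, kw = self.kernel
        ph, pw = self.pad
        w, b = self.weight, self.bias
        batch, c_in, h, wd = x.data.shape
        xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw),
                                                        axis=(2, 3))
        # (B, C, H, W, kh, kw) -> (B*H*W, C*kh*kw)
        cols2 = cols.transpose(0, 2, 3, 1, 4, 5).reshape(
            batch * h * wd, c_in * kh * kw)
        wmat = w.data.reshape(w.data.shape[0], -1)  # (O, C*kh*kw)
        out = cols2 @ wmat.T + b.data
        c_out = w.data.shape[0]
        out_data = out.reshape(batch, h, wd, c_out).transpose(0, 3, 1, 2)

        def bwd(g):
            g2 = g.transpose(0, 2, 3, 1).reshape(batch * h * wd, c_out)
            w._accum((g2.T @ cols2).reshape(w.data.shape))
            b._accum(g2.sum(axis=0))
            if x.requires_grad:
                gcols = (g2 @ wmat).reshape(batch, h, wd, c_in, kh, kw)
                gxp = np.zeros_like(xp)
                for di in range(kh):
                    for dj in range(kw):
                        gxp[:, :, di:di + h, dj:dj + wd] += (
                            gcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2))
                x._accum(gxp[:, :, ph:ph + h, pw:pw + wd])

        return Tensor._make(out_data.astype(x.data.dtype), (x, w, b), bwd)


def max_pool2d(x: Tensor, size=(2, 2)) -> Tensor:
    if isinstance(size, int):
        size = (size, size)
    sh, sw = size
    batch, ch, h, w = x.data.shape
    ho, wo = h // sh, w // sw
    view = x.data[:, :, :ho * sh, :wo * sw].reshape(
        batch, ch, ho, sh, wo, sw).transpose(0, 1, 2, 4, 3, 5).reshape(
        batch, ch, ho, wo, sh * sw)
    idx = view.argmax(axis=-1)
    out_data = np.take_along_axis(view, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gview = np.zeros((batch, ch, ho, wo, sh * sw), dtype=g.dtype)
        np.put_along_axis(gview, idx[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(x.data)
        gx[:, :, :ho * sh, :wo * sw] = gview.reshape(
            batch, ch, ho, wo, sh, sw).transpose(0, 1, 2, 4, 3, 5).reshape(
            batch, ch, ho * sh, wo * sw)
        x._accum(gx)

    return Tensor._make(out_data, (x,), bwd)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray,
                          mask: np.ndarray) -> Tensor:
    """Fused per-row softmax + masked negative log-likelihood.

    ``logits``: (B, K, 3) scores; ``labels``: (B, K) integer class per
    character row; ``mask``: (B, K) 0/1, zero for rows whose label must
    not contribute (the DNK mechanism). Returns the mean over all B*K
    rows, masked rows counting as exactly zero loss.
    """
    z = logits.data
    zmax = z.max(axis=-1, keepdims=True)
    ez = np.exp(z - zmax)
    sm = ez / ez.sum(axis=-1, keepdims=True)
    batch, k, _ = z.shape
    rows = np.arange(batch)[:, None], np.arange(k)[None, :]
    logp = (z - zmax - np.log(ez.sum(axis=-1, keepdims=True)))[rows[0], rows[1], labels]
    denom = batch * k
    loss = -(mask * logp).sum() / denom

    def bwd(g):
        onehot = np.zeros_like(sm)
        onehot[rows[0], rows[1], labels] = 1.0
        glogits = (sm - onehot) * mask[..., None] / denom
        logits._accum((g * glogits).astype(logits.data.dtype))

    return Tensor._make(np.asarray(loss, dtype=z.dtype), (logits,), bwd)


def softmax(z: np.ndarray) -> np.ndarray:
    zmax = z.max(axis=-1, keepdims=True)
    ez = np.exp(z - zmax)
    return ez / ez.sum(axis=-1, keepdims=True)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
                      ).astype(p.data.dtype)
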