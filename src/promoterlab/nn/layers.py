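"""Neural-network building blocks on top of the autodiff engine.

Layers hold named parameter tensors; a :class:`Module` tree flattens to a
``{name: ndarray}`` state dict for checkpointing.  Sizes are deliberately
small — every model in this package trains on a single CPU.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "Dense", "Conv1d", "BiLSTM", "AttentionPool", "Sequential", "Adam"]


class Module:
    """Base class: children and parameters are discovered by attribute scan."""

    def parameters(self) -> list[Tensor]:
        params = []
        for name in sorted(self.__dict__):
            v = getattr(self, name)
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix="") -> dict[str, Tensor]:
        out = {}
        for name in sorted(self.__dict__):
            v = getattr(self, name)
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                out[key] = v
            elif isinstance(v, Module):
                out.update(v.named_parameters(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(prefix=f"{key}.{i}."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _glorot(rng, n_in, n_out, (n_in, n_out))
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.W) + self.b


class Conv1d(Module):
    """1-D convolution over (batch, length, channels) via gather + matmul.

    ``padding='same'`` keeps the length (odd kernels only); ``'valid'``
    shrinks it by k-1.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 padding: str = "valid"):
        if padding == "same" and k % 2 == 0:
            raise ValueError("'same' padding requires an odd kernel width")
        self.k = k
        self.c_in = c_in
        self.padding = padding
        self.W = _glorot(rng, k * c_in, c_out, (k * c_in, c_out))
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, C = x.shape
        k = self.k
        if self.padding == "same":
            pad = (k - 1) // 2
            zeros = ad.Tensor(np.zeros((B, pad, C)))
            x = ad.concatenate([zeros, x, zeros], axis=1)
            L_out = L
        else:
            L_out = L - k + 1
        idx = np.arange(L_out)[:, None] + np.arange(k)[None, :]  # (L_out, k)
        windows = ad.take(x, idx, axis=1)  # (B, L_out, k, C)
        flat = ad.reshape(windows, (B * L_out, k * self.c_in))
        out = ad.matmul(flat, self.W) + self.b
        return ad.reshape(out, (B, L_out, -1))


def avg_pool(x: Tensor, width: int = 2) -> Tensor:
    """Non-overlapping mean pooling over the length axis (truncates remainder)."""
    B, L, C = x.shape
    L2 = (L // width) * width
    if L2 == 0:
        raise ValueError(f"cannot pool length-{L} feature map by width {width}")
    if L2 != L:
        x = x[:, :L2, :]
    x = ad.reshape(x, (B, L2 // width, width, C))
    return ad.tmean(x, axis=2)


class BiLSTM(Module):
    """Bidirectional LSTM returning the full hidden sequence (B, L, 2H)."""

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.fw = _LSTMCell(c_in, hidden, rng)
        self.bw = _LSTMCell(c_in, hidden, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, C = x.shape
        fwd = self.fw.run(x, range(L))
        bwd = self.bw.run(x, range(L - 1, -1, -1))
        bwd = bwd[::-1]
        steps = [
            ad.concatenate([f, b], axis=1) for f, b in zip(fwd, bwd)
        ]  # each (B, 2H)
        stacked = ad.concatenate(
            [ad.reshape(s, (B, 1, 2 * self.hidden)) for s in steps], axis=1
        )
        return stacked


class _LSTMCell(Module):
    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.W = _glorot(rng, c_in + hidden, 4 * hidden, (c_in + hidden, 4 * hidden))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def run(self, x: Tensor, order) -> list[Tensor]:
        B = x.shape[0]
        H = self.hidden
        h = ad.Tensor(np.zeros((B, H)))
        c = ad.Tensor(np.zeros((B, H)))
        outs = []
        for t in order:
            xt = x[:, t, :]
            z = ad.matmul(ad.concatenate([xt, h], axis=1), self.W) + self.b
            i = ad.sigmoid(z[:, 0:H])
            f = ad.sigmoid(z[:, H : 2 * H])
            g = ad.tanh(z[:, 2 * H : 3 * H])
            o = ad.sigmoid(z[:, 3 * H : 4 * H])
            c = f * c + i * g
            h = o * ad.tanh(c)
            outs.append(h)
        return outs


class AttentionPool(Module):
    """Softmax attention pooling over the length axis: (B, L, C) -> (B, C)."""

    def __init__(self, c_in: int, rng: np.random.Generator):
        self.score = Dense(c_in, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, C = x.shape
        scores = ad.reshape(self.score(ad.reshape(x, (B * L, C))), (B, L, 1))
        w = ad.softmax(scores, axis=1)
        return ad.tsum(x * w, axis=1)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class Adam:
    """Adam with optional alternative betas (WGAN training uses 0.5/0.9)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
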