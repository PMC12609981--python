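"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical engine behind the network: a :class:`Tensor` wraps an
ndarray and records the operations applied to it; :meth:`Tensor.backward`
runs the chain rule through the recorded graph.  Beyond generic elementwise
and matrix ops it provides three purpose-built primitives whose gradients
are derived by hand and verified against finite differences in the test
suite:

* :func:`unfold1d` — im2col for same-length 1-D convolution,
* :func:`lstm_layer` — a single LSTM direction with the classic
  backpropagation-through-time recursion,
* :func:`periodogram` — one-sided power spectrum |rfft|^2 / T, whose adjoint
  is an inverse rfft with the DC and Nyquist bins doubled.

Everything runs in float64, single process: results are deterministic for
fixed inputs and weights.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concat", "softmax", "unfold1d", "lstm_layer", "periodogram", "AdamW"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad = self.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _make(data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = tensor(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), back)

    __radd__ = __add__

    def __mul__(self, other):
        other = tensor(other)

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), back)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __truediv__(self, other):
        return self * tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return tensor(other) * self**-1.0

    def __pow__(self, p: float):
        d = self.data

        def back(g):
            if self.requires_grad:
                self._accum(g * p * d ** (p - 1.0))

        return Tensor._make(d**p, (self,), back)

    def sqrt(self):
        return self**0.5

    def exp(self):
        out_data = np.exp(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), back)

    def tanh(self):
        out_data = np.tanh(self.data)

        def back(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), back)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def back(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), back)

    def relu(self):
        mask = self.data > 0

        def back(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), back)

    # -- reductions and reshaping -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.shape

        def back(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), back)

    def swapaxes(self, a: int, b: int):
        def back(g):
            if self.requires_grad:
                self._accum(g.swapaxes(a, b))

        return Tensor._make(self.data.swapaxes(a, b), (self,), back)

    def __getitem__(self, idx):
        def back(g):
            if self.requires_grad:
                full = np.zeros(self.shape, dtype=np.float64)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(self.data[idx], (self,), back)

    # -- linear algebra ----------------------------------------------------
    def __matmul__(self, other):
        other = tensor(other)

        def back(g):
            if self.requires_grad:
                ga = g @ other.data.swapaxes(-1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = self.data.swapaxes(-1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._make(self.data @ other.data, (self, other), back)


def tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(parts: list[Tensor], axis: int = -1) -> Tensor:
    parts = [tensor(p) for p in parts]
    sizes = [p.data.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for p, piece in zip(parts, np.split(g, splits, axis=axis)):
            if p.requires_grad:
                p._accum(piece)

    return Tensor._make(np.concatenate([p.data for p in parts], axis=axis), tuple(parts), back)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        if x.requires_grad:
            x._accum((g - (g * y).sum(axis=axis, keepdims=True)) * y)

    return Tensor._make(y, (x,), back)


def unfold1d(x: Tensor, kernel: int) -> Tensor:
    """im2col along time: (B, T, C) -> (B, T, kernel*C), zero 'same' padding.

    A matmul of the result with a (kernel*C, C_out) weight is a stride-1
    1-D convolution without subsampling.
    """
    x = tensor(x)
    B, T, C = x.shape
    p = kernel // 2
    xp = np.pad(x.data, ((0, 0), (p, p), (0, 0)))
    cols = np.concatenate([xp[:, k : k + T, :] for k in range(kernel)], axis=2)

    def back(g):
        if not x.requires_grad:
            return
        gp = np.zeros_like(xp)
        for k in range(kernel):
            gp[:, k : k + T, :] += g[:, :, k * C : (k + 1) * C]
        x._accum(gp[:, p : p + T, :])

    return Tensor._make(cols, (x,), back)


def _sigmoid(a: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-a))


def lstm_layer(x: Tensor, wx: Tensor, wh: Tensor, b: Tensor, reverse: bool = False) -> Tensor:
    """One LSTM direction over (B, T, D) -> (B, T, H), zero initial state.

    Gate layout along the 4H axis is [input, forget, cell, output].  The
    backward pass is the standard backpropagation-through-time recursion
    over the cached per-step activations.
    """
    x, wx, wh, b = tensor(x), tensor(wx), tensor(wh), tensor(b)
    B, T, D = x.shape
    H = wh.shape[0]
    X = x.data
    xw = (X.reshape(B * T, D) @ wx.data).reshape(B, T, 4 * H) + b.data

    hs = np.empty((B, T, H))
    cache = []
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    order = range(T - 1, -1, -1) if reverse else range(T)
    Whd = wh.data
    for t in order:
        z = xw[:, t, :] + h @ Whd
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g_ = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g_
        tc = np.tanh(c_new)
        cache.append((t, h, c, i, f, g_, o, tc))
        h = o * tc
        c = c_new
        hs[:, t, :] = h

    def back(gout):
        dxw = np.zeros((B, T, 4 * H))
        dwh = np.zeros_like(Whd)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t, h_prev, c_prev, i, f, g_, o, tc in reversed(cache):
            dh = gout[:, t, :] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc**2)
            di = dc * g_
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g_**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dxw[:, t, :] = dz
            dwh += h_prev.T @ dz
            dh_next = dz @ Whd.T
            dc_next = dc * f
        if b.requires_grad:
            b._accum(dxw.sum(axis=(0, 1)))
        flat = dxw.reshape(B * T, 4 * H)
        if wx.requires_grad:
            wx._accum(X.reshape(B * T, D).T @ flat)
        if x.requires_grad:
            x._accum((flat @ wx.data.T).reshape(B, T, D))
        if wh.requires_grad:
            wh._accum(dwh)

    return Tensor._make(hs, (x, wx, wh, b), back)


def periodogram(y: Tensor) -> Tensor:
    """One-sided periodogram |rfft(y)|^2 / T along the last axis.

    For a length-T real signal the output has T//2 + 1 bins.  The adjoint
    maps a gradient on the bins back through the DFT: an inverse rfft of the
    gradient-weighted spectrum with DC and Nyquist doubled (those bins have
    no conjugate twin).
    """
    y = tensor(y)
    T = y.shape[-1]
    F = np.fft.rfft(y.data, axis=-1)
    P = (F.real**2 + F.imag**2) / T

    def back(g):
        if not y.requires_grad:
            return
        h = g * F
        h[..., 0] *= 2.0
        if T % 2 == 0:
            h[..., -1] *= 2.0
        # dL/dy = (1/T) * T * irfft(h) with the doubling above; the factors cancel
        y._accum(np.fft.irfft(h, n=T, axis=-1))

    return Tensor._make(P, (y,), back)


class AdamW:
    """Adam with decoupled weight decay, matching the standard formulation.

    ``clip_norm`` (if set) rescales the global gradient norm before the
    update — the usual stabilizer for recurrent networks.
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-2,
        clip_norm: float | None = None,
    ):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.weight_decay = float(weight_decay)
        self.clip_norm = clip_norm
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(float(np.sum(p.grad**2)) for p in self.params if p.grad is not None)
            )
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            p.data = p.data - self.lr * self.weight_decay * p.data
            self._m[k] = self.b1 * self._m[k] + (1.0 - self.b1) * g
            self._v[k] = self.b2 * self._v[k] + (1.0 - self.b2) * g * g
            mhat = self._m[k] / (1.0 - self.b1**self.t)
            vhat = self._v[k] / (1.0 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
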