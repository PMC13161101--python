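"""Reverse-mode automatic differentiation on NumPy arrays.

A small define-by-run tape: every operation returns a new :class:`Tensor`
holding a closure that propagates gradients to its inputs.  Only the
operations the network layers need are provided — dense/grouped/dilated 2-D
convolution, batched matrix multiplication, adaptive pooling, reductions,
elementwise nonlinearities, shape manipulation, and a fused softmax
cross-entropy.  All arithmetic is float32.

A process-global multiply-accumulate (MAC) counter can be armed with
:func:`mac_counting`; while armed, ``conv2d``, ``matmul`` and ``linear``
record the MACs they execute, which is how model FLOP accounting is done.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Iterable, Sequence

import numpy as np

_DTYPE = np.float32

# -- MAC counting -----------------------------------------------------------

_mac_state = {"active": False, "count": 0}


@contextmanager
def mac_counting():
    """Context manager that counts multiply-accumulates of conv/matmul ops."""
    prev_active, prev_count = _mac_state["active"], _mac_state["count"]
    _mac_state["active"], _mac_state["count"] = True, 0
    try:
        yield _mac_state
    finally:
        _mac_state["active"], _mac_state["count"] = prev_active, prev_count


def _record_macs(n: int) -> None:
    if _mac_state["active"]:
        _mac_state["count"] += int(n)


def _pair(v) -> tuple[int, int]:
    if isinstance(v, (tuple, list)):
        return int(v[0]), int(v[1])
    return int(v), int(v)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- bookkeeping --------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        # first writer keeps a reference (gradients are never mutated in
        # place afterwards: later writers allocate a fresh sum)
        if self.grad is None:
            self.grad = np.asarray(g, dtype=_DTYPE)
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=_DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._backward is not None:
                # single-use graph: free closure buffers and intermediate
                # gradients as soon as they are consumed (peak-memory bound)
                node._backward = None
                node._prev = ()
                node.grad = None

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic ---------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.shape))
            out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(
                        _unbroadcast(-g * self.data / (other.data ** 2), other.shape)
                    )
            out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        out = _make(self.data ** p, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def exp(self):
        out = _make(np.exp(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        out = _make(np.sqrt(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * 0.5 / out.data)
        return out

    def relu(self):
        out = _make(np.maximum(self.data, 0.0), (self,))
        if out.requires_grad:
            mask = self.data > 0
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def clamp(self, lo: float, hi: float):
        out = _make(np.clip(self.data, lo, hi), (self,))
        if out.requires_grad:
            mask = (self.data > lo) & (self.data < hi)
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self):
        s = np.where(self.data >= 0,
                     1.0 / (1.0 + np.exp(-np.abs(self.data))),
                     np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))))
        out = _make(s.astype(_DTYPE), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * out.data * (1.0 - out.data))
        return out

    def tanh(self):
        out = _make(np.tanh(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * (1.0 - out.data ** 2))
        return out

    def hardsigmoid(self):
        out = _make(np.clip(self.data / 6.0 + 0.5, 0.0, 1.0).astype(_DTYPE), (self,))
        if out.requires_grad:
            def _bw(g):
                mask = (self.data > -3.0) & (self.data < 3.0)
                self._accumulate(g * (mask / 6.0))
            out._backward = _bw
        return out

    def hardswish(self):
        out = _make((self.data * np.clip(self.data / 6.0 + 0.5, 0.0, 1.0)).astype(_DTYPE),
                    (self,))
        if out.requires_grad:
            def _bw(g):
                # derivative: 0 below -3, 1 above 3, x/3 + 1/2 in between
                d = np.where(self.data >= 3.0, 1.0,
                             np.where(self.data <= -3.0, 0.0, self.data / 3.0 + 0.5))
                self._accumulate(g * d.astype(_DTYPE))
            out._backward = _bw
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def _bw(g):
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.shape))
                    return
                gg = g
                if not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    axes = tuple(a % self.ndim for a in axes)
                    for a in sorted(axes):
                        gg = np.expand_dims(gg, a)
                self._accumulate(np.broadcast_to(gg, self.shape))
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis: int = -1):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- shape manipulation -------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def permute(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        out = _make(self.data.transpose(axes), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out.requires_grad:
            def _bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)
            out._backward = _bw
        return out

    # -- linear algebra ------------------------------------------------------

    def matmul(self, other: "Tensor"):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = np.matmul(self.data, other.data)
        _record_macs(out_data.size * self.shape[-1])
        out = _make(out_data, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                    self._accumulate(_unbroadcast(ga, self.shape))
                if other.requires_grad:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                    other._accumulate(_unbroadcast(gb, other.shape))
            out._backward = _bw
        return out

    __matmul__ = matmul


def _make(data: np.ndarray, prev: Iterable[Tensor]) -> Tensor:
    prev = tuple(prev)
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in prev)
    if out.requires_grad:
        out._prev = prev
    return out


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = _bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = t if isinstance(t, Tensor) else Tensor(t)
        shape = list(t.shape)
        shape.insert(axis % (t.ndim + 1), 1)
        expanded.append(t.reshape(*shape))
    return concatenate(expanded, axis=axis)


# -- convolution -------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, padding=0,
           dilation=1, groups: int = 1) -> Tensor:
    """Grouped, strided, dilated 2-D cross-correlation (NCHW layout)."""
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    Cout, cin_g, KH, KW = wd.shape
    g = int(groups)
    if C != cin_g * g:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {cin_g * g}")
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    dh, dw = _pair(dilation)
    eKH, eKW = (KH - 1) * dh + 1, (KW - 1) * dw + 1
    OH = (H + 2 * ph - eKH) // sh + 1
    OW = (W + 2 * pw - eKW) // sw + 1
    if OH < 1 or OW < 1:
        raise ValueError("conv2d: kernel larger than padded input")

    xp = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else xd
    L = OH * OW
    _record_macs(N * Cout * cin_g * KH * KW * L)

    def tap(i: int, j: int):
        return (slice(None), slice(None),
                slice(i * dh, i * dh + sh * OH, sh),
                slice(j * dw, j * dw + sw * OW, sw))

    if cin_g == 1 and g == C and Cout == C:
        # depthwise path: accumulate over kernel taps, no column matrix
        wr = wd.reshape(C, KH, KW)
        out_data = np.zeros((N, C, OH, OW), dtype=_DTYPE)
        for i in range(KH):
            for j in range(KW):
                out_data += wr[None, :, i, j, None, None] * xp[tap(i, j)]
        cols = None
    else:
        if KH == KW == 1 and sh == sw == 1 and not (ph or pw):
            cols = xd.reshape(N, g, cin_g, L)
        else:
            cols6 = np.empty((N, C, KH, KW, OH, OW), dtype=_DTYPE)
            for i in range(KH):
                for j in range(KW):
                    cols6[:, :, i, j] = xp[tap(i, j)]
            cols = cols6.reshape(N, g, cin_g * KH * KW, L)
        wg = wd.reshape(g, Cout // g, cin_g * KH * KW)
        out_data = np.matmul(wg, cols).reshape(N, Cout, OH, OW)
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)

    prev = (x, w) if b is None else (x, w, b)
    out = _make(out_data, prev)
    if out.requires_grad:
        def _bw(grad):
            if b is not None and b.requires_grad:
                b._accumulate(grad.sum(axis=(0, 2, 3)))
            if cols is None:   # depthwise
                wr = wd.reshape(C, KH, KW)
                if w.requires_grad:
                    dw_ = np.empty((C, KH, KW), dtype=_DTYPE)
                    for i in range(KH):
                        for j in range(KW):
                            dw_[:, i, j] = np.einsum("nchw,nchw->c", grad,
                                                     xp[tap(i, j)], optimize=True)
                    w._accumulate(dw_.reshape(wd.shape))
                if x.requires_grad:
                    dxp = np.zeros((N, C, H + 2 * ph, W + 2 * pw), dtype=_DTYPE)
                    for i in range(KH):
                        for j in range(KW):
                            dxp[tap(i, j)] += wr[None, :, i, j, None, None] * grad
                    x._accumulate(dxp[:, :, ph:ph + H, pw:pw + W])
                return
            go = grad.reshape(N, g, Cout // g, L)
            wg = wd.reshape(g, Cout // g, cin_g * KH * KW)
            if w.requires_grad:
                dw_ = np.matmul(go, cols.transpose(0, 1, 3, 2)).sum(axis=0)
                w._accumulate(dw_.reshape(wd.shape))
            if x.requires_grad:
                dcols = np.matmul(wg.transpose(0, 2, 1), go)
                dcols = dcols.reshape(N, C, KH, KW, OH, OW)
                dxp = np.zeros((N, C, H + 2 * ph, W + 2 * pw), dtype=_DTYPE)
                for i in range(KH):
                    for j in range(KW):
                        dxp[tap(i, j)] += dcols[:, :, i, j]
                x._accumulate(dxp[:, :, ph:ph + H, pw:pw + W])
        out._backward = _bw
    return out


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x @ w.T + b, with x of shape (..., in) and w of shape (out, in)."""
    out = x.matmul(w.permute(1, 0) if isinstance(w, Tensor) else Tensor(w).permute(1, 0))
    if b is not None:
        out = out + b
    return out


# -- pooling -----------------------------------------------------------------

def _bin_edges(n_in: int, n_out: int) -> list[tuple[int, int]]:
    return [((i * n_in) // n_out, -(-((i + 1) * n_in) // n_out)) for i in range(n_out)]


def adaptive_avg_pool2d(x: Tensor, output_size) -> Tensor:
    oh, ow = _pair(output_size)
    N, C, H, W = x.shape
    hb, wb = _bin_edges(H, oh), _bin_edges(W, ow)
    out_data = np.empty((N, C, oh, ow), dtype=_DTYPE)
    for i, (hs, he) in enumerate(hb):
        for j, (ws, we) in enumerate(wb):
            out_data[:, :, i, j] = x.data[:, :, hs:he, ws:we].mean(axis=(2, 3))
    out = _make(out_data, (x,))
    if out.requires_grad:
        def _bw(g):
            dx = np.zeros_like(x.data)
            for i, (hs, he) in enumerate(hb):
                for j, (ws, we) in enumerate(wb):
                    area = (he - hs) * (we - ws)
                    dx[:, :, hs:he, ws:we] += g[:, :, i:i + 1, j:j + 1] / area
            x._accumulate(dx)
        out._backward = _bw
    return out


def adaptive_max_pool2d(x: Tensor, output_size) -> Tensor:
    oh, ow = _pair(output_size)
    N, C, H, W = x.shape
    hb, wb = _bin_edges(H, oh), _bin_edges(W, ow)
    out_data = np.empty((N, C, oh, ow), dtype=_DTYPE)
    argmaxes = {}
    for i, (hs, he) in enumerate(hb):
        for j, (ws, we) in enumerate(wb):
            region = x.data[:, :, hs:he, ws:we].reshape(N, C, -1)
            idx = region.argmax(axis=2)
            out_data[:, :, i, j] = np.take_along_axis(region, idx[:, :, None], axis=2)[:, :, 0]
            argmaxes[(i, j)] = idx
    out = _make(out_data, (x,))
    if out.requires_grad:
        def _bw(g):
            dx = np.zeros_like(x.data)
            nn_, cc = np.meshgrid(np.arange(N), np.arange(C), indexing="ij")
            for i, (hs, he) in enumerate(hb):
                for j, (ws, we) in enumerate(wb):
                    bw_ = we - ws
                    idx = argmaxes[(i, j)]
                    rows, cols_ = idx // bw_, idx % bw_
                    np.add.at(dx, (nn_, cc, hs + rows, ws + cols_), g[:, :, i, j])
            x._accumulate(dx)
        out._backward = _bw
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """Spatial mean of an NCHW tensor, returned as (N, C)."""
    return x.mean(axis=(2, 3))


# -- loss --------------------------------------------------------------------

def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy over a batch of integer class targets."""
    targets = np.asarray(targets, dtype=np.int64)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    nll = -np.log(np.clip(p[np.arange(n), targets], 1e-12, None))
    out = _make(np.asarray(nll.mean(), dtype=_DTYPE), (logits,))
    if out.requires_grad:
        def _bw(g):
            dp = p.copy()
            dp[np.arange(n), targets] -= 1.0
            logits._accumulate(dp * (g / n))
        out._backward = _bw
    return out


def focal_loss(logits: Tensor, targets: np.ndarray, gamma: float = 2.0) -> Tensor:
    """Mean focal loss, (1-p_t)^gamma * -log p_t, via autodiff composition."""
    targets = np.asarray(targets, dtype=np.int64)
    n = logits.shape[0]
    p = logits.softmax(axis=1)
    pt = p[np.arange(n), targets]
    loss = -((1.0 - pt) ** gamma) * pt.clamp(1e-12, 1.0).log()
    return loss.mean()
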