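"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` runs reverse-mode accumulation over the recorded
graph.  Only the operations the segmentation network needs are provided —
elementwise arithmetic, (batched) matmul, 2D convolution via im2col, average
pooling, bilinear upsampling, reductions, gather and concatenation.  Dtype is
whatever the input arrays carry (float32 in the network, float64 in gradient
checks); no implicit casts are performed beyond NumPy's own promotion rules.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "avg_pool2d",
    "upsample_bilinear",
    "log_softmax",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(
            requires_grad or any(p.requires_grad for p in _parents)
        )
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- autograd driver -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without grad needs a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            if grad.dtype == self.data.dtype and grad.flags.owndata:
                self.grad = grad
            else:
                self.grad = grad.astype(self.data.dtype)
        else:
            self.grad = self.grad + grad

    # -- elementwise arithmetic ----------------------------------------------
    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        if isinstance(other, (int, float)):
            # keep python scalars at this tensor's dtype (no float64 upcast)
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(np.asarray(other))

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))
        out._backward = lambda g: self._accum(
            g * exponent * self.data ** (exponent - 1)
        )
        return out

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _parents=(self,))
        out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor(r, _parents=(self,))
        out._backward = lambda g: self._accum(g * 0.5 / r)
        return out

    # -- reductions & reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out

    def take_rows(self, index: np.ndarray):
        """Gather rows of a 2D tensor; backward scatter-adds."""
        index = np.asarray(index)
        out = Tensor(self.data[index], _parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, index, g)
            self._accum(full)

        out._backward = bw
        return out

    # -- matmul ----------------------------------------------------------------
    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def _conv_geometry(size: int, k: int, stride: int, pad: int, dil: int) -> int:
    eff = dil * (k - 1) + 1
    return (size + 2 * pad - eff) // stride + 1


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dil: int):
    """xp: padded input (N, C, Hp, Wp) -> cols (N, C*kh*kw, OH*OW)."""
    n, c, hp, wp = xp.shape
    oh = _conv_geometry(hp, kh, stride, 0, dil)
    ow = _conv_geometry(wp, kw, stride, 0, dil)
    s0, s1, s2, s3 = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, kh, kw, oh, ow),
        strides=(s0, s1, s2 * dil, s3 * dil, s2 * stride, s3 * stride),
        writeable=False,
    )
    return windows.reshape(n, c * kh * kw, oh * ow), oh, ow


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
) -> Tensor:
    """2D cross-correlation, NCHW layout, weights (O, C, kh, kw)."""
    n, c, h, wdt = x.shape
    o, cw, kh, kw = w.shape
    if cw != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cw}")
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    cols, oh, ow = _im2col(xp, kh, kw, stride, dilation)
    w2 = w.data.reshape(o, -1)
    out_data = (w2 @ cols).reshape(n, o, oh, ow)
    if b is not None:
        out_data = out_data + b.data.reshape(1, o, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _parents=parents)

    def bw(g):
        g2 = g.reshape(n, o, oh * ow)
        if w.requires_grad:
            dw = np.tensordot(g2, cols, axes=([0, 2], [0, 2]))
            w._accum(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accum(
                _conv2d_input_grad(
                    g, w.data, (h, wdt), stride, padding, dilation
                )
            )

    out._backward = bw
    return out


def _conv2d_input_grad(g, wdata, in_hw, stride, padding, dilation):
    """Gradient of conv2d w.r.t. its input, computed as a transposed conv."""
    n, o, oh, ow = g.shape
    _, c, kh, kw = wdata.shape[0], wdata.shape[1], wdata.shape[2], wdata.shape[3]
    h, wdt = in_hw
    # residual pixels lost to floor division in the forward geometry
    eff_h, eff_w = dilation * (kh - 1) + 1, dilation * (kw - 1) + 1
    rh = (h + 2 * padding - eff_h) - (oh - 1) * stride
    rw = (wdt + 2 * padding - eff_w) - (ow - 1) * stride
    if stride > 1:
        up = np.zeros((n, o, (oh - 1) * stride + 1, (ow - 1) * stride + 1), g.dtype)
        up[:, :, ::stride, ::stride] = g
        g = up
    ph, pw = dilation * (kh - 1), dilation * (kw - 1)
    g = np.pad(g, ((0, 0), (0, 0), (ph, ph + rh), (pw, pw + rw)))
    w_flip = wdata[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C, O, kh, kw)
    cols, gh, gw = _im2col(g, kh, kw, 1, dilation)
    dx_full = (w_flip.reshape(c, -1) @ cols).reshape(n, c, gh, gw)
    if padding:
        dx_full = dx_full[:, :, padding : padding + h, padding : padding + wdt]
    return dx_full


def avg_pool2d(x: Tensor, factor: int) -> Tensor:
    n, c, h, w = x.shape
    if h % factor or w % factor:
        raise ValueError(f"avg_pool2d: {h}x{w} not divisible by {factor}")
    oh, ow = h // factor, w // factor
    resh = x.data.reshape(n, c, oh, factor, ow, factor)
    out = Tensor(resh.mean(axis=(3, 5)), _parents=(x,))

    def bw(g):
        gg = np.broadcast_to(
            g[:, :, :, None, :, None], (n, c, oh, factor, ow, factor)
        ) / (factor * factor)
        x._accum(gg.reshape(n, c, h, w))

    out._backward = bw
    return out


def _bilinear_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Interpolation matrix A (n_out x n_in), half-pixel centers, edge clamped."""
    a = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    a[np.arange(n_out), lo] += 1.0 - frac
    a[np.arange(n_out), hi] += frac
    return a


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    n, c, h, w = x.shape
    ah = _bilinear_matrix(h, out_h, x.data.dtype)
    aw = _bilinear_matrix(w, out_w, x.data.dtype)
    tmp = x.data @ aw.T  # (N, C, H, out_w)
    out_data = np.einsum("oh,nchw->ncow", ah, tmp, optimize=True)
    out = Tensor(out_data, _parents=(x,))

    def bw(g):
        t = np.einsum("oh,ncow->nchw", ah, g, optimize=True)
        x._accum(t @ aw)

    out._backward = bw
    return out


def reflect_pad2d(x: Tensor, pad: int) -> Tensor:
    """Mirror-pad the two trailing (spatial) axes by ``pad`` pixels."""
    if pad == 0:
        return x
    h, w = x.shape[2], x.shape[3]
    ridx = np.pad(np.arange(h), pad, mode="reflect")
    cidx = np.pad(np.arange(w), pad, mode="reflect")
    return x[:, :, ridx][:, :, :, cidx]


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    shift = x.data - np.max(x.data, axis=axis, keepdims=True)
    e = np.exp(shift)
    z = e.sum(axis=axis, keepdims=True)
    out = Tensor(shift - np.log(z), _parents=(x,))
    s = e / z

    def bw(g):
        x._accum(g - s * g.sum(axis=axis, keepdims=True))

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    e = np.exp(x.data - np.max(x.data, axis=axis, keepdims=True))
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, _parents=(x,))

    def bw(g):
        x._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

    out._backward = bw
    return out
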