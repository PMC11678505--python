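"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

Supports exactly the operations needed by the 3D convolutional autoencoders,
the diffusion U-Net and the differentiable (MS-)SSIM loss: broadcasting
arithmetic, matmul, 3D convolution (stride 1/2 with zero padding), nearest
upsampling, average pooling, SiLU, and reductions.  Gradients are accumulated
by a topological backward pass over the recorded tape.

Floating dtypes are preserved (the networks train in float32 for speed, the
algebraic tests run in float64); convolution is implemented as an im2col matmul
whose backward pass is itself a convolution with the spatially flipped,
channel-transposed kernel (no scatter-adds), which keeps training usable on a
single CPU core.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv3d",
    "avg_pool3d",
    "upsample3d",
    "pixel_shuffle3d",
    "pixel_unshuffle3d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")
    __array_priority__ = 100  # so ndarray.__op__(Tensor) defers to us

    def __init__(self, data, requires_grad: bool = False, parents=()):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        # parents: sequence of (Tensor, grad_fn) with grad_fn(out_grad)->parent grad
        self._parents = tuple(parents)

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- tape -----------------------------------------------------------------

    @staticmethod
    def _make(data, parents) -> "Tensor":
        parents = [(p, fn) for p, fn in parents if p.requires_grad or p._parents]
        return Tensor(data, requires_grad=bool(parents), parents=parents)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS (graphs can be deep)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p, _ in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            for p, fn in node._parents:
                pg = fn(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = Tensor.as_tensor(other)
        return Tensor._make(
            self.data + other.data,
            [
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self.data, other.data
        return Tensor._make(
            a * b,
            [
                (self, lambda g: _unbroadcast(g * b, a.shape)),
                (other, lambda g: _unbroadcast(g * a, b.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self.data, other.data
        out = a / b
        return Tensor._make(
            out,
            [
                (self, lambda g: _unbroadcast(g / b, a.shape)),
                (other, lambda g: _unbroadcast(-g * out / b, b.shape)),
            ],
        )

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent: float):
        a = self.data
        out = a**exponent
        return Tensor._make(
            out, [(self, lambda g: g * exponent * a ** (exponent - 1))]
        )

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self.data, other.data
        return Tensor._make(
            a @ b,
            [
                (self, lambda g: g @ b.swapaxes(-1, -2)),
                (other, lambda g: a.swapaxes(-1, -2) @ g),
            ],
        )

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, [(self, lambda g: g * out)])

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, [(self, lambda g: g * 0.5 / out)])

    def silu(self):
        # overflow-safe sigmoid
        e = np.exp(-np.abs(self.data))
        s = np.where(self.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
        out = self.data * s
        return Tensor._make(out, [(self, lambda g: g * (s * (1.0 + self.data * (1.0 - s))))])

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, [(self, lambda g: g * mask)])

    def clamp_min(self, lo: float):
        mask = self.data >= lo
        return Tensor._make(np.maximum(self.data, lo), [(self, lambda g: g * mask)])

    # -- reductions & shaping --------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            if not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, self.data.shape).copy()

        return Tensor._make(out, [(self, grad_fn)])

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(*shape), [(self, lambda g: g.reshape(old))]
        )

    def abs(self):
        sign = np.sign(self.data)
        return Tensor._make(np.abs(self.data), [(self, lambda g: g * sign)])


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out = np.concatenate([t.data for t in tensors], axis=axis)

    def make_fn(i):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor._make(out, [(t, make_fn(i)) for i, t in enumerate(tensors)])


# ---------------------------------------------------------------------------
# 3D convolution and resampling (N, C, D, H, W)


def _out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def _pad_channels_last(x: np.ndarray, pad: int) -> np.ndarray:
    """(N,C,D,H,W) -> contiguous channels-last (N,D,H,W,C), zero padded."""
    xp = np.moveaxis(x, 1, -1)
    if pad:
        return np.pad(xp, ((0, 0), (pad, pad), (pad, pad), (pad, pad), (0, 0)))
    return np.ascontiguousarray(xp)


def _shifts(xp: np.ndarray, k: int, stride: int, out_spatial):
    """Yield (dz, dy, dx, window) with window (N, od, oh, ow, C)."""
    od, oh, ow = out_spatial
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                yield dz, dy, dx, xp[
                    :,
                    dz : dz + (od - 1) * stride + 1 : stride,
                    dy : dy + (oh - 1) * stride + 1 : stride,
                    dx : dx + (ow - 1) * stride + 1 : stride,
                    :,
                ]


def _conv3d_np(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """Forward convolution (cross-correlation) with zero padding.

    Implemented as k^3 shifted GEMMs over a channels-last copy, which keeps
    the inner loops in BLAS instead of strided reshapes.
    """
    n, c, d, h, wd = x.shape
    oc, ic, k, _, _ = w.shape
    assert ic == c, (ic, c)
    xp = _pad_channels_last(x, pad)
    out_spatial = tuple(_out_size(s, k, stride, pad) for s in (d, h, wd))
    od, oh, ow = out_spatial
    out2 = np.zeros((n * od * oh * ow, oc), dtype=x.dtype)
    for dz, dy, dx, win in _shifts(xp, k, stride, out_spatial):
        out2 += win.reshape(-1, c) @ w[:, :, dz, dy, dx].T
    return np.moveaxis(out2.reshape(n, od, oh, ow, oc), -1, 1)


def _dilate(g: np.ndarray, stride: int) -> np.ndarray:
    if stride == 1:
        return g
    n, c, d, h, w = g.shape
    out = np.zeros(
        (n, c, (d - 1) * stride + 1, (h - 1) * stride + 1, (w - 1) * stride + 1),
        dtype=g.dtype,
    )
    out[:, :, ::stride, ::stride, ::stride] = g
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           pad: int | None = None) -> Tensor:
    """3D convolution on (N, C, D, H, W); default 'same' padding for stride 1."""
    x = Tensor.as_tensor(x)
    w = Tensor.as_tensor(w)
    k = w.data.shape[2]
    if pad is None:
        pad = k // 2
    xd, wd = x.data, w.data

    # forward (keeping the padded channels-last copy for the weight gradient)
    n, c, d, h, wdim = xd.shape
    oc = wd.shape[0]
    xp = _pad_channels_last(xd, pad)
    out_spatial = tuple(_out_size(s, k, stride, pad) for s in (d, h, wdim))
    od, oh, ow = out_spatial
    out2 = np.zeros((n * od * oh * ow, oc), dtype=xd.dtype)
    for dz, dy, dx, win in _shifts(xp, k, stride, out_spatial):
        out2 += win.reshape(-1, c) @ wd[:, :, dz, dy, dx].T
    out = np.moveaxis(out2.reshape(n, od, oh, ow, oc), -1, 1)

    def grad_x(g):
        # full correlation of the (dilated) output grad with the flipped kernel
        gd = _dilate(g, stride)
        w_flip = wd[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        full = _conv3d_np(gd, w_flip, 1, k - 1)
        # crop the original zero padding; pad short edges (stride remainder)
        target = xd.shape[2:]
        full = full[:, :, pad:, pad:, pad:]
        pads = [(0, t - min(s, t)) for s, t in zip(full.shape[2:], target)]
        if any(p[1] for p in pads):
            full = np.pad(full, [(0, 0), (0, 0)] + pads)
        return full[:, :, : target[0], : target[1], : target[2]]

    def grad_w(g):
        g2 = np.ascontiguousarray(np.moveaxis(g, 1, -1)).reshape(-1, g.shape[1])
        gw = np.empty_like(wd)
        for dz, dy, dx, win in _shifts(xp, k, stride, out_spatial):
            gw[:, :, dz, dy, dx] = g2.T @ win.reshape(-1, c)
        return gw

    parents = [(x, grad_x), (w, grad_w)]
    out_t = Tensor._make(out, parents)
    if b is not None:
        out_t = out_t + b.reshape(1, -1, 1, 1, 1)
    return out_t


def avg_pool3d(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping average pooling; trailing remainder voxels are cropped."""
    x = Tensor.as_tensor(x)
    n, c, d, h, w = x.data.shape
    f = factor
    dc, hc, wc = d - d % f, h - h % f, w - w % f
    xc = x.data[:, :, :dc, :hc, :wc]
    out = xc.reshape(n, c, dc // f, f, hc // f, f, wc // f, f).mean(axis=(3, 5, 7))

    def grad_fn(g):
        g = np.repeat(np.repeat(np.repeat(g, f, 2), f, 3), f, 4) / f**3
        if (dc, hc, wc) != (d, h, w):
            g = np.pad(g, ((0, 0), (0, 0), (0, d - dc), (0, h - hc), (0, w - wc)))
        return g

    return Tensor._make(out, [(x, grad_fn)])


def pixel_shuffle3d(x: Tensor, factor: int = 2) -> Tensor:
    """Rearrange (N, C*f^3, D, H, W) -> (N, C, fD, fH, fW) (sub-voxel channels)."""
    x = Tensor.as_tensor(x)
    n, cf, d, h, w = x.data.shape
    f = factor
    c = cf // (f**3)
    if c * f**3 != cf:
        raise ValueError(f"channels {cf} not divisible by {f}^3")
    perm = (0, 1, 5, 2, 6, 3, 7, 4)  # (n,c,d,f,h,f,w,f)
    out = (
        x.data.reshape(n, c, f, f, f, d, h, w)
        .transpose(perm)
        .reshape(n, c, d * f, h * f, w * f)
    )
    inv = np.argsort(perm)

    def grad_fn(g):
        return (
            g.reshape(n, c, d, f, h, f, w, f)
            .transpose(inv)
            .reshape(n, cf, d, h, w)
        )

    return Tensor._make(out, [(x, grad_fn)])


def pixel_unshuffle3d(x: Tensor, factor: int = 2) -> Tensor:
    """Inverse of :func:`pixel_shuffle3d`: (N, C, fD, fH, fW) -> (N, C*f^3, D, H, W).

    A lossless, parameter-free downsampling that moves spatial detail into
    channels.
    """
    x = Tensor.as_tensor(x)
    n, c, df, hf, wf = x.data.shape
    f = factor
    if df % f or hf % f or wf % f:
        raise ValueError("spatial dims must be divisible by the factor")
    d, h, w = df // f, hf // f, wf // f
    perm = (0, 1, 3, 5, 7, 2, 4, 6)  # (n,c,f,f,f,d,h,w)
    out = (
        x.data.reshape(n, c, d, f, h, f, w, f)
        .transpose(perm)
        .reshape(n, c * f**3, d, h, w)
    )
    inv = np.argsort(perm)

    def grad_fn(g):
        return (
            g.reshape(n, c, f, f, f, d, h, w)
            .transpose(inv)
            .reshape(n, c, df, hf, wf)
        )

    return Tensor._make(out, [(x, grad_fn)])


def upsample3d(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour upsampling by an integer factor."""
    x = Tensor.as_tensor(x)
    f = factor
    out = np.repeat(np.repeat(np.repeat(x.data, f, 2), f, 3), f, 4)
    n, c, d, h, w = x.data.shape

    def grad_fn(g):
        return g.reshape(n, c, d, f, h, f, w, f).sum(axis=(3, 5, 7))

    return Tensor._make(out, [(x, grad_fn)])
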