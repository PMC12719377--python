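"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` plus an optional gradient.  Operations
build a dynamic graph; :meth:`Tensor.backward` walks it in reverse
topological order.  Only the ops needed by the segmentation networks are
provided (2-D convolutions, 2x2 pooling/up-convolution, instance/batch
normalisation, the activations, channel softmax, concatenation, broadcasting
add/mul and bilinear resampling).  Arrays keep whatever float dtype they are
given, so gradient checks can run in float64 while training runs in float32.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; nested U-Net++ graphs recurse deeply
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        return add(self, other)

    def __mul__(self, other: "Tensor") -> "Tensor":
        return mul(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, _parents=tuple(parents), _backward=backward if req else None)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = list(tensors)
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return _make(out_data, ts, backward)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def channel_slice(x: Tensor, start: int, stop: int) -> Tensor:
    """Slice channels ``start:stop`` of a ``(B, C, H, W)`` tensor."""
    out_data = x.data[:, start:stop]

    def backward(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            dx[:, start:stop] = g
            x._accumulate(dx)

    return _make(out_data, (x,), backward)


def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * (x.data > 0))

    return _make(out_data, (x,), backward)


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    out_data = np.where(x.data > 0, x.data, slope * x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * np.where(x.data > 0, 1.0, slope).astype(x.dtype))

    return _make(out_data, (x,), backward)


def prelu(x: Tensor, a: Tensor) -> Tensor:
    """Parametric ReLU with a single learned negative slope ``a`` (scalar)."""
    slope = a.data.reshape(())
    out_data = np.where(x.data > 0, x.data, slope * x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * np.where(x.data > 0, 1.0, slope).astype(x.dtype))
        if a.requires_grad:
            a._accumulate(np.sum(g * np.minimum(x.data, 0)).reshape(a.shape))

    return _make(out_data, (x, a), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (x,), backward)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 1 of a ``(B, C, H, W)`` tensor."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = np.sum(g * out_data, axis=1, keepdims=True)
            x._accumulate(out_data * (g - dot))

    return _make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# convolutions and pooling
# ---------------------------------------------------------------------------

def _conv2d_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """'Same'-padded stride-1 cross-correlation; returns output plus the
    im2col matrix (reused for the weight gradient)."""
    B, C, H, W = x.shape
    cout, cin, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    if ph or pw:
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    else:
        xp = x
    view = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # B,C,H,W,kh,kw
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * kh * kw)
    out = cols @ w.reshape(cout, cin * kh * kw).T
    return out.reshape(B, H, W, cout).transpose(0, 3, 1, 2), cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1, same-padded 2-D convolution (odd square kernels)."""
    cout, cin, kh, kw = w.shape
    if kh != kw or kh % 2 == 0:
        raise ValueError(f"kernel must be odd and square, got {kh}x{kw}")
    out_data, cols = _conv2d_raw(x.data, w.data)
    if b is not None:
        out_data += b.data.reshape(1, cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        B, _, H, W = g.shape
        gmat = g.transpose(0, 2, 3, 1).reshape(B * H * W, cout)
        if w.requires_grad:
            w._accumulate((gmat.T @ cols).reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            # full correlation with the flipped, channel-transposed kernel
            w_flip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            dx, _ = _conv2d_raw(g, np.ascontiguousarray(w_flip))
            x._accumulate(dx)

    return _make(out_data, parents, backward)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution with a 2x2 kernel and stride 2 (doubles H, W).

    ``w`` has shape ``(cin, cout, 2, 2)``.
    """
    B, cin, H, W = x.shape
    cin_w, cout = w.shape[:2]
    if cin_w != cin:
        raise ValueError(f"weight expects {cin_w} input channels, got {cin}")
    out_data = np.empty((B, cout, 2 * H, 2 * W), dtype=x.dtype)
    xt = x.data.transpose(0, 2, 3, 1)  # B,H,W,cin
    for i in (0, 1):
        for j in (0, 1):
            out_data[:, :, i::2, j::2] = (xt @ w.data[:, :, i, j]).transpose(0, 3, 1, 2)
    if b is not None:
        out_data += b.data.reshape(1, cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or w.requires_grad:
            dx = np.zeros_like(x.data) if x.requires_grad else None
            dw = np.empty_like(w.data) if w.requires_grad else None
            for i in (0, 1):
                for j in (0, 1):
                    gij = g[:, :, i::2, j::2].transpose(0, 2, 3, 1)  # B,H,W,cout
                    if dx is not None:
                        dx += (gij @ w.data[:, :, i, j].T).transpose(0, 3, 1, 2)
                    if dw is not None:
                        dw[:, :, i, j] = np.tensordot(xt, gij, axes=([0, 1, 2], [0, 1, 2]))
            if dx is not None:
                x._accumulate(dx)
            if dw is not None:
                w._accumulate(dw)

    return _make(out_data, parents, backward)


def max_pool2x2(x: Tensor) -> Tensor:
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"spatial size must be even for 2x2 pooling, got {(H, W)}")
    xr = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xw = xr.reshape(B, C, H // 2, W // 2, 4)
    idx = xw.argmax(axis=-1)
    out_data = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            gw = np.zeros_like(xw)
            np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
            dx = gw.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(x.shape)
            x._accumulate(dx)

    return _make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalisation over (H, W); no affine terms."""
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (x.data - mu) * inv

    def backward(g):
        if x.requires_grad:
            gm = g.mean(axis=(2, 3), keepdims=True)
            gy = (g * y).mean(axis=(2, 3), keepdims=True)
            x._accumulate(inv * (g - gm - y * gy))

    return _make(y, (x,), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running: dict,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (B, H, W) with affine parameters.

    ``running`` holds ``mean``/``var`` arrays updated in place while training.
    """
    gshape = (1, -1, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3), keepdims=True)
        var = x.data.var(axis=(0, 2, 3), keepdims=True)
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mu.ravel()
        running["var"] = (1 - momentum) * running["var"] + momentum * var.ravel()
    else:
        mu = running["mean"].reshape(gshape)
        var = running["var"].reshape(gshape)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate(np.sum(g * xhat, axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(np.sum(g, axis=(0, 2, 3)))
        if x.requires_grad:
            gx = g * gamma.data.reshape(gshape)
            if training:
                gm = gx.mean(axis=(0, 2, 3), keepdims=True)
                gy = (gx * xhat).mean(axis=(0, 2, 3), keepdims=True)
                x._accumulate(inv * (gx - gm - xhat * gy))
            else:
                x._accumulate(inv * gx)

    return _make(out_data, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _linear_resize_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Row-stochastic matrix mapping ``n_in`` samples to ``n_out`` by linear
    interpolation with endpoint alignment."""
    R = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        R[:, 0] = 1.0
        return R
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    R[np.arange(n_out), lo] += 1.0 - frac
    R[np.arange(n_out), hi] += frac
    return R


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resampling of a ``(B, C, H, W)`` tensor to ``out_hw``."""
    B, C, H, W = x.shape
    Ho, Wo = out_hw
    if (Ho, Wo) == (H, W):
        return x
    Rh = _linear_resize_matrix(Ho, H, x.dtype)
    Rw = _linear_resize_matrix(Wo, W, x.dtype)
    out_data = np.einsum("oh,bchw,pw->bcop", Rh, x.data, Rw, optimize=True)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.einsum("oh,bcop,pw->bchw", Rh, g, Rw, optimize=True))

    return _make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# padding / cropping (for inputs not divisible by the pooling factor)
# ---------------------------------------------------------------------------

def reflect_pad2d(x: Tensor, pad: tuple[int, int, int, int]) -> Tensor:
    """Reflect-pad ``(top, bottom, left, right)`` on the spatial axes."""
    t, b_, l, r = pad
    if not any(pad):
        return x
    out_data = np.pad(x.data, ((0, 0), (0, 0), (t, b_), (l, r)), mode="reflect")
    H, W = x.shape[2:]

    def backward(g):
        if x.requires_grad:
            # adjoint of reflection: fold the padded borders back inside
            dx = np.zeros_like(x.data)
            ii = np.pad(np.arange(H), (t, b_), mode="reflect")
            jj = np.pad(np.arange(W), (l, r), mode="reflect")
            np.add.at(dx, (slice(None), slice(None), ii[:, None], jj[None, :]), g)
            x._accumulate(dx)

    return _make(out_data, (x,), backward)


def crop2d(x: Tensor, h: int, w: int) -> Tensor:
    """Crop the top-left ``h x w`` window of the spatial axes."""
    if x.shape[2] == h and x.shape[3] == w:
        return x
    out_data = x.data[:, :, :h, :w]

    def backward(g):
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            dx[:, :, :h, :w] = g
            x._accumulate(dx)

    return _make(out_data, (x,), backward)
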