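"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to express and train the forecasting network: a
:class:`Tensor` wrapping an ndarray, elementwise arithmetic with numpy
broadcasting, matmul, a handful of nonlinearities and reductions, 2-D
"same" convolution (odd kernels, stride 1), dilated causal 1-D convolution,
and 2-D max pooling.  Gradients flow through a tape built implicitly by the
operations; :meth:`Tensor.backward` walks it in reverse topological order.

Every op's backward pass is exercised against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "set_default_dtype",
    "get_default_dtype",
    "relu",
    "sigmoid",
    "matmul",
    "conv2d_same",
    "causal_conv1d",
    "maxpool2d",
    "concat",
    "mean_all",
    "sum_axes",
    "mean_axes",
    "sqrt",
    "square",
    "reshape",
    "transpose",
    "dropout",
]


# float32 keeps training memory-bandwidth-bound steps fast; switch to
# float64 for high-precision work (e.g. finite-difference gradient checks)
_DEFAULT_DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global _DEFAULT_DTYPE
    if np.dtype(dtype) not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    _DEFAULT_DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return _DEFAULT_DTYPE


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_borrowed")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DEFAULT_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self._grad_borrowed = False

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        # store a borrowed reference on first use; materialize a private
        # buffer only if a second gradient arrives (avoids most copies)
        if self.grad is None:
            self.grad = grad
            self._grad_borrowed = True
        elif self._grad_borrowed:
            self.grad = self.grad + grad
            self._grad_borrowed = False
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (defaults to d(out)/d(out) = 1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None
        self._grad_borrowed = False

    # -- arithmetic -----------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        a, b = self, Tensor._coerce(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._coerce(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._coerce(other)

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / b.data**2, b.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product."""

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return Tensor._make(a.data @ b.data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    # exp may overflow for wildly diverged inputs; the limit (0 or 1) is
    # exactly what the saturated gate should return
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    return Tensor._make(s, (x,), backward)


def sqrt(x: Tensor) -> Tensor:
    r = np.sqrt(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * 0.5 / r)

    return Tensor._make(r, (x,), backward)


def square(x: Tensor) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x._accumulate(g * 2.0 * x.data)

    return Tensor._make(x.data**2, (x,), backward)


def sum_axes(x: Tensor, axes: tuple[int, ...], keepdims: bool = True) -> Tensor:
    def backward(g):
        if x.requires_grad:
            gg = g if keepdims else np.expand_dims(g, axes)
            x._accumulate(np.broadcast_to(gg, x.shape))

    return Tensor._make(x.data.sum(axis=axes, keepdims=keepdims), (x,), backward)


def mean_axes(x: Tensor, axes: tuple[int, ...], keepdims: bool = True) -> Tensor:
    count = np.prod([x.shape[a] for a in axes])
    return sum_axes(x, axes, keepdims) * (1.0 / count)


def mean_all(x: Tensor) -> Tensor:
    n = x.data.size

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.full(x.shape, float(g) / n))

    return Tensor._make(x.data.mean(), (x,), backward)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(x.shape))

    return Tensor._make(x.data.reshape(shape), (x,), backward)


def transpose(x: Tensor, axes: tuple[int, ...]) -> Tensor:
    inv = np.argsort(axes)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.transpose(inv))

    return Tensor._make(x.data.transpose(axes), (x,), backward)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, s, e in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(s, e)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in training mode."""
    if rate <= 0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep) / keep

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


# -- convolutions and pooling ------------------------------------------


def conv2d_same(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2-D cross-correlation with 'same' zero padding, stride 1.

    ``x``: (B, C, H, W); ``w``: (F, C, KH, KW) with odd KH, KW;
    ``b``: (F,).  Output: (B, F, H, W).
    """
    B, C, H, W = x.shape
    F, C2, KH, KW = w.shape
    if C != C2 or KH % 2 == 0 or KW % 2 == 0:
        raise ValueError("conv2d_same needs matching channels and odd kernels")
    ph, pw = KH // 2, KW // 2

    def corr(inp, ker):
        # inp (B,C,H,W) zero-padded; ker (F,C,KH,KW) -> (B,F,H,W)
        Bi, Ci, Hi, Wi = inp.shape
        pad = np.zeros((Bi, Ci, Hi + KH - 1, Wi + KW - 1), dtype=inp.dtype)
        pad[:, :, ph : ph + Hi, pw : pw + Wi] = inp
        s0, s1, s2, s3 = pad.strides
        view = np.lib.stride_tricks.as_strided(
            pad,
            shape=(Bi, Ci, Hi, Wi, KH, KW),
            strides=(s0, s1, s2, s3, s2, s3),
            writeable=False,
        )
        cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(Bi * Hi * Wi, Ci * KH * KW)
        out = cols @ ker.reshape(ker.shape[0], -1).T
        return out.reshape(Bi, Hi, Wi, ker.shape[0]).transpose(0, 3, 1, 2), cols

    out, cols = corr(x.data, w.data)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def backward(g):
        if w.requires_grad:
            gm = g.transpose(0, 2, 3, 1).reshape(B * H * W, F)
            w._accumulate((gm.T @ cols).reshape(w.shape))
        if x.requires_grad:
            # grad wrt input = 'same' correlation of g with spatially
            # flipped kernels, channels swapped (valid for odd kernels)
            wf = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gx, _ = corr(g, wf)
            x._accumulate(gx)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def causal_conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Dilated causal 1-D convolution, output length = input length.

    ``x``: (B, C, T); ``w``: (F, C, K); tap ``k`` reads ``x[t - (K-1-k)*d]``
    so the last tap is the current sample and output[t] never sees the
    future.  The left context is zero-padded.
    """
    B, C, T = x.shape
    F, C2, K = w.shape
    if C != C2:
        raise ValueError("causal_conv1d channel mismatch")
    d = int(dilation)
    P = (K - 1) * d
    xpad = np.zeros((B, C, T + P), dtype=x.data.dtype)
    xpad[:, :, P:] = x.data

    out = np.zeros((B, F, T), dtype=x.data.dtype)
    for k in range(K):
        seg = xpad[:, :, k * d : k * d + T]  # x[t - (K-1-k)d]
        out += np.einsum("bct,fc->bft", seg, w.data[:, :, k], optimize=True)
    if b is not None:
        out = out + b.data[None, :, None]

    def backward(g):
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for k in range(K):
                seg = xpad[:, :, k * d : k * d + T]
                gw[:, :, k] = np.einsum("bft,bct->fc", g, seg, optimize=True)
            w._accumulate(gw)
        if x.requires_grad:
            gpad = np.zeros_like(xpad)
            for k in range(K):
                gpad[:, :, k * d : k * d + T] += np.einsum(
                    "bft,fc->bct", g, w.data[:, :, k], optimize=True
                )
            x._accumulate(gpad[:, :, P:])
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def maxpool2d(x: Tensor, pool: tuple[int, int] = (2, 2)) -> Tensor:
    """Max pooling with window = stride = ``pool``; trailing remainder rows/
    columns are dropped (floor semantics)."""
    ph, pw = pool
    B, C, H, W = x.shape
    H2, W2 = H // ph, W // pw
    xr = x.data[:, :, : H2 * ph, : W2 * pw].reshape(B, C, H2, ph, W2, pw)
    xw = xr.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H2, W2, ph * pw)
    idx = xw.argmax(axis=-1)
    out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gw = np.zeros((B, C, H2, W2, ph * pw), dtype=g.dtype)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gx = np.zeros_like(x.data)
        gx[:, :, : H2 * ph, : W2 * pw] = (
            gw.reshape(B, C, H2, W2, ph, pw)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, H2 * ph, W2 * pw)
        )
        x._accumulate(gx)

    return Tensor._make(out, (x,), backward)
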