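"""Reverse-mode automatic differentiation over numpy arrays.

This is the package's tensor engine: a tape-based autodiff core with the
dense, convolutional and pooling operations the segmentation networks need.
Convolutions are lowered to im2col + BLAS matmul; everything is float32.
Gradients are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    # defer to Tensor's reflected operators when numpy arrays sit on the left
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None
        self.name = name

    # ------------------------------------------------------------------ infra

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            if g.dtype != np.float32 or not g.flags.writeable:
                g = g.astype(np.float32)
            self.grad = g
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        # iterative topological sort (graphs can be deep)
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:  # free intermediate grads; leaves keep theirs
                node.grad = None

    # ------------------------------------------------------------- arithmetic

    def __add__(self, other):
        return _binop(self, other, np.add, _add_bw)

    __radd__ = __add__

    def __mul__(self, other):
        return _binop(self, other, np.multiply, _mul_bw)

    __rmul__ = __mul__

    def __sub__(self, other):
        return _binop(self, other, np.subtract, _sub_bw)

    def __rsub__(self, other):
        return _binop(_wrap(other), self, np.subtract, _sub_bw)

    def __truediv__(self, other):
        return _binop(self, other, np.divide, _div_bw)

    def __rtruediv__(self, other):
        return _binop(_wrap(other), self, np.divide, _div_bw)

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, c):
        c = float(c)
        out = _node(self.data ** c, (self,))
        if out.requires_grad:
            def bw(g, x=self, c=c):
                if float(c - 1.0).is_integer():
                    base = x.data ** (c - 1.0)
                else:  # fractional exponent: clamp to keep the base positive
                    base = np.maximum(x.data, 1e-12) ** (c - 1.0)
                x._accumulate(g * c * base)
            out._backward = bw
        return out

    def exp(self):
        out = _node(np.exp(self.data), (self,))
        if out.requires_grad:
            def bw(g, x=self, od=out.data):
                x._accumulate(g * od)
            out._backward = bw
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        if out.requires_grad:
            def bw(g, x=self):
                x._accumulate(g / x.data)
            out._backward = bw
        return out

    def sqrt(self):
        out = _node(np.sqrt(self.data), (self,))
        if out.requires_grad:
            def bw(g, x=self, od=out.data):
                x._accumulate(g * 0.5 / np.maximum(od, 1e-12))
            out._backward = bw
        return out

    def relu(self):
        out = _node(np.maximum(self.data, 0.0), (self,))
        if out.requires_grad:
            mask = self.data > 0

            def bw(g, x=self, mask=mask):
                x._accumulate(g * mask)
            out._backward = bw
        return out

    def sigmoid(self):
        out = _node(1.0 / (1.0 + np.exp(-self.data)), (self,))
        if out.requires_grad:
            def bw(g, x=self, od=out.data):
                x._accumulate(g * od * (1.0 - od))
            out._backward = bw
        return out

    # ---------------------------------------------------------------- shaping

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        if out.requires_grad:
            def bw(g, x=self):
                x._accumulate(g.reshape(x.shape))
            out._backward = bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        out = _node(np.ascontiguousarray(self.data.transpose(axes)), (self,))
        if out.requires_grad:
            def bw(g, x=self, inv=inv):
                x._accumulate(g.transpose(inv))
            out._backward = bw
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))
        if out.requires_grad:
            def bw(g, x=self, idx=idx):
                dx = np.zeros_like(x.data)
                dx[idx] = g
                x._accumulate(dx)
            out._backward = bw
        return out

    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def bw(g, x=self, axis=axis, keepdims=keepdims):
                gg = np.asarray(g)
                if axis is not None and not keepdims:
                    ax = axis if isinstance(axis, tuple) else (axis,)
                    for a in sorted(a % x.ndim for a in ax):
                        gg = np.expand_dims(gg, a)
                x._accumulate(np.broadcast_to(gg, x.shape).astype(np.float32))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else np.prod(
            [self.shape[a % self.ndim] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
    return out


def _binop(a, b, fwd, make_bw):
    a, b = _wrap(a), _wrap(b)
    out = _node(fwd(a.data, b.data), (a, b))
    if out.requires_grad:
        out._backward = make_bw(a, b, out)
    return out


def _add_bw(a, b, out):
    def bw(g):
        ga = _unbroadcast(g, a.shape) if a.requires_grad else None
        gb = _unbroadcast(g, b.shape) if b.requires_grad else None
        if ga is g and gb is g:
            gb = g.copy()  # both parents must not alias the same buffer
        if ga is not None:
            a._accumulate(ga)
        if gb is not None:
            b._accumulate(gb)
    return bw


def _sub_bw(a, b, out):
    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.shape))
    return bw


def _mul_bw(a, b, out):
    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))
    return bw


def _div_bw(a, b, out):
    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))
    return bw


# ---------------------------------------------------------------- free functions


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = _node(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        def bw(g):
            pieces = np.split(g, len(tensors), axis=axis)
            for t, piece in zip(tensors, pieces):
                if t.requires_grad:
                    t._accumulate(np.squeeze(piece, axis=axis))
        out._backward = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = _node(a.data @ b.data, (a, b))
    if out.requires_grad:
        def bw(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)
        out._backward = bw
    return out


def softmax(x: Tensor, axis: int) -> Tensor:
    """Numerically stable softmax; the shift is a constant w.r.t. gradients."""
    x = _wrap(x)
    m = x.data.max(axis=axis, keepdims=True)
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


# ------------------------------------------------------------- conv / pooling
#
# Feature maps are channels-last (N, H, W, C): im2col/col2im then move
# contiguous channel runs, which keeps the gather/scatter phases memory-
# bandwidth-friendly on a single core.


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """x: (n, h, w, c) -> cols (n*ho*wo, kh*kw*c)."""
    n, h, w, c = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    ho = (x.shape[1] - kh) // stride + 1
    wo = (x.shape[2] - kw) // stride + 1
    v = sliding_window_view(x, (kh, kw), axis=(1, 2))[:, ::stride, ::stride]
    # (n, ho, wo, c, kh, kw) -> (n, ho, wo, kh, kw, c): innermost axis contiguous
    cols = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * ho * wo, kh * kw * c
    )
    return cols, ho, wo


def _col2im(dcols: np.ndarray, xshape, kh, kw, stride, pad, ho, wo):
    n, h, w, c = xshape
    dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=np.float32)
    d = dcols.reshape(n, ho, wo, kh, kw, c)
    for a in range(kh):
        for b in range(kw):
            dxp[:, a : a + ho * stride : stride, b : b + wo * stride : stride, :] += d[
                :, :, :, a, b, :
            ]
    if pad:
        return dxp[:, pad : h + pad, pad : w + pad, :]
    return dxp


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation, channels-last. x: (n,h,w,c); w: (kh,kw,c/g,co)."""
    x, w = _wrap(x), _wrap(w)
    xd, wd = x.data, w.data
    n, h, ww_, c = xd.shape
    kh, kw, cg, co = wd.shape
    if c % groups or co % groups or cg != c // groups:
        raise ValueError(
            f"conv2d channel/group mismatch: C_in={c}, C_out={co}, groups={groups}"
        )
    cog = co // groups
    cols_per_group, outs = [], []
    ho = wo = None
    for gi in range(groups):
        xg = xd[..., gi * cg : (gi + 1) * cg] if groups > 1 else xd
        cols, ho, wo = _im2col(xg, kh, kw, stride, padding)
        wmat = np.ascontiguousarray(wd[..., gi * cog : (gi + 1) * cog]).reshape(
            kh * kw * cg, cog
        ) if groups > 1 else wd.reshape(kh * kw * cg, co)
        outs.append(cols @ wmat)  # (n*ho*wo, cog)
        cols_per_group.append(cols)
    od = np.concatenate(outs, axis=1) if groups > 1 else outs[0]
    od = od.reshape(n, ho, wo, co)
    if b is not None:
        od += b.data
    parents = (x, w) if b is None else (x, w, b)
    out = _node(od, parents)
    if out.requires_grad:
        def bw(g):
            gmat = g.reshape(n * ho * wo, co)
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 1, 2)))
            dw = np.empty_like(wd) if w.requires_grad else None
            dx = np.empty_like(xd) if x.requires_grad else None
            for gi in range(groups):
                gm = gmat[:, gi * cog : (gi + 1) * cog]
                wmat = (
                    np.ascontiguousarray(wd[..., gi * cog : (gi + 1) * cog]).reshape(
                        kh * kw * cg, cog
                    )
                    if groups > 1
                    else wd.reshape(kh * kw * cg, co)
                )
                if w.requires_grad:
                    dw[..., gi * cog : (gi + 1) * cog] = (
                        cols_per_group[gi].T @ gm
                    ).reshape(kh, kw, cg, cog)
                if x.requires_grad:
                    dcols = gm @ wmat.T
                    dx[..., gi * cg : (gi + 1) * cg] = _col2im(
                        dcols, (n, h, ww_, cg), kh, kw, stride, padding, ho, wo
                    )
            if w.requires_grad:
                w._accumulate(dw)
            if x.requires_grad:
                x._accumulate(dx)
        out._backward = bw
    return out


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-2 2x2 transposed convolution (exact 2x upsampling, no overlap).

    x: (n, h, w, ci); w: (ci, 2, 2, co).
    """
    x, w = _wrap(x), _wrap(w)
    xd, wd = x.data, w.data
    n, h, ww_, ci = xd.shape
    ci2 = wd.shape[0]
    co = wd.shape[3]
    if ci != ci2:
        raise ValueError(f"conv_transpose2x2 channel mismatch: {ci} vs {ci2}")
    xt = xd.reshape(n * h * ww_, ci)
    wm = wd.reshape(ci, 4 * co)
    od = (xt @ wm).reshape(n, h, ww_, 2, 2, co)
    od = np.ascontiguousarray(od.transpose(0, 1, 3, 2, 4, 5)).reshape(
        n, 2 * h, 2 * ww_, co
    )
    if b is not None:
        od += b.data
    parents = (x, w) if b is None else (x, w, b)
    out = _node(od, parents)
    if out.requires_grad:
        def bw(g):
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 1, 2)))
            gt = np.ascontiguousarray(
                g.reshape(n, h, 2, ww_, 2, co).transpose(0, 1, 3, 2, 4, 5)
            ).reshape(n * h * ww_, 4 * co)
            if w.requires_grad:
                w._accumulate((xt.T @ gt).reshape(ci, 2, 2, co))
            if x.requires_grad:
                x._accumulate((gt @ wm.T).reshape(n, h, ww_, ci))
        out._backward = bw
    return out


def maxpool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    """Max pooling, channels-last."""
    x = _wrap(x)
    xd = x.data
    n, h, w, c = xd.shape
    if padding:
        xp = np.pad(
            xd, ((0, 0), (padding, padding), (padding, padding), (0, 0)),
            constant_values=-np.inf,
        )
    else:
        xp = xd
    ho = (xp.shape[1] - kernel) // stride + 1
    wo = (xp.shape[2] - kernel) // stride + 1
    win = sliding_window_view(xp, (kernel, kernel), axis=(1, 2))[:, ::stride, ::stride]
    # (n, ho, wo, c, k, k) -> flatten the window
    flat = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n, ho, wo, kernel * kernel, c
    )
    arg = flat.argmax(axis=3)
    od = np.take_along_axis(flat, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    out = _node(np.ascontiguousarray(od), (x,))
    if out.requires_grad:
        def bw(g):
            dxp = np.zeros((n, xp.shape[1], xp.shape[2], c), dtype=np.float32)
            for idx in range(kernel * kernel):
                a, bb = divmod(idx, kernel)
                dxp[:, a : a + ho * stride : stride, bb : bb + wo * stride : stride, :] += (
                    g * (arg == idx)
                )
            if padding:
                x._accumulate(dxp[:, padding : h + padding, padding : w + padding, :])
            else:
                x._accumulate(dxp)
        out._backward = bw
    return out


# -------------------------------------------------------------------- modules


class Module:
    """Minimal layer container with recursive parameter/buffer discovery."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield (prefix + name, v)
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, v in vars(self).items():
            if isinstance(v, np.ndarray):
                yield (prefix + name, v)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        d = {("param:" + k): v.data.copy() for k, v in self.named_parameters()}
        d.update({("buffer:" + k): v.copy() for k, v in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict):
        params = dict(self.named_parameters())
        for key, value in d.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unknown parameter {name!r} in state dict")
                if params[name].data.shape != value.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: {params[name].data.shape} vs {value.shape}"
                    )
                params[name].data = value.astype(np.float32).copy()
            else:
                self._set_buffer(name, value)

    def _set_buffer(self, dotted: str, value: np.ndarray):
        parts = dotted.split(".")
        obj = self
        for part in parts[:-1]:
            obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
        setattr(obj, parts[-1], value.astype(np.float32).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _resolve(obj, dotted):
    for part in dotted.split("."):
        obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
    return obj


try:  # fused update kernel; pure-numpy fallback below
    from numba import njit

    @njit(fastmath=True, cache=False)
    def _adam_update(p, g, m, v, lr, b1, b2, bc1, bc2, eps):
        for i in range(p.size):
            mi = b1 * m[i] + (1.0 - b1) * g[i]
            vi = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
            m[i] = mi
            v[i] = vi
            p[i] -= lr * (mi / bc1) / (np.sqrt(vi / bc2) + eps)

except ImportError:  # pragma: no cover
    _adam_update = None


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if _adam_update is not None and p.data.flags.c_contiguous:
                _adam_update(
                    p.data.ravel(), np.ascontiguousarray(g).ravel(),
                    m.ravel(), v.ravel(),
                    np.float32(self.lr), np.float32(b1), np.float32(b2),
                    np.float32(bc1), np.float32(bc2), np.float32(self.eps),
                )
                continue
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def state_dict(self) -> dict:
        d = {"t": np.asarray(self.t), "lr": np.asarray(self.lr)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            d[f"m{i}"] = m
            d[f"v{i}"] = v
        return d

    def load_state_dict(self, d: dict):
        self.t = int(d["t"])
        self.lr = float(d["lr"])
        for i in range(len(self.params)):
            self.m[i] = d[f"m{i}"].copy()
            self.v[i] = d[f"v{i}"].copy()
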