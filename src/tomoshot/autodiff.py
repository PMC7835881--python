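"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the Siamese volume network needs: broadcasted
elementwise arithmetic, matrix multiplication, 3D convolution (im2col),
2x max-pooling, 2x trilinear upsampling, reductions and the usual pointwise
nonlinearities. Gradients are accumulated by topological traversal of the
recorded tape; every op is covered by finite-difference checks in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ---- construction helpers -------------------------------------------
    @staticmethod
    def _make(data, parents, backward, requires_grad):
        t = Tensor(data, requires_grad=requires_grad)
        if requires_grad:
            t._parents = parents
            t._backward = backward
        return t

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- elementwise arithmetic -----------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        req = self.requires_grad or other.requires_grad
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward, req)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,), self.requires_grad)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        req = self.requires_grad or other.requires_grad
        a, b = self.data, other.data

        def backward(g):
            return (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape))

        return Tensor._make(a * b, (self, other), backward, req)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        req = self.requires_grad or other.requires_grad
        a, b = self.data, other.data

        def backward(g):
            return (
                _unbroadcast(g / b, a.shape),
                _unbroadcast(-g * a / (b * b), b.shape),
            )

        return Tensor._make(a / b, (self, other), backward, req)

    # ---- shaping ---------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),),
            self.requires_grad,
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,),
            lambda g: (g.transpose(inv),), self.requires_grad,
        )

    def __getitem__(self, idx):
        src_shape = self.data.shape

        def backward(g):
            full = np.zeros(src_shape, dtype=g.dtype)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(self.data[idx], (self,), backward, self.requires_grad)

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        shape = self.data.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, shape).copy(),)

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward,
            self.requires_grad,
        )

    def mean(self, axis=None, keepdims=False):
        shape = self.data.shape
        if axis is None:
            n = self.data.size
        else:
            ax = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([shape[a] for a in ax]))

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g / n, shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2 / n, shape).copy(),)

        return Tensor._make(
            self.data.mean(axis=axis, keepdims=keepdims), (self,), backward,
            self.requires_grad,
        )

    # ---- pointwise nonlinearities ---------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._make(
            self.data * mask, (self,), lambda g: (g * mask,), self.requires_grad
        )

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return Tensor._make(
            out, (self,), lambda g: (g * out * (1.0 - out),), self.requires_grad
        )

    def logsigmoid(self):
        """log(sigmoid(x)), computed stably; gradient 1 - sigmoid(x)."""
        x = self.data
        out = np.where(x > 0, -np.log1p(np.exp(-x)), x - np.log1p(np.exp(x)))
        sig = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return Tensor._make(out, (self,), lambda g: (g * (1.0 - sig),),
                            self.requires_grad)

    def log(self):
        a = self.data
        return Tensor._make(np.log(a), (self,), lambda g: (g / a,), self.requires_grad)

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(
            out, (self,), lambda g: (g * 0.5 / out,), self.requires_grad
        )

    def abs(self):
        s = np.sign(self.data)
        return Tensor._make(
            np.abs(self.data), (self,), lambda g: (g * s,), self.requires_grad
        )

    def clip(self, lo, hi):
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._make(
            np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,),
            self.requires_grad,
        )

    # ---- linear algebra --------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        req = self.requires_grad or other.requires_grad
        a, b = self.data, other.data

        def backward(g):
            return (g @ b.T, a.T @ g)

        return Tensor._make(a @ b, (self, other), backward, req)

    __matmul__ = matmul

    # ---- spatial ops (B, C, H, W, D) -------------------------------------
    def conv3d(self, weight: "Tensor", bias: "Tensor | None" = None) -> "Tensor":
        """3D convolution, kernel 3x3x3 or 1x1x1, stride 1, 'same' padding.

        weight: (C_out, C_in, k, k, k); bias: (C_out,). The input gradient is
        itself a convolution with the channel-transposed, spatially flipped
        kernel, so both passes run as im2col matrix products.
        """
        x = self.data
        w = weight.data
        B, C, H, W, D = x.shape
        C_out, C_in, k, _, _ = w.shape
        if C_in != C:
            raise ValueError(f"channel mismatch: input {C}, weight expects {C_in}")
        cols = _im2col(x, k)  # (BHWD, C*k^3)
        w2 = w.reshape(C_out, C * k**3)
        out = cols @ w2.T  # (BHWD, C_out)
        if bias is not None:
            out = out + bias.data
        out = out.reshape(B, H, W, D, C_out).transpose(0, 4, 1, 2, 3)

        def backward(g):
            g2 = g.transpose(0, 2, 3, 4, 1).reshape(B * H * W * D, C_out)
            grad_w = (g2.T @ cols).reshape(w.shape)
            w_flip = np.ascontiguousarray(
                w.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
            ).reshape(C, C_out * k**3)
            g_cols = _im2col(np.ascontiguousarray(g), k)  # (BHWD, C_out*k^3)
            grad_x = (g_cols @ w_flip.T).reshape(B, H, W, D, C).transpose(
                0, 4, 1, 2, 3
            )
            grads = [grad_x, grad_w]
            if bias is not None:
                grads.append(g2.sum(axis=0))
            return tuple(grads)

        parents = (self, weight) if bias is None else (self, weight, bias)
        req = any(t.requires_grad for t in parents)
        return Tensor._make(out, parents, backward, req)

    def maxpool3d(self) -> "Tensor":
        """2x2x2 max pooling, stride 2. Spatial dims must be even."""
        x = self.data
        B, C, H, W, D = x.shape
        r = x.reshape(B, C, H // 2, 2, W // 2, 2, D // 2, 2)
        r = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(B, C, H // 2, W // 2, D // 2, 8)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            gr = np.zeros((B, C, H // 2, W // 2, D // 2, 8), dtype=g.dtype)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gr = gr.reshape(B, C, H // 2, W // 2, D // 2, 2, 2, 2)
            gr = gr.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(B, C, H, W, D)
            return (gr,)

        return Tensor._make(out, (self,), backward, self.requires_grad)

    def upsample3d(self) -> "Tensor":
        """2x trilinear upsampling (align_corners=False convention)."""
        x = self.data
        B, C, H, W, D = x.shape
        mats = [_upsample_matrix(n) for n in (H, W, D)]
        out = np.einsum("ah,bchwd->bcawd", mats[0], x)
        out = np.einsum("aw,bchwd->bchad", mats[1], out)
        out = np.einsum("ad,bchwd->bchwa", mats[2], out)

        def backward(g):
            gg = np.einsum("ah,bcawd->bchwd", mats[0], g)
            gg = np.einsum("aw,bchad->bchwd", mats[1], gg)
            gg = np.einsum("ad,bchwa->bchwd", mats[2], gg)
            return (gg,)

        return Tensor._make(out, (self,), backward, self.requires_grad)

    # ---- autodiff driver -------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(np.float32, copy=True)
                else:
                    parent.grad = parent.grad + g


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W, D) -> (B*H*W*D, C*k^3) patch matrix, 'same' padding."""
    B, C, H, W, D = x.shape
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    return win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(B * H * W * D, C * k**3)


_UPSAMPLE_CACHE: dict[int, np.ndarray] = {}


def _upsample_matrix(n: int) -> np.ndarray:
    """(2n x n) 1D linear-interpolation matrix for 2x upsampling."""
    m = _UPSAMPLE_CACHE.get(n)
    if m is not None:
        return m
    m = np.zeros((2 * n, n), dtype=np.float32)
    for i in range(2 * n):
        src = (i + 0.5) / 2.0 - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n - 1)
        hi_c = min(max(lo + 1, 0), n - 1)
        m[i, lo_c] += 1.0 - frac
        m[i, hi_c] += frac
    _UPSAMPLE_CACHE[n] = m
    return m


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    req = any(t.requires_grad for t in tensors)
    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), backward, req)
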