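"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine providing exactly the operations the unrolled
reconstruction network needs: same-padded 2D convolution (im2col / GEMM),
ReLU, elementwise addition, bias broadcast, the hard data-consistency
projection (treated as one linear node with a self-adjoint backward pass),
and a mean-squared-error loss.  Gradients are accumulated by topological
traversal of the recorded graph; correctness is pinned against central
finite differences in the test suite.

Arrays are float32 throughout; complex images are carried as 2 real
channels (real, imaginary).
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "conv2d", "relu", "add", "add_bias", "dc_project", "mse_loss",
    "concat0", "split0",
]


class Tensor:
    """A node in the computation graph wrapping a float32 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        bwd: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._bwd = bwd

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def _accum_slice(self, g: np.ndarray, lo: int, hi: int) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad[lo:hi] += g

    def backward(self) -> None:
        """Backpropagate from a scalar node through the recorded graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss node")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor) -> None:
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen or not n.requires_grad:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bwd is not None and node.grad is not None:
                node._bwd(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def __add__(self, other: "Tensor") -> "Tensor":
        return add(self, other)


_EINSUM_PATHS: dict = {}


def _es(subscripts: str, *ops: np.ndarray) -> np.ndarray:
    """einsum with a memoized contraction path (keyed by shapes)."""
    key = (subscripts, tuple(o.shape for o in ops))
    path = _EINSUM_PATHS.get(key)
    if path is None:
        path = np.einsum_path(subscripts, *ops, optimize="optimal")[0]
        _EINSUM_PATHS[key] = path
    return np.einsum(subscripts, *ops, optimize=path)


def _patches(x: np.ndarray, k: int) -> np.ndarray:
    """Same-padding sliding windows: (B, C, H, W) -> (B, C, H, W, k, k)."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    return sliding_window_view(xp, (k, k), axis=(2, 3))


def _conv_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Plain same-padded correlation: x (B,Cin,H,W), w (Cout,Cin,k,k)."""
    k = w.shape[-1]
    v = _patches(x, k)  # (B, Cin, H, W, k, k)
    return _es("bchwij,ocij->bohw", v, w)


def conv2d(x: Tensor, w: Tensor) -> Tensor:
    """Same-padded 2D convolution (cross-correlation) on the last two axes."""
    k = w.data.shape[-1]
    if k % 2 != 1:
        raise ValueError("kernel size must be odd for same padding")
    out_data = _conv_raw(x.data, w.data)
    out = Tensor(out_data, parents=(x, w))

    def bwd(g: np.ndarray) -> None:
        if w.requires_grad:
            # dW[o,c,i,j] = sum_{b,y,x} g[b,o,y,x] * patches[b,c,y,x,i,j]
            v = _patches(x.data, k)
            w._accum(_es("bohw,bchwij->ocij", g, v))
        if x.requires_grad:
            # dx = correlation of g with spatially flipped, channel-swapped w
            wt = w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
            x._accum(_conv_raw(g, wt))

    out._bwd = bwd
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError("add requires equal shapes")
    out = Tensor(a.data + b.data, parents=(a, b))

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accum(g)
        if b.requires_grad:
            b._accum(g)

    out._bwd = bwd
    return out


def add_bias(x: Tensor, b: Tensor) -> Tensor:
    """Broadcast a per-channel bias (C,) over (B, C, H, W)."""
    out = Tensor(x.data + b.data[None, :, None, None], parents=(x, b))

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(g)
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    out._bwd = bwd
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(g * mask)

    out._bwd = bwd
    return out


def dc_project(x: Tensor, y_k: np.ndarray, line_mask: np.ndarray) -> Tensor:
    """Hard data consistency on a 2-channel complex image (B, 2, H, W).

    Computes IFT(mask * y + (1 - mask) * FT(x)) with the centered orthonormal
    transform.  The map is real-linear and self-adjoint in the unsampled
    subspace, so the backward pass reapplies the (1 - mask) projection.
    """
    from .kspace import image_to_kspace, kspace_to_image

    def project(arr: np.ndarray, replace: np.ndarray | None) -> np.ndarray:
        z = arr[:, 0].astype(np.complex128) + 1j * arr[:, 1].astype(np.complex128)
        k = image_to_kspace(z)
        if replace is None:
            k[:, line_mask, :] = 0
        else:
            k[:, line_mask, :] = replace[None, line_mask, :] if replace.ndim == 2 else replace[:, line_mask, :]
        img = kspace_to_image(k)
        return np.stack([img.real, img.imag], axis=1).astype(np.float32)

    out = Tensor(project(x.data, y_k), parents=(x,))

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(project(g, None))

    out._bwd = bwd
    return out


def concat0(parts: list[Tensor]) -> Tensor:
    """Concatenate along axis 0 (used to stack frames into one batch)."""
    out = Tensor(np.concatenate([p.data for p in parts], axis=0), parents=tuple(parts))
    sizes = [p.data.shape[0] for p in parts]

    def bwd(g: np.ndarray) -> None:
        lo = 0
        for p, n in zip(parts, sizes):
            if p.requires_grad:
                p._accum(g[lo : lo + n])
            lo += n

    out._bwd = bwd
    return out


def split0(x: Tensor, n_parts: int) -> list[Tensor]:
    """Split axis 0 into equal parts; inverse of :func:`concat0`."""
    total = x.data.shape[0]
    if total % n_parts:
        raise ValueError("axis 0 not divisible by n_parts")
    step = total // n_parts
    outs = []
    for i in range(n_parts):
        lo = i * step

        def make_bwd(lo: int):
            def bwd(g: np.ndarray) -> None:
                if x.requires_grad:
                    x._accum_slice(g, lo, lo + step)

            return bwd

        outs.append(
            Tensor(x.data[lo : lo + step], parents=(x,), bwd=make_bwd(lo))
        )
    return outs


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target."""
    t = np.asarray(target, dtype=np.float32)
    diff = pred.data - t
    out = Tensor(np.array(np.mean(diff**2), dtype=np.float32), parents=(pred,))

    def bwd(g: np.ndarray) -> None:
        if pred.requires_grad:
            pred._accum((2.0 / diff.size) * diff * g)

    out._bwd = bwd
    return out
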