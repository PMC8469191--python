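"""Minimal reverse-mode autodiff kernel for 1D convolutional networks.

Implements exactly the operations the multi-atrous U-Net needs — dilated
same-padding 1D convolution, ReLU, window-2 max pooling, nearest-neighbour
x2 upsampling, channel concatenation and a mean-absolute-error loss — on
float32 NumPy arrays with shape ``(batch, channels, length)``, plus an Adam
optimizer.  Gradients flow through an explicit tape (topologically sorted
backward pass), so DAG topologies with shared skip tensors accumulate
gradients correctly.
"""

from __future__ import annotations

import numpy as np

#: Working precision of the engine.  float32 is the training default; tests
#: switch to float64 for finite-difference gradient verification.
DTYPE = np.float32


class Tensor:
    """A node in the computation tape: value, gradient, and backward rule."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; recursion would overflow on deep nets
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


def conv1d(x: Tensor, w: Tensor, b: Tensor, dilation: int = 1) -> Tensor:
    """Same-padding dilated 1D convolution.

    ``x``: (B, Cin, L); ``w``: (Cout, Cin, K); ``b``: (Cout,).  Output keeps
    length L; the effective kernel extent is ``(K-1)*dilation + 1``.
    """
    B, Cin, L = x.data.shape
    Cout, Cin_w, K = w.data.shape
    assert Cin == Cin_w, f"channel mismatch {Cin} vs {Cin_w}"
    eff = (K - 1) * dilation + 1
    if eff > L:
        raise ValueError(f"kernel extent {eff} exceeds input length {L}")
    pl = (eff - 1) // 2
    pr = eff - 1 - pl
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    y = np.empty((B, Cout, L), dtype=xp.dtype)
    np.einsum("oc,bcl->bol", w.data[:, :, 0], xp[:, :, :L], out=y, optimize=True)
    for j in range(1, K):
        y += np.einsum("oc,bcl->bol", w.data[:, :, j], xp[:, :, j * dilation : j * dilation + L],
                       optimize=True)
    y += b.data[None, :, None]

    def _backward(gy: np.ndarray) -> None:
        if b.requires_grad:
            b._accumulate(gy.sum(axis=(0, 2)))
        gxp = np.zeros_like(xp) if x.requires_grad else None
        for j in range(K):
            sl = slice(j * dilation, j * dilation + L)
            if w.requires_grad:
                gw_j = np.einsum("bol,bcl->oc", gy, xp[:, :, sl], optimize=True)
                if w.grad is None:
                    w.grad = np.zeros_like(w.data)
                w.grad[:, :, j] += gw_j
            if gxp is not None:
                gxp[:, :, sl] += np.einsum("oc,bol->bcl", w.data[:, :, j], gy, optimize=True)
        if gxp is not None:
            x._accumulate(gxp[:, :, pl : pl + L])

    return Tensor(y, parents=(x, w, b), backward=_backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    y = x.data * mask

    def _backward(gy):
        x._accumulate(gy * mask)

    return Tensor(y, parents=(x,), backward=_backward)


def maxpool2(x: Tensor) -> Tensor:
    """Window-2 stride-2 max pooling along the temporal axis (even length)."""
    B, C, L = x.data.shape
    assert L % 2 == 0, "maxpool2 needs an even temporal length"
    xr = x.data.reshape(B, C, L // 2, 2)
    arg = xr.argmax(axis=3)
    y = np.take_along_axis(xr, arg[..., None], axis=3)[..., 0]

    def _backward(gy):
        gx = np.zeros((B, C, L // 2, 2), dtype=x.data.dtype)
        np.put_along_axis(gx, arg[..., None], gy[..., None], axis=3)
        x._accumulate(gx.reshape(B, C, L))

    return Tensor(y, parents=(x,), backward=_backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling along the temporal axis."""
    y = np.repeat(x.data, 2, axis=2)
    B, C, L = x.data.shape

    def _backward(gy):
        x._accumulate(gy.reshape(B, C, L, 2).sum(axis=3))

    return Tensor(y, parents=(x,), backward=_backward)


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    y = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.data.shape[1] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward(gy):
        for t, a, b_ in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accumulate(gy[:, a:b_, :])

    return Tensor(y, parents=tuple(tensors), backward=_backward)


def mae_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean absolute error over every element of the batch."""
    target = np.asarray(target, dtype=pred.data.dtype)
    diff = pred.data - target
    y = np.abs(diff).mean()

    def _backward(gy):
        pred._accumulate(gy * np.sign(diff) / diff.size)

    return Tensor(y, parents=(pred,), backward=_backward)


class Conv1dLayer:
    """Conv weights + bias with He-scaled initialization."""

    def __init__(self, cin: int, cout: int, kernel_size: int, dilation: int,
                 rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * kernel_size))
        self.w = parameter(rng.normal(0.0, std, size=(cout, cin, kernel_size)))
        self.b = parameter(np.zeros(cout))
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, self.dilation)

    @property
    def parameters(self) -> list[Tensor]:
        return [self.w, self.b]

    @property
    def n_params(self) -> int:
        return self.w.data.size + self.b.data.size


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
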