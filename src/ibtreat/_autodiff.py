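"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the model needs (dense affine maps, ELU,
softmax-style compositions, Gaussian/Bernoulli log-likelihoods) on float64
arrays with numpy broadcasting. Gradients are accumulated by reverse
topological sweep from a scalar output.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "log_softmax", "softplus", "sigmoid", "elu"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # ---- graph plumbing -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- coercion -------------------------------------------------------

    @staticmethod
    def as_tensor(value) -> "Tensor":
        return value if isinstance(value, Tensor) else Tensor(value)

    # ---- arithmetic -----------------------------------------------------

    def __add__(self, other):
        other = Tensor.as_tensor(other)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad):
            if self.requires_grad:
                self._accumulate(-grad)

        return Tensor(-self.data, parents=(self,), backward=backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-grad * self.data / other.data**2, other.shape)
                )

        return Tensor(self.data / other.data, parents=(self, other), backward=backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent: float):
        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * exponent * self.data ** (exponent - 1))

        return Tensor(self.data**exponent, parents=(self,), backward=backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ grad)

        return Tensor(self.data @ other.data, parents=(self, other), backward=backward)

    # ---- elementwise nonlinearities -------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * out_data)

        return Tensor(out_data, parents=(self,), backward=backward)

    def log(self):
        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=backward)

    # ---- reductions and shaping -----------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(grad):
            if not self.requires_grad:
                return
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape))

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old_shape = self.shape

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad.reshape(old_shape))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=backward)

    def __getitem__(self, index):
        def backward(grad):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, index, grad)
            self._accumulate(full)

        return Tensor(self.data[index], parents=(self,), backward=backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * grad.ndim
                sl[axis if axis >= 0 else grad.ndim + axis] = slice(lo, hi)
                t._accumulate(grad[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=backward,
    )


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    pos = x.data > 0
    out_data = np.where(pos, x.data, alpha * np.expm1(x.data))

    def backward(grad):
        if x.requires_grad:
            x._accumulate(grad * np.where(pos, 1.0, out_data + alpha))

    return Tensor(out_data, parents=(x,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 0.5 * (1.0 + np.tanh(0.5 * x.data))  # stable logistic

    def backward(grad):
        if x.requires_grad:
            x._accumulate(grad * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(x,), backward=backward)


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), stable for large |x|; gradient is the logistic."""
    out_data = np.logaddexp(0.0, x.data)

    def backward(grad):
        if x.requires_grad:
            x._accumulate(grad * 0.5 * (1.0 + np.tanh(0.5 * x.data)))

    return Tensor(out_data, parents=(x,), backward=backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    # The max shift is constant w.r.t. the gradient (shift invariance).
    shift = np.max(x.data, axis=axis, keepdims=True)
    shifted = x - Tensor(shift)
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()
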