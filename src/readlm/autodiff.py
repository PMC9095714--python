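"""Minimal reverse-mode automatic differentiation and neural-network core.

A small tape-based autodiff engine over numpy ndarrays, with exactly the
operations the recurrent language model and classification heads require:
broadcast-aware arithmetic, matmul, sigmoid/tanh/relu, log-softmax, reductions,
max-pooling, concatenation and (advanced) indexing. On top of it sit the layers
used across the package — embedding lookup, LSTM layers, linear maps, 1-d batch
normalization, dropout — and an Adam optimizer with per-parameter-group
learning rates (needed for discriminative-rate fine-tuning).

Everything runs single-threaded on CPU in a configurable dtype (float32 by
default, for matmul throughput) and is deterministic given a seeded
``numpy.random.Generator``.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

#: global float dtype for all tensors; float32 favors CPU matmul throughput
DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None, name: str = ""):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward
        self.name = name

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, self.requires_grad or other.requires_grad, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, self.requires_grad or other.requires_grad, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = backward
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                buf = np.zeros_like(self.data)
                np.add.at(buf, idx, g)
                self._accumulate(buf)

        out._backward = backward
        return out

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g / self.data)
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * (1 - val**2))
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * val * (1 - val))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * mask)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * 0.5 / val)
        return out

    # -- reductions & shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims: bool = False):
        val = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor(val, self.requires_grad, (self,))

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            vk = val if keepdims else np.expand_dims(val, axis)
            gk = g if keepdims else np.expand_dims(g, axis)
            mask = self.data == vk
            # split gradient over ties so the total flow is conserved
            mask = mask / mask.sum(axis=axis, keepdims=True)
            self._accumulate(mask * gk)

        out._backward = backward
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g.reshape(self.shape))
        return out

    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        ls = shifted - lse
        out = Tensor(ls, self.requires_grad, (self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g - np.exp(ls) * g.sum(axis=axis, keepdims=True))

        out._backward = backward
        return out

    # -- graph traversal ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, req, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        offset = 0
        for t, size in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(offset, offset + size)
                t._accumulate(g[tuple(sl)])
            offset += size

    out._backward = backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(data, any(t.requires_grad for t in tensors), tuple(tensors))

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    out._backward = backward
    return out


def nll_loss(log_probs: Tensor, targets: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer targets under (N, C) log-probs.

    Equivalent to cross-entropy when ``log_probs`` comes from log-softmax.
    """
    targets = np.asarray(targets, dtype=int)
    n = log_probs.data.shape[0]
    picked = log_probs[(np.arange(n), targets)]
    return -picked.mean()


# ---------------------------------------------------------------------------
# layers


class Parameter(Tensor):
    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True, name=name)


class Module:
    """Base class: parameter collection, train/eval mode, freezing."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def set_requires_grad(self, flag: bool):
        for p in self.parameters():
            p.requires_grad = flag

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}

        def visit(obj, prefix):
            for key, value in obj.__dict__.items():
                if isinstance(value, Parameter):
                    state[prefix + key] = value.data.copy()
                elif isinstance(value, Module):
                    visit(value, f"{prefix}{key}.")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            visit(item, f"{prefix}{key}.{i}.")
                elif isinstance(value, np.ndarray):
                    state[prefix + key] = value.copy()

        visit(self, "")
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        def visit(obj, prefix):
            for key, value in obj.__dict__.items():
                if isinstance(value, Parameter):
                    value.data = state[prefix + key].copy()
                elif isinstance(value, Module):
                    visit(value, f"{prefix}{key}.")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            visit(item, f"{prefix}{key}.{i}.")
                elif isinstance(value, np.ndarray):
                    setattr(obj, key, state[prefix + key].copy())

        visit(self, "")


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 0.1, size=(n_tokens, dim)), "embedding.weight")

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight[np.asarray(ids, dtype=int)]


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "linear"):
        super().__init__()
        bound = 1.0 / math.sqrt(n_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)), f"{name}.weight")
        self.bias = Parameter(np.zeros(n_out), f"{name}.bias")

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LSTMLayer(Module):
    """One LSTM layer unrolled over time with explicit state passing.

    Gate order in the fused weight matrices is (input, forget, cell, output).
    Forget-gate bias initialized to 1 — standard practice that stabilizes
    early training of the recurrence.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator, name: str = "lstm"):
        super().__init__()
        self.n_in, self.n_hidden = n_in, n_hidden
        bound = 1.0 / math.sqrt(n_hidden)
        self.w_ih = Parameter(rng.uniform(-bound, bound, size=(n_in, 4 * n_hidden)), f"{name}.w_ih")
        # orthogonal recurrent blocks (one per gate): keeps recurrent dynamics
        # well-conditioned and able to sustain the oscillatory modes that
        # positional structure in sequences requires
        blocks = []
        for _ in range(4):
            q, _r = np.linalg.qr(rng.normal(size=(n_hidden, n_hidden)))
            blocks.append(q)
        self.w_hh = Parameter(np.concatenate(blocks, axis=1), f"{name}.w_hh")
        bias = np.zeros(4 * n_hidden)
        bias[n_hidden : 2 * n_hidden] = 1.0
        self.bias = Parameter(bias, f"{name}.bias")

    def init_state(self, batch: int) -> tuple[Tensor, Tensor]:
        return Tensor(np.zeros((batch, self.n_hidden))), Tensor(np.zeros((batch, self.n_hidden)))

    def step(self, x: Tensor, state: tuple[Tensor, Tensor]) -> tuple[Tensor, tuple[Tensor, Tensor]]:
        h, c = state
        gates = x @ self.w_ih + h @ self.w_hh + self.bias
        nh = self.n_hidden
        i = gates[:, 0 * nh : 1 * nh].sigmoid()
        f = gates[:, 1 * nh : 2 * nh].sigmoid()
        g = gates[:, 2 * nh : 3 * nh].tanh()
        o = gates[:, 3 * nh : 4 * nh].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, (h_new, c_new)


class BatchNorm1d(Module):
    """Batch normalization over the batch axis of (N, D) inputs."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        super().__init__()
        self.gamma = Parameter(np.ones(dim), f"{name}.gamma")
        self.beta = Parameter(np.zeros(dim), f"{name}.beta")
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self.track_stats = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=0, keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=0, keepdims=True)
            if self.track_stats:
                self.running_mean = (
                    (1 - self.momentum) * self.running_mean + self.momentum * mean.data.ravel()
                )
                self.running_var = (
                    (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
                )
            norm = centered / (var + self.eps).sqrt()
        else:
            norm = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return norm * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0:
            return x
        mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * mask


class Adam:
    """Adam with independent learning rates per parameter group."""

    def __init__(self, groups: Sequence[tuple[Sequence[Parameter], float]],
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.groups = [(list(params), lr) for params, lr in groups]
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for params, lr in self.groups:
            for p in params:
                if p.grad is None:
                    continue
                key = id(p)
                if key not in self.m:
                    self.m[key] = np.zeros_like(p.data)
                    self.v[key] = np.zeros_like(p.data)
                self.m[key] = b1 * self.m[key] + (1 - b1) * p.grad
                self.v[key] = b2 * self.v[key] + (1 - b2) * p.grad**2
                m_hat = self.m[key] / (1 - b1**self.t)
                v_hat = self.v[key] / (1 - b2**self.t)
                p.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


def clip_grad_norm(params: Iterable[Parameter], max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``."""
    params = [p for p in params if p.grad is not None]
    total = math.sqrt(sum(float((p.grad**2).sum()) for p in params))
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale
    return total
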