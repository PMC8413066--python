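"""Minimal NumPy neural-network kernel used by the view-pooling models.

A small reverse-mode tape over NumPy arrays plus exactly the layer types
the gesture-recognition networks need: 3-wide convolutions over the
electrode axis, 1x1 convolutions, locally connected (untied-weight) 1x1
layers, batch normalization with running statistics (and an adaptation
mode that re-estimates them from calibration data), dropout, dense layers
and a softmax cross-entropy loss.  All gradients are exercised against
numerical differentiation in the test suite.

Feature maps are ``(N, F, C)`` arrays: batch, depth (feature channels) and
electrode position.  The singleton height axis of the ``M_i x C x 1``
input layout is implicit, so the 3x3 convolutions of the architecture act
as 3-tap convolutions along the electrode axis (the height taps would only
ever see zero padding).
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor", "Parameter", "Module", "Dense", "Conv3", "Conv1x1",
    "LocallyConnected1x1", "BatchNorm", "Dropout", "relu", "concat",
    "add_n", "maximum_n", "mean_n", "flatten", "softmax",
    "softmax_cross_entropy", "nll_of_summed_scores", "SGD",
]


# ---------------------------------------------------------------------------
# autodiff tape
# ---------------------------------------------------------------------------

class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "grad_fn")

    def __init__(self, data, parents: tuple = (),
                 grad_fn: Callable[[np.ndarray], tuple] | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self.grad_fn = grad_fn

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor") -> None:
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n.parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node.grad_fn is None or node.grad is None:
                continue
            for parent, g in zip(node.parents, node.grad_fn(node.grad)):
                if g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g.copy()
                else:
                    parent.grad += g


class Parameter(Tensor):
    """A learnable leaf tensor."""

    def __init__(self, data):
        super().__init__(data)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(x.data * mask, (x,), lambda g: (g * mask,))


def flatten(x: Tensor) -> Tensor:
    shape = x.data.shape
    out = x.data.reshape(shape[0], -1)
    return Tensor(out, (x,), lambda g: (g.reshape(shape),))


def concat(xs: Sequence[Tensor], axis: int = 1) -> Tensor:
    xs = [_as_tensor(x) for x in xs]
    sizes = [x.data.shape[axis] for x in xs]
    out = np.concatenate([x.data for x in xs], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, tuple(xs), grad_fn)


def add_n(xs: Sequence[Tensor]) -> Tensor:
    xs = [_as_tensor(x) for x in xs]
    out = xs[0].data.copy()
    for x in xs[1:]:
        out += x.data
    return Tensor(out, tuple(xs), lambda g: tuple(g for _ in xs))


def mean_n(xs: Sequence[Tensor]) -> Tensor:
    n = len(xs)
    s = add_n(xs)
    return Tensor(s.data / n, (s,), lambda g: (g / n,))


def maximum_n(xs: Sequence[Tensor]) -> Tensor:
    """Element-wise maximum over equally shaped maps (ties -> first input)."""
    xs = [_as_tensor(x) for x in xs]
    stack = np.stack([x.data for x in xs])
    amax = stack.argmax(axis=0)
    out = np.take_along_axis(stack, amax[None], axis=0)[0]

    def grad_fn(g):
        return tuple(g * (amax == i) for i in range(len(xs)))

    return Tensor(out, tuple(xs), grad_fn)


def softmax(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)

    def grad_fn(g):
        dot = (g * p).sum(axis=1, keepdims=True)
        return (p * (g - dot),)

    return Tensor(p, (x,), grad_fn)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under row-softmax of logits."""
    labels = np.asarray(labels, dtype=np.int64)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(n), labels].mean()
    p = np.exp(logp)

    def grad_fn(g):
        d = p.copy()
        d[np.arange(n), labels] -= 1.0
        return (g * d / n,)

    return Tensor(loss, (logits,), grad_fn)


def nll_of_summed_scores(scores: Tensor, labels: np.ndarray,
                         n_heads: int) -> Tensor:
    """Negative log-likelihood of summed softmax scores (``summed_score`` loss).

    Treats ``scores / n_heads`` as the predictive distribution.
    """
    labels = np.asarray(labels, dtype=np.int64)
    n = scores.data.shape[0]
    picked = scores.data[np.arange(n), labels]
    loss = -np.mean(np.log(picked / n_heads))

    def grad_fn(g):
        d = np.zeros_like(scores.data)
        d[np.arange(n), labels] = -g / (n * picked)
        return (d,)

    return Tensor(loss, (scores,), grad_fn)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Composable container with parameter discovery and a training flag."""

    def __init__(self):
        self.training = False

    def named_parameters(self, prefix: str = "") -> Iterable[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterable["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, flag: bool = True) -> "Module":
        for m in self.modules():
            m.training = flag
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- serialization ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = state[name].copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm):
                m.running_mean = state[f"__bn{i}.running_mean"].copy()
                m.running_var = state[f"__bn{i}.running_var"].copy()


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Dense(Module):
    """Fully connected layer ``y = x W + b`` on ``(N, D)`` input."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = Parameter(_he(rng, (d_in, d_out), d_in))
        self.b = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        W, b = self.W, self.b
        out = x.data @ W.data + b.data

        def grad_fn(g):
            return (g @ W.data.T, x.data.T @ g, g.sum(axis=0))

        return Tensor(out, (x, W, b), grad_fn)


class Conv3(Module):
    """3-tap convolution along the electrode axis, zero padding 1, stride 1.

    Input ``(N, I, C)`` -> output ``(N, O, C)``; the spatial extent ``C``
    is preserved, as the hierarchy's shape algebra requires.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = Parameter(_he(rng, (c_out, c_in, 3), 3 * c_in))
        self.b = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        W, b = self.W, self.b
        N, I, C = x.data.shape
        xp = np.zeros((N, I, C + 2))
        xp[:, :, 1:-1] = x.data
        Xw = np.lib.stride_tricks.sliding_window_view(xp, 3, axis=2)
        out = np.einsum("nicr,oir->noc", Xw, W.data, optimize=True)
        out += b.data[:, None]

        def grad_fn(g):
            gW = np.einsum("nicr,noc->oir", Xw, g, optimize=True)
            gb = g.sum(axis=(0, 2))
            gp = np.zeros((N, I, C + 2))
            for r in range(3):
                gp[:, :, r:r + C] += np.einsum(
                    "noc,oi->nic", g, W.data[:, :, r], optimize=True)
            return (gp[:, :, 1:-1], gW, gb)

        return Tensor(out, (x, W, b), grad_fn)


class Conv1x1(Module):
    """Pointwise (1x1) convolution across depth: ``(N, I, C) -> (N, O, C)``."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = Parameter(_he(rng, (c_out, c_in), c_in))
        self.b = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        W, b = self.W, self.b
        out = np.einsum("oi,nic->noc", W.data, x.data, optimize=True)
        out += b.data[:, None]

        def grad_fn(g):
            gW = np.einsum("noc,nic->oi", g, x.data, optimize=True)
            gb = g.sum(axis=(0, 2))
            gx = np.einsum("oi,noc->nic", W.data, g, optimize=True)
            return (gx, gW, gb)

        return Tensor(out, (x, W, b), grad_fn)


class LocallyConnected1x1(Module):
    """1x1 layer with untied weights per electrode position.

    With a height-1 map of width ``C`` this is ``C`` independent linear
    transforms of the depth vector, one per position.
    """

    def __init__(self, c_in: int, c_out: int, width: int,
                 rng: np.random.Generator):
        super().__init__()
        self.W = Parameter(_he(rng, (width, c_out, c_in), c_in))
        self.b = Parameter(np.zeros((width, c_out)))

    def __call__(self, x: Tensor) -> Tensor:
        W, b = self.W, self.b
        out = np.einsum("coi,nic->noc", W.data, x.data, optimize=True)
        out += b.data.T[None]

        def grad_fn(g):
            gW = np.einsum("noc,nic->coi", g, x.data, optimize=True)
            gb = np.einsum("noc->co", g)
            gx = np.einsum("coi,noc->nic", W.data, g, optimize=True)
            return (gx, gW, gb)

        return Tensor(out, (x, W, b), grad_fn)


class BatchNorm(Module):
    """Batch normalization with running statistics and an adaptation mode.

    ``spatial=True`` normalizes ``(N, F, C)`` maps per depth channel over
    batch and electrode position; otherwise ``(N, F)`` per feature.
    Running statistics use the biased variance estimator throughout, so a
    direct moment computation over a calibration set reproduces them
    exactly.  In adaptation mode the layer normalizes with batch statistics
    while accumulating exact sums; :meth:`finish_adapt` then replaces the
    running statistics with the aggregated calibration moments, touching no
    learnable weight.
    """

    def __init__(self, num_features: int, spatial: bool = False,
                 momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.spatial = spatial
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.adapting = False
        self._adapt_sum = None
        self._adapt_sumsq = None
        self._adapt_count = 0

    def begin_adapt(self) -> None:
        self.adapting = True
        self._adapt_sum = np.zeros_like(self.running_mean)
        self._adapt_sumsq = np.zeros_like(self.running_var)
        self._adapt_count = 0

    def finish_adapt(self) -> None:
        if self._adapt_count == 0:
            raise ValueError("no calibration batches seen")
        mean = self._adapt_sum / self._adapt_count
        var = self._adapt_sumsq / self._adapt_count - mean ** 2
        self.running_mean = mean
        self.running_var = np.maximum(var, 0.0)
        self.adapting = False
        self._adapt_sum = self._adapt_sumsq = None
        self._adapt_count = 0

    def _expand(self, v: np.ndarray, x: np.ndarray) -> np.ndarray:
        return v[None, :, None] if x.ndim == 3 else v[None, :]

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0, 2) if (self.spatial and x.data.ndim == 3) else (0,)
        count = int(np.prod([x.data.shape[a] for a in axes]))
        use_batch_stats = self.training or self.adapting
        if use_batch_stats:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            if self.adapting:
                self._adapt_sum += x.data.sum(axis=axes)
                self._adapt_sumsq += (x.data ** 2).sum(axis=axes)
                self._adapt_count += count
            else:
                m = self.momentum
                self.running_mean = (1 - m) * self.running_mean + m * mu
                self.running_var = (1 - m) * self.running_var + m * var
        else:
            mu, var = self.running_mean, self.running_var

        std = np.sqrt(var + self.eps)
        xhat = (x.data - self._expand(mu, x.data)) / self._expand(std, x.data)
        out = self._expand(self.gamma.data, x.data) * xhat \
            + self._expand(self.beta.data, x.data)
        gamma, beta = self.gamma, self.beta

        def grad_fn(g):
            ggamma = (g * xhat).sum(axis=axes)
            gbeta = g.sum(axis=axes)
            dxhat = g * self._expand(gamma.data, g)
            inv = self._expand(1.0 / std, g)
            if use_batch_stats:
                s1 = dxhat.sum(axis=axes)
                s2 = (dxhat * xhat).sum(axis=axes)
                gx = inv * (dxhat
                            - self._expand(s1, g) / count
                            - xhat * self._expand(s2, g) / count)
            else:
                gx = dxhat * inv
            return (gx, ggamma, gbeta)

        return Tensor(out, (x, gamma, beta), grad_fn)


class Dropout(Module):
    """Inverted dropout, active only in training mode."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an RNG")
        mask = (rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return Tensor(x.data * mask, (x,), lambda g: (g * mask,))


class SGD:
    """Stochastic gradient descent with optional momentum and weight decay."""

    def __init__(self, params: Sequence[Parameter], lr: float,
                 momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            if self.momentum:
                v *= self.momentum
                v += g
                g = v
            p.data -= self.lr * g
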