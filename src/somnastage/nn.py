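"""Minimal reverse-mode autodiff over numpy arrays, with the layers and the
optimizer the staging network needs.

This is deliberately small: a ``Tensor`` records its parents and a gradient
function per parent; ``backward`` walks the tape in reverse topological
order.  Layers are ``Module`` objects holding ``Parameter`` tensors.  All
arithmetic is float32.

Implemented ops cover exactly what the model uses: 1-D convolution (im2col,
optional causal left-padding), max pooling, dense layers, layer
normalization, ReLU/sigmoid/softmax, dropout, batched matmul, concat /
reshape / transpose / slicing, means, and a fused weighted cross-entropy on
logits.  The optimizer is Adam with optional AMSGrad and L2 weight decay,
plus a step learning-rate schedule.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=DTYPE)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_grad_fns")

    def __init__(self, data, requires_grad: bool = False,
                 parents=(), grad_fns=()):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._grad_fns = tuple(grad_fns)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _op(data, parents, grad_fns) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        if not req:
            return Tensor(data)
        return Tensor(data, requires_grad=True, parents=parents,
                      grad_fns=grad_fns)

    # -- backward -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = _as_array(grad)
        for node in reversed(topo):
            g = node.grad
            if g is None:
                continue
            for parent, fn in zip(node._parents, node._grad_fns):
                if not parent.requires_grad or fn is None:
                    continue
                pg = fn(g)
                if parent.grad is None:
                    parent.grad = pg.astype(DTYPE, copy=True)
                else:
                    parent.grad += pg

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        out = a.data + b.data
        return Tensor._op(out, (a, b),
                          (lambda g: _unbroadcast(g, a.data.shape),
                           lambda g: _unbroadcast(g, b.data.shape)))

    def __mul__(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        out = a.data * b.data
        return Tensor._op(out, (a, b),
                          (lambda g: _unbroadcast(g * b.data, a.data.shape),
                           lambda g: _unbroadcast(g * a.data, b.data.shape)))

    def scale(self, c: float) -> "Tensor":
        return Tensor._op(self.data * c, (self,), (lambda g: g * c,))

    def reshape(self, *shape) -> "Tensor":
        src = self.data.shape
        return Tensor._op(self.data.reshape(*shape), (self,),
                          (lambda g: g.reshape(src),))

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)
        return Tensor._op(self.data.transpose(*axes), (self,),
                          (lambda g: g.transpose(*inv),))

    def mean(self, axis: int, keepdims: bool = False) -> "Tensor":
        n = self.data.shape[axis]
        out = self.data.mean(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g / n, self.data.shape).astype(DTYPE)

        return Tensor._op(out, (self,), (grad_fn,))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def tensor(data) -> Tensor:
    return Tensor(data)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor._op(x.data * mask, (x,), (lambda g: g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor._op(y, (x,), (lambda g: g * y * (1.0 - y),))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def grad_fn(g):
        return y * (g - (g * y).sum(axis=axis, keepdims=True))

    return Tensor._op(y, (x,), (grad_fn,))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matmul; batch dimensions of a and b must match exactly."""
    if a.data.shape[:-2] != b.data.shape[:-2]:
        raise ValueError("matmul batch dims must match")
    out = np.matmul(a.data, b.data)
    return Tensor._op(
        out, (a, b),
        (lambda g: np.matmul(g, np.swapaxes(b.data, -1, -2)),
         lambda g: np.matmul(np.swapaxes(a.data, -1, -2), g)))


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_fn(i):
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(offsets[i], offsets[i + 1])
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor._op(data, tuple(tensors),
                      tuple(make_fn(i) for i in range(len(tensors))))


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(DTYPE) / DTYPE(1.0 - p)
    return Tensor._op(x.data * keep, (x,), (lambda g: g * keep,))


def conv1d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           pad: tuple[int, int] = (0, 0)) -> Tensor:
    """1-D convolution (cross-correlation). x: [N,Cin,L]; w: [Cout,Cin,K]."""
    n, cin, length = x.data.shape
    cout, cin_w, k = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv1d channel mismatch: input {cin}, weight {cin_w}")
    pl, pr = pad
    xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
    lp = xp.shape[2]
    lout = (lp - k) // stride + 1
    if lout <= 0:
        raise ValueError("conv1d output length would be non-positive")
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
    win = win[:, :, ::stride][:, :, :lout]          # [N,Cin,Lout,K] (view)
    # im2col -> GEMM: [N*Lout, Cin*K] @ [Cin*K, Cout]
    cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
        n * lout, cin * k)
    w2 = w.data.reshape(cout, cin * k)
    out = (cols @ w2.T).reshape(n, lout, cout).transpose(0, 2, 1)
    if b is not None:
        out = out + b.data[None, :, None]

    def grad_x(g):
        gt = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(
            n * lout, cout)
        dcols = (gt @ w2).reshape(n, lout, cin, k).transpose(0, 2, 1, 3)
        # col2im by kernel-offset blocks: position = stride*(l+q) + r with
        # kk = q*stride + r, so each q contributes one contiguous block
        nq = -(-k // stride)
        buf = np.zeros((n, cin, (lout + nq) * stride), dtype=DTYPE)
        bview = buf.reshape(n, cin, lout + nq, stride)
        for q in range(nq):
            width = min(stride, k - q * stride)
            bview[:, :, q:q + lout, :width] += \
                dcols[:, :, :, q * stride:q * stride + width]
        gxp = buf[:, :, :lp]
        return gxp[:, :, pl:lp - pr] if pr else gxp[:, :, pl:]

    def grad_w(g):
        gt = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(
            n * lout, cout)
        return (gt.T @ cols).reshape(cout, cin, k)

    parents = [x, w]
    fns = [grad_x, grad_w]
    if b is not None:
        parents.append(b)
        fns.append(lambda g: g.sum(axis=(0, 2)))
    return Tensor._op(out, tuple(parents), tuple(fns))


def maxpool1d(x: Tensor, k: int, stride: int, pad: int = 0) -> Tensor:
    n, c, length = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)),
                constant_values=-np.inf)
    lp = xp.shape[2]
    lout = (lp - k) // stride + 1
    if lout <= 0:
        raise ValueError("maxpool1d output length would be non-positive")
    # window max by kernel-offset blocks (kk = q*stride + r): q-blocks are
    # contiguous views, so the compare passes stay cheap
    nq = -(-k // stride)
    buf = np.full((n, c, (lout + nq) * stride), -np.inf, dtype=DTYPE)
    buf[:, :, :lp] = xp
    bview = buf.reshape(n, c, lout + nq, stride)
    best = np.full((n, c, lout, stride), -np.inf, dtype=DTYPE)
    bestq = np.zeros((n, c, lout, stride), dtype=np.int8)
    for q in range(nq):
        width = min(stride, k - q * stride)
        cand = bview[:, :, q:q + lout, :width]
        better = cand > best[:, :, :, :width]
        np.copyto(best[:, :, :, :width], cand, where=better)
        bestq[:, :, :, :width][better] = q
    r_star = best.argmax(axis=3)
    out = np.take_along_axis(best, r_star[..., None], axis=3)[..., 0]
    q_star = np.take_along_axis(bestq, r_star[..., None], axis=3)[..., 0]
    idx = q_star.astype(np.int64) * stride + r_star

    def grad_fn(g):
        gxp = np.zeros((n * c, lp), dtype=DTYPE)
        cols = stride * np.arange(lout)[None, :] + idx.reshape(n * c, lout)
        rows = np.repeat(np.arange(n * c), lout)
        np.add.at(gxp, (rows, cols.ravel()), g.reshape(-1))
        gxp = gxp.reshape(n, c, lp)
        return gxp[:, :, pad:lp - pad] if pad else gxp

    return Tensor._op(out, (x,), (grad_fn,))


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma.data + beta.data
    d = x.data.shape[-1]

    def grad_x(g):
        gh = g * gamma.data
        return inv * (gh - gh.mean(axis=-1, keepdims=True)
                      - xhat * (gh * xhat).mean(axis=-1, keepdims=True))

    def grad_gamma(g):
        return _unbroadcast(g * xhat, gamma.data.shape)

    def grad_beta(g):
        return _unbroadcast(g, beta.data.shape)

    return Tensor._op(out, (x, gamma, beta), (grad_x, grad_gamma, grad_beta))


def weighted_cross_entropy_logits(logits: Tensor, labels: np.ndarray,
                                  sample_weights: np.ndarray) -> Tensor:
    """Weighted-mean cross-entropy on raw logits (numerically stable).

    loss = sum_i w_i * (-log softmax(logits_i)[y_i]) / sum_i w_i
    """
    y = np.asarray(labels, dtype=np.int64)
    w = _as_array(sample_weights)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    n = logits.data.shape[0]
    wsum = w.sum()
    loss = -(w * logp[np.arange(n), y]).sum() / wsum

    def grad_fn(g):
        p = np.exp(logp)
        p[np.arange(n), y] -= 1.0
        return (g * p * (w / wsum)[:, None]).astype(DTYPE)

    return Tensor._op(np.array(loss, dtype=DTYPE), (logits,), (grad_fn,))


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: tracks sub-modules and parameters by attribute scan."""

    def __init__(self):
        self.training = True

    def modules(self) -> list["Module"]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.append(v)
            elif isinstance(v, (list, tuple)):
                out.extend(m for m in v if isinstance(m, Module))
        return out

    def parameters(self) -> list[Parameter]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        params.extend(m.parameters())
                    elif isinstance(m, Parameter):
                        params.append(m)
        return params

    def train(self) -> "Module":
        self.training = True
        for m in self.modules():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self.modules():
            m.eval()
        return self

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state shape mismatch")
            p.data = _as_array(a)


def _uniform_fan_in(rng: np.random.Generator, shape: tuple,
                    fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Conv1d(Module):
    """1-D convolution layer; ``causal=True`` left-pads by k-1 so the output
    at time t depends only on inputs at times <= t."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, pad: tuple[int, int] | int = 0,
                 causal: bool = False, bias: bool = True, *,
                 rng: np.random.Generator):
        super().__init__()
        self.stride = stride
        if causal:
            self.pad = (kernel_size - 1, 0)
        elif isinstance(pad, int):
            self.pad = (pad, pad)
        else:
            self.pad = tuple(pad)
        fan_in = in_channels * kernel_size
        self.weight = Parameter(_uniform_fan_in(
            rng, (out_channels, in_channels, kernel_size), fan_in))
        self.bias = Parameter(_uniform_fan_in(rng, (out_channels,), fan_in)) \
            if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.stride, self.pad)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_uniform_fan_in(
            rng, (in_features, out_features), in_features))
        self.bias = Parameter(_uniform_fan_in(rng, (out_features,),
                                              in_features)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = matmul(x, self.weight) if x.data.ndim == 2 else None
        if out is None:
            # position-wise application on [..., in_features]
            flat = x.reshape(-1, self.weight.data.shape[0])
            out = matmul(flat, self.weight)
            if self.bias is not None:
                out = out + self.bias
            return out.reshape(*x.data.shape[:-1], self.weight.data.shape[1])
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, width: int):
        super().__init__()
        self.gamma = Parameter(np.ones(width, dtype=DTYPE))
        self.beta = Parameter(np.zeros(width, dtype=DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        return dropout(x, self.p, self.rng, self.training)


class MaxPool1d(Module):
    def __init__(self, kernel_size: int, stride: int, pad: int = 0):
        super().__init__()
        self.k, self.stride, self.pad = kernel_size, stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return maxpool1d(x, self.k, self.stride, self.pad)


# ---------------------------------------------------------------------------
# optimizer and schedule
# ---------------------------------------------------------------------------

class Adam:
    """Adam with optional AMSGrad and L2 weight decay (decay added to the
    gradient, matching the common deep-learning convention)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0,
                 amsgrad: bool = False):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.amsgrad = amsgrad
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.vmax = [np.zeros_like(p.data, dtype=np.float64) for p in params] \
            if amsgrad else None

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.data.astype(np.float64)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            if self.amsgrad:
                np.maximum(self.vmax[i], self.v[i], out=self.vmax[i])
                vhat = self.vmax[i] / bc2
            else:
                vhat = self.v[i] / bc2
            p.data = (p.data.astype(np.float64)
                      - self.lr * mhat / (np.sqrt(vhat) + self.eps)
                      ).astype(DTYPE)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class StepLR:
    """Halve (or scale by gamma) the learning rate every ``step_size`` epochs."""

    def __init__(self, optimizer: Adam, step_size: int = 10,
                 gamma: float = 0.5):
        self.optimizer = optimizer
        self.step_size = step_size
        self.gamma = gamma
        self.base_lr = optimizer.lr
        self.epoch = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr

    def step(self) -> None:
        """Advance one epoch and update the optimizer's learning rate."""
        self.epoch += 1
        self.optimizer.lr = self.base_lr * self.gamma ** (
            self.epoch // self.step_size)

    def lr_at(self, epoch: int) -> float:
        return self.base_lr * self.gamma ** (epoch // self.step_size)
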