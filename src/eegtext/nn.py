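"""Small neural-network layer library on top of :mod:`eegtext.autodiff`.

Provides the building blocks used by the dual-encoder model: linear layers,
1-D convolution / max-pooling via ``unfold``, batch normalization with running
statistics, dropout and an Adam optimizer with parameter groups.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, im2col, unfold

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "BatchNorm",
    "Dropout",
    "max_pool1d",
    "Adam",
]


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{key}.{i}", item

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(prefix=f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(prefix=f"{key}.{i}.")
            elif isinstance(value, np.ndarray) and getattr(self, "_buffer_names", None) \
                    and name in self._buffer_names:
                yield key, value

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data = np.asarray(value, dtype=params[name].data.dtype)
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unexpected state entry {name!r}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_kaiming(rng, in_features, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Valid-mode 1-D convolution over the last axis, implemented as unfold+matmul."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        fan_in = in_channels * kernel_size
        self.weight = Tensor(_kaiming(rng, fan_in, (fan_in, out_channels)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        # x: (n, C_in, T) -> (n, C_out, T_out)
        n = x.shape[0]
        patches = im2col(x, self.kernel_size, self.stride)       # (n, T_out, C_in*k)
        t_out, ck = patches.shape[1], patches.shape[2]
        out = patches.reshape(n * t_out, ck) @ self.weight       # one big GEMM
        out = out.reshape(n, t_out, self.weight.shape[1]) + self.bias
        return out.transpose(0, 2, 1)


def max_pool1d(x: Tensor, size: int, stride: int | None = None) -> Tensor:
    """Non-overlapping (by default) max pooling over the last axis."""
    return unfold(x, size, stride or size).max(axis=-1)


class BatchNorm(Module):
    """Batch normalization over all axes except the feature axis (axis 1).

    ``cumulative`` switches the running-statistics update from an exponential
    moving average to an equal-weight average, used when recalibrating the
    statistics after training (see :func:`recalibrate_batchnorm`).
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.cumulative = False
        self._count = 0
        self.gamma = Tensor(np.ones(num_features, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self._buffer_names = ("running_mean", "running_var")

    def forward(self, x: Tensor) -> Tensor:
        axes = (0,) + tuple(range(2, x.ndim))
        shape = (1, x.shape[1]) + (1,) * (x.ndim - 2)
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=axes, keepdims=True)
            if self.cumulative:
                self._count += 1
                alpha = 1.0 / self._count
            else:
                alpha = self.momentum
            self.running_mean += alpha * (mean.data.reshape(-1) - self.running_mean)
            self.running_var += alpha * (var.data.reshape(-1) - self.running_var)
            norm = centered * (var + self.eps) ** -0.5
        else:
            mean = self.running_mean.reshape(shape)
            var = self.running_var.reshape(shape)
            norm = (x - mean) * ((var + self.eps) ** -0.5)
        return norm * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(x.data.dtype)
        return x * Tensor(keep / (1.0 - self.p))


def recalibrate_batchnorm(model: Module, forward_fn, batches) -> None:
    """Re-estimate batch-norm running statistics with dropout disabled.

    Statistics gathered while dropout perturbs activations do not match the
    inference-time activation distribution; after training, a few clean
    forward passes restore agreement. ``forward_fn(batch)`` must route the
    batch through the model.
    """
    bns = [m for m in model.modules() if isinstance(m, BatchNorm)]
    if not bns:
        return
    drops = [m for m in model.modules() if isinstance(m, Dropout)]
    saved_p = [d.p for d in drops]
    was_training = model.training
    for d in drops:
        d.p = 0.0
    for bn in bns:
        bn.cumulative = True
        bn._count = 0
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 0.0
    model.train()
    try:
        for batch in batches:
            forward_fn(batch)
    finally:
        for bn in bns:
            bn.cumulative = False
        for d, p in zip(drops, saved_p):
            d.p = p
        model.train(was_training)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy for integer class labels."""
    n = logits.shape[0]
    const_max = Tensor(logits.data.max(axis=1, keepdims=True))  # detached
    lse = (logits - const_max).exp().sum(axis=1).log() + const_max.reshape(n)
    picked = logits[np.arange(n), np.asarray(labels, dtype=np.int64)]
    return (lse - picked).mean()


class Adam:
    """Adam with L2 weight decay and per-group learning rates."""

    def __init__(self, param_groups: list[dict], betas=(0.9, 0.999), eps: float = 1e-8):
        self.groups = []
        seen: set[int] = set()
        for group in param_groups:
            params = list(group["params"])
            for p in params:
                if id(p) in seen:
                    raise ValueError("parameter appears in more than one group")
                seen.add(id(p))
            self.groups.append({
                "params": params,
                "lr": float(group["lr"]),
                "weight_decay": float(group.get("weight_decay", 0.0)),
                "m": [np.zeros_like(p.data, dtype=np.float32) for p in params],
                "v": [np.zeros_like(p.data, dtype=np.float32) for p in params],
            })
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0

    def zero_grad(self):
        for group in self.groups:
            for p in group["params"]:
                p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for group in self.groups:
            lr, wd = group["lr"], group["weight_decay"]
            if lr == 0.0:
                continue
            for p, m, v in zip(group["params"], group["m"], group["v"]):
                if p.grad is None:
                    continue
                g = p.grad.astype(np.float32)
                if wd:
                    g = g + wd * p.data
                m += (1.0 - b1) * (g - m)
                v += (1.0 - b2) * (g * g - v)
                update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
                p.data = (p.data - lr * update).astype(p.data.dtype)
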