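"""Neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container: tracks parameters and submodules by attribute."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    collect(v)

        collect(self)
        return params

    def named_parameters(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}

        def collect(obj, prefix):
            if isinstance(obj, Parameter):
                out[prefix] = obj
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    collect(v, f"{prefix}.{k}" if prefix else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    collect(v, f"{prefix}.{i}")
            elif isinstance(obj, dict):
                for k, v in obj.items():
                    collect(v, f"{prefix}.{k}")

        collect(self, "")
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        named = self.named_parameters()
        missing = set(named) - set(state)
        extra = set(state) - set(named)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in named.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = np.asarray(state[k], dtype=np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1, *,
                 rng: np.random.Generator, zero_init: bool = False, bias: bool = True):
        if kernel % 2 == 0:
            raise ValueError("Conv3d requires an odd kernel")
        self.stride = stride
        shape = (out_ch, in_ch, kernel, kernel, kernel)
        if zero_init:
            self.weight = Parameter(np.zeros(shape, dtype=np.float32))
        else:
            self.weight = Parameter(_he_init(rng, shape, in_ch * kernel ** 3))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv3d(x, self.weight, self.bias, stride=self.stride)


class ConvTranspose3d2x(Module):
    """Kernel-2 / stride-2 transpose convolution: exact spatial doubling."""

    def __init__(self, in_ch: int, out_ch: int, *, rng: np.random.Generator):
        self.weight = Parameter(_he_init(rng, (in_ch, out_ch, 2, 2, 2), in_ch * 8))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv_transpose3d_2x(x, self.weight, self.bias)


class InstanceNorm(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ad.instance_norm(x, self.gamma, self.beta, self.eps)


class LayerNorm(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gamma, self.beta, self.eps)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, *, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            self.weight = Parameter(np.zeros((in_dim, out_dim), dtype=np.float32))
        else:
            # Xavier-style init for token projections
            std = np.sqrt(1.0 / in_dim)
            self.weight = Parameter(rng.normal(0.0, std, (in_dim, out_dim)).astype(np.float32))
        self.bias = Parameter(np.zeros(out_dim, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.weight), self.bias)


class SGD:
    """SGD with Nesterov momentum, weight decay, polynomial LR decay and
    global gradient-norm clipping."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3, momentum: float = 0.99,
                 nesterov: bool = True, weight_decay: float = 3e-5, clip_norm: float = 12.0):
        self.params = list(params)
        self.base_lr = lr
        self.lr = lr
        self.momentum = momentum
        self.nesterov = nesterov
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def set_poly_lr(self, step: int, total_steps: int, power: float = 0.9):
        frac = min(step / max(total_steps, 1), 1.0)
        self.lr = self.base_lr * (1.0 - frac) ** power

    def step(self):
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        for p, g, v in zip(self.params, grads, self._vel):
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            if self.nesterov:
                p.data -= self.lr * (g + self.momentum * v)
            else:
                p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
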