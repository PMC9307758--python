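"""Layer and optimizer building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autograd import DTYPE, Tensor, add, conv2d, leaky_relu, matmul

__all__ = ["Module", "Linear", "Conv2d", "Adam", "init_rng"]


def init_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


class Module:
    """Tiny module base: named parameter registry plus state dict I/O."""

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self) -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((name, val))
            elif isinstance(val, Module):
                out.extend((f"{name}.{k}", p) for k, p in val.named_parameters())
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(
                            (f"{name}.{i}.{k}", p) for k, p in item.named_parameters()
                        )
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{name}.{i}", item))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(
                f"state dict mismatch (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for parameter {k!r}")
            p.data[...] = state[k].astype(DTYPE)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, gain: float = 1.0):
        scale = gain / np.sqrt(n_in)
        self.weight = Tensor(
            rng.standard_normal((n_in, n_out)) * scale, requires_grad=True
        )
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.weight), self.bias)


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        gain: float = np.sqrt(2.0),
    ):
        fan_in = c_in * kernel * kernel
        self.weight = Tensor(
            rng.standard_normal((c_out, c_in, kernel, kernel)) * gain / np.sqrt(fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Adam:
    """Adam with the hyper-parameter layout used throughout training."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float,
        beta1: float = 0.0,
        beta2: float = 0.99,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
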