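"""Trainable layers and the Adam optimizer used by both network models."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Module:
    """Lightweight parameter container with recursive collection."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]


class Linear(Module):
    """Affine map with Kaiming-uniform-style init."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        bound = np.sqrt(6.0 / d_in)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    """Normalization over the last axis with learned scale/offset."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        m = x.mean(axis=-1, keepdims=True)
        centered = x - m
        var = (centered**2).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps) ** 0.5 * self.gamma + self.beta


class BatchNorm(Module):
    """Per-channel batch normalization for (B, C, H, W) feature maps.

    Uses batch statistics in both passes (the stem is only exercised at
    desk scale where train == eval conditions); running statistics are
    tracked for checkpointing completeness.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))

    def __call__(self, x: Tensor) -> Tensor:
        m = x.mean(axis=(0, 2, 3), keepdims=True)
        centered = x - m
        var = (centered**2).mean(axis=(0, 2, 3), keepdims=True)
        self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * m.data
        self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data
        return centered / (var + self.eps) ** 0.5 * self.gamma + self.beta


def mse(pred: Tensor, target: np.ndarray | Tensor) -> Tensor:
    t = target if isinstance(target, Tensor) else Tensor(target)
    return ((pred - t) ** 2).mean()


def cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy against one-hot rows."""
    logp = logits.log_softmax(axis=-1)
    return -(logp * Tensor(onehot)).sum() * (1.0 / logits.shape[0])


def binary_cross_entropy_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean per-(sample, class) BCE on sigmoid logits, numerically stable."""
    t = Tensor(targets)
    # log(1 + e^x) = relu(x) + log(1 + e^-|x|)
    abs_neg = -(logits * Tensor(np.sign(logits.data) + (logits.data == 0)))
    softplus = logits.relu() + (abs_neg.exp() + 1.0).log()
    return (softplus - logits * t).mean()


class Adam:
    """Adam with classic L2 weight decay added to the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
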