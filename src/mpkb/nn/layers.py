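"""Parameterized layers and the SGD optimizer used by the segmentation net."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Container with recursive parameter discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
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

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_checksum(self) -> str:
        import hashlib
        h = hashlib.sha256()
        for p in self.parameters():
            h.update(np.ascontiguousarray(p.data, dtype=np.float64).tobytes())
        return h.hexdigest()

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(p_list := self.parameters(), state, strict=True):
            p.data = s.copy().astype(p.data.dtype)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        fan_in = cin * k * k
        w = rng.standard_normal((cout, cin, k, k)) * np.sqrt(2.0 / fan_in)
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 dtype=np.float32):
        w = rng.standard_normal((cin, cout)) * np.sqrt(2.0 / cin)
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.add(ag.matmul(x, self.weight), self.bias)


class SGD:
    """Stochastic gradient descent with (Nesterov) momentum.

    Gradients are clipped to a global L2 norm (``clip_norm``) before the
    momentum update; with high momentum and no normalization layers this
    guards against the rare step where a large gradient would otherwise
    send the weights into overflow.
    """

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.99,
                 nesterov: bool = True, clip_norm: float = 12.0):
        self.params = params
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.nesterov = nesterov
        self.clip_norm = float(clip_norm)
        self._velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def _clip_scale(self) -> float:
        if not np.isfinite(self.clip_norm) or self.clip_norm <= 0:
            return 1.0
        sq = sum(float((p.grad ** 2).sum()) for p in self.params
                 if p.grad is not None)
        norm = np.sqrt(sq)
        return 1.0 if norm <= self.clip_norm else self.clip_norm / norm

    def step(self) -> None:
        scale = self._clip_scale()
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad * scale
            v *= self.momentum
            v -= self.lr * g
            if self.nesterov:
                p.data = p.data + self.momentum * v - self.lr * g
            else:
                p.data = p.data + v
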