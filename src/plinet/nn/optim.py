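"""Adam with decoupled weight decay, and the training hyperparameters.

Moment updates are the standard exponential averages with bias correction
m_hat = m / (1 - beta1^t), v_hat = v / (1 - beta2^t). The weight-decay term
is applied decoupled from the adaptive step,

    theta <- (1 - alpha * lambda) * theta - alpha * m_hat / (sqrt(v_hat) + eps),

the well-posed form (a decay term divided by sqrt(v_hat) + eps degenerates
as v_hat -> 0). Decay touches convolution weights only, never biases or
normalization parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..containers import ValidationError
from .model import Sequential


@dataclass
class TrainConfig:
    """Optimizer, loss and cross-validation hyperparameters."""

    batch_size: int = 32
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weight_decay: float = 0.2
    epochs: int = 1000
    class_weights: np.ndarray | None = None  # default uniform
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValidationError("beta1/beta2 must lie in (0, 1)")
        for name in ("batch_size", "learning_rate", "eps", "epochs"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.weight_decay < 0:
            raise ValidationError("weight_decay must be >= 0")


class Adam:
    """Per-parameter first/second moment state over a Sequential model."""

    def __init__(self, model: Sequential, config: TrainConfig):
        self.model = model
        self.config = config
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}
        for i, layer in enumerate(model.layers):
            for pname, p in layer.params.items():
                self.m[(i, pname)] = np.zeros_like(p)
                self.v[(i, pname)] = np.zeros_like(p)

    def step(self) -> None:
        cfg = self.config
        self.t += 1
        bc1 = 1.0 - cfg.beta1 ** self.t
        bc2 = 1.0 - cfg.beta2 ** self.t
        for i, layer in enumerate(self.model.layers):
            for pname, p in layer.params.items():
                g = layer.grads.get(pname)
                if g is None:
                    continue
                if not np.all(np.isfinite(g)):
                    raise FloatingPointError(
                        f"non-finite gradient for {layer.name}.{pname}")
                key = (i, pname)
                self.m[key] = cfg.beta1 * self.m[key] + (1 - cfg.beta1) * g
                self.v[key] = cfg.beta2 * self.v[key] + (1 - cfg.beta2) * g * g
                m_hat = self.m[key] / bc1
                v_hat = self.v[key] / bc2
                if pname in layer.decay and cfg.weight_decay:
                    p *= 1.0 - cfg.learning_rate * cfg.weight_decay
                p -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + cfg.eps)
        self.model.apply_constraints()
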