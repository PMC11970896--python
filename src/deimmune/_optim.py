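"""Minimal Adam optimizer over dicts of numpy arrays."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "clip_grad_norm", "global_norm"]


def global_norm(grads: dict[str, np.ndarray]) -> float:
    """L2 norm over all entries of all arrays."""
    total = 0.0
    for g in grads.values():
        total += float(np.sum(g * g))
    return float(np.sqrt(total))


def clip_grad_norm(grads: dict[str, np.ndarray], max_norm: float) -> dict[str, np.ndarray]:
    """Rescale *grads* so their global norm is at most *max_norm*."""
    norm = global_norm(grads)
    if norm > max_norm > 0:
        scale = max_norm / norm
        return {k: g * scale for k, g in grads.items()}
    return grads


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        learning_rate: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        if learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        self.lr = float(learning_rate)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        """Apply one descent step in place (*grads* point uphill in loss)."""
        self.t += 1
        for k, p in params.items():
            g = grads[k]
            m = self._m.setdefault(k, np.zeros_like(p))
            v = self._v.setdefault(k, np.zeros_like(p))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            m_hat = m / (1 - self.beta1**self.t)
            v_hat = v / (1 - self.beta2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
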