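"""Adam and the lookahead wrapper used by the training recipe."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter

__all__ = ["Adam", "Lookahead", "lookahead_update"]


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def lookahead_update(fast, slow, step: int, k: int, alpha: float):
    """One lookahead bookkeeping step on parallel weight collections.

    Every ``k`` inner-optimizer steps the slow weights move a fraction
    ``alpha`` toward the fast weights and the fast weights are reset onto
    the updated slow weights; other steps leave both unchanged. Accepts
    scalars or (lists of) numpy arrays; returns ``(fast, slow)`` copies.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    scalar = np.isscalar(fast) or isinstance(fast, np.ndarray)
    fasts = [fast] if scalar else list(fast)
    slows = [slow] if scalar else list(slow)
    if step % k != 0:
        out_f = [np.copy(f) for f in fasts]
        out_s = [np.copy(s) for s in slows]
    else:
        out_s = [s + alpha * (np.asarray(f) - s) for f, s in zip(fasts, slows)]
        out_f = [np.copy(s) for s in out_s]
    if scalar:
        return out_f[0], out_s[0]
    return out_f, out_s


class Lookahead:
    """Wraps an inner optimizer; synchronises slow weights every ``k`` steps."""

    def __init__(self, inner: Adam, k: int = 5, alpha: float = 0.5):
        if k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        self.inner = inner
        self.k = k
        self.alpha = alpha
        self.step_count = 0
        self.slow = [p.data.copy() for p in inner.params]

    def step(self) -> None:
        self.inner.step()
        self.step_count += 1
        if self.step_count % self.k == 0:
            for p, s in zip(self.inner.params, self.slow):
                s += self.alpha * (p.data - s)
                p.data = s.copy()

    def zero_grad(self) -> None:
        self.inner.zero_grad()
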