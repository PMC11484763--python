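"""Adam optimiser over ParamDicts.

Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8) with bias correction.

The optimiser exposes :meth:`direction` — the amount subtracted from the
parameters at this step — rather than mutating parameters itself.  Local
training accumulates these amounts into a running total ``acc`` and always
evaluates the current parameters as ``initial - acc``.  The accumulated
total is exactly the pseudo-gradient (initial minus final parameters) that
clients report to the server, so the server's update re-evaluates the very
same floating-point expression the client used; the single-client
learning-rate-1 reduction of the protocol is therefore bit-exact rather
than merely close.

Clients create a fresh instance every local training round, so optimiser
moments never leak into the pseudo-gradients exchanged with the server.
"""

from __future__ import annotations

import numpy as np

from .params import ParamDict

__all__ = ["Adam"]


class Adam:
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self._m: dict[str, dict[str, np.ndarray]] = {}
        self._v: dict[str, dict[str, np.ndarray]] = {}
        self._t: dict[str, int] = {}

    def direction(self, grads: ParamDict, group: str = "default") -> ParamDict:
        """The update amount for this step; caller subtracts it.

        Distinct parameter sets (model, knowledge vector, filter) stepped by
        one optimiser instance must use distinct group names so their
        moments stay separate.
        """
        if group not in self._m:
            self._m[group] = {k: np.zeros_like(grads[k]) for k in grads}
            self._v[group] = {k: np.zeros_like(grads[k]) for k in grads}
            self._t[group] = 0
        m, v = self._m[group], self._v[group]
        self._t[group] += 1
        t = self._t[group]
        out = {}
        for k in grads:
            g = grads[k]
            m[k] = self.beta1 * m[k] + (1.0 - self.beta1) * g
            v[k] = self.beta2 * v[k] + (1.0 - self.beta2) * (g * g)
            mhat = m[k] / (1.0 - self.beta1 ** t)
            vhat = v[k] / (1.0 - self.beta2 ** t)
            out[k] = self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return ParamDict(out)

    def step(self, params: ParamDict, grads: ParamDict, group: str = "default") -> ParamDict:
        """Convenience: parameters minus this step's direction."""
        return params - self.direction(grads, group)
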