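"""Adam optimizer over ``Module`` parameter trees."""

from __future__ import annotations

import numpy as np

from .layers import Module


class Adam:
    def __init__(self, modules: list[Module], lr=1e-5, betas=(0.9, 0.999), eps=1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._slots = []
        for mod in modules:
            for m, k in mod.parameters():
                self._slots.append(
                    (m, k, np.zeros_like(m.params[k], dtype=np.float64),
                     np.zeros_like(m.params[k], dtype=np.float64))
                )

    def zero_grad(self):
        seen = set()
        for m, k, _, _ in self._slots:
            if id(m) not in seen:
                seen.add(id(m))
                for key in m.params:
                    m.grads[key] = np.zeros_like(m.params[key])

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for m, k, mom, vel in self._slots:
            g = m.grads.get(k)
            if g is None:
                continue
            mom *= self.b1
            mom += (1 - self.b1) * g
            vel *= self.b2
            vel += (1 - self.b2) * g * g
            update = (self.lr / bc1) * mom / (np.sqrt(vel / bc2) + self.eps)
            m.params[k] = (m.params[k] - update).astype(m.params[k].dtype)
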