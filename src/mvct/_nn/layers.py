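"""Minimal layer/module system with explicit forward tapes.

Each ``forward`` returns ``(output, tape)`` where the tape holds whatever the
matching ``backward`` needs.  Tapes are values, not layer state, so one module
can appear several times in a single training step (e.g. a generator used in
both halves of a cycle) without its caches clobbering each other.  ``backward``
accumulates parameter gradients into ``self.grads``.
"""

from __future__ import annotations

import numpy as np

from . import functional as F


class Module:
    """Base class: parameter bookkeeping plus the (forward, backward) contract."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._children: list[Module] = []

    def add_child(self, child: "Module") -> "Module":
        self._children.append(child)
        return child

    def modules(self):
        yield self
        for c in self._children:
            yield from c.modules()

    def parameters(self):
        """Yield (module, key) pairs for every trainable array."""
        for m in self.modules():
            for k in m.params:
                yield m, k

    def n_parameters(self) -> int:
        return sum(m.params[k].size for m, k in self.parameters())

    def zero_grad(self):
        for m in self.modules():
            for k in m.params:
                m.grads[k] = np.zeros_like(m.params[k])

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy, tape):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        y, _ = self.forward(x)
        return y

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, m in enumerate(self.modules()):
            for k, v in m.params.items():
                out[f"{i}.{k}"] = v
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for i, m in enumerate(self.modules()):
            for k in m.params:
                v = np.asarray(state[f"{i}.{k}"])
                if v.shape != m.params[k].shape:
                    raise ValueError(
                        f"shape mismatch for {i}.{k}: "
                        f"{v.shape} vs {m.params[k].shape}"
                    )
                m.params[k] = v.astype(m.params[k].dtype)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=None, *, rng, dtype=np.float32):
        super().__init__()
        self.stride = stride
        self.pad = (kernel - 1) // 2 if pad is None else pad
        w = rng.normal(0.0, 0.02, size=(out_ch, in_ch, kernel, kernel))
        self.params["w"] = w.astype(dtype)
        self.params["b"] = np.zeros(out_ch, dtype=dtype)

    def forward(self, x):
        return F.conv2d_forward(x, self.params["w"], self.params["b"], self.stride, self.pad)

    def backward(self, dy, tape):
        dx, dw, db = F.conv2d_backward(dy, self.params["w"], self.stride, self.pad, tape)
        self.grads["w"] += dw
        self.grads["b"] += db
        return dx


class ConvTranspose2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=2, pad=1, output_pad=1, *, rng, dtype=np.float32):
        super().__init__()
        self.stride, self.pad, self.output_pad = stride, pad, output_pad
        w = rng.normal(0.0, 0.02, size=(in_ch, out_ch, kernel, kernel))
        self.params["w"] = w.astype(dtype)
        self.params["b"] = np.zeros(out_ch, dtype=dtype)

    def forward(self, x):
        return F.conv_transpose2d_forward(
            x, self.params["w"], self.params["b"], self.stride, self.pad, self.output_pad
        )

    def backward(self, dy, tape):
        dx, dw, db = F.conv_transpose2d_backward(
            dy, self.params["w"], self.stride, self.pad, self.output_pad, tape
        )
        self.grads["w"] += dw
        self.grads["b"] += db
        return dx


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization with affine parameters."""

    def __init__(self, ch, eps=1e-5, *, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(ch, dtype=dtype)
        self.params["beta"] = np.zeros(ch, dtype=dtype)

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        y = self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]
        return y, (xhat, inv)

    def backward(self, dy, tape):
        xhat, inv = tape
        g = self.params["gamma"][None, :, None, None]
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        m = xhat.shape[2] * xhat.shape[3]
        dxhat = dy * g
        dx = inv * (
            dxhat
            - dxhat.mean(axis=(2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        )
        return dx


class ReLU(Module):
    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, dy, tape):
        return dy * tape


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        mask = x > 0
        y = np.where(mask, x, self.slope * x)
        return y, mask

    def backward(self, dy, tape):
        return np.where(tape, dy, self.slope * dy)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for l in self.layers:
            self.add_child(l)

    def forward(self, x):
        tapes = []
        for l in self.layers:
            x, t = l.forward(x)
            tapes.append(t)
        return x, tapes

    def backward(self, dy, tapes):
        for l, t in zip(reversed(self.layers), reversed(tapes)):
            dy = l.backward(dy, t)
        return dy


class ResidualAdd(Module):
    """y = x + body(x); optional ReLU after the addition."""

    def __init__(self, body: Module, relu_after=False):
        super().__init__()
        self.body = self.add_child(body)
        self.relu_after = relu_after

    def forward(self, x):
        h, t = self.body.forward(x)
        y = x + h
        mask = None
        if self.relu_after:
            mask = y > 0
            y = y * mask
        return y, (t, mask)

    def backward(self, dy, tape):
        t, mask = tape
        if mask is not None:
            dy = dy * mask
        dx_body = self.body.backward(dy, t)
        return dy + dx_body
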