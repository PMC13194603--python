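"""Network builders.

Three fixed families:

* ``rescnn`` generator — downsampling encoder (Conv-IN-ReLU x3, strides
  1/2/2, channels 32/64/128 by default, 7x7 first kernel), six residual
  transfer blocks, upsampling decoder (two Deconv-IN-ReLU blocks) and a 7x7
  output convolution.  Total downsampling factor 4.
* ``redcnn`` generator — fully convolutional encoder-decoder (no down/up
  sampling): 5 conv + 5 deconv layers, 96 channels, kernel 5, symmetric
  shortcut additions with ReLU after each addition and a linear output.
* ``patchgan`` discriminator — strided 4x4 convolutions with instance norm
  and leaky ReLU producing a spatial map of per-patch realness scores.

All sizes are spec fields so tiny desk-scale variants use the same machinery.
Generators output the full image (linear final activation); intensity
normalization to [-1, 1] is the data pipeline's job.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._nn import (
    Conv2d,
    ConvTranspose2d,
    InstanceNorm2d,
    LeakyReLU,
    Module,
    ReLU,
    ResidualAdd,
    Sequential,
)


@dataclass(frozen=True)
class GeneratorSpec:
    family: str = "rescnn"
    in_channels: int = 1
    base_channels: tuple[int, ...] = (32, 64, 128)
    n_residual_blocks: int = 6
    first_last_kernel: int = 7
    interior_kernel: int = 3
    redcnn_channels: int = 96
    redcnn_depth: int = 5
    redcnn_kernel: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("rescnn", "redcnn"):
            raise ValueError(f"unknown generator family {self.family!r}")
        if self.family == "rescnn" and len(self.base_channels) != 3:
            raise ValueError("rescnn expects three encoder channel counts")
        if self.family == "redcnn" and self.redcnn_depth < 1:
            raise ValueError("redcnn_depth must be >= 1")


@dataclass(frozen=True)
class DiscriminatorSpec:
    family: str = "patchgan"
    n_layers: int = 3
    base_channels: int = 64
    kernel: int = 4
    norm: str = "instance"  # "instance" or "none"
    seed: int = 0

    def __post_init__(self):
        if self.family != "patchgan":
            raise ValueError(f"unknown discriminator family {self.family!r}")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.norm not in ("instance", "none"):
            raise ValueError(f"unknown norm {self.norm!r}")


def tiny_generator_spec(family: str = "rescnn", seed: int = 0) -> GeneratorSpec:
    """Desk-scale variant for tests and CPU experiments."""
    return GeneratorSpec(
        family=family,
        base_channels=(4, 8, 16),
        n_residual_blocks=1,
        redcnn_channels=16,
        redcnn_depth=3,
        seed=seed,
    )


def tiny_discriminator_spec(seed: int = 0) -> DiscriminatorSpec:
    return DiscriminatorSpec(n_layers=2, base_channels=8, seed=seed)


class ResCNN(Module):
    """Encoder / residual transfer / decoder generator; downsampling factor 4."""

    downsample_factor = 4

    def __init__(self, spec: GeneratorSpec):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        c1, c2, c3 = spec.base_channels
        kf, ki = spec.first_last_kernel, spec.interior_kernel
        layers: list[Module] = [
            Conv2d(spec.in_channels, c1, kf, stride=1, rng=rng),
            InstanceNorm2d(c1),
            ReLU(),
            Conv2d(c1, c2, ki, stride=2, rng=rng),
            InstanceNorm2d(c2),
            ReLU(),
            Conv2d(c2, c3, ki, stride=2, rng=rng),
            InstanceNorm2d(c3),
            ReLU(),
        ]
        for _ in range(spec.n_residual_blocks):
            body = Sequential(
                Conv2d(c3, c3, ki, stride=1, rng=rng),
                InstanceNorm2d(c3),
                ReLU(),
                Conv2d(c3, c3, ki, stride=1, rng=rng),
                InstanceNorm2d(c3),
            )
            layers.append(ResidualAdd(body))
        layers += [
            ConvTranspose2d(c3, c2, ki, stride=2, pad=1, output_pad=1, rng=rng),
            InstanceNorm2d(c2),
            ReLU(),
            ConvTranspose2d(c2, c1, ki, stride=2, pad=1, output_pad=1, rng=rng),
            InstanceNorm2d(c1),
            ReLU(),
            Conv2d(c1, spec.in_channels, kf, stride=1, rng=rng),
        ]
        self.net = self.add_child(Sequential(*layers))

    def forward(self, x):
        h, w = x.shape[-2:]
        if h % self.downsample_factor or w % self.downsample_factor:
            raise ValueError(
                f"ResCNN input dims must be divisible by {self.downsample_factor}, "
                f"got {(h, w)}"
            )
        return self.net.forward(x)

    def backward(self, dy, tape):
        return self.net.backward(dy, tape)


class REDCNN(Module):
    """Fully convolutional encoder-decoder with symmetric shortcut additions.

    Shortcuts run from the input and every second encoder activation to the
    mirrored decoder layer output; ReLU is applied after each interior
    addition, the output layer is linear.
    """

    downsample_factor = 1

    def __init__(self, spec: GeneratorSpec):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        c = spec.redcnn_channels
        d = spec.redcnn_depth
        self.depth = d
        k = spec.redcnn_kernel
        self.convs = [
            self.add_child(
                Conv2d(spec.in_channels if i == 0 else c, c, k, stride=1, rng=rng)
            )
            for i in range(d)
        ]
        self.deconvs = [
            self.add_child(
                Conv2d(c, spec.in_channels if j == d - 1 else c, k, stride=1, rng=rng)
            )
            for j in range(d)
        ]
        # decoder layer j (1-based) gets a shortcut when j is odd: encoder
        # feature d-j (0 = the input itself)
        self.skip_at = {j for j in range(1, d + 1) if j % 2 == 1}

    def forward(self, x):
        feats = [x]
        tapes_enc = []
        h = x
        for conv in self.convs:
            h, t = conv.forward(h)
            mask = h > 0
            h = h * mask
            tapes_enc.append((t, mask))
            feats.append(h)
        tapes_dec = []
        for j, deconv in enumerate(self.deconvs, start=1):
            h, t = deconv.forward(h)
            skip_idx = None
            if j in self.skip_at:
                skip_idx = self.depth - j
                h = h + feats[skip_idx]
            mask = None
            if j < self.depth:
                mask = h > 0
                h = h * mask
            tapes_dec.append((t, skip_idx, mask))
        return h, (tapes_enc, tapes_dec)

    def backward(self, dy, tape):
        tapes_enc, tapes_dec = tape
        d = self.depth
        skip_grads: dict[int, np.ndarray] = {}
        g = dy
        for j in range(d, 0, -1):
            t, skip_idx, mask = tapes_dec[j - 1]
            if mask is not None:
                g = g * mask
            if skip_idx is not None:
                skip_grads[skip_idx] = skip_grads.get(skip_idx, 0) + g
            g = self.deconvs[j - 1].backward(g, t)
        for i in range(d, 0, -1):
            if i in skip_grads:  # grad into encoder activation i via shortcut
                g = g + skip_grads[i]
            t, mask = tapes_enc[i - 1]
            g = g * mask
            g = self.convs[i - 1].backward(g, t)
        if 0 in skip_grads:
            g = g + skip_grads[0]
        return g


class PatchGAN(Module):
    """Discriminator emitting a spatial score map (one score per local patch)."""

    def __init__(self, spec: DiscriminatorSpec):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        k = spec.kernel
        b = spec.base_channels
        def norm_of(ch):
            return [InstanceNorm2d(ch)] if spec.norm == "instance" else []

        layers: list[Module] = [Conv2d(1, b, k, stride=2, pad=1, rng=rng), LeakyReLU(0.2)]
        ch = b
        for _ in range(1, spec.n_layers):
            nxt = min(2 * ch, 8 * b)
            layers += [
                Conv2d(ch, nxt, k, stride=2, pad=1, rng=rng),
                *norm_of(nxt),
                LeakyReLU(0.2),
            ]
            ch = nxt
        nxt = min(2 * ch, 8 * b)
        layers += [
            Conv2d(ch, nxt, k, stride=1, pad=1, rng=rng),
            *norm_of(nxt),
            LeakyReLU(0.2),
            Conv2d(nxt, 1, k, stride=1, pad=1, rng=rng),
        ]
        self.net = self.add_child(Sequential(*layers))

    def forward(self, x):
        y, tape = self.net.forward(x)
        if y.shape[-1] < 1 or y.shape[-2] < 1:
            raise ValueError(f"input {x.shape[-2:]} smaller than the receptive field")
        return y, tape

    def backward(self, dy, tape):
        return self.net.backward(dy, tape)


def build_generator(spec: GeneratorSpec) -> Module:
    if spec.family == "rescnn":
        return ResCNN(spec)
    return REDCNN(spec)


def build_discriminator(spec: DiscriminatorSpec) -> Module:
    return PatchGAN(spec)


def patchgan_output_shape(spec: DiscriminatorSpec, input_shape: tuple[int, int]):
    """Closed-form score-map shape from stride/kernel arithmetic."""
    h, w = input_shape

    def conv_out(size, k, s, p):
        out = (size + 2 * p - k) // s + 1
        if out < 1:
            raise ValueError("input smaller than the receptive field")
        return out

    k = spec.kernel
    for _ in range(spec.n_layers):
        h, w = conv_out(h, k, 2, 1), conv_out(w, k, 2, 1)
    for _ in range(2):
        h, w = conv_out(h, k, 1, 1), conv_out(w, k, 1, 1)
    return h, w


def save_network(net: Module, spec, path: str | Path) -> Path:
    """Checkpoint = weights (npz) + the spec needed to rebuild the graph."""
    path = Path(path)
    kind = "generator" if isinstance(spec, GeneratorSpec) else "discriminator"
    np.savez(
        path,
        __spec__=json.dumps({"kind": kind, **asdict(spec)}),
        **net.state_dict(),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_network(path: str | Path):
    """Returns (net, spec) rebuilt from a checkpoint."""
    with np.load(str(path), allow_pickle=False) as data:
        meta = json.loads(str(data["__spec__"]))
        kind = meta.pop("kind")
        state = {k: data[k] for k in data.files if k != "__spec__"}
    if kind == "generator":
        meta["base_channels"] = tuple(meta["base_channels"])
        spec = GeneratorSpec(**meta)
        net = build_generator(spec)
    else:
        spec = DiscriminatorSpec(**meta)
        net = build_discriminator(spec)
    net.load_state_dict(state)
    return net, spec


def describe(net: Module, spec) -> str:
    lines = [f"{type(net).__name__}: {net.n_parameters():,} parameters"]
    lines.append(f"spec: {asdict(spec)}")
    return "\n".join(lines)
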