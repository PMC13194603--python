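"""Closed-form training losses for the unpaired translation stages.

Adversarial terms follow the least-squares GAN convention (real target 1,
fake target 0), averaged over the batch and over every position of the
discriminator's patch score map.  Cycle consistency is an L1 round-trip
penalty.  The stage-1 generator objective is

    L = L_gan(G_xy) + L_gan(G_yx) + lambda * L_cyc,   lambda = 10 by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

Array = np.ndarray


def _check_batch(batch: Array, name: str):
    batch = np.asarray(batch)
    if batch.size == 0 or batch.shape[0] == 0:
        raise ValueError(f"{name} is empty")
    return batch


def l1_mean(a: Array, b: Array) -> float:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a - b)))


def cycle_loss(x_batch: Array, y_batch: Array, g_xy, g_yx) -> float:
    """E_x |G_yx(G_xy(x)) - x|_1 + E_y |G_xy(G_yx(y)) - y|_1."""
    x = _check_batch(x_batch, "x_batch")
    y = _check_batch(y_batch, "y_batch")
    return l1_mean(g_yx(g_xy(x)), x) + l1_mean(g_xy(g_yx(y)), y)


def lsgan_d_loss(d, real_batch: Array, fake_batch: Array) -> float:
    """0.5 * [ mean((d(real) - 1)^2) + mean(d(fake)^2) ]."""
    real = _check_batch(real_batch, "real_batch")
    fake = _check_batch(fake_batch, "fake_batch")
    s_real = np.asarray(d(real), dtype=np.float64)
    s_fake = np.asarray(d(fake), dtype=np.float64)
    return 0.5 * (float(np.mean((s_real - 1.0) ** 2)) + float(np.mean(s_fake**2)))


def lsgan_g_loss(d, fake_batch: Array) -> float:
    """0.5 * mean((d(fake) - 1)^2)."""
    fake = _check_batch(fake_batch, "fake_batch")
    s = np.asarray(d(fake), dtype=np.float64)
    return 0.5 * float(np.mean((s - 1.0) ** 2))


def stage1_generator_objective(
    gan_xy: float, gan_yx: float, cycle: float, lam: float = 10.0
) -> float:
    """gan(G_xy) + gan(G_yx) + lambda * cycle."""
    if lam < 0:
        raise ValueError(f"lambda must be nonnegative, got {lam}")
    for v in (gan_xy, gan_yx, cycle):
        if not np.isfinite(v):
            raise ValueError("loss components must be finite")
    return float(gan_xy + gan_yx + lam * cycle)


@dataclass
class LossReport:
    """Per-iteration loss record written to the training log."""

    iteration: int
    cycle: float
    gan_g: float
    gan_d: float
    total: float
    lam: float
    extras: dict | None = None

    def as_dict(self) -> dict:
        d = {
            "iteration": self.iteration,
            "cycle": self.cycle,
            "gan_g": self.gan_g,
            "gan_d": self.gan_d,
            "total": self.total,
            "lambda": self.lam,
        }
        if self.extras:
            d.update(self.extras)
        return d
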