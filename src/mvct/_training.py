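"""Shared training plumbing: intensity normalization, patch sampling, batched
full-slice inference, and analytic gradients of the scalar losses."""

from __future__ import annotations

import numpy as np

from ._nn import Module

DEFAULT_HU_WINDOW = (-1000.0, 400.0)


def normalize(img: np.ndarray, window=DEFAULT_HU_WINDOW) -> np.ndarray:
    """Affine map of the Hounsfield window to [-1, 1] (values may exceed it)."""
    lo, hi = window
    return (2.0 * (np.asarray(img, dtype=np.float64) - lo) / (hi - lo) - 1.0).astype(
        np.float32
    )


def denormalize(img: np.ndarray, window=DEFAULT_HU_WINDOW) -> np.ndarray:
    lo, hi = window
    return (np.asarray(img, dtype=np.float64) + 1.0) * 0.5 * (hi - lo) + lo


def to_batch(images) -> np.ndarray:
    """Stack 2D arrays into an (N, 1, H, W) float32 batch."""
    return np.stack([np.asarray(im, dtype=np.float32) for im in images])[:, None]


def sample_patches(rng, images, patch: int, per_image: int) -> np.ndarray:
    """Random aligned-free patch crops; returns (len(images)*per_image,1,p,p)."""
    crops = []
    for im in images:
        h, w = im.shape
        if patch > h or patch > w:
            raise ValueError(f"patch_size {patch} exceeds slice dims {(h, w)}")
        for _ in range(per_image):
            i = int(rng.integers(0, h - patch + 1))
            j = int(rng.integers(0, w - patch + 1))
            crops.append(im[i : i + patch, j : j + patch])
    return to_batch(crops)


def l1_value_and_grad(pred: np.ndarray, target: np.ndarray):
    """mean |pred - target| and its gradient wrt pred."""
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff, dtype=pred.dtype) / diff.size


def lsgan_target_grad(scores: np.ndarray, target: float):
    """0.5 * mean((s - target)^2) and gradient wrt s."""
    d = scores - target
    return 0.5 * float(np.mean(d**2)), (d / d.size).astype(scores.dtype)


def _pad_to_multiple(img: np.ndarray, factor: int):
    h, w = img.shape
    ph = (-h) % factor
    pw = (-w) % factor
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
    return img, (h, w)


def apply_generator_slices(
    net: Module,
    slices,
    window=DEFAULT_HU_WINDOW,
    chunk: int = 16,
) -> list[np.ndarray]:
    """Full-slice inference: normalize -> (reflect-pad to the net's
    downsampling factor) -> batched forward -> crop -> denormalize."""
    factor = getattr(net, "downsample_factor", 1)
    out: list[np.ndarray] = []
    padded = []
    for s in slices:
        p, orig = _pad_to_multiple(normalize(s, window), factor)
        padded.append((p, orig))
    for start in range(0, len(padded), chunk):
        block = padded[start : start + chunk]
        batch = to_batch([p for p, _ in block])
        pred = net(batch)
        for k, (_, (h, w)) in enumerate(block):
            out.append(denormalize(pred[k, 0, :h, :w], window))
    return out
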