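"""Cycle-consistency-weighted fusion of view-complementary predictions.

For the three predictions aligned to one axial image, each view's reliability
is judged per pixel by mapping the prediction back to the reference domain
with the inverse generator and taking the absolute difference against the
real reference image:

    diff_v = | G_inv(pred_v) - reference |     (v in {a, s, c})
    Diff   = diff_a + diff_s + diff_c

    w_s = (diff_a + diff_c) / (2 * Diff)
    w_c = (diff_a + diff_s) / (2 * Diff)
    w_a = 1 - w_s - w_c

so the view with the *smallest* cycle-reconstruction error receives the
*largest* weight.  Weights sum to one at every pixel and each lies in
[0, 1/2] wherever Diff > 0; pixels with Diff == 0 (all views reconstruct
perfectly) degenerate to uniform 1/3 weights.  The fused pseudo-image is the
per-pixel convex combination of the three predictions; plain averaging is
kept as the ablation baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

Array = np.ndarray


def _unpack(triple) -> tuple[Array, Array, Array]:
    """Accept a ViewPredictionTriple-like object or a 3-sequence of arrays."""
    if hasattr(triple, "from_axial"):
        parts = (triple.from_axial, triple.from_sagittal, triple.from_coronal)
    else:
        parts = tuple(triple)
        if len(parts) != 3:
            raise ValueError("expected exactly three view predictions")
    a, s, c = (np.asarray(p, dtype=np.float64) for p in parts)
    if not (a.shape == s.shape == c.shape):
        raise ValueError(
            f"prediction shapes differ: {a.shape}, {s.shape}, {c.shape}"
        )
    return a, s, c


@dataclass
class DifferenceMaps:
    diff_a: Array
    diff_s: Array
    diff_c: Array

    def __post_init__(self):
        for name in ("diff_a", "diff_s", "diff_c"):
            m = np.asarray(getattr(self, name), dtype=np.float64)
            if np.any(m < 0):
                raise ValueError(f"{name} contains negative entries")
            setattr(self, name, m)
        if not (self.diff_a.shape == self.diff_s.shape == self.diff_c.shape):
            raise ValueError("difference maps must share one shape")

    @property
    def total(self) -> Array:
        return self.diff_a + self.diff_s + self.diff_c


@dataclass
class WeightMaps:
    w_a: Array
    w_s: Array
    w_c: Array

    def stack(self) -> Array:
        return np.stack([self.w_a, self.w_s, self.w_c])


def cycle_difference_maps(triple, reference: Array, inverse_generator) -> DifferenceMaps:
    """Per-view absolute reconstruction-error maps against ``reference``.

    ``inverse_generator`` maps a 2D prediction back to the reference's domain
    (pass ``lambda img: img`` for an identity check).
    """
    a, s, c = _unpack(triple)
    ref = np.asarray(reference, dtype=np.float64)
    if ref.shape != a.shape:
        raise ValueError(f"reference shape {ref.shape} != prediction shape {a.shape}")
    maps = [np.abs(np.asarray(inverse_generator(p), dtype=np.float64) - ref) for p in (a, s, c)]
    return DifferenceMaps(*maps)


def weight_maps_from_diffs(diffs: DifferenceMaps, per_pixel: bool = True) -> WeightMaps:
    """View weights from difference maps; uniform 1/3 where the total
    difference is zero.

    ``per_pixel=False`` collapses each difference map to its scalar mean
    first (one weight per view per image — an ablation mode, not the
    default).
    """
    if not per_pixel:
        diffs = DifferenceMaps(
            np.full_like(diffs.diff_a, diffs.diff_a.mean()),
            np.full_like(diffs.diff_s, diffs.diff_s.mean()),
            np.full_like(diffs.diff_c, diffs.diff_c.mean()),
        )
    total = diffs.total
    safe = np.where(total > 0, total, 1.0)
    w_s = 0.5 * (diffs.diff_a + diffs.diff_c) / safe
    w_c = 0.5 * (diffs.diff_a + diffs.diff_s) / safe
    w_a = 1.0 - w_s - w_c
    # exact degeneracies: where all three diffs coincide (including the
    # all-zero case) the formula collapses to exactly 1/3 per view
    equal = (diffs.diff_a == diffs.diff_s) & (diffs.diff_s == diffs.diff_c)
    if np.any(equal):
        third = 1.0 / 3.0
        w_a = np.where(equal, third, w_a)
        w_s = np.where(equal, third, w_s)
        w_c = np.where(equal, third, w_c)
    return WeightMaps(w_a=w_a, w_s=w_s, w_c=w_c)


def weighted_fuse(triple, weights: WeightMaps, tol: float = 1e-6) -> Array:
    """Convex per-pixel combination  w_a*p_a + w_s*p_s + w_c*p_c."""
    a, s, c = _unpack(triple)
    for w in (weights.w_a, weights.w_s, weights.w_c):
        if np.shape(w) not in ((), a.shape):
            raise ValueError("weight map shape incompatible with predictions")
    total = weights.w_a + weights.w_s + weights.w_c
    if np.max(np.abs(total - 1.0)) > tol:
        raise ValueError("weights do not sum to one within tolerance")
    return weights.w_a * a + weights.w_s * s + weights.w_c * c


def average_fuse(triple) -> Array:
    """Unweighted mean of the three predictions (the ablation baseline).

    Implemented as the uniform-weight case of :func:`weighted_fuse` so the
    equal-difference degeneracy of the weighted scheme reproduces it
    bit-exactly.
    """
    a, s, c = _unpack(triple)
    third = 1.0 / 3.0
    return third * a + third * s + third * c


def fuse_with_cycle_weights(triple, reference: Array, inverse_generator):
    """Convenience composition: diffs -> weights -> fused image.

    Returns (fused, weights, diffs).
    """
    diffs = cycle_difference_maps(triple, reference, inverse_generator)
    weights = weight_maps_from_diffs(diffs)
    return weighted_fuse(triple, weights), weights, diffs
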