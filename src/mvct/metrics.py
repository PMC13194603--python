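"""Image-quality metrics (PSNR, SSIM, relative MAE) and paired test-set
evaluation.

Conventions
-----------
* PSNR: ``10*log10(data_range^2 / MSE)``; identical inputs return ``inf``.
* SSIM: standard Gaussian-windowed formulation (k1=0.01, k2=0.03), delegated
  to scikit-image.
* RMAE: the exact published formula/scale for the relative mean absolute
  error is not recoverable, so this package uses the documented stand-in
  ``100 * sum|pred - ref| / sum|ref - offset|`` with ``offset = -1024`` (air
  floor) so the denominator is positive for Hounsfield-like data.  The scale
  and offset are configurable.
* Metrics are computed on full slices at native intensity scale, not on
  display-windowed images.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.metrics import structural_similarity

from .geometry import CTVolume

RMAE_OFFSET_HU = -1024.0


def _check_shapes(pred, ref):
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    return pred, ref


def psnr(pred, ref, data_range: float) -> float:
    """Peak signal-to-noise ratio in dB."""
    pred, ref = _check_shapes(pred, ref)
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((pred - ref) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(data_range**2 / mse)


def ssim(pred, ref, data_range: float, win_size: int | None = None) -> float:
    """Structural similarity (Gaussian window, k1=0.01, k2=0.03)."""
    pred, ref = _check_shapes(pred, ref)
    eff_win = win_size if win_size is not None else 11
    if eff_win > min(pred.shape):
        raise ValueError(f"window {eff_win} larger than image {pred.shape}")
    return float(
        structural_similarity(
            ref,
            pred,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            win_size=win_size,
        )
    )


def rmae(pred, ref, scale: float = 100.0, offset: float = RMAE_OFFSET_HU) -> float:
    """Relative mean absolute error: scale * sum|pred-ref| / sum|ref-offset|."""
    pred, ref = _check_shapes(pred, ref)
    denom = float(np.sum(np.abs(ref - offset)))
    if denom == 0.0:
        raise ValueError("reference is identically equal to the offset; RMAE undefined")
    return scale * float(np.sum(np.abs(pred - ref))) / denom


@dataclass
class MetricRecord:
    volume_id: str
    slice_index: int
    psnr: float
    ssim: float
    rmae: float


@dataclass
class EvaluationResult:
    records: list[MetricRecord]
    data_range: float

    def _values(self, name):
        return np.array([getattr(r, name) for r in self.records], dtype=np.float64)

    def summary(self) -> dict:
        out = {"n_slices": len(self.records), "data_range": self.data_range}
        for name in ("psnr", "ssim", "rmae"):
            v = self._values(name)
            finite = v[np.isfinite(v)]
            out[f"{name}_mean"] = float(finite.mean()) if finite.size else math.nan
            out[f"{name}_sd"] = float(finite.std(ddof=1)) if finite.size > 1 else 0.0
        return out

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", newline="") as f:
            writer = csv.writer(f)
            writer.writerow(["volume_id", "slice_index", "psnr", "ssim", "rmae"])
            for r in self.records:
                writer.writerow([r.volume_id, r.slice_index, r.psnr, r.ssim, r.rmae])
            s = self.summary()
            writer.writerow([])
            writer.writerow(["# summary"] + [f"{k}={v}" for k, v in s.items()])
        return path


def evaluate_testset(
    model,
    paired_test_volumes: list[tuple[CTVolume, CTVolume]],
    data_range: float | None = None,
) -> EvaluationResult:
    """Per-axial-slice metrics of ``model`` on paired (low, high) volumes.

    ``model`` is anything with a ``CTVolume -> CTVolume`` call path: a
    callable, an object with ``denoise``/``denoise_axial``, or ``None`` for
    the identity (which reproduces the noisy-input metric row).
    """
    if not paired_test_volumes:
        raise ValueError("no test volumes given")
    for ld, hd in paired_test_volumes:
        if ld.shape != hd.shape:
            raise ValueError(
                f"unpaired test input: shapes {ld.shape} vs {hd.shape} "
                f"({ld.volume_id!r}/{hd.volume_id!r})"
            )

    if data_range is None:
        lo = min(float(hd.intensities.min()) for _, hd in paired_test_volumes)
        hi = max(float(hd.intensities.max()) for _, hd in paired_test_volumes)
        data_range = hi - lo
        if data_range <= 0:
            raise ValueError("degenerate reference intensity range")

    if model is None:
        apply = lambda v: v  # noqa: E731
    elif callable(model):
        apply = model
    else:
        raise TypeError("model must be callable or None")

    records = []
    for ld, hd in paired_test_volumes:
        pred = apply(ld)
        if pred.shape != hd.shape:
            raise ValueError("model changed the volume shape")
        for i in range(hd.shape[0]):
            p, r = pred.intensities[i], hd.intensities[i]
            records.append(
                MetricRecord(
                    volume_id=hd.volume_id,
                    slice_index=i,
                    psnr=psnr(p, r, data_range),
                    ssim=ssim(p, r, data_range),
                    rmae=rmae(p, r),
                )
            )
    return EvaluationResult(records=records, data_range=data_range)
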