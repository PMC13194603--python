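"""Synthetic anisotropic CT phantoms and low-dose simulation.

High-dose ground truth is a piecewise-smooth phantom (air background, body
envelope, ellipsoidal inclusions).  Low-dose counterparts are produced either
by inserting Poisson noise into parallel-beam projection data of each axial
slice and reconstructing with filtered back-projection — which yields the
correlated, view-dependent streaky noise character of real low-dose scans —
or by a fast image-domain Gaussian fallback with variance proportional to
1/dose_factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import iradon, radon

from .geometry import CTVolume, SliceSet, split_volume

#: linear attenuation of water, mm^-1, at a representative diagnostic energy
MU_WATER = 0.0192

AIR_HU = -1000.0
BODY_HU = 40.0


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.5, 1.0, 1.0)
    n_structures: int = 6
    intensity_range: tuple[float, float] = (-1000.0, 400.0)
    seed: int = 0
    smooth_sigma: float = 1.0

    def __post_init__(self):
        if any(d < 8 for d in self.shape):
            raise ValueError(f"phantom dimensions must be >= 8, got {self.shape}")
        lo, hi = self.intensity_range
        if not lo < hi:
            raise ValueError(f"intensity_range must be ordered, got {self.intensity_range}")
        if self.n_structures < 0:
            raise ValueError("n_structures must be >= 0")


@dataclass(frozen=True)
class DoseSpec:
    dose_factor: float = 0.25
    incident_photons: float = 1e5
    noise_mode: str = "projection_poisson"
    seed: int = 0
    n_angles: int = 180
    gaussian_sigma_full_dose: float = 25.0  # HU, image_gaussian mode at dose 1

    def __post_init__(self):
        if not 0.0 < self.dose_factor <= 1.0:
            raise ValueError(f"dose_factor must be in (0, 1], got {self.dose_factor}")
        if self.incident_photons <= 0:
            raise ValueError("incident_photons must be positive")
        if self.noise_mode not in ("projection_poisson", "image_gaussian"):
            raise ValueError(f"unknown noise_mode {self.noise_mode!r}")


def _ellipsoid_mask(shape, center, semi_axes):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    az, ay, ax = semi_axes
    return (
        ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2
    ) <= 1.0


def generate_phantom(spec: PhantomSpec) -> CTVolume:
    """Deterministic piecewise-smooth phantom: body envelope + inclusions."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    lo, hi = spec.intensity_range

    vol = np.full(shape, AIR_HU, dtype=np.float64)
    center = tuple((d - 1) / 2.0 for d in shape)
    body_axes = tuple(0.46 * d for d in shape)
    body = _ellipsoid_mask(shape, center, body_axes)
    vol[body] = BODY_HU

    for _ in range(spec.n_structures):
        # keep inclusions inside the body envelope
        c = tuple(
            center[i] + rng.uniform(-0.25, 0.25) * shape[i] for i in range(3)
        )
        axes = tuple(rng.uniform(0.04, 0.16) * shape[i] for i in range(3))
        intensity = rng.uniform(-350.0, hi)
        mask = _ellipsoid_mask(shape, c, axes) & body
        vol[mask] = intensity

    if spec.smooth_sigma > 0:
        vol = gaussian_filter(vol, spec.smooth_sigma)
    np.clip(vol, lo, hi, out=vol)
    return CTVolume(vol, spacing=spec.spacing, volume_id=f"phantom{spec.seed}")


def hu_to_mu(hu: np.ndarray) -> np.ndarray:
    return np.maximum(MU_WATER * (1.0 + hu / 1000.0), 0.0)


def mu_to_hu(mu: np.ndarray) -> np.ndarray:
    return (mu / MU_WATER - 1.0) * 1000.0


def _fbp_slice(hu_slice, spacing_mm, theta, incident_photons, rng):
    """Forward-project one axial slice, optionally corrupt counts, reconstruct.

    ``incident_photons=None`` means noiseless (counts used exactly).
    """
    h, w = hu_slice.shape
    n = max(h, w)
    mu = hu_to_mu(hu_slice)
    if (h, w) != (n, n):  # pad to square with air (mu = 0)
        canvas = np.zeros((n, n), dtype=np.float64)
        oy, ox = (n - h) // 2, (n - w) // 2
        canvas[oy : oy + h, ox : ox + w] = mu
        mu = canvas
    else:
        oy = ox = 0
    sino = radon(mu, theta=theta, circle=False) * spacing_mm
    if incident_photons is not None:
        counts = incident_photons * np.exp(-sino)
        counts = rng.poisson(counts).astype(np.float64)
        np.maximum(counts, 1.0, out=counts)
        sino = -np.log(counts / incident_photons)
    recon = iradon(sino, theta=theta, circle=False, output_size=n) / spacing_mm
    recon = mu_to_hu(recon)
    return recon[oy : oy + h, ox : ox + w]


def simulate_low_dose(hdct: CTVolume, dose: DoseSpec) -> CTVolume:
    """Simulate a low-dose counterpart of ``hdct``.  Pure function: the input
    volume is left untouched and the output has the same shape and spacing."""
    rng = np.random.default_rng(dose.seed)
    if dose.noise_mode == "image_gaussian":
        sigma = dose.gaussian_sigma_full_dose / np.sqrt(dose.dose_factor)
        noisy = hdct.intensities + rng.normal(0.0, sigma, size=hdct.shape)
        return CTVolume(noisy, spacing=hdct.spacing, volume_id=hdct.volume_id + "_ld")

    theta = np.linspace(0.0, 180.0, dose.n_angles, endpoint=False)
    i0 = dose.incident_photons * dose.dose_factor
    spacing_mm = hdct.spacing[2]  # in-plane pixel size along x
    out = np.empty(hdct.shape, dtype=np.float64)
    for i in range(hdct.shape[0]):
        out[i] = _fbp_slice(hdct.intensities[i], spacing_mm, theta, i0, rng)
    return CTVolume(out, spacing=hdct.spacing, volume_id=hdct.volume_id + "_ld")


def fbp_reference(hdct: CTVolume, n_angles: int = 180) -> CTVolume:
    """Noiseless FBP round-trip of the clean projections (the zero-noise limit
    of :func:`simulate_low_dose` in projection mode)."""
    theta = np.linspace(0.0, 180.0, n_angles, endpoint=False)
    spacing_mm = hdct.spacing[2]
    out = np.empty(hdct.shape, dtype=np.float64)
    for i in range(hdct.shape[0]):
        out[i] = _fbp_slice(hdct.intensities[i], spacing_mm, theta, None, None)
    return CTVolume(out, spacing=hdct.spacing, volume_id=hdct.volume_id + "_fbp")


@dataclass
class SliceRecord:
    """One 2D slice with provenance back to its source volume."""

    source_id: str
    index: int
    image: np.ndarray


@dataclass
class UnpairedSliceDataset:
    low: list[SliceRecord]
    high: list[SliceRecord]
    view: str
    paired: bool = False

    def __post_init__(self):
        shapes = {r.image.shape for r in self.low} | {r.image.shape for r in self.high}
        if len(shapes) > 1:
            raise ValueError(
                f"mixed slice shapes within view {self.view!r}: {sorted(shapes)}; "
                "cannot batch"
            )

    @property
    def slice_shape(self):
        return self.low[0].image.shape if self.low else None


def _records(volumes: list[CTVolume], view: str) -> list[SliceRecord]:
    recs = []
    for v in volumes:
        ss = split_volume(v, view)
        recs.extend(
            SliceRecord(source_id=v.volume_id, index=i, image=s)
            for i, s in enumerate(ss.slices)
        )
    return recs


def build_unpaired_dataset(
    ldct_volumes: list[CTVolume],
    hdct_volumes: list[CTVolume],
    view: str,
    shuffle_seed: int | None = 0,
) -> UnpairedSliceDataset:
    """Split volumes into view-specific slice pools; independently shuffle each
    pool to destroy pairing (``shuffle_seed=None`` keeps pairing, for test sets).
    """
    if not ldct_volumes or not hdct_volumes:
        raise ValueError("volume lists must be nonempty")
    low = _records(ldct_volumes, view)
    high = _records(hdct_volumes, view)
    paired = True
    if shuffle_seed is not None:
        rng = np.random.default_rng(shuffle_seed)
        rng.shuffle(low)
        rng.shuffle(high)
        paired = False
    return UnpairedSliceDataset(low=low, high=high, view=view, paired=paired)
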