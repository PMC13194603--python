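"""Volume I/O: NIfTI and a raw-array container with a JSON sidecar.

NIfTI files are reoriented to closest-canonical (RAS) at load time and the
data array is transposed to the package's (z, y, x) convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import CTVolume


def save_nifti(volume: CTVolume, path: str | Path) -> Path:
    path = Path(path)
    # internal (z,y,x) -> NIfTI (x,y,z)
    data = np.ascontiguousarray(volume.intensities.transpose(2, 1, 0))
    sz, sy, sx = volume.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((sx, sy, sz))
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path, volume_id: str | None = None) -> CTVolume:
    path = Path(path)
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D NIfTI volume, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    return CTVolume(
        np.ascontiguousarray(data.transpose(2, 1, 0)),
        spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        volume_id=volume_id or path.name.split(".")[0],
    )


def save_raw(volume: CTVolume, path: str | Path) -> Path:
    """Write ``<path>.raw`` (C-order binary) plus ``<path>.json`` sidecar."""
    path = Path(path)
    raw = path.with_suffix(".raw")
    sidecar = path.with_suffix(".json")
    arr = np.ascontiguousarray(volume.intensities)
    arr.tofile(raw)
    sidecar.write_text(
        json.dumps(
            {
                "shape": list(arr.shape),
                "spacing": list(volume.spacing),
                "dtype": arr.dtype.str,
                "axis_order": "zyx",
                "volume_id": volume.volume_id,
            },
            indent=2,
        )
    )
    return raw


def load_raw(path: str | Path) -> CTVolume:
    path = Path(path)
    raw = path.with_suffix(".raw")
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    arr = np.fromfile(raw, dtype=np.dtype(meta["dtype"])).reshape(meta["shape"])
    return CTVolume(
        arr,
        spacing=tuple(meta["spacing"]),
        volume_id=meta.get("volume_id", path.stem),
    )


def load_volume(path: str | Path) -> CTVolume:
    """Dispatch on extension: .nii/.nii.gz or raw container."""
    name = str(path)
    if name.endswith((".nii", ".nii.gz")):
        return load_nifti(path)
    return load_raw(path)
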