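"""Volume/slice geometry: lossless splitting of 3D volumes into 2D slice sets
per anatomical view, and exact reassembly.

Canonical axis order is (z, y, x): axis 0 = axial slice index, axis 1 =
coronal, axis 2 = sagittal.  Splitting is pure indexing — no interpolation,
no resampling — so ``stack_slices(split_volume(v, view)) == v`` bit-exactly
for every view, regardless of anisotropic spacing (spacing travels along as
metadata only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VIEWS = ("axial", "sagittal", "coronal")

#: canonical array axis sliced by each view
VIEW_AXIS = {"axial": 0, "coronal": 1, "sagittal": 2}


def _check_view(view: str) -> str:
    if view not in VIEWS:
        raise ValueError(f"unknown view {view!r}; expected one of {VIEWS}")
    return view


@dataclass
class CTVolume:
    """A 3D intensity volume in Hounsfield-like units, axes ordered (z, y, x)."""

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    volume_id: str = ""
    axis_order: str = field(default="zyx", repr=False)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.intensities.ndim}")
        if any(d < 1 for d in self.intensities.shape):
            raise ValueError(f"degenerate shape {self.intensities.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        if self.axis_order != "zyx":
            raise ValueError("axis_order must be the canonical 'zyx'")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def copy(self) -> "CTVolume":
        return CTVolume(self.intensities.copy(), self.spacing, self.volume_id)


@dataclass
class SliceSet:
    """Ordered 2D slices extracted from one view of a volume."""

    view: str
    slices: list[np.ndarray]
    source_shape: tuple[int, int, int]
    source_id: str = ""
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        _check_view(self.view)
        self.source_shape = tuple(int(d) for d in self.source_shape)
        axis = VIEW_AXIS[self.view]
        if len(self.slices) != self.source_shape[axis]:
            raise ValueError(
                f"{self.view} slice count {len(self.slices)} does not match "
                f"source dimension {self.source_shape[axis]}"
            )
        expected = tuple(d for i, d in enumerate(self.source_shape) if i != axis)
        for s in self.slices:
            if s.shape != expected:
                raise ValueError(f"slice shape {s.shape} != expected {expected}")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def slice_shape(self) -> tuple[int, int]:
        axis = VIEW_AXIS[self.view]
        return tuple(d for i, d in enumerate(self.source_shape) if i != axis)


def split_volume(volume: CTVolume, view: str) -> SliceSet:
    """Split ``volume`` into 2D slices along the given view's axis.

    axial: z slices of (y, x); coronal: y slices of (z, x);
    sagittal: x slices of (z, y).  Pure indexing, lossless.
    """
    _check_view(view)
    axis = VIEW_AXIS[view]
    moved = np.moveaxis(volume.intensities, axis, 0)
    slices = [np.ascontiguousarray(moved[i]) for i in range(moved.shape[0])]
    return SliceSet(
        view=view,
        slices=slices,
        source_shape=volume.shape,
        source_id=volume.volume_id,
        spacing=volume.spacing,
    )


def stack_slices(slice_set: SliceSet) -> CTVolume:
    """Exact inverse of :func:`split_volume`: place slices back at their
    original voxel coordinates."""
    axis = VIEW_AXIS[slice_set.view]
    stacked = np.stack(slice_set.slices, axis=0)
    vol = np.moveaxis(stacked, 0, axis)
    if vol.shape != slice_set.source_shape:
        raise ValueError(
            f"restacked shape {vol.shape} inconsistent with source "
            f"{slice_set.source_shape}"
        )
    return CTVolume(
        np.ascontiguousarray(vol),
        spacing=slice_set.spacing,
        volume_id=slice_set.source_id,
    )


def resplit_axial(volume: CTVolume) -> SliceSet:
    """Convenience composition: ``split_volume(volume, "axial")``."""
    return split_volume(volume, "axial")
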