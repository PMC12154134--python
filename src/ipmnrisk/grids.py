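"""Voxel-grid containers shared by every pipeline stage.

A :class:`VolumeGrid` is a 3D scalar intensity array together with its
physical voxel spacing in millimetres; a :class:`MaskVolume` is a binary
array on the same grid.  Axis order is (x, y, z) with z the slice axis,
so ``spacing[2]`` is the slice thickness.  NIfTI round-tripping goes
through nibabel with the spacing written into the affine diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "MaskVolume", "load_volume", "load_mask"]


@dataclass
class VolumeGrid:
    """3D intensity volume with per-axis voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.data.copy(), self.spacing)

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))


@dataclass
class MaskVolume:
    """Binary ROI volume on the same grid as its companion :class:`VolumeGrid`."""

    values: np.ndarray
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be binary {0, 1}")
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        self.values = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def sum(self) -> int:
        return int(self.values.sum())

    def copy(self) -> "MaskVolume":
        return MaskVolume(self.values.copy(), self.spacing)

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag([*self.spacing, 1.0])
        nib.save(nib.Nifti1Image(self.values.astype(np.uint8), affine), str(path))


def _spacing_from(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def load_volume(path: str | Path) -> VolumeGrid:
    img = nib.load(str(path))
    return VolumeGrid(np.asarray(img.dataobj, dtype=np.float64), _spacing_from(img))


def load_mask(path: str | Path) -> MaskVolume:
    img = nib.load(str(path))
    vals = (np.asarray(img.dataobj) > 0.5).astype(np.uint8)
    return MaskVolume(vals, _spacing_from(img))
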