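"""Core gridded data types and NIfTI I/O.

An adaptive-radiotherapy course is a sequence of 3D images (planning CT,
per-fraction CBCT or synthetic CT) with per-structure binary contours, all
resampled to one voxel grid.  Displacement fields live on the same grid and
are stored in voxel units.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

MIN_DIM = 8


class GridMismatchError(ValueError):
    """Two gridded objects that must share a grid do not."""


@dataclasses.dataclass
class ImageVolume:
    """A 3D scalar image with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"image must be 3D, got shape {self.data.shape}")
        if any(s < MIN_DIM for s in self.data.shape):
            raise ValueError(f"all dimensions must be >= {MIN_DIM}, got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclasses.dataclass
class StructureSet:
    """Named binary masks sharing one grid, in a fixed structure order."""

    masks: dict[str, np.ndarray]

    def __post_init__(self):
        if not self.masks:
            self.masks = {}
            return
        shapes = set()
        clean = {}
        for name, m in self.masks.items():
            arr = np.asarray(m)
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"mask '{name}' is not binary")
            clean[name] = arr.astype(np.uint8)
            shapes.add(arr.shape)
        if len(shapes) > 1:
            raise GridMismatchError(f"masks on different grids: {shapes}")
        self.masks = clean

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    @property
    def shape(self):
        return next(iter(self.masks.values())).shape if self.masks else None

    def __len__(self):
        return len(self.masks)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]


@dataclasses.dataclass
class DisplacementField:
    """Per-voxel displacement (voxel units), shape (D, H, W, 3)."""

    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(f"DVF must have shape (D, H, W, 3), got {self.vectors.shape}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("DVF contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    @property
    def max_norm(self) -> float:
        return float(np.sqrt((self.vectors ** 2).sum(axis=-1)).max())


# -- NIfTI I/O ----------------------------------------------------------

def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def save_image(img: ImageVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(img.data.astype(np.float32), _affine(img.spacing)), str(path))


def load_image(path: str | Path) -> ImageVolume:
    n = nib.load(str(path))
    spacing = tuple(float(z) for z in n.header.get_zooms()[:3])
    return ImageVolume(np.asarray(n.dataobj, dtype=np.float64), spacing)


def save_mask(mask: np.ndarray, path: str | Path, spacing=(1.0, 1.0, 1.0)) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing)), str(path))


def load_mask(path: str | Path) -> np.ndarray:
    return (np.asarray(nib.load(str(path)).dataobj) > 0.5).astype(np.uint8)


def save_dvf(dvf: DisplacementField, path: str | Path, spacing=(1.0, 1.0, 1.0)) -> None:
    nib.save(nib.Nifti1Image(dvf.vectors.astype(np.float32), _affine(spacing)), str(path))


def load_dvf(path: str | Path) -> DisplacementField:
    return DisplacementField(np.asarray(nib.load(str(path)).dataobj, dtype=np.float64))
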