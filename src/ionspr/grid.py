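"""Voxel grids and scalar volumes — the common currency of all stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass(frozen=True)
class Grid3D:
    """Axis-aligned voxel grid: shape, isotropic-or-not spacing (mm), origin (mm).

    World coordinates refer to voxel centers: x_world = origin + index * spacing.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous index coordinates of world points (mm); shape (..., 3)."""
        return (np.asarray(points_mm, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij")

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (mm) of all voxel centers."""
        ii, jj, kk = self.index_grids()
        o, s = self.origin, self.spacing
        return o[0] + ii * s[0], o[1] + jj * s[1], o[2] + kk * s[2]

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class ScalarVolume:
    """A scalar field (CT number, ED, EAN, SPR, dose) on a grid."""

    data: np.ndarray
    grid: Grid3D

    def __post_init__(self) -> None:
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise ValueError("data shape does not match grid")

    def same_grid(self, other: "ScalarVolume") -> bool:
        return (
            self.grid.shape == other.grid.shape
            and np.allclose(self.grid.spacing, other.grid.spacing)
            and np.allclose(self.grid.origin, other.grid.origin)
        )

    def to_nifti(self, path: str | Path, dtype=np.float32) -> None:
        img = nib.Nifti1Image(self.data.astype(dtype), self.grid.affine())
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ScalarVolume":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(aff[i, i]) for i in range(3))
        origin = tuple(float(aff[i, 3]) for i in range(3))
        data = np.asarray(img.dataobj)
        return cls(data=np.asarray(data), grid=Grid3D(tuple(data.shape), spacing, origin))
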