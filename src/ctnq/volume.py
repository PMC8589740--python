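"""Minimal 3D volume container used throughout the pipeline.

A :class:`Volume` couples a scalar (or integer label) grid with a NIfTI-style
4x4 voxel-to-world affine.  All pipeline stages exchange volumes rather than
bare arrays so that voxel spacing and orientation travel with the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume"]


@dataclass
class Volume:
    """A 3D image with a voxel-to-world affine map.

    Parameters
    ----------
    data:
        3D array of intensities, probabilities or integer labels.
    affine:
        4x4 voxel-index -> world-mm map (NIfTI convention).
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume requires a 3D array, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm along each axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    def like(self, data: np.ndarray) -> "Volume":
        """New volume with the same grid and the given data."""
        return Volume(np.asarray(data), self.affine.copy())

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())

    # -- I/O ----------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arr = self.data
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        nib.save(nib.Nifti1Image(arr, self.affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Volume":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj), np.asarray(img.affine))
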