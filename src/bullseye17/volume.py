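"""Scalar CT volume container with physical geometry.

The whole package works on a single in-memory representation: a float32
Hounsfield-unit array indexed ``[x, y, z]`` together with a per-axis voxel
spacing and a world-space origin (mm).  The world frame is the NIfTI RAS
frame with an axis-aligned affine ``diag(spacing) @ index + origin``; slices
are taken along z, and after short-axis alignment the apex sits at the lowest
z index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

AIR_HU = -1024.0


@dataclass
class Volume3D:
    """A 3D scalar volume (HU) on a regular anisotropic grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities in Hounsfield units.
    spacing : ndarray, shape (3,)
        Voxel size along x, y, z in mm.
    origin : ndarray, shape (3,)
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 3:
            raise ValueError("Volume3D.data must be 3-dimensional")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")

    # ---- geometry -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.spacing + self.origin

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing

    def contains_world(self, world: np.ndarray) -> bool:
        idx = self.world_to_index(world)
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.array(self.shape) - 0.5))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    # ---- I/O -------------------------------------------------------------
    def save_nifti(self, path: str) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_zooms(tuple(self.spacing))
        nib.save(img, path)

    @classmethod
    def load_nifti(cls, path: str) -> "Volume3D":
        img = nib.load(path)
        aff = img.affine
        rot = aff[:3, :3]
        if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
            raise ValueError("only axis-aligned NIfTI volumes are supported")
        spacing = np.diag(rot).copy()
        origin = aff[:3, 3].copy()
        data = np.asanyarray(img.dataobj).astype(np.float32)
        # normalise negative spacings (flipped axes) to a positive-step grid
        for ax in range(3):
            if spacing[ax] < 0:
                data = np.flip(data, axis=ax)
                origin[ax] = origin[ax] + spacing[ax] * (data.shape[ax] - 1)
                spacing[ax] = -spacing[ax]
        return cls(data=data, spacing=spacing, origin=origin)


def save_label_nifti(labels: np.ndarray, like: "Volume3D | None", path: str,
                     spacing=None, origin=None) -> None:
    """Save an integer label volume as NIfTI, borrowing geometry from a volume."""
    if like is not None:
        spacing, origin = like.spacing, like.origin
    vol = Volume3D(np.zeros_like(labels, dtype=np.float32), spacing, origin)
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), vol.affine)
    nib.save(img, path)


def load_label_nifti(path: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Load an integer label volume; returns (labels, spacing, origin)."""
    vol = Volume3D.load_nifti(path)
    return vol.data.astype(np.int16), vol.spacing, vol.origin
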