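"""Short-axis reorientation of the cardiac volume.

The short-axis view is defined by the LV long axis, the line from the center
of the mitral valve to the apex.  A single rigid rotation takes that axis
onto the slice normal (+z, apex at the lower slice index) and the volume is
resampled onto an axis-aligned grid: trilinear interpolation for HU,
out-of-field voxels filled with air (-1024 HU), in-plane spacing made
isotropic at the finer of the two input in-plane spacings, slice spacing
preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import AIR_HU, Volume3D


@dataclass
class Landmarks:
    """Manually placed LV landmarks in world (mm) coordinates.

    SP1/SP2/SP3 are the seed points used by the region-growing step: SP1 the
    midpoint of apex and endo-apex, SP2 the midpoint of the long axis, SP3
    the mitral-valve center.
    """

    mitral_center: np.ndarray
    apex: np.ndarray
    endo_apex: np.ndarray

    def __post_init__(self) -> None:
        self.mitral_center = np.asarray(self.mitral_center, dtype=float).reshape(3)
        self.apex = np.asarray(self.apex, dtype=float).reshape(3)
        self.endo_apex = np.asarray(self.endo_apex, dtype=float).reshape(3)
        if np.allclose(self.apex, self.mitral_center):
            raise ValueError("apex and mitral center must differ")

    @property
    def sp1(self) -> np.ndarray:
        return (self.apex + self.endo_apex) / 2.0

    @property
    def sp2(self) -> np.ndarray:
        return (self.apex + self.mitral_center) / 2.0

    @property
    def sp3(self) -> np.ndarray:
        return self.mitral_center

    @property
    def long_axis(self) -> np.ndarray:
        """Unit vector pointing from apex to mitral center."""
        v = self.mitral_center - self.apex
        return v / np.linalg.norm(v)

    def transformed(self, rot: np.ndarray, center: np.ndarray) -> "Landmarks":
        f = lambda p: rot @ (p - center) + center  # noqa: E731
        return Landmarks(mitral_center=f(self.mitral_center), apex=f(self.apex),
                         endo_apex=f(self.endo_apex))

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({k: list(map(float, getattr(self, k)))
                       for k in ("mitral_center", "apex", "endo_apex")}, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "Landmarks":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**{k: np.array(d[k]) for k in ("mitral_center", "apex", "endo_apex")})


def rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector v onto +z (Rodrigues)."""
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    ez = np.array([0.0, 0.0, 1.0])
    axis = np.cross(v, ez)
    s = np.linalg.norm(axis)
    c = float(np.dot(v, ez))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 degrees about x
        return np.diag([1.0, -1.0, -1.0])
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    ang = np.arctan2(s, c)
    return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)


def reorient_short_axis(vol: Volume3D, lm: Landmarks,
                        order: int = 1, fill: float = AIR_HU
                        ) -> tuple[Volume3D, Landmarks]:
    """Rigidly rotate + resample the volume into the short-axis frame.

    After the call the mitral->apex direction is parallel to the slice
    normal with the apex at the lower slice index, and the landmarks are
    transformed consistently.  ``order=0`` gives nearest-neighbour sampling
    (for label/mask volumes).
    """
    for name in ("mitral_center", "apex", "endo_apex"):
        if not vol.contains_world(getattr(lm, name)):
            raise ValueError(f"landmark {name} lies outside the volume")
    axis = lm.mitral_center - lm.apex
    n = np.linalg.norm(axis)
    if n < 1e-9:
        raise ValueError("degenerate long axis: apex equals mitral center")
    rot = rotation_to_z(axis / n)
    center = lm.sp2

    # output grid: isotropic in-plane at the finer input in-plane spacing
    sp_in = vol.spacing
    out_spacing = np.array([min(sp_in[0], sp_in[1]), min(sp_in[0], sp_in[1]), sp_in[2]])

    # bounds of the rotated input bounding box
    lo_w = vol.origin
    hi_w = vol.index_to_world(np.array(vol.shape) - 1)
    corners = np.array([[x, y, z]
                        for x in (lo_w[0], hi_w[0])
                        for y in (lo_w[1], hi_w[1])
                        for z in (lo_w[2], hi_w[2])])
    rc = (corners - center) @ rot.T + center
    lo = rc.min(axis=0)
    hi = rc.max(axis=0)
    out_shape = np.ceil((hi - lo) / out_spacing).astype(int) + 1
    out_origin = lo

    ox = out_origin[0] + out_spacing[0] * np.arange(out_shape[0])
    oy = out_origin[1] + out_spacing[1] * np.arange(out_shape[1])
    oz = out_origin[2] + out_spacing[2] * np.arange(out_shape[2])
    X, Y, Z = np.meshgrid(ox, oy, oz, indexing="ij")
    W = np.stack([X, Y, Z], axis=-1)
    # inverse map: output world -> input world -> input index
    Win = (W - center) @ rot + center
    idx = (Win - vol.origin) / vol.spacing
    coords = np.moveaxis(idx, -1, 0)
    out = ndimage.map_coordinates(vol.data, coords, order=order, mode="constant",
                                  cval=fill, prefilter=(order > 1))

    out_vol = Volume3D(data=out.astype(np.float32), spacing=out_spacing,
                       origin=out_origin)
    out_lm = lm.transformed(rot, center)
    return out_vol, out_lm
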