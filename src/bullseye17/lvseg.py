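"""Left-ventricle segmentation: seeded region growing, 10-point spline
contours, mask construction and aortic-root removal.

The blood pool is recovered as the 26-connected component above the 200 HU
contrast threshold that contains the mid-long-axis seed; the epicardial
extent uses the same machinery at a lower threshold that includes the
myocardium.  Per slice, a closed periodic cubic spline through 10 control
points (ray-cast from the component centroid to its directional extent)
models each border, the masks are polygon fills of those splines, and the
aortic root is finally carved out of the basal septal sector by strict
HU > 200 thresholding with a morphological closing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline
from shapely.geometry import Polygon
from skimage.draw import polygon2mask

from .alignment import Landmarks
from .angles import alpha_from_theta, septum_span, theta_of
from .volume import Volume3D

N_CONTROL_POINTS = 10  # fixed size of the closed spline contour model
DEFAULT_HU_MIN = 200.0       # blood-pool threshold (contrast blood > 200 HU)
DEFAULT_HU_EPI_MIN = 50.0    # epicardial threshold: myocardium + blood


@dataclass
class Contour:
    """A closed spline contour on one short-axis slice.

    ``control_points`` are 10 ordered in-plane world coordinates (mm); the
    curve through them is a periodic interpolating cubic spline with uniform
    parameterization.
    """

    slice_index: int
    role: str  # "epicardial" | "endocardial"
    control_points: np.ndarray

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.control_points.shape != (N_CONTROL_POINTS, 2):
            raise ValueError(
                f"contour must have exactly {N_CONTROL_POINTS} control points")
        if self.role not in ("epicardial", "endocardial"):
            raise ValueError(f"unknown contour role {self.role!r}")

    def dense(self, n: int = 720) -> np.ndarray:
        """Sample the closed spline at n points (does not repeat the start)."""
        pts = np.vstack([self.control_points, self.control_points[:1]])
        t = np.arange(N_CONTROL_POINTS + 1, dtype=float)
        cs = CubicSpline(t, pts, bc_type="periodic", axis=0)
        return cs(np.linspace(0.0, N_CONTROL_POINTS, n, endpoint=False))


@dataclass
class ContourStack:
    """Epicardial and endocardial contours for a contiguous run of slices.

    Apex-cap slices (solid wall, no chamber) carry an epicardial contour
    only.  Grid geometry is kept so masks can be rasterized.
    """

    epi: dict[int, Contour]
    endo: dict[int, Contour]
    spacing: np.ndarray
    origin: np.ndarray
    shape: tuple[int, int, int]

    @property
    def slices(self) -> list[int]:
        return sorted(self.epi)

    def to_json(self, path: str) -> None:
        recs = []
        for d in (self.epi, self.endo):
            for c in d.values():
                recs.append({"slice_index": c.slice_index, "role": c.role,
                             "control_points": c.control_points.tolist()})
        with open(path, "w") as fh:
            json.dump({"contours": recs,
                       "spacing": self.spacing.tolist(),
                       "origin": self.origin.tolist(),
                       "shape": list(self.shape)}, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "ContourStack":
        with open(path) as fh:
            d = json.load(fh)
        epi, endo = {}, {}
        for rec in d["contours"]:
            c = Contour(rec["slice_index"], rec["role"],
                        np.array(rec["control_points"]))
            (epi if c.role == "epicardial" else endo)[c.slice_index] = c
        return cls(epi=epi, endo=endo, spacing=np.array(d["spacing"]),
                   origin=np.array(d["origin"]), shape=tuple(d["shape"]))


@dataclass
class LVMask:
    """Voxel masks of the segmented LV: myocardium and chamber are disjoint."""

    myocardium: np.ndarray = field(repr=False)
    chamber: np.ndarray = field(repr=False)
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.myocardium & self.chamber):
            raise ValueError("myocardium and chamber masks overlap")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def myocardial_slices(self) -> np.ndarray:
        return np.where(self.myocardium.any(axis=(0, 1)))[0]

    def to_labels(self) -> np.ndarray:
        """0 background, 1 myocardium, 2 chamber."""
        lab = np.zeros(self.myocardium.shape, dtype=np.int16)
        lab[self.myocardium] = 1
        lab[self.chamber] = 2
        return lab

    @classmethod
    def from_labels(cls, lab: np.ndarray, spacing, origin) -> "LVMask":
        return cls(myocardium=lab == 1, chamber=lab == 2,
                   spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# seeded region growing
# ---------------------------------------------------------------------------

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def region_grow(vol: Volume3D, lm: Landmarks,
                hu_min: float = DEFAULT_HU_MIN) -> np.ndarray:
    """3D connected component >= hu_min containing the long-axis seed.

    Returns a boolean voxel set: the 26-connected component of the
    thresholded volume that contains SP2 (falling back to SP1 then SP3 if
    SP2 sits below threshold), clipped to the slices between the apex and
    the mitral plane.
    """
    above = vol.data >= hu_min
    seeds = {"SP2": lm.sp2, "SP1": lm.sp1, "SP3": lm.sp3}
    seed_idx = {}
    failed = []
    for name, world in seeds.items():
        idx = np.round(vol.world_to_index(world)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(vol.shape)):
            raise ValueError(f"seed {name} lies outside the volume")
        if above[tuple(idx)]:
            seed_idx[name] = idx
        else:
            failed.append(name)
    if not seed_idx:
        raise ValueError(
            "no voxel >= hu_min at any seed point (failed: " + ", ".join(failed) + ")")

    labels, _ = ndimage.label(above, structure=_STRUCT26)
    for name in ("SP2", "SP1", "SP3"):
        if name in seed_idx:
            comp_label = labels[tuple(seed_idx[name])]
            break
    comp = labels == comp_label

    z_apex = int(np.round(vol.world_to_index(lm.apex)[2]))
    z_mitral = int(np.round(vol.world_to_index(lm.mitral_center)[2]))
    z_lo, z_hi = min(z_apex, z_mitral), max(z_apex, z_mitral)
    comp[:, :, :max(z_lo, 0)] = False
    comp[:, :, z_hi + 1:] = False
    return comp


# ---------------------------------------------------------------------------
# initial contours
# ---------------------------------------------------------------------------

def initial_contour(component_slice: np.ndarray, spacing2, origin2,
                    slice_index: int, role: str) -> Contour:
    """Place 10 control points at the directional extent of a slice component.

    Rays are cast from the component centroid at 36-degree steps; each
    control point sits at the farthest in-component sample along its ray
    (the maximum boundary of the connected component in that direction).
    """
    comp = np.asarray(component_slice, dtype=bool)
    spacing2 = np.asarray(spacing2, dtype=float)
    origin2 = np.asarray(origin2, dtype=float)
    if not comp.any():
        raise ValueError(f"empty slice component at slice {slice_index}")
    ii, jj = np.nonzero(comp)
    if (ii.max() - ii.min() + 1) < 2 or (jj.max() - jj.min() + 1) < 2:
        raise ValueError(
            f"slice {slice_index} component thinner than 2 voxels")

    c_mm = np.array([ii.mean() * spacing2[0], jj.mean() * spacing2[1]])
    max_r = float(np.hypot((ii.max() - ii.min() + 2) * spacing2[0],
                           (jj.max() - jj.min() + 2) * spacing2[1]))
    step = 0.25 * float(spacing2.min())
    rho = np.arange(0.0, max_r + step, step)

    pts = np.empty((N_CONTROL_POINTS, 2))
    for k in range(N_CONTROL_POINTS):
        ang = np.radians(360.0 * k / N_CONTROL_POINTS)
        d = np.array([np.cos(ang), np.sin(ang)])
        sample = c_mm[None, :] + rho[:, None] * d[None, :]
        si = np.round(sample[:, 0] / spacing2[0]).astype(int)
        sj = np.round(sample[:, 1] / spacing2[1]).astype(int)
        ok = (si >= 0) & (si < comp.shape[0]) & (sj >= 0) & (sj < comp.shape[1])
        inside = np.zeros(len(rho), dtype=bool)
        inside[ok] = comp[si[ok], sj[ok]]
        hit = np.nonzero(inside)[0]
        r_max = rho[hit[-1]] if hit.size else 0.0
        pts[k] = c_mm + r_max * d
    return Contour(slice_index=slice_index, role=role,
                   control_points=pts + origin2)


def contours_from_component(comp: np.ndarray, vol: Volume3D,
                            role: str) -> dict[int, Contour]:
    """Fit an initial contour on every slice where the component is usable."""
    out: dict[int, Contour] = {}
    for z in np.where(comp.any(axis=(0, 1)))[0]:
        try:
            out[int(z)] = initial_contour(comp[:, :, z], vol.spacing[:2],
                                          vol.origin[:2], int(z), role)
        except ValueError:
            continue  # slices too thin to contour are dropped
    return out


# ---------------------------------------------------------------------------
# mask construction
# ---------------------------------------------------------------------------

def _fill_polygon(curve_mm: np.ndarray, spacing2, origin2,
                  shape2: tuple[int, int]) -> np.ndarray:
    poly_idx = (curve_mm - np.asarray(origin2)) / np.asarray(spacing2)
    return polygon2mask(shape2, poly_idx)


def build_lv_mask(stack: ContourStack, spacing=None) -> LVMask:
    """Rasterize the contour stack into myocardium and chamber masks.

    Myocardium is the region between the endo- and epicardial splines on
    each slice (the full epicardial fill on apex-cap slices without an
    endocardial contour); the chamber is the endocardial fill.
    """
    spacing = stack.spacing if spacing is None else np.asarray(spacing, dtype=float)
    myo = np.zeros(stack.shape, dtype=bool)
    cham = np.zeros(stack.shape, dtype=bool)
    shape2 = stack.shape[:2]
    for z in stack.slices:
        epi_curve = stack.epi[z].dense()
        epi_fill = _fill_polygon(epi_curve, spacing[:2], stack.origin[:2], shape2)
        if z in stack.endo:
            endo_curve = stack.endo[z].dense()
            epi_poly = Polygon(epi_curve).buffer(1e-6)
            if not epi_poly.covers(Polygon(endo_curve)):
                raise ValueError(
                    f"endocardial contour outside epicardial contour on slice {z}")
            endo_fill = _fill_polygon(endo_curve, spacing[:2], stack.origin[:2], shape2)
            myo[:, :, z] = epi_fill & ~endo_fill
            cham[:, :, z] = endo_fill
        else:
            myo[:, :, z] = epi_fill
    return LVMask(myocardium=myo, chamber=cham, spacing=spacing,
                  origin=stack.origin)


# ---------------------------------------------------------------------------
# aortic-root removal
# ---------------------------------------------------------------------------

def _ellipsoid_structure(radius_mm: float, spacing) -> np.ndarray:
    r_vox = np.maximum(np.round(radius_mm / np.asarray(spacing)).astype(int), 0)
    if np.all(r_vox == 0):
        return np.ones((1, 1, 1), dtype=bool)
    ax = [np.arange(-r, r + 1) for r in r_vox]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = sum((np.where(r > 0, g / max(r, 1), 0.0)) ** 2
                for g, r in zip((X, Y, Z), r_vox))
    return d <= 1.0 + 1e-9


def remove_aortic_root(mask: LVMask, vol: Volume3D,
                       hu_thresh: float = DEFAULT_HU_MIN,
                       morph_radius_mm: float = 2.0,
                       sector: tuple[float, float] | None = None,
                       basal_fraction: float = 1.0 / 3.0) -> LVMask:
    """Carve the aortic root out of the basal septal sector of the LV mask.

    The root is the set of myocardial-mask voxels strictly above
    ``hu_thresh`` (200 HU by default) within the septal angular sector on
    the basal portion of the stack, closed by dilate-then-erode so the
    lower-intensity valve is included, then removed from both compartments.

    Parameters
    ----------
    sector : (anterior_deg, posterior_deg) or None
        Septal arc about the per-slice myocardial centroid (anterior to
        posterior groove in segment order).  ``None`` disables the angular
        restriction.
    basal_fraction : float
        Fraction of the slice stack, counted down from the base, that is
        searched.  Use 1.0 to search every slice.
    """
    zs = mask.myocardial_slices
    if zs.size == 0:
        return mask
    n_basal = max(int(np.ceil(len(zs) * basal_fraction)), 1)
    basal_slices = set(int(z) for z in zs[-n_basal:])

    candidate = np.zeros_like(mask.myocardium)
    for z in zs:
        if int(z) not in basal_slices:
            continue
        sl = mask.myocardium[:, :, z]
        if not sl.any():
            continue
        hot = sl & (vol.data[:, :, z] > hu_thresh)
        if sector is not None and hot.any():
            ii, jj = np.nonzero(sl)
            ci, cj = ii.mean(), jj.mean()
            hi, hj = np.nonzero(hot)
            theta = theta_of((hi - ci) * mask.spacing[0],
                             (hj - cj) * mask.spacing[1])
            anterior, posterior = sector
            span = septum_span(anterior, posterior)
            keep = alpha_from_theta(theta, anterior) < span
            hot = np.zeros_like(hot)
            hot[hi[keep], hj[keep]] = True
        candidate[:, :, z] = hot

    if not candidate.any():
        return mask  # nothing exceeds the threshold: no-op

    if morph_radius_mm > 0:
        struct = _ellipsoid_structure(morph_radius_mm, mask.spacing)
        removed = ndimage.binary_closing(candidate, structure=struct)
    else:
        removed = candidate
    return LVMask(myocardium=mask.myocardium & ~removed,
                  chamber=mask.chamber & ~removed,
                  spacing=mask.spacing, origin=mask.origin)


# ---------------------------------------------------------------------------
# high-level driver
# ---------------------------------------------------------------------------

def segment_lv(vol: Volume3D, lm: Landmarks,
               hu_min: float = DEFAULT_HU_MIN,
               hu_epi_min: float = DEFAULT_HU_EPI_MIN
               ) -> tuple[ContourStack, LVMask]:
    """Run region growing and contour fitting; return contours and masks.

    The endocardial border comes from the blood-pool component
    (>= ``hu_min``), the epicardial border from the component at the lower
    ``hu_epi_min`` threshold which includes the myocardium.
    """
    blood = region_grow(vol, lm, hu_min=hu_min)
    lvall = region_grow(vol, lm, hu_min=hu_epi_min)
    epi = contours_from_component(lvall, vol, role="epicardial")
    endo = contours_from_component(blood, vol, role="endocardial")
    endo = {z: c for z, c in endo.items() if z in epi}
    stack = ContourStack(epi=epi, endo=endo, spacing=vol.spacing,
                         origin=vol.origin, shape=vol.shape)
    mask = build_lv_mask(stack)
    return stack, mask
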