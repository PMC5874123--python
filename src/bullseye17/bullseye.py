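"""Bull's-eye polar projection, wall-thickness measurement and segment areas.

The LV is unrolled onto a fixed-radius polar raster with the apex at the
center and the mitral plane at the rim.  Ring boundaries sit at one-third
and two-thirds of the maximum radius (mid/apical and basal/mid); within each
ring the radius encodes the proportional long-axis position of the slice.
Wall thickness is measured per slice and sample angle as the distance from
the endocardial border point at that angle to the closest point of the
epicardial border on the same slice.  Segment areas are obtained by
counting raster pixels per label and converting with the square of the
display dot pitch (0.2692 mm for the reference monitor), reported in cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .angles import ang_diff, theta_of, wrap_deg
from .lvseg import ContourStack, LVMask
from .segments17 import APEX_LABEL, SLABS, SegmentLabelMap

DEFAULT_DOT_PITCH_MM = 0.2692  # reference display pixel size
DEFAULT_DENSITY_G_PER_CM3 = 1.05  # myocardial tissue density


@dataclass
class BullseyeSpec:
    """Geometry of the polar raster."""

    size: int = 512                      # square canvas, pixels
    max_radius: float = 255.0            # R, pixels
    apex_cap_radius: float | None = None  # segment-17 disc; default R/6
    dot_pitch_mm: float = DEFAULT_DOT_PITCH_MM

    def __post_init__(self) -> None:
        if self.apex_cap_radius is None:
            self.apex_cap_radius = self.max_radius / 6.0
        R = self.max_radius
        if not (0 < self.apex_cap_radius < R / 3.0 < 2.0 * R / 3.0 < R <= self.size / 2.0):
            raise ValueError(
                "require apex_cap_radius < R/3 < 2R/3 < R <= size/2")

    @property
    def ring_radii(self) -> tuple[float, float]:
        """(mid/apical, basal/mid) boundary radii in pixels."""
        return (self.max_radius / 3.0, 2.0 * self.max_radius / 3.0)


@dataclass
class ThicknessField:
    """Wall thickness sampled on a (slice, angle) grid.

    Rows are ordered apex to base and cover the non-apex slices (those with
    an endocardial border).  ``endo_points``/``epi_points`` hold the
    endocardial sample and its closest epicardial point (world mm).
    """

    z_slices: np.ndarray                 # (ns,)
    angles_deg: np.ndarray               # (na,)
    thickness_mm: np.ndarray = field(repr=False)   # (ns, na)
    endo_points: np.ndarray = field(repr=False)    # (ns, na, 2)
    epi_points: np.ndarray = field(repr=False)     # (ns, na, 2)
    centers: np.ndarray = field(repr=False)        # (ns, 2)

    @property
    def midwall_points(self) -> np.ndarray:
        return (self.endo_points + self.epi_points) / 2.0


@dataclass
class BullseyeRaster:
    """Polar raster of a quantitative parameter plus segment labels."""

    values: np.ndarray = field(repr=False)   # (size, size), NaN outside
    labels: np.ndarray = field(repr=False)   # (size, size) int16, 0 outside
    spec: BullseyeSpec = field(default_factory=BullseyeSpec)
    boundary_angles: dict = field(default_factory=dict)  # slab -> [deg, ...]

    @property
    def center_px(self) -> float:
        return (self.spec.size - 1) / 2.0


# ---------------------------------------------------------------------------
# centerline
# ---------------------------------------------------------------------------

def compute_centerline(stack: ContourStack) -> dict[int, np.ndarray]:
    """Per-slice myocardial center: mean of epi- and endocardial centroids.

    On apex-cap slices (no endocardial border) the epicardial centroid
    alone is used.
    """
    centers: dict[int, np.ndarray] = {}
    for z in stack.slices:
        epi_c = np.asarray(Polygon(stack.epi[z].dense()).centroid.coords[0])
        if z in stack.endo:
            endo_c = np.asarray(Polygon(stack.endo[z].dense()).centroid.coords[0])
            centers[z] = (epi_c + endo_c) / 2.0
        else:
            centers[z] = epi_c
    if not centers:
        raise ValueError("empty contour stack")
    return centers


# ---------------------------------------------------------------------------
# thickness
# ---------------------------------------------------------------------------

def _closest_on_polyline(points: np.ndarray, poly: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Distance and closest point from each query point to a closed polyline."""
    a = poly
    b = np.roll(poly, -1, axis=0)
    ab = b - a                                       # (k, 2)
    denom = np.maximum((ab * ab).sum(axis=1), 1e-12)
    ap = points[:, None, :] - a[None, :, :]          # (m, k, 2)
    t = np.clip((ap * ab[None, :, :]).sum(axis=2) / denom[None, :], 0.0, 1.0)
    proj = a[None, :, :] + t[..., None] * ab[None, :, :]
    d2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    k = np.argmin(d2, axis=1)
    m = np.arange(len(points))
    return np.sqrt(d2[m, k]), proj[m, k]


def _thickness_slice(endo: np.ndarray, epi: np.ndarray, center: np.ndarray,
                     angles: np.ndarray):
    """Per-angle endocardial point and its closest epicardial distance."""
    th_e = theta_of(endo[:, 0] - center[0], endo[:, 1] - center[1])
    # nearest dense endocardial sample per target angle (wrap-aware)
    dmat = np.abs(ang_diff(th_e[None, :], angles[:, None]))
    pts = endo[np.argmin(dmat, axis=1)]
    dist, proj = _closest_on_polyline(pts, epi)
    return pts, proj, dist


def measure_thickness(stack: ContourStack,
                      centers: dict[int, np.ndarray] | None = None,
                      angular_step: float = 1.0,
                      dense_n: int = 720) -> ThicknessField:
    """Closest-point wall thickness on every slice with both borders.

    For each sample angle the endocardial point at that angle from the
    slice center is located and the thickness is its Euclidean distance to
    the nearest point of the epicardial border on the same slice.
    """
    centers = centers or compute_centerline(stack)
    z_list = sorted(z for z in stack.slices if z in stack.endo)
    if not z_list:
        raise ValueError("no slice carries both borders; cannot measure thickness")
    angles = np.arange(0.0, 360.0, angular_step)
    na = len(angles)
    ns = len(z_list)
    thick = np.empty((ns, na))
    endo_pts = np.empty((ns, na, 2))
    epi_pts = np.empty((ns, na, 2))
    ctr = np.empty((ns, 2))
    for i, z in enumerate(z_list):
        if z not in stack.epi:
            raise ValueError(f"missing epicardial contour on slice {z}")
        c = centers[z]
        endo = stack.endo[z].dense(dense_n)
        epi = stack.epi[z].dense(dense_n)
        endo_pts[i], epi_pts[i], thick[i] = _thickness_slice(endo, epi, c, angles)
        ctr[i] = c
    return ThicknessField(z_slices=np.array(z_list), angles_deg=angles,
                          thickness_mm=thick, endo_points=endo_pts,
                          epi_points=epi_pts, centers=ctr)


def measure_thickness_from_mask(mask: LVMask,
                                angular_step: float = 1.0) -> ThicknessField:
    """Closest-point wall thickness measured on the voxel masks directly.

    Sub-voxel borders are traced with marching squares on the chamber
    (endocardial) and chamber+myocardium (epicardial) masks.  Unlike the
    10-control-point contour model this resolves sharp regional thickening
    at the voxel scale; accuracy is limited by voxelization (about half a
    voxel per border).
    """
    from skimage import measure as skmeasure

    angles = np.arange(0.0, 360.0, angular_step)
    na = len(angles)
    z_list = [int(z) for z in mask.myocardial_slices
              if mask.chamber[:, :, z].any()]
    if not z_list:
        raise ValueError("no slice carries both borders; cannot measure thickness")
    sp2 = mask.spacing[:2]
    or2 = mask.origin[:2]
    ns = len(z_list)
    thick = np.empty((ns, na))
    endo_pts = np.empty((ns, na, 2))
    epi_pts = np.empty((ns, na, 2))
    ctr = np.empty((ns, 2))
    for i, z in enumerate(z_list):
        cham = mask.chamber[:, :, z]
        lv = cham | mask.myocardium[:, :, z]
        endo = max(skmeasure.find_contours(cham.astype(float), 0.5), key=len)
        epi = max(skmeasure.find_contours(lv.astype(float), 0.5), key=len)
        endo = endo * sp2 + or2
        epi = epi * sp2 + or2
        c = (Polygon(endo).centroid.coords[0] + np.asarray(
            Polygon(epi).centroid.coords[0])) / 2.0
        endo_pts[i], epi_pts[i], thick[i] = _thickness_slice(endo, epi, c, angles)
        ctr[i] = c
    return ThicknessField(z_slices=np.array(z_list), angles_deg=angles,
                          thickness_mm=thick, endo_points=endo_pts,
                          epi_points=epi_pts, centers=ctr)


def sample_labels(labels: SegmentLabelMap, fld: ThicknessField) -> np.ndarray:
    """Segment label per (slice, angle) sample: that of the nearest
    myocardial voxel to the midwall point of the sample."""
    out = np.zeros(fld.thickness_mm.shape, dtype=np.int16)
    mid = fld.midwall_points
    for i, z in enumerate(fld.z_slices):
        sl = labels.data[:, :, z]
        ii, jj = np.nonzero(sl > 0)
        if ii.size == 0:
            continue
        coords = np.stack([ii * labels.spacing[0] + labels.origin[0],
                           jj * labels.spacing[1] + labels.origin[1]], axis=1)
        tree = cKDTree(coords)
        _, nearest = tree.query(mid[i])
        out[i] = sl[ii[nearest], jj[nearest]]
    return out


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project_bullseye(fld: ThicknessField, labels: SegmentLabelMap,
                     spec: BullseyeSpec | None = None) -> BullseyeRaster:
    """Inverse-map every raster pixel to (slice, sample angle).

    The radial bands [cap, R/3), [R/3, 2R/3), [2R/3, R] map linearly onto
    the apical, mid and basal slice groups so that the printed ring circles
    coincide exactly with the slab boundaries; pixels inside the apex cap
    take segment 17 with the value of the innermost measured slice.
    """
    spec = spec or BullseyeSpec()
    if fld.thickness_mm.size == 0:
        raise ValueError("empty thickness field")
    if labels.wedges:
        # exact angular rule recorded by the divider: no voxel quantization
        seg_samples = np.stack([labels.labels_at(int(z), fld.angles_deg)
                                for z in fld.z_slices])
    else:
        seg_samples = sample_labels(labels, fld)

    slab_rows: dict[str, list[int]] = {s: [] for s in SLABS}
    for i, z in enumerate(fld.z_slices):
        slab = labels.slabs.get(int(z))
        if slab in slab_rows:
            slab_rows[slab].append(i)

    size = spec.size
    c = (size - 1) / 2.0
    col, row = np.meshgrid(np.arange(size), np.arange(size), indexing="xy")
    x = col - c
    y = c - row
    r = np.hypot(x, y)
    theta = theta_of(x, y)
    ang_idx = np.round(theta / (fld.angles_deg[1] - fld.angles_deg[0])).astype(int) \
        % len(fld.angles_deg)

    R = spec.max_radius
    cap = spec.apex_cap_radius
    r1, r2 = spec.ring_radii
    bands = [("apical", cap, r1), ("mid", r1, r2), ("basal", r2, R)]

    values = np.full((size, size), np.nan)
    lab = np.zeros((size, size), dtype=np.int16)

    in_cap = r < cap
    lab[in_cap] = APEX_LABEL
    values[in_cap] = fld.thickness_mm[0][ang_idx[in_cap]]

    all_rows = list(range(len(fld.z_slices)))
    for slab, lo, hi in bands:
        rows = slab_rows[slab] or all_rows  # fallback if a slab is unpopulated
        sel = (r >= lo) & (r <= hi) if slab == "basal" else (r >= lo) & (r < hi)
        f = (r[sel] - lo) / (hi - lo)
        k = np.minimum((f * len(rows)).astype(int), len(rows) - 1)
        srow = np.asarray(rows)[k]
        values[sel] = fld.thickness_mm[srow, ang_idx[sel]]
        lab[sel] = seg_samples[srow, ang_idx[sel]]

    boundary_angles = _boundary_angles(seg_samples, fld, labels, slab_rows)
    return BullseyeRaster(values=values, labels=lab, spec=spec,
                          boundary_angles=boundary_angles)


def _boundary_angles(seg_samples: np.ndarray, fld: ThicknessField,
                     labels: SegmentLabelMap,
                     slab_rows: dict[str, list[int]]) -> dict[str, np.ndarray]:
    """Circumferential wedge-boundary angles per slab (middle slice)."""
    out = {}
    angles = fld.angles_deg
    step = angles[1] - angles[0]
    for slab, rows in slab_rows.items():
        if not rows:
            continue
        mid_row = rows[len(rows) // 2]
        z = int(fld.z_slices[mid_row])
        if z in labels.wedges:
            ref, starts, _ = labels.wedges[z]
            out[slab] = wrap_deg(ref - np.asarray(starts, dtype=float))
        else:
            rowv = seg_samples[mid_row]
            jumps = np.nonzero(rowv != np.roll(rowv, 1))[0]
            out[slab] = wrap_deg(angles[jumps] - step / 2.0)
    return out


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def segment_areas(raster: BullseyeRaster, spec: BullseyeSpec | None = None
                  ) -> pd.DataFrame:
    """Per-segment bull's-eye area: pixel count times dot pitch squared (cm^2)."""
    spec = spec or raster.spec
    if not (raster.labels > 0).any():
        raise ValueError("raster carries no segment labels")
    vals, cts = np.unique(raster.labels[raster.labels > 0], return_counts=True)
    counts = pd.Series(cts, index=vals).reindex(range(1, 18), fill_value=0)
    area_cm2 = counts * spec.dot_pitch_mm ** 2 / 100.0
    return pd.DataFrame({"segment": counts.index, "pixels": counts.to_numpy(),
                         "area_cm2": area_cm2.to_numpy()})


def segment_scalars(labels: SegmentLabelMap, fld: ThicknessField, mask: LVMask,
                    density: float = DEFAULT_DENSITY_G_PER_CM3) -> pd.DataFrame:
    """Per-segment 3D scalars: maximum wall thickness (mm) and mass (g).

    Thickness samples contribute to the segment of their nearest myocardial
    voxel; segments with no thickness sample (e.g. the apex cap) report NaN
    rather than zero.  Mass is labeled voxel count x voxel volume x density.
    """
    seg_samples = sample_labels(labels, fld)
    voxvol_cm3 = mask.voxel_volume_mm3 / 1000.0
    counts = labels.counts()
    rows = []
    for s in range(1, 18):
        sel = seg_samples == s
        tmax = float(np.max(fld.thickness_mm[sel])) if sel.any() else np.nan
        rows.append({"segment": s, "max_thickness_mm": tmax,
                     "mass_g": counts[s] * voxvol_cm3 * density})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def save_bullseye_png(raster: BullseyeRaster, path: str,
                      cmap: str = "gray", title: str | None = None) -> None:
    """Write the raster as a PNG with ring and segment-boundary overlays."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec = raster.spec
    c = raster.center_px
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(raster.values, cmap=cmap, origin="upper")
    for rr in (*spec.ring_radii, spec.max_radius, spec.apex_cap_radius):
        ax.add_patch(plt.Circle((c, c), rr, fill=False, color="tab:red", lw=0.8))
    band = {"apical": (spec.apex_cap_radius, spec.ring_radii[0]),
            "mid": spec.ring_radii,
            "basal": (spec.ring_radii[1], spec.max_radius)}
    for slab, angs in raster.boundary_angles.items():
        lo, hi = band.get(slab, (0, spec.max_radius))
        for a in np.atleast_1d(angs):
            t = np.radians(a)
            # raster x right, y up with row index down
            ax.plot([c + lo * np.cos(t), c + hi * np.cos(t)],
                    [c - lo * np.sin(t), c - hi * np.sin(t)],
                    color="tab:red", lw=0.8)
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8, label="thickness (mm)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
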