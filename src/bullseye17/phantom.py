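"""Synthetic contrast-CT left-ventricle phantoms with known ground truth.

The phantom emulates a contrast-enhanced LV on ECG-gated cardiac CT: a
bright blood pool inside a mid-intensity myocardial shell, an optional
bright aortic-root region contaminating the basal septum, and a dark
background.  Geometrically it is a truncated half-ellipsoid: per short-axis
slice the epicardial border is an ellipse scaled by the ellipsoid height
profile and the endocardial border is the epicardial border shrunk by the
(possibly angle-dependent) wall thickness, so the in-plane wall width equals
the requested thickness everywhere the chamber exists.  The apex is a solid
cap, the base is open at the mitral plane.

The interventricular grooves are encoded as ground-truth angles only (no
image ridge); downstream code consumes them through the same annotation
pathway a human operator would use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .alignment import Landmarks
from .angles import ang_diff, septum_span, theta_from_alpha, wrap_deg
from .volume import Volume3D

#: HU threshold separating blood pool from myocardium throughout the method.
BLOOD_POOL_HU_THRESHOLD = 200.0


@dataclass
class ThickPatch:
    """A localized wall-thickening patch (e.g. a hypertrophic septal bulge).

    ``center_theta_deg`` is the absolute in-plane angle of the patch center.
    The added thickness follows a raised-cosine profile peaking at
    ``extra_mm`` in the center and tapering to zero at ``width_deg/2`` away
    (hypertrophy is smooth; a hard-edged step could not be represented by a
    10-control-point spline contour anyway).
    """

    center_theta_deg: float
    width_deg: float
    extra_mm: float

    def extra_at(self, theta_deg) -> np.ndarray:
        d = np.abs(ang_diff(theta_deg, self.center_theta_deg))
        half = self.width_deg / 2.0
        return np.where(d <= half,
                        self.extra_mm * 0.5 * (1.0 + np.cos(np.pi * d / half)),
                        0.0)


@dataclass
class PhantomSpec:
    """Parameters of a synthetic LV phantom.

    Defaults describe a control-like adult LV: 70 mm long axis, 30 mm
    epicardial radius at the base, 10 mm uniform wall, 120 degree septal arc,
    contrast-opacified blood at 350 HU over 100 HU myocardium.
    """

    long_axis_len: float = 70.0              # mm, mitral plane to apex tip
    epi_radii: tuple[float, float] = (30.0, 30.0)  # mm, basal ellipse semi-axes
    wall_thickness: float = 10.0             # mm, uniform in-plane wall width
    thick_patch: ThickPatch | None = None    # optional regional thickening
    septum_span_deg: float = 120.0           # groove-to-groove septal arc
    groove_anterior_deg: float = 60.0        # absolute angle of anterior groove
    groove_twist_deg_per_slice: float = 0.0  # base-to-apex groove rotation
    hu_blood: float = 350.0
    hu_myo: float = 100.0
    hu_root: float = 400.0
    hu_background: float = -80.0
    include_aortic_root: bool = False
    aortic_root_radius_mm: float = 8.0
    aortic_root_height_mm: float = 15.0
    aortic_root_clearance_mm: float = 3.0   # keep root off the blood pool
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation_tilt_deg: float = 0.0        # tilt of long axis vs volume z
    noise_sd: float = 0.0                    # HU
    seed: int = 0
    margin_mm: float = 8.0

    @property
    def groove_posterior_deg(self) -> float:
        return float(wrap_deg(self.groove_anterior_deg - self.septum_span_deg))

    def validate(self) -> None:
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")
        if min(self.voxel_spacing) <= 0:
            raise ValueError("voxel spacing must be positive")
        if not (0 < self.septum_span_deg < 360):
            raise ValueError("septum_span_deg must lie in (0, 360)")
        if not (0 <= self.groove_anterior_deg < 360):
            raise ValueError("groove angles must lie in [0, 360)")
        if self.long_axis_len <= self.wall_thickness:
            raise ValueError("long axis must exceed the wall thickness")
        if min(self.epi_radii) <= self.wall_thickness:
            raise ValueError("epicardial radii must exceed the wall thickness")
        if self.hu_myo >= BLOOD_POOL_HU_THRESHOLD:
            raise ValueError(
                "hu_myo must stay below the 200 HU blood-pool threshold that "
                "separates chamber from myocardium downstream")
        if self.hu_blood <= BLOOD_POOL_HU_THRESHOLD:
            raise ValueError(
                "hu_blood must exceed the 200 HU blood-pool threshold that "
                "separates chamber from myocardium downstream")

    def to_json(self, path: str) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "PhantomSpec":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("thick_patch") is not None:
            d["thick_patch"] = ThickPatch(**d["thick_patch"])
        for key in ("epi_radii", "voxel_spacing"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom (world mm coordinates)."""

    mitral_center: np.ndarray
    apex: np.ndarray
    endo_apex: np.ndarray
    groove_angles: pd.DataFrame          # slice_index, anterior_deg, posterior_deg
    septum_span_deg: float
    wall_thickness: float
    thick_patch: ThickPatch | None
    long_axis_dir: np.ndarray            # unit vector apex -> mitral center
    myocardium: np.ndarray = field(repr=False)
    chamber: np.ndarray = field(repr=False)
    root: np.ndarray = field(repr=False)

    @property
    def landmarks(self) -> Landmarks:
        return Landmarks(mitral_center=self.mitral_center, apex=self.apex,
                         endo_apex=self.endo_apex)

    def thickness_at(self, theta_deg) -> np.ndarray:
        """True in-plane wall thickness (mm) at absolute angle(s) theta."""
        t = np.full(np.shape(np.asarray(theta_deg, dtype=float)), self.wall_thickness)
        if self.thick_patch is not None:
            t = t + self.thick_patch.extra_at(theta_deg)
        return t

    @property
    def septal_area_fraction(self) -> float:
        """True fraction of each ring occupied by the septal arc."""
        return self.septum_span_deg / 360.0

    def to_json(self, path: str) -> None:
        d = {
            "mitral_center": list(map(float, self.mitral_center)),
            "apex": list(map(float, self.apex)),
            "endo_apex": list(map(float, self.endo_apex)),
            "septum_span_deg": self.septum_span_deg,
            "wall_thickness": self.wall_thickness,
            "long_axis_dir": list(map(float, self.long_axis_dir)),
            "groove_angles": self.groove_angles.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def _ellipse_radius(a: float, b: float, theta_rad: np.ndarray) -> np.ndarray:
    """Radius of an axis-aligned ellipse at polar angle theta."""
    return a * b / np.hypot(b * np.cos(theta_rad), a * np.sin(theta_rad))


def _tilt_rotation(tilt_deg: float) -> np.ndarray:
    """Rotation about the y axis tilting the phantom long axis off +z."""
    t = np.radians(tilt_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def generate_lv_phantom(spec: PhantomSpec) -> tuple[Volume3D, PhantomTruth]:
    """Voxelize a phantom LV and return the volume plus its ground truth.

    The phantom frame puts the apex tip at the origin and the mitral-plane
    center at (0, 0, L); an optional rigid tilt about the y axis is applied
    before voxelization to exercise short-axis alignment.
    """
    spec.validate()
    a, b = spec.epi_radii
    L = spec.long_axis_len
    m = spec.margin_mm
    R = _tilt_rotation(spec.orientation_tilt_deg)
    pivot = np.array([0.0, 0.0, L / 2.0])

    # world-frame bounds: rotate the untilted bounding box
    corners = np.array([[sx, sy, sz]
                        for sx in (-a - m, a + m)
                        for sy in (-b - m, b + m)
                        for sz in (-m, L + m)])
    world_corners = (corners - pivot) @ R.T + pivot
    lo = world_corners.min(axis=0)
    hi = world_corners.max(axis=0)

    spacing = np.asarray(spec.voxel_spacing, dtype=float)
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    origin = lo

    ix = origin[0] + spacing[0] * np.arange(shape[0])
    iy = origin[1] + spacing[1] * np.arange(shape[1])
    iz = origin[2] + spacing[2] * np.arange(shape[2])
    X, Y, Z = np.meshgrid(ix, iy, iz, indexing="ij")
    W = np.stack([X, Y, Z], axis=-1)

    # phantom-frame coordinates of every voxel center
    Q = (W - pivot) @ R + pivot  # R^T applied from the right
    qx, qy, qz = Q[..., 0], Q[..., 1], Q[..., 2]

    with np.errstate(invalid="ignore"):
        h = (L - qz) / L                       # 1 at apex tip, 0 at base
        s = np.sqrt(np.clip(1.0 - h * h, 0.0, None))
    theta = np.arctan2(qy, qx)
    r = np.hypot(qx, qy)
    r_epi = s * _ellipse_radius(a, b, theta)

    theta_deg = np.degrees(theta)
    thick = np.full_like(r, spec.wall_thickness)
    if spec.thick_patch is not None:
        thick = thick + spec.thick_patch.extra_at(theta_deg)
    r_endo = np.clip(r_epi - thick, 0.0, None)

    in_long_axis = (qz >= 0.0) & (qz <= L)
    myo = in_long_axis & (r <= r_epi) & (r > r_endo)
    blood = in_long_axis & (r <= r_endo) & (r_endo > 0)

    root = np.zeros_like(myo)
    if spec.include_aortic_root:
        theta_c = np.radians(theta_from_alpha(spec.septum_span_deg / 2.0,
                                              spec.groove_anterior_deg))
        rc = _ellipse_radius(a, b, np.array(theta_c)) - spec.wall_thickness / 2.0
        axis_xy = rc * np.array([np.cos(theta_c), np.sin(theta_c)])
        d_axis = np.hypot(qx - axis_xy[0], qy - axis_xy[1])
        # outer-wall only: a clearance band keeps the root region
        # disconnected from the contrast blood pool
        root = myo & (d_axis <= spec.aortic_root_radius_mm) \
            & (qz >= L - spec.aortic_root_height_mm) \
            & (r >= r_endo + spec.aortic_root_clearance_mm)
        myo = myo & ~root

    data = np.full(shape, spec.hu_background, dtype=np.float32)
    data[myo] = spec.hu_myo
    data[blood] = spec.hu_blood
    data[root] = spec.hu_root
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape).astype(np.float32)

    vol = Volume3D(data=data, spacing=spacing, origin=origin)

    # ---- ground truth ----------------------------------------------------
    apex_ph = np.array([0.0, 0.0, 0.0])
    mitral_ph = np.array([0.0, 0.0, L])
    to_world = lambda p: (p - pivot) @ R.T + pivot  # noqa: E731

    lv = myo | blood | root
    z_has_myo = np.where(lv.any(axis=(0, 1)))[0]
    z_has_blood = np.where(blood.any(axis=(0, 1)))[0]
    if z_has_blood.size == 0:
        raise ValueError("phantom degenerate: no blood pool voxels")
    # endo-apex: lowest chamber point on the long axis, in phantom frame
    z_endo_apex = float(iz[z_has_blood[0]]) if spec.orientation_tilt_deg == 0 \
        else L - (L - spec.wall_thickness)  # analytic fallback under tilt
    if spec.orientation_tilt_deg == 0:
        endo_apex_ph = np.array([0.0, 0.0, z_endo_apex])
    else:
        # analytic: chamber reaches down to where r_endo first becomes > 0
        endo_apex_ph = np.array([0.0, 0.0, L * (1 - np.sqrt(max(
            1 - (spec.wall_thickness / min(a, b)) ** 2, 0.0)))])
        endo_apex_ph[2] = max(endo_apex_ph[2], spec.wall_thickness)

    base_idx = int(z_has_myo[-1])
    rows = []
    for k in z_has_myo:
        ant = wrap_deg(spec.groove_anterior_deg
                       + spec.groove_twist_deg_per_slice * (base_idx - k))
        rows.append({"slice_index": int(k), "anterior_deg": float(ant),
                     "posterior_deg": float(wrap_deg(ant - spec.septum_span_deg))})
    grooves = pd.DataFrame(rows)
    assert np.allclose(septum_span(grooves.anterior_deg, grooves.posterior_deg),
                       spec.septum_span_deg)

    axis_dir = R @ np.array([0.0, 0.0, 1.0])
    truth = PhantomTruth(
        mitral_center=to_world(mitral_ph),
        apex=to_world(apex_ph),
        endo_apex=to_world(endo_apex_ph),
        groove_angles=grooves,
        septum_span_deg=spec.septum_span_deg,
        wall_thickness=spec.wall_thickness,
        thick_patch=spec.thick_patch,
        long_axis_dir=axis_dir,
        myocardium=myo,
        chamber=blood,
        root=root,
    )
    return vol, truth


def truth_contours(spec: PhantomSpec, vol: Volume3D, truth: PhantomTruth,
                   n_points: int = 10):
    """Expert-grade contour stack from the analytic phantom geometry.

    Emulates the manually corrected surface contours of the clinical
    workflow: control points are placed exactly on the analytic epi- and
    endocardial borders of each slice (untilted phantoms only).  Returns a
    :class:`bullseye17.lvseg.ContourStack`.
    """
    from .lvseg import Contour, ContourStack  # local import avoids a cycle

    if spec.orientation_tilt_deg != 0:
        raise ValueError("truth contours require an untilted phantom")
    a, b = spec.epi_radii
    L = spec.long_axis_len
    ang = np.radians(np.arange(n_points) * 360.0 / n_points)
    dirs = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    thick = truth.thickness_at(np.degrees(ang))

    epi: dict[int, Contour] = {}
    endo: dict[int, Contour] = {}
    zc = vol.axis_coords(2)
    lv = truth.myocardium | truth.chamber | truth.root
    for z in np.where(lv.any(axis=(0, 1)))[0]:
        h = (L - zc[z]) / L
        if not (0.0 <= zc[z] <= L):
            continue
        s = np.sqrt(max(1.0 - h * h, 0.0))
        re = s * _ellipse_radius(a, b, ang)
        if np.all(re < 1e-6):
            continue
        epi[int(z)] = Contour(int(z), "epicardial", dirs * re[:, None])
        ri = re - thick
        if np.all(ri > 0):
            endo[int(z)] = Contour(int(z), "endocardial", dirs * ri[:, None])
    return ContourStack(epi=epi, endo=endo, spacing=vol.spacing,
                        origin=vol.origin, shape=vol.shape)


def analytic_shell_volume(spec: PhantomSpec, n_steps: int = 20000) -> float:
    """Independent 1D-quadrature oracle for the myocardial shell volume (mm^3).

    Integrates the per-slice annulus area pi*(re^2 - ri^2) (solid disc where
    the wall fills the cross-section) along the long axis.  Only valid for
    circular cross-sections without a thickening patch.
    """
    a, b = spec.epi_radii
    if not np.isclose(a, b) or spec.thick_patch is not None:
        raise ValueError("analytic oracle requires a circular, uniform-wall phantom")
    L, t = spec.long_axis_len, spec.wall_thickness
    z = (np.arange(n_steps) + 0.5) * (L / n_steps)
    s = np.sqrt(np.clip(1.0 - ((L - z) / L) ** 2, 0.0, None))
    re = s * a
    ri = np.clip(re - t, 0.0, None)
    return float(np.sum(np.pi * (re ** 2 - ri ** 2)) * (L / n_steps))
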