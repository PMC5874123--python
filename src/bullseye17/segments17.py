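"""Division of the myocardium into the 17 AHA segments.

Two dividers are provided.  The conventional divider splits basal and
mid-cavity slices into six 60-degree wedges and apical slices into four
90-degree wedges about the per-slice myocardial center.  The
patient-specific divider instead anchors the circumferential boundaries on
the anterior and posterior interventricular grooves: the septal arc between
them (anterior -> posterior in segment order) is split equally into the two
septal segments (kept whole as segment 14 apically), and the free-wall arc
is split equally into four wedges (basal/mid) or three (apical), ordered
4,5,6,1 / 10,11,12,7 / 15,16,13 from the posterior groove.

Label semantics follow the AHA numbering: 1 basal anterior, 2 basal
anteroseptal, 3 basal inferoseptal, 4 basal inferior, 5 basal inferolateral,
6 basal anterolateral; 7-12 their mid-cavity analogues; 13 apical anterior,
14 apical septal, 15 apical inferior, 16 apical lateral; 17 apex cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import Landmarks
from .angles import alpha_from_theta, ang_diff, septum_span, theta_of, wrap_deg
from .lvseg import LVMask

SLABS = ("apical", "mid", "basal")
APEX_LABEL = 17

# circumferential label order (increasing alpha) per slab for the
# conventional divider; the reference angle is the segment 1|2 boundary
_CONV_ORDER = {
    "basal": (2, 3, 4, 5, 6, 1),
    "mid": (8, 9, 10, 11, 12, 7),
}
_CONV_APICAL_ORDER = (14, 15, 16, 13)  # 90-degree wedges, offset +15 deg
_SEPTAL = {"basal": (2, 3), "mid": (8, 9)}
_FREE = {"basal": (4, 5, 6, 1), "mid": (10, 11, 12, 7), "apical": (15, 16, 13)}


@dataclass
class GrooveAnnotation:
    """Per-slice anterior/posterior interventricular groove angles.

    Angles are absolute in-plane degrees about the per-slice myocardial
    center.  Annotation may be sparse; dividers interpolate over slices.
    """

    records: pd.DataFrame  # columns: slice_index, anterior_deg, posterior_deg

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        required = {"slice_index", "anterior_deg", "posterior_deg"}
        if not required.issubset(df.columns):
            raise ValueError(f"groove annotation needs columns {sorted(required)}")
        if len(df) == 0:
            raise ValueError("empty groove annotation")
        df = df.sort_values("slice_index").reset_index(drop=True)
        df["anterior_deg"] = wrap_deg(df["anterior_deg"].to_numpy(dtype=float))
        df["posterior_deg"] = wrap_deg(df["posterior_deg"].to_numpy(dtype=float))
        if np.any(np.isclose(df["anterior_deg"], df["posterior_deg"])):
            raise ValueError("anterior and posterior groove angles coincide")
        self.records = df

    @classmethod
    def from_csv(cls, path: str) -> "GrooveAnnotation":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str) -> None:
        self.records.to_csv(path, index=False)


def interpolate_grooves(ann: GrooveAnnotation, slices) -> pd.DataFrame:
    """Wrap-aware linear interpolation of groove angles over slice index.

    Each angle is unwrapped along the annotated slices via shortest angular
    path, interpolated linearly in slice index, and extrapolated as constant
    beyond the annotated range.
    """
    slices = np.asarray(list(slices), dtype=int)
    df = ann.records
    out = {"slice_index": slices}
    zk = df["slice_index"].to_numpy(dtype=float)
    for col in ("anterior_deg", "posterior_deg"):
        a = df[col].to_numpy(dtype=float)
        if len(a) == 1:
            out[col] = np.full(len(slices), a[0])
            continue
        unwrapped = np.concatenate([[a[0]], a[0] + np.cumsum(ang_diff(a[1:], a[:-1]))])
        out[col] = wrap_deg(np.interp(slices.astype(float), zk, unwrapped))
    return pd.DataFrame(out)


@dataclass
class SegmentLabelMap:
    """Voxel-wise assignment of the myocardium to segments 1-17.

    ``wedges`` optionally records, per non-apex slice, the exact angular
    rule that produced the voxel labels: ``(reference_deg, starts, labels)``
    where ``starts`` are wedge start angles in the segment-ordered alpha
    coordinate.  Dividers fill it in; maps loaded from disk may lack it.
    """

    data: np.ndarray = field(repr=False)  # int16, 0 = background
    slabs: dict[int, str] = field(default_factory=dict)  # slice -> slab name
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    wedges: dict[int, tuple] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int16)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def labels_present(self) -> np.ndarray:
        u = np.unique(self.data)
        return u[u > 0]

    def counts(self) -> pd.Series:
        vals, cts = np.unique(self.data[self.data > 0], return_counts=True)
        return pd.Series(cts, index=vals).reindex(range(1, 18), fill_value=0)

    def labels_at(self, z: int, theta_deg: np.ndarray) -> np.ndarray:
        """Exact segment label at absolute angle(s) theta on slice z.

        Requires the angular rule (``wedges``) for that slice; apex-slab
        slices return 17 everywhere.
        """
        if self.slabs.get(int(z)) == "apex":
            return np.full(np.shape(theta_deg), APEX_LABEL, dtype=np.int16)
        if int(z) not in self.wedges:
            raise KeyError(f"no angular rule recorded for slice {z}")
        ref, starts, labs = self.wedges[int(z)]
        alpha = alpha_from_theta(theta_deg, ref)
        idx = np.searchsorted(starts, alpha, side="right") - 1
        idx = np.where(idx < 0, len(labs) - 1, idx)
        return labs[idx]


def assign_slabs(mask: LVMask, lm: Landmarks | None = None) -> dict[int, str]:
    """Split the slice stack into apex / apical / mid / basal slabs.

    The apex-to-mitral range is cut into three equal thirds (apical, mid,
    basal, counting up from the apex); slices of the solid apical cap (no
    chamber) are assigned to the apex slab regardless.
    """
    zs = mask.myocardial_slices
    if len(zs) < 4:
        raise ValueError("need at least 4 myocardial slices to assign slabs")
    z0, n = zs[0], len(zs)
    out: dict[int, str] = {}
    for z in zs:
        if not mask.chamber[:, :, z].any():
            out[int(z)] = "apex"
            continue
        f = (z - z0 + 0.5) / n
        out[int(z)] = SLABS[min(int(f * 3), 2)]
    return out


def _slice_centers(mask: LVMask, slabs: dict[int, str]) -> dict[int, np.ndarray]:
    centers = {}
    for z in slabs:
        sl = mask.myocardium[:, :, z] | mask.chamber[:, :, z]
        if not sl.any():
            raise ValueError(f"missing center: no LV voxels on slice {z}")
        ii, jj = np.nonzero(sl)
        centers[z] = np.array([ii.mean() * mask.spacing[0],
                               jj.mean() * mask.spacing[1]])
    return centers


def _voxel_alphas(mask: LVMask, z: int, center_mm: np.ndarray,
                  reference_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ii, jj = np.nonzero(mask.myocardium[:, :, z])
    theta = theta_of(ii * mask.spacing[0] - center_mm[0],
                     jj * mask.spacing[1] - center_mm[1])
    return ii, jj, alpha_from_theta(theta, reference_deg)


def divide_conventional(mask: LVMask, slabs: dict[int, str],
                        reference_deg: float = 60.0,
                        centers: dict[int, np.ndarray] | None = None
                        ) -> SegmentLabelMap:
    """Fixed-angle AHA divider: 60-degree wedges basal/mid, 90-degree apical.

    ``reference_deg`` is the absolute angle of the segment 1|2 boundary
    (place it at the anterior groove to compare against the
    patient-specific divider).  Apical wedges are offset so the septal
    segment 14 is centered on the conventional septum.
    """
    centers = centers or _slice_centers(mask, slabs)
    lab = np.zeros(mask.myocardium.shape, dtype=np.int16)
    wedges: dict[int, tuple] = {}
    for z, slab in slabs.items():
        if slab == "apex":
            lab[:, :, z][mask.myocardium[:, :, z]] = APEX_LABEL
            continue
        if slab in ("basal", "mid"):
            starts = np.arange(6) * 60.0
            labs = np.array(_CONV_ORDER[slab], dtype=np.int16)
        else:  # apical: four 90-degree wedges, septal segment 14 centered
            starts = 15.0 + np.arange(4) * 90.0
            labs = np.array(_CONV_APICAL_ORDER, dtype=np.int16)
        wedges[int(z)] = (reference_deg, starts, labs)
        ii, jj, alpha = _voxel_alphas(mask, z, centers[z], reference_deg)
        idx = np.searchsorted(starts, alpha, side="right") - 1
        idx = np.where(idx < 0, len(labs) - 1, idx)
        lab[ii, jj, z] = labs[idx]
    return SegmentLabelMap(data=lab, slabs=dict(slabs), spacing=mask.spacing,
                           origin=mask.origin, wedges=wedges)


def divide_patient_specific(mask: LVMask, slabs: dict[int, str],
                            grooves: GrooveAnnotation | pd.DataFrame,
                            centers: dict[int, np.ndarray] | None = None
                            ) -> SegmentLabelMap:
    """Groove-anchored divider producing the patient-specific segment map.

    Per slice, the septal arc (anterior groove -> posterior groove in
    segment order) is halved into the two septal segments on basal and mid
    slices and kept whole as segment 14 apically; the free-wall arc is
    split into four (basal/mid) or three (apical) equal wedges starting at
    the posterior groove.
    """
    centers = centers or _slice_centers(mask, slabs)
    non_apex = sorted(z for z, s in slabs.items() if s != "apex")
    if isinstance(grooves, GrooveAnnotation):
        gdf = interpolate_grooves(grooves, non_apex)
    else:
        gdf = pd.DataFrame(grooves)
    gdf = gdf.set_index("slice_index")

    lab = np.zeros(mask.myocardium.shape, dtype=np.int16)
    wedges: dict[int, tuple] = {}
    for z, slab in slabs.items():
        if slab == "apex":
            lab[:, :, z][mask.myocardium[:, :, z]] = APEX_LABEL
            continue
        if z not in gdf.index:
            raise ValueError(f"no groove angles available for slice {z}")
        ant = float(gdf.loc[z, "anterior_deg"])
        post = float(gdf.loc[z, "posterior_deg"])
        span = float(septum_span(ant, post))
        if span <= 0 or np.isclose(span, 0.0) or np.isclose(span, 360.0):
            raise ValueError(f"groove angles coincide on slice {z}")
        free = np.array(_FREE[slab], dtype=np.int16)
        w = (360.0 - span) / len(free)
        if slab in ("basal", "mid"):
            starts = np.concatenate([[0.0, span / 2.0],
                                     span + w * np.arange(len(free))])
            labs = np.concatenate([np.array(_SEPTAL[slab], dtype=np.int16), free])
        else:
            starts = np.concatenate([[0.0], span + w * np.arange(len(free))])
            labs = np.concatenate([np.array([14], dtype=np.int16), free])
        wedges[int(z)] = (ant, starts, labs)
        ii, jj, alpha = _voxel_alphas(mask, z, centers[z], ant)
        idx = np.searchsorted(starts, alpha, side="right") - 1
        idx = np.where(idx < 0, len(labs) - 1, idx)
        lab[ii, jj, z] = labs[idx]
    return SegmentLabelMap(data=lab, slabs=dict(slabs), spacing=mask.spacing,
                           origin=mask.origin, wedges=wedges)
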