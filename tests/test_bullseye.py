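import numpy as np
import pytest

import bullseye17 as b
from bullseye17.angles import ang_diff
from conftest import circle_contour


def _two_circle_stack(epi_r=25.0, endo_r=15.0, endo_center=(0.0, 0.0), z=0):
    epi = {z: circle_contour(z, "epicardial", epi_r)}
    endo = {z: circle_contour(z, "endocardial", endo_r, endo_center)}
    return b.ContourStack(epi=epi, endo=endo,
                          spacing=np.array([0.5, 0.5, 1.0]),
                          origin=np.array([-30.0, -30.0, 0.0]),
                          shape=(121, 121, 1))


# ---------------------------------------------------------------------------
# centerline
# ---------------------------------------------------------------------------

class TestCenterline:
    def test_concentric_circles_share_center(self):
        centers = b.compute_centerline(_two_circle_stack())
        assert np.allclose(centers[0], [0.0, 0.0], atol=1e-6)

    def test_center_is_mean_of_border_centroids(self):
        centers = b.compute_centerline(
            _two_circle_stack(endo_r=10.0, endo_center=(10.0, 0.0)))
        assert np.allclose(centers[0], [5.0, 0.0], atol=1e-6)

    def test_pipeline_centers_track_truth_axis(self, truth_field):
        _, centers, _ = truth_field
        # untilted phantom: the true centerline is x = y = 0 on every slice
        for c in centers.values():
            assert np.linalg.norm(c) <= 1.0  # within one voxel


# ---------------------------------------------------------------------------
# thickness
# ---------------------------------------------------------------------------

class TestThickness:
    def test_concentric_annulus_uniform_thickness(self):
        fld = b.measure_thickness(_two_circle_stack())
        assert np.all(np.abs(fld.thickness_mm - 10.0) <= 0.25)

    def test_offset_circles_match_analytic_oracle(self):
        # endo radius 15 centered at (5,0) inside epi radius 25 at origin:
        # distance from an endo point p to the epi circle is 25 - |p|
        fld = b.measure_thickness(
            _two_circle_stack(endo_r=15.0, endo_center=(5.0, 0.0)))
        p = fld.endo_points[0]
        oracle = 25.0 - np.linalg.norm(p, axis=1)
        assert np.allclose(fld.thickness_mm[0], oracle, atol=0.05)
        assert fld.thickness_mm.min() == pytest.approx(5.0, abs=0.25)
        assert fld.thickness_mm.max() == pytest.approx(15.0, abs=0.25)

    def test_invariant_to_in_plane_rotation(self):
        base = b.measure_thickness(
            _two_circle_stack(endo_r=15.0, endo_center=(5.0, 0.0)))
        rot = np.radians(30.0)
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        stack = _two_circle_stack(endo_r=15.0, endo_center=(5.0, 0.0))
        for d in (stack.epi, stack.endo):
            for c in d.values():
                c.control_points = c.control_points @ R.T
        rotated = b.measure_thickness(stack)
        assert np.allclose(np.sort(base.thickness_mm[0]),
                           np.sort(rotated.thickness_mm[0]), atol=0.05)

    def test_uniform_phantom_recovers_wall_everywhere(self, truth_field):
        _, _, fld = truth_field
        assert np.all(np.abs(fld.thickness_mm - 10.0) <= 0.5)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

class TestProjection:
    def test_uniform_field_fills_every_labeled_pixel(self, default_report,
                                                     truth_field):
        _, _, fld = truth_field
        raster = b.project_bullseye(fld, default_report["labels_patient"])
        vals = raster.values[raster.labels > 0]
        assert np.all(np.abs(vals - 10.0) <= 0.25)

    def test_basal_mid_ring_at_two_thirds_radius(self, default_report):
        raster = default_report["raster_patient"]
        spec = raster.spec
        assert spec.ring_radii[1] == pytest.approx(2.0 * spec.max_radius / 3.0)
        # measured on the raster: along a ray inside segment 1 (basal) /
        # segment 7 (mid), the label switches at the ring radius
        c = raster.center_px
        n = int(spec.max_radius)
        theta = np.radians(60.0 + 1e-3)  # just inside segment 1's wedge
        rr = np.arange(1, n)
        px = np.clip(np.round(c + rr * np.cos(theta)).astype(int), 0, spec.size - 1)
        py = np.clip(np.round(c - rr * np.sin(theta)).astype(int), 0, spec.size - 1)
        labs = raster.labels[py, px]
        basal_start = rr[np.nonzero(np.isin(labs, range(1, 7)))[0][0]]
        assert basal_start == pytest.approx(spec.ring_radii[1], abs=1.5)

    def test_boundary_angles_pass_through_grooves(self, default_report):
        raster = default_report["raster_patient"]
        for slab in ("basal", "mid", "apical"):
            angs = raster.boundary_angles[slab]
            for groove in (60.0, 300.0):
                assert np.min(np.abs(ang_diff(angs, groove))) <= 1e-9

    def test_empty_field_rejected(self, default_report):
        fld = default_report["thickness"]
        import dataclasses
        bad = dataclasses.replace(fld, thickness_mm=np.empty((0, 0)))
        with pytest.raises(ValueError, match="empty"):
            b.project_bullseye(bad, default_report["labels_patient"])


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

class TestAreas:
    def test_total_area_equals_pixel_count_times_pitch_squared(self,
                                                               default_report):
        raster = default_report["raster_patient"]
        table = b.segment_areas(raster)
        labeled = np.sum(raster.labels > 0)
        assert table.area_cm2.sum() == pytest.approx(
            labeled * 0.2692 ** 2 / 100.0, rel=1e-12)
        assert table.pixels.sum() == labeled

    def test_ten_thousand_pixels_convert_to_7p247_cm2(self, default_report):
        raster = default_report["raster_patient"]
        labels = np.zeros_like(raster.labels)
        labels.flat[:10000] = 1
        import dataclasses
        toy = dataclasses.replace(raster, labels=labels)
        table = b.segment_areas(toy).set_index("segment")
        assert table.loc[1, "area_cm2"] == pytest.approx(7.247, abs=1e-3)

    def test_symmetric_phantom_equal_basal_areas(self, default_report):
        table = b.segment_areas(
            default_report["raster_conventional"]).set_index("segment")
        basal = table.loc[1:6, "area_cm2"]
        assert (basal.max() - basal.min()) / basal.mean() < 0.01

    def test_septal_fraction_recovers_septum_span(self, default_report):
        table = b.segment_areas(
            default_report["raster_patient"]).set_index("segment")
        basal = table.loc[1:6, "area_cm2"]
        frac = (basal[2] + basal[3]) / basal.sum()
        assert frac == pytest.approx(120.0 / 360.0, rel=0.02)

    def test_doubling_raster_converges(self, default_report, truth_field):
        _, _, fld = truth_field
        lab = default_report["labels_patient"]
        a1 = b.segment_areas(b.project_bullseye(
            fld, lab, b.BullseyeSpec(size=512, max_radius=255.0)))
        a2 = b.segment_areas(b.project_bullseye(
            fld, lab, b.BullseyeSpec(size=1024, max_radius=510.0)))
        f1 = a1.area_cm2 / a1.area_cm2.sum()
        f2 = a2.area_cm2 / a2.area_cm2.sum()
        assert np.all(np.abs(f1 - f2) / f2 < 0.01)

    def test_patient_areas_monotone_in_span(self, default_report, truth_field):
        import pandas as pd
        _, _, fld = truth_field
        mask = default_report["mask"]
        slabs = default_report["slabs"]
        septal = []
        for span in (100.0, 120.0, 140.0):
            rows = [{"slice_index": z, "anterior_deg": 60.0,
                     "posterior_deg": (60.0 - span) % 360.0}
                    for z in sorted(slabs)]
            lab = b.divide_patient_specific(
                mask, slabs, b.GrooveAnnotation(pd.DataFrame(rows)))
            t = b.segment_areas(b.project_bullseye(fld, lab)).set_index("segment")
            septal.append(t.loc[[2, 3, 8, 9, 14], "area_cm2"].sum())
        assert septal[0] < septal[1] < septal[2]


class TestScalars:
    def test_uniform_shell_max_thickness(self, default_report, truth_field):
        _, _, fld = truth_field
        table = b.segment_scalars(default_report["labels_patient"], fld,
                                  default_report["mask"]).set_index("segment")
        present = table.loc[1:16, "max_thickness_mm"].dropna()
        assert np.all(np.abs(present - 10.0) <= 0.5)

    def test_total_mass_conserved(self, default_report):
        fld = default_report["thickness"]
        mask = default_report["mask"]
        table = b.segment_scalars(default_report["labels_patient"], fld, mask)
        expected = mask.myocardium.sum() * mask.voxel_volume_mm3 / 1000.0 * 1.05
        assert table.mass_g.sum() == pytest.approx(expected, rel=1e-12)

    def test_septal_patch_raises_segment2_thickness(self):
        # patch peaking at 16 mm, support well inside segment 2 (alpha 4-44)
        patch = b.ThickPatch(center_theta_deg=36.0, width_deg=40.0, extra_mm=6.0)
        spec = b.PhantomSpec(thick_patch=patch)
        vol, truth = b.generate_lv_phantom(spec)
        # mask-based thickness resolves the sharp notch at voxel scale
        mask = b.LVMask(myocardium=truth.myocardium, chamber=truth.chamber,
                        spacing=vol.spacing, origin=vol.origin)
        slabs = b.assign_slabs(mask)
        lab = b.divide_patient_specific(mask, slabs,
                                        b.GrooveAnnotation(truth.groove_angles))
        fld = b.measure_thickness_from_mask(mask)
        table = b.segment_scalars(lab, fld, mask).set_index("segment")
        assert table.loc[2, "max_thickness_mm"] == pytest.approx(16.0, abs=1.0)
        for seg in (1, 4, 5, 6):
            assert table.loc[seg, "max_thickness_mm"] == pytest.approx(10.0, abs=1.0)
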