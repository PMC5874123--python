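import numpy as np
import pytest

import bullseye17 as b


def circle_contour(z, role, radius, center=(0.0, 0.0), n=10):
    """Contour with control points placed exactly on a circle."""
    ang = np.radians(np.arange(n) * 360.0 / n)
    pts = np.stack([center[0] + radius * np.cos(ang),
                    center[1] + radius * np.sin(ang)], axis=1)
    return b.Contour(slice_index=z, role=role, control_points=pts)


@pytest.fixture(scope="session")
def default_spec():
    return b.PhantomSpec()


@pytest.fixture(scope="session")
def default_case(default_spec):
    vol, truth = b.generate_lv_phantom(default_spec)
    return vol, truth


@pytest.fixture(scope="session")
def default_report(default_spec, default_case):
    """Full automatic pipeline on the symmetric noise-free phantom."""
    vol, truth = default_case
    grooves = b.GrooveAnnotation(truth.groove_angles)
    return b.run_pipeline(vol, truth.landmarks, grooves, remove_root=False)


@pytest.fixture(scope="session")
def truth_field(default_spec, default_case):
    """Expert-grade (analytic) contours, centers and thickness field."""
    vol, truth = default_case
    stack = b.truth_contours(default_spec, vol, truth)
    centers = b.compute_centerline(stack)
    fld = b.measure_thickness(stack, centers)
    return stack, centers, fld


@pytest.fixture(scope="session")
def coarse_case():
    """Coarser symmetric phantom for simulation-heavy statistics tests."""
    spec = b.PhantomSpec(voxel_spacing=(1.5, 1.5, 1.5))
    vol, truth = b.generate_lv_phantom(spec)
    grooves = b.GrooveAnnotation(truth.groove_angles)
    rep = b.run_pipeline(vol, truth.landmarks, grooves, remove_root=False)
    return spec, vol, truth, rep
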