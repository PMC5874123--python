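"""Circumferential angle bookkeeping shared across the pipeline.

Absolute in-plane angles theta are measured with ``atan2(dy, dx)`` in degrees,
wrapped to [0, 360).  The segment dividers work in a relative coordinate

    alpha = (anterior_groove_deg - theta) mod 360

i.e. alpha runs from the anterior interventricular groove in the direction of
increasing AHA segment number, so the septal arc is ``alpha in [0, span)``
with ``span = (anterior - posterior) mod 360`` and the free wall follows as
4, 5, 6, 1 (basal) starting at the posterior groove.
"""

from __future__ import annotations

import numpy as np


def wrap_deg(a):
    """Wrap angle(s) to [0, 360)."""
    return np.mod(a, 360.0)


def ang_diff(a, b):
    """Signed shortest angular difference a - b in (-180, 180]."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 180.0, 360.0) - 180.0
    return d


def theta_of(dx, dy):
    """Absolute angle (deg, [0, 360)) of in-plane offsets."""
    return wrap_deg(np.degrees(np.arctan2(dy, dx)))


def alpha_from_theta(theta_deg, anterior_deg):
    """Segment-ordered angle measured from the anterior groove."""
    return wrap_deg(anterior_deg - np.asarray(theta_deg, dtype=float))


def theta_from_alpha(alpha_deg, anterior_deg):
    return wrap_deg(anterior_deg - np.asarray(alpha_deg, dtype=float))


def septum_span(anterior_deg, posterior_deg):
    """Angular extent of the septal arc, anterior -> posterior through the septum."""
    return wrap_deg(np.asarray(anterior_deg, dtype=float) - np.asarray(posterior_deg, dtype=float))
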