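"""Axial (180-degree periodic) angle helpers.

Planar polarity is a nematic quantity: an axis, not a direction. All public
angles are reported in degrees in the half-open interval (-90, +90], with 0
along the image x-axis and +90 pointing up (mathematical y-up frame).
"""
from __future__ import annotations

import numpy as np


def wrap_axial_deg(angle_deg):
    """Wrap angle(s) in degrees into the axial interval (-90, +90]."""
    a = np.asarray(angle_deg, dtype=float)
    wrapped = np.mod(a + 90.0, 180.0) - 90.0
    # map -90 to +90 so the interval is half-open on the left
    wrapped = np.where(np.isclose(wrapped, -90.0), 90.0, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


def axial_difference_deg(a_deg, b_deg):
    """Smallest axial angle between two axes, in [0, 90]."""
    d = np.abs(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 180.0
    d = np.minimum(d, 180.0 - d)
    return d if d.ndim else float(d)


def axial_mean_deg(angles_deg, weights=None):
    """Circular mean of axial angles via the doubled-angle embedding."""
    a = np.radians(np.asarray(angles_deg, dtype=float)) * 2.0
    if weights is None:
        weights = np.ones_like(a)
    w = np.asarray(weights, dtype=float)
    z = np.sum(w * np.exp(1j * a))
    if np.abs(z) == 0:
        raise ValueError("axial mean undefined: resultant length is zero")
    return wrap_axial_deg(np.degrees(np.angle(z) / 2.0))
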