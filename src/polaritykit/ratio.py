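"""Ratio (rotating-quadrant) polarity.

The angular intensity profile is resampled onto a uniform angular grid by
circular linear interpolation, then grouped into four 90-degree bins for
every trial axis. The asymmetry at a trial axis is the summed mean intensity
of one opposite bin pair over the other, oriented so it is >= 1. Asymmetries
are rounded to 1e-3; the polarity magnitude is the maximum asymmetry and the
polarity angle is the circular (axial) mean of all maximizing trial axes.

Using bin *means* (not sums) makes the readout independent of junction
length. An asymmetry of exactly 1 means zero polarization.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._angles import axial_mean_deg, wrap_axial_deg
from .profiles import BoundaryProfile, DegenerateSignalError
from .readout import PolarityReadout

ROUND_DECIMALS = 3


@dataclass(frozen=True)
class RatioScan:
    """Asymmetry as a function of trial axis (degrees)."""
    axes_deg: np.ndarray
    asymmetries: np.ndarray

    @property
    def max_asymmetry(self) -> float:
        return float(np.nanmax(self.asymmetries))

    @property
    def maximizer_axes(self) -> np.ndarray:
        m = np.nanmax(self.asymmetries)
        return self.axes_deg[self.asymmetries == m]


def _resample_circular(profile: BoundaryProfile, step_deg: float):
    """Linear interpolation of I(theta) onto a uniform angular grid."""
    th = profile.thetas
    I = profile.intensities
    grid = np.radians(np.arange(-180.0, 180.0, step_deg))
    th_ext = np.r_[th[-1] - 2 * np.pi, th, th[0] + 2 * np.pi]
    I_ext = np.r_[I[-1], I, I[0]]
    return grid, np.interp(grid, th_ext, I_ext)


def ratio_scan(profile: BoundaryProfile, angle_step: float = 1.0,
               resample_step: float = 1.0) -> RatioScan:
    grid, I = _resample_circular(profile, resample_step)
    deg = np.degrees(grid)
    phis = np.arange(0.0, 90.0, angle_step)
    axes, asyms = [], []
    for phi in phis:
        binid = (np.mod(deg - phi + 45.0, 360.0) // 90.0).astype(int)
        means = np.array([I[binid == k].mean() if np.any(binid == k) else np.nan
                          for k in range(4)])
        if np.any(np.isnan(means)):
            continue
        pair_a = means[0] + means[2]   # bins centered on phi and phi+180
        pair_b = means[1] + means[3]
        if pair_a >= pair_b:
            num, den, axis = pair_a, pair_b, phi
        else:
            num, den, axis = pair_b, pair_a, phi + 90.0
        if den == 0:
            warnings.warn(f"zero-intensity bin pair at trial axis {phi} deg; skipped")
            continue
        axes.append(wrap_axial_deg(axis))
        asyms.append(round(num / den, ROUND_DECIMALS))
    if not asyms:
        raise DegenerateSignalError("asymmetry undefined at every trial axis")
    return RatioScan(axes_deg=np.array(axes), asymmetries=np.array(asyms))


def ratio_polarity(profile: BoundaryProfile, angle_step: float = 1.0,
                   resample_step: float = 1.0) -> PolarityReadout:
    scan = ratio_scan(profile, angle_step=angle_step, resample_step=resample_step)
    p = scan.max_asymmetry
    try:
        angle = axial_mean_deg(scan.maximizer_axes)
    except ValueError:
        angle = None  # maximizers cancel (e.g. perfectly uniform profile)
    if p <= 1.0:
        angle = None
    return PolarityReadout(cell_id=profile.cell_id, method="ratio",
                           magnitude=p, angle_deg=angle)
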