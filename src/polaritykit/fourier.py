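"""Fourier-series (second harmonic) polarity.

The angular intensity distribution is projected onto its second circular
harmonic; the resulting nematic tensor components are normalized by the
total weighted intensity so the readout is independent of image brightness:

    Q1 = (1/N) sum_i I_i cos(2 theta_i) dtheta_i
    Q2 = (1/N) sum_i I_i sin(2 theta_i) dtheta_i,   N = sum_i I_i dtheta_i

    p = sqrt(Q1^2 + Q2^2),   theta = (1/2) atan2(Q2, Q1)

p is 0 for a homogeneous distribution and grows with bipolar asymmetry.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._angles import wrap_axial_deg
from .profiles import BoundaryProfile, DegenerateSignalError
from .readout import PolarityReadout

_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class FourierComponents:
    Q1: float
    Q2: float
    N: float

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.Q1, self.Q2))

    @property
    def angle_deg(self) -> float:
        return wrap_axial_deg(np.degrees(0.5 * np.arctan2(self.Q2, self.Q1)))


def fourier_components(profile: BoundaryProfile) -> FourierComponents:
    I, th, w = profile.intensities, profile.thetas, profile.weights
    N = float(np.sum(I * w))
    if N <= _ZERO_TOL:
        raise DegenerateSignalError("all-zero intensity profile")
    Q1 = float(np.sum(I * np.cos(2 * th) * w) / N)
    Q2 = float(np.sum(I * np.sin(2 * th) * w) / N)
    return FourierComponents(Q1=Q1, Q2=Q2, N=N)


def fourier_polarity(profile: BoundaryProfile) -> PolarityReadout:
    comp = fourier_components(profile)
    p = comp.magnitude
    angle = comp.angle_deg if p > _ZERO_TOL else None
    return PolarityReadout(cell_id=profile.cell_id, method="fourier",
                           magnitude=p, angle_deg=angle)
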