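"""Per-cell angular intensity profiles.

Every polarity method consumes the same object: the junctional intensity
sampled along the cell boundary, expressed as a function of the
centroid-relative angle theta, with circular midpoint quadrature weights
dtheta_i that compensate for non-uniform angular density of boundary pixels.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .segmentation import CellBoundary


class DegenerateSignalError(ValueError):
    """Raised when a profile carries no usable intensity signal."""


@dataclass(frozen=True)
class BoundaryProfile:
    """Ordered angular intensity profile of one cell.

    xy : (n, 2) boundary sample positions relative to the centroid (y-up).
    intensities : (n,) junctional intensities (a.u.), >= 0.
    thetas : (n,) centroid-relative angles, sorted ascending in (-pi, pi].
    weights : (n,) angular quadrature weights dtheta_i, summing to 2*pi.
    """

    cell_id: int
    xy: np.ndarray
    intensities: np.ndarray
    thetas: np.ndarray
    weights: np.ndarray
    centroid_xy: tuple = (0.0, 0.0)

    @classmethod
    def from_points(cls, xy, intensities, cell_id: int = 0,
                    centroid_xy=(0.0, 0.0)) -> "BoundaryProfile":
        """Build a profile from centroid-relative points; sorts by angle and
        attaches midpoint angular weights."""
        xy = np.asarray(xy, dtype=float)
        inten = np.asarray(intensities, dtype=float)
        if len(xy) < 3:
            raise ValueError("profile needs at least 3 boundary points")
        if np.any(inten < 0):
            raise ValueError("negative intensities")
        th = np.arctan2(xy[:, 1], xy[:, 0])
        order = np.argsort(th, kind="stable")
        th = th[order]
        prof = cls(cell_id=cell_id, xy=xy[order], intensities=inten[order],
                   thetas=th, weights=_midpoint_weights(th),
                   centroid_xy=tuple(centroid_xy))
        return prof

    @property
    def n(self) -> int:
        return len(self.thetas)

    def with_intensities(self, intensities) -> "BoundaryProfile":
        return replace(self, intensities=np.asarray(intensities, dtype=float))


def _midpoint_weights(thetas_sorted: np.ndarray) -> np.ndarray:
    """Circular midpoint-rule weights: each point owns half the angular gap
    to each of its neighbors; the weights partition the circle exactly."""
    if len(thetas_sorted) < 3:
        raise ValueError("angular weights need at least 3 points")
    gaps = np.diff(thetas_sorted, append=thetas_sorted[0] + 2 * np.pi)
    if np.any(gaps < 0):
        raise ValueError("thetas must be sorted ascending")
    return (gaps + np.roll(gaps, 1)) / 2.0


def angular_weights(profile: BoundaryProfile) -> BoundaryProfile:
    """Recompute midpoint weights of a profile (already applied by the
    constructor; exposed for transformed coordinates)."""
    return replace(profile, weights=_midpoint_weights(profile.thetas))


def smooth_image(image, thickness: float = 3.0) -> np.ndarray:
    """Mean-filter an intensity image with a disk footprint of the given
    diameter (px). thickness=1 returns the image unchanged."""
    img = np.asarray(image, dtype=float)
    if thickness < 1:
        raise ValueError("thickness must be >= 1 px")
    if thickness == 1:
        return img
    rad = thickness / 2.0
    span = int(np.floor(rad))
    yy, xx = np.mgrid[-span:span + 1, -span:span + 1]
    footprint = (xx ** 2 + yy ** 2) <= rad ** 2
    return ndimage.convolve(img, footprint / footprint.sum(), mode="nearest")


def _disk_footprint(thickness: float) -> np.ndarray:
    rad = thickness / 2.0
    span = int(np.floor(rad))
    yy, xx = np.mgrid[-span:span + 1, -span:span + 1]
    return (xx ** 2 + yy ** 2) <= rad ** 2


def junction_mean_image(image, mask, thickness: float = 3.0) -> np.ndarray:
    """Mean intensity over mask (junction) pixels within a disk of diameter
    `thickness` around each pixel. Restricting the average to the skeleton
    keeps the readout free of geometry-dependent dilution by cell-interior
    background."""
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask, dtype=float)
    if thickness < 1:
        raise ValueError("thickness must be >= 1 px")
    if thickness == 1:
        return img
    fp = _disk_footprint(thickness).astype(float)
    num = ndimage.convolve(img * m, fp, mode="constant", cval=0.0)
    den = ndimage.convolve(m, fp, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = 0.0
    return out


def sample_intensity(boundary: CellBoundary, image, thickness: float = 3.0,
                     smoothed=None, mask=None) -> BoundaryProfile:
    """Sample junctional intensity along a traced boundary.

    Each boundary pixel's intensity is the mean image intensity within a
    disk of diameter `thickness` centered on it. When `mask` (the skeleton)
    is given, the mean runs over junction pixels only, which avoids diluting
    the signal with cell-interior background. Pass a precomputed `smoothed`
    image to amortize the filtering over many cells.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("intensity image must be 2D")
    if smoothed is None:
        if mask is not None:
            smoothed = junction_mean_image(img, mask, thickness)
        else:
            smoothed = smooth_image(img, thickness)
    rc = boundary.points_rc
    if rc[:, 0].max() >= img.shape[0] or rc[:, 1].max() >= img.shape[1]:
        raise ValueError("boundary and image dimensions do not match")
    inten = smoothed[rc[:, 0], rc[:, 1]]
    cx, cy = boundary.centroid_xy
    xy = boundary.xy - np.array([cx, cy])
    return BoundaryProfile.from_points(xy, inten, cell_id=boundary.cell_id,
                                       centroid_xy=(cx, cy))
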