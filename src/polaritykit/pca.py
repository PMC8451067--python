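"""PCA-based polarity, insensitive to cell shape.

Pipeline per cell:

1. *Compression* — the boundary is rotated so the fitted ellipse's major
   axis lies along x, compressed along that axis by alpha = b/a, and rotated
   back. This maps an elongated cell onto a regular one, so the angular
   intensity distribution seen by the subsequent steps no longer depends on
   cell eccentricity. Angles and angular weights are recomputed from the
   transformed coordinates.
2. *Intensity normalization* — I'_i = k * I_i / <I>_dtheta with k = 1e3,
   which removes any dependence on image brightness and bit depth.
3. *Radial embedding* — each boundary sample becomes the point
   (R_i cos theta_i, R_i sin theta_i) with radius R_i = ln(I'_i). The large
   constant k puts the cloud on a ring of radius ~ln(k), so the log-radius
   perturbations encode relative (fold-change) intensity asymmetries; this
   is what makes the magnitude respond linearly to the logarithm of the
   peak-to-base intensity ratio and symmetrically to complementary coverage
   patterns.
4. *Weighted covariance* — sigma_ab = sum_i w_i (a_i - a_bar)(b_i - b_bar)
   / w_sum with the dtheta_i weights. The polarity magnitude and axis come
   from its eigensystem:

       p = lambda_1 - lambda_2
       theta = (1/2) atan2(2 sigma_xy, sigma_xx - sigma_yy)

   For a homogeneous distribution the cloud is a circle, lambda_1 =
   lambda_2 and p = 0; the greater the bipolarity, the greater the
   eigenvalue difference.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._angles import wrap_axial_deg
from .profiles import BoundaryProfile, DegenerateSignalError
from .readout import PolarityReadout
from .shape import EllipseFit, fit_ellipse

DEFAULT_K = 1.0e3
_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class CompressionTransform:
    """Rotation + axis compression that circularizes a cell's ellipse."""
    theta_deg: float
    alpha: float
    centroid_xy: tuple = (0.0, 0.0)

    def apply(self, xy: np.ndarray) -> np.ndarray:
        th = np.radians(self.theta_deg)
        c, s = np.cos(th), np.sin(th)
        rot = np.array([[c, s], [-s, c]])          # rotate by -theta
        back = np.array([[c, -s], [s, c]])         # rotate by +theta
        p = (np.asarray(xy, dtype=float)) @ rot.T
        p[:, 0] *= self.alpha                      # compress the major axis
        return p @ back.T


def compress_cell(profile: BoundaryProfile, fit: EllipseFit = None,
                  alpha: float = None) -> BoundaryProfile:
    """Compress a cell's boundary profile so its ellipse becomes a circle.

    alpha defaults to b/a of the cell's own ellipse fit; intensities travel
    with their points and angles/weights are recomputed afterwards.
    """
    if fit is None:
        fit = fit_ellipse(profile.xy)
    if alpha is None:
        alpha = fit.alpha
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"compression factor must be in (0, 1], got {alpha}")
    tf = CompressionTransform(theta_deg=fit.theta_deg, alpha=alpha,
                              centroid_xy=profile.centroid_xy)
    return BoundaryProfile.from_points(tf.apply(profile.xy),
                                       profile.intensities,
                                       cell_id=profile.cell_id,
                                       centroid_xy=profile.centroid_xy)


def normalize_intensities(profile: BoundaryProfile,
                          k: float = DEFAULT_K) -> BoundaryProfile:
    """I'_i = k * I_i / (weighted mean of I); invariant under I -> c*I."""
    wmean = float(np.sum(profile.weights * profile.intensities)
                  / np.sum(profile.weights))
    if wmean <= _ZERO_TOL:
        raise DegenerateSignalError("all-zero intensity profile")
    return profile.with_intensities(k * profile.intensities / wmean)


def intensity_coords(profile: BoundaryProfile,
                     embedding: str = "log") -> np.ndarray:
    """Embed intensities as radial distances from the centroid.

    embedding="log" (default) uses R_i = ln(max(I'_i, 1)); "linear" uses
    R_i = I'_i directly.
    """
    if embedding == "log":
        r = np.log(np.maximum(profile.intensities, 1.0))
    elif embedding == "linear":
        r = profile.intensities
    else:
        raise ValueError(f"unknown embedding {embedding!r}")
    return np.c_[r * np.cos(profile.thetas), r * np.sin(profile.thetas)]


def weighted_covariance(points: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """2x2 weighted covariance of a point cloud about its weighted mean."""
    pts = np.asarray(points, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    w_sum = w.sum()
    mean = (w[:, None] * pts).sum(axis=0) / w_sum
    d = pts - mean
    return (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / w_sum


def _eigen_split(sigma: np.ndarray):
    trace = sigma[0, 0] + sigma[1, 1]
    diff = np.hypot(sigma[0, 0] - sigma[1, 1], 2 * sigma[0, 1])
    return (trace + diff) / 2.0, (trace - diff) / 2.0


def pca_polarity(profile: BoundaryProfile, fit: EllipseFit = None,
                 k: float = DEFAULT_K, alpha: float = None,
                 embedding: str = "log") -> PolarityReadout:
    """Full PCA polarity readout for one cell."""
    compressed = compress_cell(profile, fit=fit, alpha=alpha)
    normalized = normalize_intensities(compressed, k=k)
    pts = intensity_coords(normalized, embedding=embedding)
    sigma = weighted_covariance(pts, normalized.weights)
    l1, l2 = _eigen_split(sigma)
    p = float(l1 - l2)
    if p > _ZERO_TOL:
        angle = wrap_axial_deg(np.degrees(
            0.5 * np.arctan2(2 * sigma[0, 1], sigma[0, 0] - sigma[1, 1])))
    else:
        p = max(p, 0.0)
        angle = None
    return PolarityReadout(cell_id=profile.cell_id, method="pca",
                           magnitude=p, angle_deg=angle)
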