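"""Per-cell morphology: area, perimeter, least-squares ellipse fit,
eccentricity, orientation, polygonal shape regularity and junction count.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import EllipseModel

from ._angles import wrap_axial_deg
from .segmentation import CellBoundary


class EllipseFitError(ValueError):
    """Raised when boundary points do not determine an ellipse."""


@dataclass(frozen=True)
class EllipseFit:
    """Least-squares ellipse: semi-axes a >= b, orientation theta (degrees,
    axial, measured from the image x-axis in the y-up frame), center (x, y).
    """
    a: float
    b: float
    theta_deg: float
    center: tuple

    @property
    def eccentricity(self) -> float:
        return eccentricity(self)

    @property
    def alpha(self) -> float:
        """Compression factor b/a that maps this ellipse to a circle."""
        return self.b / self.a

    def sample(self, n: int = 100) -> np.ndarray:
        """n points exactly on the ellipse (for tests and overlays)."""
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        th = np.radians(self.theta_deg)
        x = self.a * np.cos(t)
        y = self.b * np.sin(t)
        xr = x * np.cos(th) - y * np.sin(th) + self.center[0]
        yr = x * np.sin(th) + y * np.cos(th) + self.center[1]
        return np.c_[xr, yr]


def fit_ellipse(points_xy) -> EllipseFit:
    """Direct least-squares ellipse fit to boundary points (x, y).

    Uses the ellipse-constrained algebraic formulation, which cannot return
    a hyperbola on noisy rasters; axes are ordered a >= b and the orientation
    wrapped into (-90, +90].
    """
    if isinstance(points_xy, CellBoundary):
        points_xy = points_xy.resample_arc(max(60, min(720, len(points_xy.points_rc))))
    pts = np.asarray(points_xy, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 6:
        raise EllipseFitError("need at least 6 two-dimensional points")
    try:
        model = EllipseModel.from_estimate(pts)
        ok = bool(model)
    except AttributeError:                      # older scikit-image
        model = EllipseModel()
        ok = model.estimate(pts)
    if not ok:
        raise EllipseFitError("degenerate point set: ellipse fit failed")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])):
        raise EllipseFitError("degenerate point set: ellipse fit failed")
    if b > a:
        a, b = b, a
        theta += np.pi / 2
    if b <= 0:
        raise EllipseFitError("degenerate ellipse (zero minor axis)")
    return EllipseFit(a=float(a), b=float(b),
                      theta_deg=wrap_axial_deg(np.degrees(theta)),
                      center=(float(xc), float(yc)))


def eccentricity(fit: EllipseFit) -> float:
    """epsilon = sqrt(1 - b^2/a^2), 0 for a circle, -> 1 when elongated."""
    if fit.b > fit.a:
        raise ValueError("inconsistent ellipse: b > a")
    return float(np.sqrt(1.0 - (fit.b / fit.a) ** 2))


def area_perimeter(boundary: CellBoundary) -> tuple:
    """(area in px^2 = pixel count of the region, perimeter in px = raster
    path length of the traced loop, diagonal steps counting sqrt(2))."""
    if len(boundary.points_rc) < 3:
        raise ValueError("open or degenerate boundary loop")
    return float(boundary.area), boundary.perimeter


def interior_angles(vertices_xy) -> np.ndarray:
    """Interior angles (radians) of a simple polygon given its ordered
    vertices. Computed as pi minus the signed turn at each vertex, so the
    angles of any simple polygon sum to (n-2)*pi."""
    v = np.asarray(vertices_xy, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("polygon needs at least 3 vertices")
    prev = np.roll(v, 1, axis=0)
    nxt = np.roll(v, -1, axis=0)
    d1 = v - prev
    d2 = nxt - v
    turn = np.arctan2(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0],
                      (d1 * d2).sum(axis=1))
    # signed area decides orientation; make turns positive for CCW loops
    area2 = np.sum(v[:, 0] * nxt[:, 1] - nxt[:, 0] * v[:, 1])
    if area2 < 0:
        turn = -turn
    return np.pi - turn


def polygon_regularity(vertices_xy) -> float:
    """Shape regularity mu in [0, 1] of a polygon.

    Deviation from the regular n-gon is scored from its equilateral and
    equiangular properties:

        D = sum_i |l_i - l_median| / l_sum
            + (1/n) sum_i |phi_i - phi_reg| / phi_reg,   phi_reg = (n-2)pi/n
        mu = max(0, 1 - D)

    mu = 1 iff all edges are equally long and all interior angles equal the
    regular-polygon angle.
    """
    v = np.asarray(vertices_xy, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("polygon needs at least 3 vertices")
    edges = np.roll(v, -1, axis=0) - v
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    l_sum = lengths.sum()
    if l_sum == 0:
        return 0.0
    phi = interior_angles(v)
    phi_reg = (n - 2) * np.pi / n
    d = (np.abs(lengths - np.median(lengths)).sum() / l_sum
         + np.abs(phi - phi_reg).sum() / (n * phi_reg))
    return float(max(0.0, 1.0 - d))


def regularity(boundary: CellBoundary) -> float:
    """Shape regularity of a traced cell, polygonized at its merged vertices.

    Edge lengths are vertex-to-vertex chord lengths (not raster path
    lengths); angles are measured between incident chords.
    """
    if len(boundary.edges) < 3:
        raise ValueError("cell polygonization needs at least 3 vertices")
    return polygon_regularity(boundary.polygon_vertices_xy())


def count_junctions(edge_lengths, min_fraction: float = 0.10) -> int:
    """Number of junctions (cell sides): edges shorter than min_fraction of
    the cell's mean junctional length do not count as a side."""
    lengths = np.asarray(edge_lengths, dtype=float)
    if lengths.size == 0:
        return 0
    return int(np.sum(lengths >= min_fraction * lengths.mean()))


@dataclass(frozen=True)
class ShapeMetrics:
    cell_id: int
    area: float
    perimeter: float
    regularity: float
    eccentricity: float
    orientation_deg: float
    n_junctions: int


def shape_metrics(boundary: CellBoundary) -> ShapeMetrics:
    """All morphology readouts for one traced cell."""
    area, perim = area_perimeter(boundary)
    fit = fit_ellipse(boundary.xy)
    if len(boundary.edges) >= 3:
        mu = regularity(boundary)
        n_j = count_junctions(boundary.edge_lengths)
    else:
        mu = float("nan")
        n_j = 0
    return ShapeMetrics(cell_id=boundary.cell_id, area=area, perimeter=perim,
                        regularity=mu, eccentricity=fit.eccentricity,
                        orientation_deg=fit.theta_deg, n_junctions=n_j)
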