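"""Simulated epithelial cells with controlled geometry and junctional
intensity patterns, plus ground truth.

A cell is built as a polygon (regular n-gon by default, vertex on the +x
axis), optionally jittered to a target shape regularity and anisotropically
scaled (x*s, y/s, area-preserving) to a target eccentricity, then rasterized
to a 1-pixel-wide closed boundary ("skeleton") on a canvas with an 8-px
margin. Junctional intensity is painted onto the boundary pixels:

two-level : peak (default 255 a.u.) on a chosen placement, base (default
    40 a.u.) elsewhere. Placements are defined by the *material* angle psi
    (the pre-elongation angle of a boundary point), so the same junctions
    carry peak protein at every eccentricity:
      - vertical_junctions: |psi| <= 60 deg of either x-pole (the two
        vertical-junction edge pairs of a vertex-at-0 hexagon);
      - horizontal_junctions: the complement;
      - ("sector", d): |psi| within d degrees of either pole;
      - ("coverage", u): u perimeter units of peak (nominal perimeter
        scale), grown symmetrically along the boundary from the two poles
        at theta = 0 and 180 deg.
puncta : Gaussian bumps every `spacing` degrees; each punctum's amplitude
    follows a two-level envelope (peak on the chosen placement, base
    elsewhere), intensity relaxing to the base floor between puncta. Sigma
    is interpreted in degrees by default, making the angular profile
    independent of cell size; arc-pixel units are available as an option.

The ground-truth polarity axis of every peak-on-vertical-junction pattern is
0 degrees by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import draw

from .segmentation import CellBoundary, label_cells, trace_boundary
from .shape import fit_ellipse, polygon_regularity

PEAK_DEFAULT = 255.0
BASE_DEFAULT = 40.0
MARGIN_PX = 8


class GeneratorError(RuntimeError):
    """Raised when a geometry target cannot be realized."""


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Full parameterization of one simulated cell."""

    n_sides: int = 6
    area: Optional[float] = None            # target interior area, px^2
    perimeter: Optional[float] = 440.0      # target polygon perimeter, px
    eccentricity: float = 0.0
    regularity: Optional[float] = None      # None = perfectly regular
    intensity_model: str = "two_level"      # or "puncta"
    placement: object = "vertical_junctions"
    peak: float = PEAK_DEFAULT
    base: float = BASE_DEFAULT
    puncta_spacing_deg: float = 15.0
    puncta_sigma: float = 4.47
    puncta_sigma_units: str = "deg"         # or "px"
    bit_depth: int = 8
    seed: int = 0

    def validate(self):
        if self.n_sides < 3:
            raise ValueError("polygon needs >= 3 sides")
        if not (self.peak >= self.base > 0):
            raise ValueError("need peak >= base > 0")
        if not (0 <= self.eccentricity < 1):
            raise ValueError("eccentricity must be in [0, 1)")
        if self.area is None and self.perimeter is None:
            raise ValueError("give a target area or perimeter")
        if self.intensity_model not in ("two_level", "puncta"):
            raise ValueError(f"unknown intensity model {self.intensity_model!r}")
        if self.puncta_sigma <= 0:
            raise ValueError("puncta sigma must be positive")
        if self.puncta_sigma_units not in ("deg", "px"):
            raise ValueError("puncta sigma units must be 'deg' or 'px'")
        if isinstance(self.placement, tuple):
            kind, value = self.placement
            if kind == "coverage":
                nominal = self.perimeter if self.perimeter else 0
                if not (0 <= value <= (nominal or np.inf)):
                    raise ValueError("coverage outside [0, perimeter]")
            elif kind != "sector":
                raise ValueError(f"unknown placement {self.placement!r}")
        elif self.placement not in ("vertical_junctions", "horizontal_junctions"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass
class SyntheticCell:
    """Rasterized simulated cell: intensity image, skeleton and ground truth."""

    spec: SyntheticCellSpec
    image: np.ndarray               # integer intensity image
    skeleton: np.ndarray            # boolean boundary mask
    boundary: CellBoundary          # traced loop of the boundary pixels
    loop_intensities: np.ndarray    # painted intensity per loop pixel (a.u.)
    truth: dict = field(default_factory=dict)

    @property
    def max_value(self) -> int:
        return 2 ** self.spec.bit_depth - 1

    @property
    def scale(self) -> float:
        """a.u. -> stored integer scale factor (255 a.u. = full range)."""
        return self.max_value / 255.0


# ----------------------------------------------------------------- geometry

def _regular_polygon(n: int, circumradius: float) -> np.ndarray:
    ang = np.arange(n) * 2 * np.pi / n   # vertex on the +x axis
    return circumradius * np.c_[np.cos(ang), np.sin(ang)]


def _polygon_samples(v: np.ndarray, n: int = 240) -> np.ndarray:
    """Points evenly spaced in arc length along a polygon outline."""
    closed = np.vstack([v, v[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.r_[0.0, np.cumsum(seg)]
    t = np.linspace(0.0, s[-1], n, endpoint=False)
    return np.c_[np.interp(t, s, closed[:, 0]), np.interp(t, s, closed[:, 1])]


def _jitter_to_regularity(v0: np.ndarray, target: float, rng,
                          tol: float = 0.02, max_ecc: float = 0.15,
                          max_tries: int = 5000) -> np.ndarray:
    """Seeded rejection sampling of vertex jitter until mu hits the target.

    Candidates whose jitter induces overall cell elongation (fitted-ellipse
    eccentricity above max_ecc) are rejected, so the regularity sweep varies
    shape regularity at approximately constant eccentricity.
    """
    n = len(v0)
    radius = np.hypot(v0[:, 0], v0[:, 1]).mean()
    ang0 = np.arctan2(v0[:, 1], v0[:, 0])
    for _ in range(max_tries):
        eta = rng.uniform(0.0, 0.5)
        rho = radius * (1 + rng.uniform(-eta, eta, n))
        dang = rng.uniform(-eta, eta, n) * np.pi / n
        v = np.c_[rho * np.cos(ang0 + dang), rho * np.sin(ang0 + dang)]
        if not Polygon(v).is_valid:
            continue
        # remove the net elongation the jitter induced (rotate, compress
        # along the fitted major axis, rotate back) so regularity varies at
        # near-constant eccentricity
        fit = fit_ellipse(_polygon_samples(v))
        th = np.radians(fit.theta_deg)
        c, si = np.cos(th), np.sin(th)
        rot = np.array([[c, si], [-si, c]])
        w = v @ rot.T
        w[:, 0] *= fit.alpha
        v = w @ np.array([[c, -si], [si, c]]).T
        if not Polygon(v).is_valid:
            continue
        if abs(polygon_regularity(v) - target) > tol:
            continue
        if fit_ellipse(_polygon_samples(v)).eccentricity > max_ecc:
            continue
        return v
    raise GeneratorError(f"could not reach regularity {target} within {max_tries} tries")


def _build_polygon(spec: SyntheticCellSpec, rng) -> tuple:
    """Returns (vertices, s) with s the elongation factor applied as
    (x*s, y/s); vertices are centered on the polygon centroid."""
    if spec.perimeter is not None:
        side = spec.perimeter / spec.n_sides
        R = side / (2 * np.sin(np.pi / spec.n_sides))
    else:
        R = np.sqrt(2 * spec.area / (spec.n_sides * np.sin(2 * np.pi / spec.n_sides)))
    v = _regular_polygon(spec.n_sides, R)
    if spec.regularity is not None:
        v = _jitter_to_regularity(v, spec.regularity, rng)
    if spec.area is not None:
        v *= np.sqrt(spec.area / Polygon(v).area)
    c = Polygon(v).centroid
    v = v - np.array([c.x, c.y])
    s = (1.0 - spec.eccentricity ** 2) ** -0.25
    return v, s


def _rasterize(vertices_xy: np.ndarray) -> tuple:
    """Rasterize a polygon to (skeleton mask, origin) with an 8-px margin.

    The y-up polygon frame maps to image rows as row = y_max - y + margin.
    """
    x, y = vertices_xy[:, 0], vertices_xy[:, 1]
    x0, y1 = x.min() - MARGIN_PX, y.max() + MARGIN_PX
    cols = x - x0
    rows = y1 - y
    h = int(np.ceil(rows.max())) + MARGIN_PX + 1
    w = int(np.ceil(cols.max())) + MARGIN_PX + 1
    rr, cc = draw.polygon_perimeter(rows, cols, shape=(h, w), clip=True)
    skeleton = np.zeros((h, w), dtype=bool)
    skeleton[rr, cc] = True
    return skeleton, (y1, x0)


# ----------------------------------------------------------------- painting

def _material_angles(boundary: CellBoundary, s: float) -> np.ndarray:
    """Pre-elongation ('material') angle psi in degrees of each loop pixel."""
    xy = boundary.xy - np.array(boundary.centroid_xy)
    return np.degrees(np.arctan2(xy[:, 1] * s, xy[:, 0] / s))


def _sector_mask(psi_deg: np.ndarray, half_width_deg: float) -> np.ndarray:
    a = np.abs(psi_deg)
    return (a <= half_width_deg) | (a >= 180.0 - half_width_deg)


def _sector_fraction(psi_deg: np.ndarray, half_width_deg: float) -> np.ndarray:
    """Anti-aliased sector membership: pixels whose angular footprint
    straddles a sector edge get the covered fraction instead of 0/1.

    psi_deg must be in loop order so each pixel's footprint can be taken
    from the angular spacing of its loop neighbors.
    """
    psi = np.radians(np.asarray(psi_deg, dtype=float))
    step = np.abs(np.angle(np.exp(1j * (np.roll(psi, -1) - psi))))
    span = np.degrees((step + np.roll(step, 1)) / 2.0) + 1e-9
    a = np.degrees(np.abs(np.angle(np.exp(1j * psi))))
    a = np.minimum(a, 180.0 - a)            # distance to the nearest pole axis
    d_edge = half_width_deg - a              # > 0 inside the sector
    return np.clip(0.5 + d_edge / span, 0.0, 1.0)


def _arc_positions(boundary: CellBoundary) -> np.ndarray:
    """Arc-length position of each loop pixel along the traced loop."""
    return np.r_[0.0, np.cumsum(boundary.step_lengths[:-1])]


def _pole_arc_distance(boundary: CellBoundary) -> np.ndarray:
    """Arc distance of every loop pixel to the nearest theta = 0/180 pole."""
    xy = boundary.xy - np.array(boundary.centroid_xy)
    th = np.arctan2(xy[:, 1], xy[:, 0])
    s = _arc_positions(boundary)
    total = boundary.perimeter
    out = np.full(len(s), np.inf)
    for target in (0.0, np.pi):
        i = np.argmin(np.abs(np.angle(np.exp(1j * (th - target)))))
        d = np.abs(s - s[i])
        out = np.minimum(out, np.minimum(d, total - d))
    return out


def paint_two_level(boundary: CellBoundary, placement, s: float = 1.0,
                    peak: float = PEAK_DEFAULT, base: float = BASE_DEFAULT,
                    nominal_perimeter: Optional[float] = None) -> np.ndarray:
    """Per-loop-pixel intensities for a two-level pattern."""
    psi = _material_angles(boundary, s)
    if placement == "vertical_junctions":
        frac = _sector_fraction(psi, 60.0)
    elif placement == "horizontal_junctions":
        frac = 1.0 - _sector_fraction(psi, 60.0)
    elif isinstance(placement, tuple) and placement[0] == "sector":
        frac = _sector_fraction(psi, float(placement[1]))
    elif isinstance(placement, tuple) and placement[0] == "coverage":
        units = float(placement[1])
        nominal = nominal_perimeter or boundary.perimeter
        if not (0 <= units <= nominal):
            raise ValueError("coverage outside [0, perimeter]")
        limit = (units / nominal) * boundary.perimeter / 4.0
        step = boundary.step_lengths
        span = (step + np.roll(step, 1)) / 2.0 + 1e-9
        frac = np.clip(0.5 + (limit - _pole_arc_distance(boundary)) / span, 0.0, 1.0)
        if units == 0:
            frac[:] = 0.0
        elif units >= nominal:
            frac[:] = 1.0
    else:
        raise ValueError(f"unknown placement {placement!r}")
    return float(base) + (float(peak) - float(base)) * frac


def paint_puncta(boundary: CellBoundary, placement="vertical_junctions",
                 s: float = 1.0, peak: float = PEAK_DEFAULT,
                 base: float = BASE_DEFAULT, spacing_deg: float = 15.0,
                 sigma: float = 4.47, sigma_units: str = "deg") -> np.ndarray:
    """Per-loop-pixel intensities for a punctate pattern.

    Puncta centers sit every spacing_deg of material angle; each punctum's
    amplitude is the two-level envelope value at its center, and intensity
    decays as a Gaussian of the distance to the nearest center (angular
    degrees by default, arc pixels optionally), relaxing to the base floor.
    """
    if 360.0 % spacing_deg:
        raise ValueError("puncta spacing must divide 360 degrees")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    psi = _material_angles(boundary, s)
    centers = np.arange(-180.0, 180.0, spacing_deg)
    # punctum amplitude from the two-level envelope evaluated analytically at
    # the punctum's center angle (a punctum exactly on a sector edge counts
    # as peak), so the pattern is identical at every raster scale
    if placement == "vertical_junctions":
        in_peak = _sector_mask(centers, 60.0)
    elif placement == "horizontal_junctions":
        in_peak = ~_sector_mask(centers, 60.0)
    elif isinstance(placement, tuple) and placement[0] == "sector":
        in_peak = _sector_mask(centers, float(placement[1]))
    else:
        raise ValueError(f"puncta placement {placement!r} not supported")
    amp = np.where(in_peak, float(peak), float(base))
    center_idx = np.array([
        int(np.argmin(np.abs(np.angle(np.exp(1j * np.radians(psi - c))))))
        for c in centers])
    if sigma_units == "deg":
        d = np.abs(np.degrees(np.angle(
            np.exp(1j * np.radians(psi[:, None] - centers[None, :])))))
    else:
        pos = _arc_positions(boundary)
        total = boundary.perimeter
        d = np.abs(pos[:, None] - pos[center_idx][None, :])
        d = np.minimum(d, total - d)
    j_near = np.argmin(d, axis=1)
    d_near = d[np.arange(len(psi)), j_near]
    a_near = amp[j_near]
    return base + (a_near - base) * np.exp(-d_near ** 2 / (2 * sigma ** 2))


# ----------------------------------------------------------------- assembly

def make_cell(spec: SyntheticCellSpec) -> SyntheticCell:
    """Build a simulated cell from its spec. Deterministic given spec.seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    verts, s = _build_polygon(spec, rng)

    # closed-loop calibration: rasterize, measure, adjust. The boundary ring
    # eats ~1 perimeter of interior pixels (area bias) and rasterization
    # leaves a small sub-pixel shape anisotropy (eccentricity bias); both are
    # removed by iterating the polygon scale and the stretch factor against
    # the measured readouts.
    r_target = (1.0 - spec.eccentricity ** 2) ** -0.5  # x:y extent ratio
    best = None
    for it in range(6):
        stretched = verts * np.array([s, 1.0 / s])
        skeleton, _origin = _rasterize(stretched)
        lattice = label_cells(skeleton)
        cid = max(lattice.interior_ids(), key=lattice.area)
        boundary = trace_boundary(lattice, cid)
        fit = fit_ellipse(boundary)
        ratio = spec.area / boundary.area if spec.area is not None else 1.0
        # at target eccentricity 0 the regular polygon itself is ground truth
        # and the residual fitted eccentricity is oracle noise, so only
        # genuinely elongated specs calibrate the stretch factor
        ecc_err = (abs(fit.eccentricity - spec.eccentricity)
                   if spec.eccentricity > 0 else 0.0)
        err = abs(ratio - 1) / 0.05 + ecc_err / 0.02
        if best is None or err < best[0]:
            best = (err, skeleton, lattice, cid, boundary, s)
        if abs(ratio - 1) < 0.005 and ecc_err < 0.01:
            break
        verts = verts * np.sqrt(ratio)
        if spec.eccentricity > 0:
            r_meas = fit.a / fit.b if abs(fit.theta_deg) <= 45 else fit.b / fit.a
            s = s * np.sqrt(r_target / r_meas)
    _, skeleton, lattice, cid, boundary, s = best

    if spec.intensity_model == "two_level":
        loop_I = paint_two_level(boundary, spec.placement, s=s, peak=spec.peak,
                                 base=spec.base,
                                 nominal_perimeter=spec.perimeter)
    else:
        loop_I = paint_puncta(boundary, spec.placement, s=s, peak=spec.peak,
                              base=spec.base, spacing_deg=spec.puncta_spacing_deg,
                              sigma=spec.puncta_sigma,
                              sigma_units=spec.puncta_sigma_units)

    scale = (2 ** spec.bit_depth - 1) / 255.0
    dtype = np.uint8 if spec.bit_depth <= 8 else np.uint16
    values = np.zeros(skeleton.shape)
    rc = boundary.points_rc
    painted = np.zeros(skeleton.shape, dtype=bool)
    painted[rc[:, 0], rc[:, 1]] = True
    values[rc[:, 0], rc[:, 1]] = loop_I
    # the ordered loop can skip the odd corner pixel of the drawn outline;
    # give every remaining skeleton pixel the value of its nearest painted one
    leftover = skeleton & ~painted
    if leftover.any():
        _, (ir, ic) = ndimage.distance_transform_edt(~painted, return_indices=True)
        values[leftover] = values[ir[leftover], ic[leftover]]
    image = np.zeros(skeleton.shape, dtype=dtype)
    image[skeleton] = np.round(values[skeleton] * scale).astype(dtype)

    fit = fit_ellipse(boundary)
    axis = 90.0 if spec.placement == "horizontal_junctions" else 0.0
    truth = {
        "axis_deg": axis,
        "area": boundary.area,
        "eccentricity": fit.eccentricity,
        "orientation_deg": fit.theta_deg,
        "regularity": polygon_regularity(verts),
        "perimeter": boundary.perimeter,
        "elongation_factor": s,
    }
    return SyntheticCell(spec=spec, image=image, skeleton=skeleton,
                         boundary=boundary, loop_intensities=loop_I, truth=truth)


def add_noise(cell: SyntheticCell, snr: float, seed: int = 0) -> SyntheticCell:
    """Add zero-mean Gaussian noise scaled so that
    (mean boundary signal)/(noise sd) = snr, clipped to the bit range."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    signal = float(cell.image[cell.boundary.points_rc[:, 0],
                              cell.boundary.points_rc[:, 1]].mean())
    sd = signal / snr
    noisy = cell.image.astype(float) + rng.normal(0.0, sd, cell.image.shape)
    noisy = np.clip(np.round(noisy), 0, cell.max_value).astype(cell.image.dtype)
    return replace(cell, image=noisy)


# ------------------------------------------------------------------- sweeps

AREA_GRID = (1500, 3000, 6000, 12000, 24000, 46000)
REGULARITY_GRID = (0.50, 0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85)
ECCENTRICITY_GRID = tuple(np.round(np.arange(0.0, 0.81, 0.1), 1))
COVERAGE_GRID = tuple(range(0, 441, 40))
PEAK_GRID = (60.0, 80.0, 120.0, 160.0, 200.0, 255.0)
SNR_GRID = (4.0, 8.0, 16.0, 32.0)


def coverage_sweep(**kw):
    """Regular perimeter-440 hexagon, peak coverage grown from the poles."""
    return [make_cell(SyntheticCellSpec(perimeter=440.0,
                                        placement=("coverage", u), **kw))
            for u in COVERAGE_GRID]


def area_sweep(model: str = "two_level", **kw):
    """Apical area 1500-46000 px^2 at fixed +-60 deg peak sector."""
    return [make_cell(SyntheticCellSpec(area=float(a), perimeter=None,
                                        placement=("sector", 60.0),
                                        intensity_model=model, **kw))
            for a in AREA_GRID]


def regularity_sweep(model: str = "two_level", area: float = 14000.0,
                     seed: int = 0, **kw):
    """Shape regularity 0.5-0.85 at fixed area, +-30 deg peak sector."""
    return [make_cell(SyntheticCellSpec(area=area, perimeter=None,
                                        regularity=float(mu),
                                        placement=("sector", 30.0),
                                        intensity_model=model, seed=seed, **kw))
            for mu in REGULARITY_GRID]


def eccentricity_sweep(placement: str = "vertical_junctions",
                       area: float = 14000.0, **kw):
    """Eccentricity 0-0.8 at constant area, peak on the material junctions."""
    return [make_cell(SyntheticCellSpec(area=area, perimeter=None,
                                        eccentricity=float(e),
                                        placement=placement, **kw))
            for e in ECCENTRICITY_GRID]


def peak_ratio_sweep(base: float = BASE_DEFAULT, **kw):
    """Increasing peak intensity at fixed base on vertical junctions."""
    return [make_cell(SyntheticCellSpec(perimeter=440.0, peak=float(p),
                                        base=base,
                                        placement="vertical_junctions", **kw))
            for p in PEAK_GRID]
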