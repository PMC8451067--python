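"""Tissue-scale polarity statistics.

Polarity angles are axial (180-degree periodic), so every vector operation
here works on the doubled-angle circle: a cell with magnitude p and axis
theta is represented by the vector (p cos 2theta, p sin 2theta). The
resultant of such vectors captures both strength and coordination; its norm
can never exceed the plain average of magnitudes, with equality exactly when
all axes agree.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._angles import axial_difference_deg, wrap_axial_deg
from .readout import PolarityReadout


def _mags(readouts):
    return np.array([r.magnitude for r in readouts], dtype=float)


def _angled(readouts):
    return [r for r in readouts if r.angle_deg is not None]


def average_magnitude(readouts: Sequence[PolarityReadout]) -> float:
    """Arithmetic mean of polarity magnitudes, ignoring angles."""
    if not readouts:
        raise ValueError("no readouts")
    return float(_mags(readouts).mean())


def vector_average(readouts: Sequence) -> tuple:
    """(p_vec, theta_vec_deg): norm and axis of the mean doubled-angle
    polarity vector. p_vec <= average_magnitude, equality iff all axes equal."""
    rs = _angled(readouts)
    if not rs:
        raise ValueError("no readouts with defined angles")
    p = _mags(rs)
    th2 = 2 * np.radians([r.angle_deg for r in rs])
    vx, vy = (p * np.cos(th2)).mean(), (p * np.sin(th2)).mean()
    p_vec = float(np.hypot(vx, vy))
    theta = wrap_axial_deg(np.degrees(0.5 * np.arctan2(vy, vx))) if p_vec > 0 else None
    return p_vec, theta


@dataclass(frozen=True)
class GroupSummary:
    cell_ids: tuple
    centroid_xy: tuple
    p_vec: float
    theta_vec_deg: Optional[float]


def coarse_grain(readouts: Sequence, centroids: dict,
                 group_size: int) -> list:
    """Partition cells into spatially contiguous groups of ~group_size and
    vector-average each group.

    centroids maps cell_id -> (x, y). Cells are tiled on a centroid grid
    whose tile area holds about group_size cells.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    rs = [r for r in readouts if r.cell_id in centroids]
    n = len(rs)
    if n == 0:
        raise ValueError("no readouts with centroids")
    if group_size > n:
        warnings.warn("group_size exceeds cell count; using a single group")
        group_size = n
    xy = np.array([centroids[r.cell_id] for r in rs], dtype=float)
    n_groups = max(1, round(n / group_size))
    # split the tissue along its longer extent first so tiles stay compact
    ext_x = np.ptp(xy[:, 0]) + 1e-9
    ext_y = np.ptp(xy[:, 1]) + 1e-9
    nx = int(np.clip(np.round(np.sqrt(n_groups * ext_x / ext_y)), 1, n_groups))
    ny = max(1, int(np.ceil(n_groups / nx)))
    # rank-based tiling gives (nearly) equal-count tiles
    ix = np.minimum((np.argsort(np.argsort(xy[:, 0])) * nx) // n, nx - 1)
    groups = {}
    for tile_x in range(nx):
        sel = np.nonzero(ix == tile_x)[0]
        if sel.size == 0:
            continue
        iy = np.minimum((np.argsort(np.argsort(xy[sel, 1])) * ny) // sel.size, ny - 1)
        for tile_y in range(ny):
            members = sel[iy == tile_y]
            if members.size:
                groups[(tile_x, tile_y)] = members
    out = []
    for members in groups.values():
        sub = [rs[i] for i in members]
        try:
            p_vec, theta = vector_average(sub)
        except ValueError:
            p_vec, theta = 0.0, None
        out.append(GroupSummary(cell_ids=tuple(r.cell_id for r in sub),
                                centroid_xy=tuple(xy[members].mean(axis=0)),
                                p_vec=p_vec, theta_vec_deg=theta))
    return out


def neighbor_vector(readouts: Sequence, adjacency: dict) -> tuple:
    """Per-cell vector average over each cell and its immediate neighbors,
    plus the tissue mean of those values.

    Returns (per_cell: dict cell_id -> (p_vec, theta_deg), tissue_mean).
    """
    by_id = {r.cell_id: r for r in readouts}
    per_cell = {}
    for cid, r in by_id.items():
        group = [r] + [by_id[nb] for nb in adjacency.get(cid, ()) if nb in by_id]
        try:
            per_cell[cid] = vector_average(group)
        except ValueError:
            per_cell[cid] = (0.0, None)
    if not per_cell:
        raise ValueError("no readouts")
    tissue_mean = float(np.mean([v[0] for v in per_cell.values()]))
    return per_cell, tissue_mean


def angle_variance(readouts: Sequence) -> float:
    """Circular variance of polarity axes on the doubled-angle circle:
    1 - |mean exp(2i theta)|. 0 = perfect alignment, 1 = full misalignment."""
    rs = _angled(readouts)
    if not rs:
        raise ValueError("no readouts with defined angles")
    th2 = 2 * np.radians([r.angle_deg for r in rs])
    return float(1.0 - np.abs(np.exp(1j * th2).mean()))


def mean_angle_difference(readouts_a: Sequence, readouts_b: Sequence) -> float:
    """Mean per-cell axial angle difference (degrees, in [0, 90]) between two
    methods' readouts over the same cells."""
    a = {r.cell_id: r.angle_deg for r in readouts_a if r.angle_deg is not None}
    b = {r.cell_id: r.angle_deg for r in readouts_b if r.angle_deg is not None}
    common = sorted(set(a) & set(b))
    if set(a) != set(b):
        raise ValueError("readout cell id sets differ")
    if not common:
        raise ValueError("no cells with defined angles in both sets")
    d = [axial_difference_deg(a[c], b[c]) for c in common]
    return float(np.mean(d))


def weighted_circular_histogram(readouts: Sequence, n_bins: int = 20) -> tuple:
    """Magnitude-weighted histogram of polarity axes over 0-360 degrees.

    Each axis is plotted twice (theta and theta+180). Bin height = count in
    bin x mean magnitude in bin. Returns (bin_edges_deg, heights)."""
    rs = _angled(readouts)
    if not rs:
        raise ValueError("no readouts with defined angles")
    ang = np.array([r.angle_deg % 360.0 for r in rs])
    ang = np.r_[ang, (ang + 180.0) % 360.0]
    mags = np.r_[_mags(rs), _mags(rs)]
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    idx = np.minimum((ang // (360.0 / n_bins)).astype(int), n_bins - 1)
    heights = np.zeros(n_bins)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            heights[b] = sel.sum() * mags[sel].mean()
    return edges, heights


def normalize_across_dataset(readouts: Sequence) -> list:
    """Dataset-normalized magnitudes: PCA/Fourier p/max(p); Ratio
    (r-1)/max(r-1). The maximal cell maps to exactly 1."""
    if not readouts:
        raise ValueError("no readouts")
    methods = {r.method for r in readouts}
    if len(methods) != 1:
        raise ValueError("normalize one method at a time")
    raw = _mags(readouts)
    if next(iter(methods)) == "ratio":
        raw = raw - 1.0
    mx = raw.max()
    if mx <= 0:
        warnings.warn("maximum magnitude is zero; all normalized values set to 0")
        return [r.with_norm(0.0) for r in readouts]
    return [r.with_norm(float(v / mx)) for r, v in zip(readouts, raw)]
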