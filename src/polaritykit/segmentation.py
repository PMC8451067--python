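"""Parsing skeletonized epithelial segmentations into cells, vertices and
neighbor relations.

The input is the standard output format of watershed-style segmentation
tools: a binary image in which 1-pixel-wide boundary lines (the "skeleton")
separate cell interiors. Cells are 4-connected regions of background; the
boundary network is treated as 8-connected, the complementary pairing that
prevents regions from tunnelling through diagonal line pixels.

A vertex (tricellular junction) is a skeleton pixel whose vertex degree
k = n3x3 - 1 (number of foreground pixels in its 3x3 neighborhood, center
excluded) is at least 3, i.e. a pixel where three or more edges meet.
Rasterization often produces small clusters of such pixels at one biological
vertex; 8-connected clusters are merged to a single vertex at their mean
position.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
EIGHT_CONN = np.ones((3, 3), dtype=bool)


class SkeletonFormatError(ValueError):
    """Raised when the boundary image is not a binary skeleton."""


class EmptyLatticeError(ValueError):
    """Raised when a segmentation contains no usable (enclosed) cell."""


def as_skeleton(mask) -> np.ndarray:
    """Validate and coerce a boundary image into a boolean skeleton mask.

    Any nonzero pixel counts as boundary. Raises SkeletonFormatError for
    non-2D input.
    """
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise SkeletonFormatError(f"skeleton must be 2D, got shape {arr.shape}")
    return arr != 0


@dataclass
class CellBoundary:
    """Ordered closed pixel loop of one cell's junctional boundary.

    points_rc : (n, 2) int array of (row, col) boundary pixels in loop order,
        counter-clockwise in the mathematical y-up frame.
    centroid_rc : (row, col) sub-pixel area centroid of the cell region.
    step_lengths : (n,) distances from each point to the next (1 or sqrt 2).
    vertex_positions : (m, 2) float array of merged vertex (row, col).
    edges : list of (i, j) indices into vertex_positions for consecutive
        vertex-to-vertex segments along the loop.
    edge_lengths : chord lengths of those segments (used for polygonal shape
        metrics; the raster path length is used for the perimeter).
    """

    cell_id: int
    points_rc: np.ndarray
    centroid_rc: tuple
    area: float
    step_lengths: np.ndarray = None
    vertex_positions: np.ndarray = None
    edges: list = field(default_factory=list)

    def __post_init__(self):
        if self.step_lengths is None:
            d = np.diff(np.vstack([self.points_rc, self.points_rc[:1]]), axis=0)
            self.step_lengths = np.hypot(d[:, 0], d[:, 1])

    @property
    def perimeter(self) -> float:
        return float(self.step_lengths.sum())

    @property
    def xy(self) -> np.ndarray:
        """Boundary points as (x, y) in the y-up mathematical frame."""
        return np.c_[self.points_rc[:, 1].astype(float), -self.points_rc[:, 0].astype(float)]

    @property
    def centroid_xy(self) -> tuple:
        return (float(self.centroid_rc[1]), -float(self.centroid_rc[0]))

    @property
    def edge_lengths(self) -> np.ndarray:
        if not self.edges:
            return np.array([])
        v = self.vertex_positions
        return np.array([np.hypot(*(v[j] - v[i])) for i, j in self.edges])

    def resample_arc(self, n: int = 360) -> np.ndarray:
        """(n, 2) points evenly spaced in arc length along the loop (x, y).

        Evens out the direction-dependent pixel density of raster lines;
        used for ellipse fitting so a symmetric cell fits a symmetric ellipse.
        """
        pts = np.vstack([self.xy, self.xy[:1]])
        seg = np.hypot(*np.diff(pts, axis=0).T)
        s = np.r_[0.0, np.cumsum(seg)]
        target = np.linspace(0.0, s[-1], n, endpoint=False)
        return np.c_[np.interp(target, s, pts[:, 0]),
                     np.interp(target, s, pts[:, 1])]

    def polygon_vertices_xy(self) -> np.ndarray:
        """Merged vertices as (x, y), ordered along the loop."""
        order = [i for i, _ in self.edges]
        v = self.vertex_positions[order]
        return np.c_[v[:, 1], -v[:, 0]]


@dataclass
class CellLattice:
    """Labeled cell map plus vertex set and adjacency."""

    labels: np.ndarray
    skeleton: np.ndarray
    vertices: np.ndarray          # (m, 2) merged vertex positions (row, col)
    vertex_mask: np.ndarray       # boolean mask of raw vertex pixels
    vertex_ids: np.ndarray        # int map: cluster id per pixel (0 = none)
    adjacency: dict               # cell id -> set of neighboring cell ids
    border_cells: set             # ids of cells touching the image frame

    @property
    def cell_ids(self):
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]

    def interior_ids(self):
        return [i for i in self.cell_ids if i not in self.border_cells]

    def area(self, cell_id: int) -> int:
        return int(np.sum(self.labels == cell_id))


def detect_vertices(skeleton) -> np.ndarray:
    """Vertex pixels of a skeleton: foreground pixels with degree k >= 3.

    k counts foreground pixels in the 3x3 neighborhood excluding the center.
    Returns the boolean mask of raw vertex pixels.
    """
    sk = as_skeleton(skeleton)
    n3x3 = ndimage.convolve(sk.astype(np.uint8), np.ones((3, 3), np.uint8),
                            mode="constant", cval=0)
    degree = n3x3 - 1
    return sk & (degree >= 3)


def merge_vertex_clusters(vertex_mask) -> tuple:
    """Merge 8-connected vertex-pixel clusters to their mean positions.

    Returns (positions (m,2) float array, cluster id map with 0 = no vertex).
    """
    lab, n = ndimage.label(vertex_mask, structure=EIGHT_CONN)
    if n == 0:
        return np.empty((0, 2)), lab
    pos = np.array(ndimage.center_of_mass(vertex_mask, lab, np.arange(1, n + 1)))
    return pos, lab


def label_cells(skeleton) -> CellLattice:
    """Label 4-connected cell regions of a skeletonized segmentation."""
    sk = as_skeleton(skeleton)
    labels, n = ndimage.label(~sk, structure=FOUR_CONN)
    if n == 0:
        raise EmptyLatticeError("no cell regions found (mask is all boundary)")
    border = set()
    frame = np.zeros_like(labels, dtype=bool)
    frame[0, :] = frame[-1, :] = frame[:, 0] = frame[:, -1] = True
    for lab_id in np.unique(labels[frame]):
        if lab_id != 0:
            border.add(int(lab_id))
    if len(border) == n:
        raise EmptyLatticeError("no enclosed cell region (all regions touch the frame)")
    vmask = detect_vertices(sk)
    vpos, vids = merge_vertex_clusters(vmask)
    lattice = CellLattice(labels=labels, skeleton=sk, vertices=vpos,
                          vertex_mask=vmask, vertex_ids=vids,
                          adjacency={}, border_cells=border)
    lattice.adjacency = find_neighbors(lattice)
    return lattice


def find_neighbors(lattice: CellLattice, min_shared_pixels: int = 2) -> dict:
    """Cell adjacency: two cells are neighbors iff they share a boundary
    segment, operationalized as >= min_shared_pixels skeleton pixels having
    both cells in their 8-neighborhood (a single shared pixel is vertex-only
    contact and does not count)."""
    labels = lattice.labels
    counts = {}
    rows, cols = np.nonzero(lattice.skeleton)
    h, w = labels.shape
    for r, c in zip(rows, cols):
        seen = set()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    lab_id = labels[rr, cc]
                    if lab_id != 0:
                        seen.add(int(lab_id))
        for a in seen:
            for b in seen:
                if a < b:
                    counts[(a, b)] = counts.get((a, b), 0) + 1
    adj = {cid: set() for cid in lattice.cell_ids}
    for (a, b), k in counts.items():
        if k >= min_shared_pixels:
            adj[a].add(b)
            adj[b].add(a)
    return adj


def filter_cells(lattice: CellLattice, min_area: float = 1.0,
                 drop_border: bool = True) -> CellLattice:
    """Remove image-border cells and cells below an area threshold.

    Surviving cell ids are preserved; removed cells' pixels become
    background. Adjacency is rebuilt on the filtered lattice, so links into
    removed cells disappear.
    """
    if min_area < 0:
        raise ValueError("min_area must be non-negative")
    labels = lattice.labels.copy()
    keep = []
    for cid in lattice.cell_ids:
        if drop_border and cid in lattice.border_cells:
            labels[labels == cid] = 0
        elif lattice.area(cid) < min_area:
            labels[labels == cid] = 0
        else:
            keep.append(cid)
    out = CellLattice(labels=labels, skeleton=lattice.skeleton,
                      vertices=lattice.vertices, vertex_mask=lattice.vertex_mask,
                      vertex_ids=lattice.vertex_ids, adjacency={},
                      border_cells={c for c in lattice.border_cells if c in keep})
    out.adjacency = find_neighbors(out)
    return out


# Moore neighborhood in clockwise order starting from west (row, col offsets).
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


_MOORE_INDEX = {off: i for i, off in enumerate(_MOORE)}

# walk preferences: 4-neighbors before diagonals so thin curves are followed
# pixel by pixel instead of cutting corners
_WALK_OFFSETS = [(0, 1), (1, 0), (0, -1), (-1, 0),
                 (1, 1), (1, -1), (-1, 1), (-1, -1)]


def _walk_ring(ring_mask: np.ndarray) -> np.ndarray:
    """Order the pixels of a thin closed 8-connected curve into a loop.

    Greedy walk over unvisited ring pixels, preferring 4-connected steps;
    at local double-pixel clumps (raster corners) the occasional pixel may be
    left out of the loop, which only perturbs the path length marginally.
    """
    rows, cols = np.nonzero(ring_mask)
    if rows.size == 0:
        raise ValueError("empty ring")
    pixels = set(zip(rows.tolist(), cols.tolist()))
    r0 = int(rows.min())
    start = (r0, int(cols[rows == r0].min()))
    loop = [start]
    visited = {start}
    cur = start
    while True:
        nxt = None
        for dr, dc in _WALK_OFFSETS:
            p = (cur[0] + dr, cur[1] + dc)
            if p in pixels and p not in visited:
                nxt = p
                break
        if nxt is None:
            break
        loop.append(nxt)
        visited.add(nxt)
        cur = nxt
    return np.array(loop, dtype=int)


def _moore_trace(mask: np.ndarray) -> np.ndarray:
    """Ordered outer boundary pixels of a connected mask (Moore-neighbor
    tracing with Jacob's stopping criterion). Returns (n, 2) of (row, col)."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    r0 = int(rows.min())
    start = (r0, int(cols[rows == r0].min()))
    h, w = mask.shape

    def fg(p):
        r, c = p
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    contour = [start]
    cur = start
    b_dir = 0  # direction from cur to its backtrack (background) pixel; west
    state0 = (start, b_dir)
    for _ in range(4 * int(mask.sum()) + 8):
        for k in range(1, 9):
            d = (b_dir + k) % 8
            nxt = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if fg(nxt):
                break
        else:
            return np.array(contour, dtype=int)  # isolated pixel
        back = (cur[0] + _MOORE[(b_dir + k - 1) % 8][0],
                cur[1] + _MOORE[(b_dir + k - 1) % 8][1])
        nxt_b_dir = _MOORE_INDEX[(back[0] - nxt[0], back[1] - nxt[1])]
        if (nxt, nxt_b_dir) == state0:
            return np.array(contour, dtype=int)  # walk would repeat itself
        contour.append(nxt)
        cur, b_dir = nxt, nxt_b_dir
    raise RuntimeError("boundary tracing failed to terminate")


def _signed_area_rc(points_rc: np.ndarray) -> float:
    """Shoelace signed area of a (row, col) loop in the y-up frame."""
    x = points_rc[:, 1].astype(float)
    y = -points_rc[:, 0].astype(float)
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def trace_boundary(lattice: CellLattice, cell_id: int) -> CellBoundary:
    """Ordered loop of the skeleton pixels around one cell.

    The loop runs counter-clockwise in the mathematical (y-up) frame. The
    centroid is the area centroid of the labeled cell region.
    """
    region = lattice.labels == cell_id
    if not region.any():
        raise KeyError(f"no cell with id {cell_id}")
    ring = ndimage.binary_dilation(region, structure=EIGHT_CONN) & (lattice.labels == 0)
    loop = _walk_ring(ring)
    if _signed_area_rc(loop) < 0:
        loop = loop[::-1]
    r, c = np.nonzero(region)
    centroid = (float(r.mean()), float(c.mean()))
    boundary = CellBoundary(cell_id=cell_id, points_rc=loop,
                            centroid_rc=centroid, area=float(region.sum()))
    _attach_vertices(boundary, lattice)
    return boundary


def _attach_vertices(boundary: CellBoundary, lattice: CellLattice) -> None:
    """Locate merged vertices along the loop and build the edge list."""
    ids = lattice.vertex_ids[boundary.points_rc[:, 0], boundary.points_rc[:, 1]]
    hit = np.nonzero(ids)[0]
    if hit.size == 0:
        boundary.vertex_positions = np.empty((0, 2))
        boundary.edges = []
        return
    # compress consecutive runs of the same cluster id along the loop
    seq = []
    for idx in hit:
        cid = ids[idx]
        if not seq or seq[-1][0] != cid:
            seq.append((cid, idx))
    if len(seq) > 1 and seq[0][0] == seq[-1][0]:
        seq.pop()
    cluster_ids = [cid for cid, _ in seq]
    boundary.vertex_positions = lattice.vertices[np.array(cluster_ids) - 1]
    m = len(cluster_ids)
    boundary.edges = [(i, (i + 1) % m) for i in range(m)] if m >= 2 else []
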