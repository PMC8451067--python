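import numpy as np
import pytest
from hypothesis import settings

import polaritykit as pk

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def square_grid_skeleton(n_cells: int = 3, pitch: int = 13,
                         frame: bool = True) -> np.ndarray:
    """Skeleton of an n x n grid of square cells (lines every `pitch` px).

    With frame=False the outer lines are omitted, so the outer cells touch
    the image border and get flagged as border cells.
    """
    size = n_cells * pitch + 1
    sk = np.zeros((size, size), dtype=bool)
    lines = range(0, size, pitch) if frame else range(pitch, size - 1, pitch)
    for k in lines:
        sk[k, :] = True
        sk[:, k] = True
    return sk


@pytest.fixture(scope="session")
def grid_lattice():
    return pk.label_cells(square_grid_skeleton(3, 13, frame=True))


@pytest.fixture(scope="session")
def hexagon_cell():
    """Standard two-level validation cell: regular hexagon, perimeter 440,
    peak 255 on the vertical junctions, base 40 elsewhere."""
    return pk.make_cell(pk.SyntheticCellSpec(perimeter=440.0,
                                             placement="vertical_junctions"))


@pytest.fixture(scope="session")
def hexagon_readouts(hexagon_cell):
    return pk.measure_cell(hexagon_cell)


def dense_profile(intensity_fn, n: int = 2000, radius: float = 50.0):
    """Analytic circular-cell profile: n points on a circle with intensity
    given by intensity_fn(theta)."""
    th = np.linspace(-np.pi, np.pi, n, endpoint=False)
    xy = radius * np.c_[np.cos(th), np.sin(th)]
    return pk.BoundaryProfile.from_points(xy, intensity_fn(th))


def readout(cell_id, method, magnitude, angle):
    return pk.PolarityReadout(cell_id=cell_id, method=method,
                              magnitude=magnitude, angle_deg=angle)
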