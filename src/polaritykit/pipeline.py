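"""End-to-end analysis: images in, per-cell tables and summaries out.

The minimal contract: an intensity image plus its matching skeletonized
segmentation yield one row per retained cell in the shape table and one row
per cell and method in the polarity table, plus tissue-scale summaries.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import tissue
from .fourier import fourier_polarity
from .pca import pca_polarity
from .profiles import junction_mean_image, sample_intensity
from .ratio import ratio_polarity
from .readout import PolarityReadout
from .segmentation import (CellLattice, EmptyLatticeError, filter_cells,
                           label_cells, trace_boundary)
from .shape import fit_ellipse, shape_metrics
from .synthetic import SyntheticCell

log = logging.getLogger("polaritykit")

SCHEMA_VERSION = "polaritykit-csv-v1"
ALL_METHODS = ("pca", "fourier", "ratio")


@dataclass
class RunConfig:
    methods: Sequence[str] = ALL_METHODS
    min_area: float = 20.0
    drop_border: bool = True
    thickness: float = 3.0
    ratio_angle_step: float = 1.0
    ratio_resample_step: float = 1.0
    pca_k: float = 1.0e3
    group_size: int = 10
    normalize_per_image: bool = True
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown or not self.methods:
            raise ValueError(f"method selection must be a nonempty subset of {ALL_METHODS}")


def measure_boundary(profile, fit, method: str, config: RunConfig = None) -> PolarityReadout:
    config = config or RunConfig()
    if method == "pca":
        return pca_polarity(profile, fit=fit, k=config.pca_k)
    if method == "fourier":
        return fourier_polarity(profile)
    if method == "ratio":
        return ratio_polarity(profile, angle_step=config.ratio_angle_step,
                              resample_step=config.ratio_resample_step)
    raise ValueError(f"unknown method {method!r}")


def analyze_lattice(image, lattice: CellLattice, config: RunConfig = None) -> dict:
    """Measure every cell of a labeled lattice.

    Returns dict with 'shape' and 'polarity' DataFrames, 'readouts'
    (method -> list of PolarityReadout with dataset-normalized magnitudes),
    'centroids' and the lattice itself.
    """
    config = config or RunConfig()
    smoothed = junction_mean_image(image, lattice.skeleton, config.thickness)
    shapes, centroids = [], {}
    readouts = {m: [] for m in config.methods}
    for cid in lattice.cell_ids:
        boundary = trace_boundary(lattice, cid)
        try:
            fit = fit_ellipse(boundary)
        except Exception as exc:            # skip unfittable slivers
            log.warning("cell %d skipped: %s", cid, exc)
            continue
        shapes.append(shape_metrics(boundary))
        centroids[cid] = boundary.centroid_xy
        profile = sample_intensity(boundary, image, config.thickness, smoothed=smoothed)
        for m in config.methods:
            readouts[m].append(measure_boundary(profile, fit, m, config))
    if not shapes:
        raise EmptyLatticeError("no measurable cells in lattice")
    readouts = {m: tissue.normalize_across_dataset(rs) for m, rs in readouts.items()}
    shape_df = pd.DataFrame([asdict(s) for s in shapes])
    pol_df = pd.DataFrame([
        {"cell_id": r.cell_id, "method": m, "magnitude_raw": r.magnitude,
         "magnitude_norm": r.magnitude_norm, "angle_deg": r.angle_deg}
        for m, rs in readouts.items() for r in rs])
    return {"shape": shape_df, "polarity": pol_df, "readouts": readouts,
            "centroids": centroids, "lattice": lattice}


def tissue_summary(result: dict, config: RunConfig = None) -> pd.DataFrame:
    config = config or RunConfig()
    rows = []
    for m, rs in result["readouts"].items():
        p_avg = tissue.average_magnitude(rs)
        try:
            p_vec, theta_vec = tissue.vector_average(rs)
            var = tissue.angle_variance(rs)
        except ValueError:
            p_vec, theta_vec, var = float("nan"), None, float("nan")
        try:
            _, nb_mean = tissue.neighbor_vector(rs, result["lattice"].adjacency)
        except ValueError:
            nb_mean = float("nan")
        rows.append({"method": m, "n_cells": len(rs), "p_average": p_avg,
                     "p_vector": p_vec, "theta_vector_deg": theta_vec,
                     "neighbor_vector_mean": nb_mean, "angle_variance": var})
    return pd.DataFrame(rows)


def run_image(intensity_path, skeleton_path, out_dir,
              config: RunConfig = None, roi_paths: Sequence = ()) -> dict:
    """Analyze one intensity/skeleton image pair and write the result bundle."""
    import tifffile
    from imageio.v3 import imread

    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _read(path):
        path = str(path)
        if path.lower().endswith((".tif", ".tiff")):
            return tifffile.imread(path)
        return imread(path)

    image = np.asarray(_read(intensity_path))
    skeleton = np.asarray(_read(skeleton_path)) != 0
    if image.shape != skeleton.shape:
        raise ValueError(f"dimension mismatch: image {image.shape} vs skeleton {skeleton.shape}")
    lattice = filter_cells(label_cells(skeleton), min_area=config.min_area,
                           drop_border=config.drop_border)
    result = analyze_lattice(image, lattice, config)
    summary = tissue_summary(result, config)

    def _write(df, name):
        path = out / name
        with open(path, "w") as fh:
            fh.write(f"# {SCHEMA_VERSION}\n")
            df.to_csv(fh, index=False)

    _write(result["shape"], "shape.csv")
    _write(result["polarity"], "polarity.csv")
    _write(summary, "tissue.csv")
    for m, rs in result["readouts"].items():
        try:
            edges, heights = tissue.weighted_circular_histogram(rs)
        except ValueError:
            continue
        _write(pd.DataFrame({"bin_left_deg": edges[:-1], "bin_right_deg": edges[1:],
                             "weighted_height": heights}), f"histogram_{m}.csv")
        groups = tissue.coarse_grain(rs, result["centroids"], config.group_size)
        _write(pd.DataFrame([
            {"group_x": g.centroid_xy[0], "group_y": g.centroid_xy[1],
             "n_cells": len(g.cell_ids), "p_vector": g.p_vec,
             "theta_vector_deg": g.theta_vec_deg} for g in groups]),
            f"coarse_grain_{m}.csv")
    for i, roi_path in enumerate(roi_paths):
        mask = np.asarray(_read(roi_path)) != 0
        rows = []
        for m, rs in result["readouts"].items():
            sel = [r for r in rs if _in_roi(result["centroids"].get(r.cell_id), mask)]
            if sel:
                p_vec, theta_vec = tissue.vector_average(sel)
                rows.append({"roi": i, "method": m, "n_cells": len(sel),
                             "p_average": tissue.average_magnitude(sel),
                             "p_vector": p_vec, "theta_vector_deg": theta_vec})
        if rows:
            _write(pd.DataFrame(rows), f"roi_{i}.csv")
    try:
        save_overlays(image, result, out)
    except Exception as exc:                       # plotting is best-effort
        log.warning("overlay rendering failed: %s", exc)
    with open(out / "run.json", "w") as fh:
        json.dump({"config": {**asdict(config), "methods": list(config.methods)},
                   "intensity": str(intensity_path),
                   "skeleton": str(skeleton_path),
                   "n_cells": int(result["shape"].shape[0])}, fh, indent=2)
    return {**result, "summary": summary, "out_dir": out}


def _in_roi(centroid_xy, mask) -> bool:
    if centroid_xy is None:
        return False
    col = int(round(centroid_xy[0]))
    row = int(round(-centroid_xy[1]))
    return (0 <= row < mask.shape[0] and 0 <= col < mask.shape[1]
            and bool(mask[row, col]))


def save_overlays(image, result: dict, out_dir, bar_scale: float = 0.8):
    """Polarity-bar overlay per method and a colormapped eccentricity map."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    shape_df = result["shape"]
    for m, rs in result["readouts"].items():
        fig, ax = plt.subplots(figsize=(6, 6))
        ax.imshow(image, cmap="gray")
        for r in rs:
            if r.angle_deg is None or not r.magnitude_norm:
                continue
            cx, cy = result["centroids"][r.cell_id]
            row = shape_df.loc[shape_df.cell_id == r.cell_id]
            diam = float(np.sqrt(row.area.iloc[0] / np.pi)) * 2
            L = bar_scale * r.magnitude_norm * diam / 2
            th = np.radians(r.angle_deg)
            dx, dy = L * np.cos(th), L * np.sin(th)
            ax.plot([cx - dx, cx + dx], [-cy + dy, -cy - dy], lw=2)
        ax.set_axis_off()
        fig.savefig(out / f"overlay_{m}.png", dpi=120, bbox_inches="tight")
        plt.close(fig)


def run_batch(folder, out_dir, config: RunConfig = None,
              intensity_suffix: str = "_intensity.tif",
              skeleton_suffix: str = "_skeleton.png") -> pd.DataFrame:
    """Process every matched image pair in a folder.

    Pairs are matched by shared stem: <stem><intensity_suffix> with
    <stem><skeleton_suffix>. Per-image failures are logged, not fatal.
    Returns the combined long-format polarity table.
    """
    folder = Path(folder)
    out = Path(out_dir)
    pairs = []
    for p in sorted(folder.glob(f"*{intensity_suffix}")):
        stem = p.name[: -len(intensity_suffix)]
        sk = folder / f"{stem}{skeleton_suffix}"
        if sk.exists():
            pairs.append((stem, p, sk))
    if not pairs:
        raise FileNotFoundError(f"no matched image pairs in {folder}")
    combined, failures = [], []
    for stem, ipath, spath in pairs:
        try:
            res = run_image(ipath, spath, out / stem, config)
            df = res["polarity"].copy()
            df.insert(0, "image_id", stem)
            combined.append(df)
        except Exception as exc:
            failures.append(stem)
            log.error("image %s failed: %s", stem, exc)
    if not combined:
        raise RuntimeError("all images in batch failed")
    table = pd.concat(combined, ignore_index=True)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "combined_polarity.csv", "w") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        table.to_csv(fh, index=False)
    if failures:
        log.warning("batch finished with %d failed image(s): %s",
                    len(failures), ", ".join(failures))
    return table


# -------------------------------------------------- synthetic-cell analysis

def measure_cell(cell: SyntheticCell, methods: Sequence[str] = ALL_METHODS,
                 config: RunConfig = None) -> dict:
    """Run polarity methods on one simulated cell (its own raster pipeline:
    label, trace, ellipse fit, profile, method). Returns method -> readout."""
    config = config or RunConfig(methods=methods)
    lattice = label_cells(cell.skeleton)
    cid = max(lattice.interior_ids(), key=lattice.area)
    boundary = trace_boundary(lattice, cid)
    profile = sample_intensity(boundary, cell.image.astype(float), config.thickness,
                               mask=lattice.skeleton)
    fit = fit_ellipse(boundary)
    return {m: measure_boundary(profile, fit, m, config) for m in methods}
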