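"""Validation studies on simulated cells.

Each function generates its fixtures with the synthetic module, runs the
polarity methods through the standard measurement pipeline, and reduces the
readouts to the summary quantities of interest (argmax positions, relative
spreads, worst-case errors). These are the canonical experiments for
characterizing the three methods; the test suite and the reproduction script
both call them.
"""
from __future__ import annotations

import numpy as np

from ._angles import axial_difference_deg
from .pipeline import ALL_METHODS, RunConfig, measure_cell
from .synthetic import (AREA_GRID, COVERAGE_GRID, ECCENTRICITY_GRID,
                        PEAK_GRID, REGULARITY_GRID, SNR_GRID,
                        SyntheticCellSpec, add_noise, area_sweep,
                        coverage_sweep, eccentricity_sweep, make_cell,
                        peak_ratio_sweep, regularity_sweep)

BASE = 40.0

# Noiseless fixtures carry their junctional signal on the 1-px painted
# boundary, so they are sampled at thickness 1 (no averaging needed); the
# noise study uses the standard 3-px junction disk, as for real images.
NOISELESS = RunConfig(thickness=1.0)


def _measure_sweep(cells, config=None):
    out = {m: {"magnitude": [], "angle": []} for m in ALL_METHODS}
    for cell in cells:
        res = measure_cell(cell, config=config)
        for m in ALL_METHODS:
            out[m]["magnitude"].append(res[m].magnitude)
            out[m]["angle"].append(res[m].angle_deg)
    for m in ALL_METHODS:
        out[m]["magnitude"] = np.array(out[m]["magnitude"])
    return out


def coverage_study() -> dict:
    """Peak-coverage sweep on the perimeter-440 hexagon: the coverage (px)
    maximizing each method's polarity magnitude."""
    res = _measure_sweep(coverage_sweep(), config=NOISELESS)
    grid = np.array(COVERAGE_GRID)
    return {m: {"argmax_coverage": float(grid[np.argmax(res[m]["magnitude"])]),
                "magnitudes": res[m]["magnitude"]} for m in ALL_METHODS}


def eccentricity_study(placement: str = "vertical_junctions") -> dict:
    """Eccentricity sweep 0-0.8 with peak protein on the vertical junctions."""
    res = _measure_sweep(eccentricity_sweep(placement=placement), config=NOISELESS)
    grid = np.array(ECCENTRICITY_GRID)
    truth_axis = 90.0 if placement == "horizontal_junctions" else 0.0
    out = {}
    for m in ALL_METHODS:
        mags = res[m]["magnitude"]
        angs = np.array([axial_difference_deg(a, truth_axis)
                         for a in res[m]["angle"]])
        out[m] = {
            "argmax_eccentricity": float(grid[np.argmax(mags)]),
            "relative_spread": float((mags.max() - mags.min()) / mags.mean()),
            "max_angle_error_deg": float(angs.max()),
            "magnitudes": mags,
        }
    return out


def _fluctuation(mags: np.ndarray) -> float:
    """Max relative deviation from the sweep mean, on the raw magnitude scale."""
    return float(np.abs(mags - mags.mean()).max() / mags.mean())


def invariance_study(model: str = "two_level") -> dict:
    """Area and regularity sweeps: per-method magnitude fluctuation (relative
    to the sweep mean, raw magnitude scale) and worst angle error."""
    out = {}
    for name, cells in (("area", area_sweep(model=model)),
                        ("regularity", regularity_sweep(model=model))):
        res = _measure_sweep(cells, config=NOISELESS)
        out[name] = {m: {
            "fluctuation": _fluctuation(res[m]["magnitude"]),
            "max_angle_error_deg": float(max(
                axial_difference_deg(a, 0.0) for a in res[m]["angle"]
                if a is not None)),
        } for m in ALL_METHODS}
    return out


def brightness_study(factors=(0.25, 0.5, 1.0)) -> dict:
    """Global image-brightness scaling at constant peak-to-base ratio: the
    readouts should not move."""
    mags = {m: [] for m in ALL_METHODS}
    angs = {m: [] for m in ALL_METHODS}
    for f in factors:
        cell = make_cell(SyntheticCellSpec(perimeter=440.0, peak=255.0 * f,
                                           base=BASE * f))
        res = measure_cell(cell, config=NOISELESS)
        for m in ALL_METHODS:
            mags[m].append(res[m].magnitude)
            angs[m].append(res[m].angle_deg)
    return {m: {
        "fluctuation": _fluctuation(np.array(mags[m])),
        "max_angle_error_deg": float(max(axial_difference_deg(a, 0.0)
                                         for a in angs[m])),
    } for m in ALL_METHODS}


def noise_study(seed: int = 0, snr_grid=SNR_GRID, n_seeds: int = 20) -> dict:
    """Gaussian-noise robustness across the SNR grid.

    Per method: max relative magnitude error (vs the noiseless readout, raw
    magnitude scale). For the Ratio method also the max absolute axial angle
    deviation from the 0-degree ground truth.
    """
    rng = np.random.default_rng(seed)
    cell = make_cell(SyntheticCellSpec(perimeter=440.0,
                                       placement="vertical_junctions"))
    clean = measure_cell(cell)
    max_err = {m: 0.0 for m in ALL_METHODS}
    max_angle = 0.0
    for snr in snr_grid:
        for _ in range(n_seeds):
            noisy = add_noise(cell, snr, seed=int(rng.integers(2 ** 31)))
            res = measure_cell(noisy)
            for m in ALL_METHODS:
                err = abs(res[m].magnitude - clean[m].magnitude) / clean[m].magnitude
                max_err[m] = max(max_err[m], err)
            max_angle = max(max_angle,
                            axial_difference_deg(res["ratio"].angle_deg, 0.0))
    return {"max_relative_error": max_err,
            "ratio_max_angle_error_deg": float(max_angle)}


def puncta_study() -> dict:
    """Punctate-distribution stability over the area and regularity sweeps."""
    return invariance_study(model="puncta")


def base_intensity_study(bases=(40.0, 30.0, 20.0, 10.0, 5.0, 2.0, 1.0)) -> dict:
    """PCA magnitude when the base level drops at fixed peak 255: the maximum
    relative decrease versus the standard base-40 fixture (0 if the readout
    never falls below it)."""
    mags = []
    for b in bases:
        cell = make_cell(SyntheticCellSpec(perimeter=440.0, base=float(b),
                                           placement="vertical_junctions"))
        mags.append(measure_cell(cell, methods=("pca",), config=NOISELESS)["pca"].magnitude)
    ref = mags[0]
    max_drop = max(0.0, max((ref - m) / ref for m in mags))
    return {"max_relative_decrease": float(max_drop), "magnitudes": mags}


def loglinearity_study() -> dict:
    """Linearity of magnitude vs log peak-to-base ratio on noiseless
    two-level cells (R^2 of a straight-line fit in log-x)."""
    cells = peak_ratio_sweep()
    res = _measure_sweep(cells, config=NOISELESS)
    x = np.log(np.array(PEAK_GRID) / BASE)
    out = {}
    for m in ALL_METHODS:
        y = res[m]["magnitude"] - (1.0 if m == "ratio" else 0.0)
        A = np.c_[x, np.ones_like(x)]
        coef, resid, *_ = np.linalg.lstsq(A, y, rcond=None)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float(resid[0]) / ss_tot if len(resid) else 1.0
        out[m] = {"r_squared": r2, "slope": float(coef[0]),
                  "monotone": bool(np.all(np.diff(y) > 0))}
    return out
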