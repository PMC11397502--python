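"""Measurement pipeline on segmented-cell and EdU-nucleus tables.

Works on flat tables of epidermal cells (one row per cell, with normalized
petal coordinates: pos_pd 0 = base, 1 = tip; pos_lat 0/1 = margins) or
EdU-labeled nuclei. The central-stripe convention, windowed area profile,
Savitzky-Golay smoothing and plateau rule reproduce the automatic boundary
detection used on segmented petals; for pigmented stages the boundary is
the pigment transition instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import gaussian_kde

from .errors import ContiguityError, EmptySelectionWarning, UndefinedRatioError

__all__ = [
    "CELL_COLUMNS",
    "EDU_COLUMNS",
    "BoundaryEstimate",
    "read_cell_table",
    "read_edu_table",
    "central_stripe",
    "detect_boundary_area",
    "detect_boundary_pigment",
    "edu_pdf",
    "region_summary",
    "bullseye_proportion",
]

CELL_COLUMNS = ["stage", "replicate", "pos_pd", "pos_lat", "area",
                "aspect_ratio", "circularity", "pigmented"]
EDU_COLUMNS = ["stage", "replicate", "pos_pd", "pos_lat"]


@dataclass(frozen=True)
class BoundaryEstimate:
    """Detected proximal/distal boundary along the PD axis."""

    boundary_pos: float
    method: str  # "area_peak" or "pigment_transition"
    windows_used: int
    stage: str | None = None
    replicate: int | None = None
    degenerate: bool = False


def _validate_coords(df: pd.DataFrame, what: str) -> None:
    bad = df.index[(df["pos_pd"] < 0) | (df["pos_pd"] > 1)
                   | (df["pos_lat"] < 0) | (df["pos_lat"] > 1)]
    if len(bad):
        raise ValueError(
            f"{what}: normalized coordinates outside [0,1] in rows {list(bad[:10])}")


def read_cell_table(path) -> pd.DataFrame:
    """Load a segmented-cell CSV, validating columns and coordinate ranges."""
    df = pd.read_csv(path)
    missing = [c for c in CELL_COLUMNS if c not in df.columns and c != "pigmented"]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    _validate_coords(df, "cell table")
    bad = df.index[df["area"] <= 0]
    if len(bad):
        raise ValueError(f"cell table: non-positive area in rows {list(bad[:10])}")
    if "pigmented" in df.columns:
        df["pigmented"] = df["pigmented"].astype(bool)
    return df


def read_edu_table(path) -> pd.DataFrame:
    """Load an EdU-nucleus CSV (one labeled nucleus per row)."""
    df = pd.read_csv(path)
    missing = [c for c in EDU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"EdU table missing columns: {missing}")
    _validate_coords(df, "EdU table")
    return df


def central_stripe(records: pd.DataFrame, width_fraction: float = 0.2) -> pd.DataFrame:
    """Keep cells in a central lateral stripe (|pos_lat − 0.5| ≤ width/2).

    A 20% stripe at the widest point is the standard sampling region for PD
    profiles, avoiding the curved petal margins.
    """
    if not 0 < width_fraction <= 1:
        raise ValueError("width_fraction must be in (0, 1]")
    out = records[(records["pos_lat"] - 0.5).abs() <= width_fraction / 2]
    if out.empty:
        warnings.warn("central stripe selection removed every record",
                      EmptySelectionWarning, stacklevel=2)
    return out


def _window_profile(pos: np.ndarray, values: np.ndarray, window: float):
    """Mean value per contiguous PD window; empty windows linearly interpolated.

    Windows are half-open [k·w, (k+1)·w), the last closed; a window's
    position is its centre.
    """
    n_win = int(round(1.0 / window))
    idx = np.minimum((pos / window).astype(int), n_win - 1)
    sums = np.bincount(idx, weights=values, minlength=n_win)
    counts = np.bincount(idx, minlength=n_win)
    centers = (np.arange(n_win) + 0.5) * window
    means = np.full(n_win, np.nan)
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]
    if not nz.any():
        raise ValueError("no cells in any window")
    if (~nz).any():
        means[~nz] = np.interp(centers[~nz], centers[nz], means[nz])
    return centers, means, int(nz.sum())


def detect_boundary_area(records: pd.DataFrame, window: float = 0.05,
                         plateau_tol: float = 0.025,
                         sg_window: int = 7, sg_polyorder: int = 2,
                         stage: str | None = None,
                         replicate: int | None = None) -> BoundaryEstimate:
    """Boundary from the peak of largest cells in the window-averaged area profile.

    Cells are binned into contiguous PD windows (default 5%), the mean-area
    profile is Savitzky-Golay smoothed, and the boundary is the mean centre
    of all windows whose smoothed area is within ``plateau_tol`` (relative,
    default 2.5%) of the maximum. Invariant to uniform area rescaling.
    """
    if records.empty:
        raise ValueError("empty cell table")
    pos = records["pos_pd"].to_numpy(dtype=float)
    area = records["area"].to_numpy(dtype=float)
    centers, means, occupied = _window_profile(pos, area, window)
    if occupied < 3:
        raise ValueError("need cells in at least 3 windows")
    if len(means) >= sg_window:
        smooth = savgol_filter(means, sg_window, sg_polyorder)
    else:
        warnings.warn("fewer windows than smoother length; using raw profile",
                      UserWarning, stacklevel=2)
        smooth = means
    plateau = smooth >= (1.0 - plateau_tol) * smooth.max()
    boundary = float(centers[plateau].mean())
    return BoundaryEstimate(boundary_pos=boundary, method="area_peak",
                            windows_used=int(plateau.sum()),
                            stage=stage, replicate=replicate)


def detect_boundary_pigment(records: pd.DataFrame,
                            stage: str | None = None,
                            replicate: int | None = None) -> BoundaryEstimate:
    """Boundary as the pigment transition: midpoint between the last
    pigmented and first unpigmented cell along the PD axis.

    Requires the pigmented cells to form one basal block in PD order.
    """
    if "pigmented" not in records.columns:
        raise ValueError("records carry no pigment flags")
    ordered = records.sort_values("pos_pd", kind="stable").reset_index()
    pig = ordered["pigmented"].to_numpy(dtype=bool)
    if not pig.any():
        return BoundaryEstimate(0.0, "pigment_transition", 0, stage, replicate,
                                degenerate=True)
    if pig.all():
        return BoundaryEstimate(1.0, "pigment_transition", len(pig), stage,
                                replicate, degenerate=True)
    last_pig = int(np.max(np.flatnonzero(pig)))
    first_unpig = int(np.min(np.flatnonzero(~pig)))
    if first_unpig < last_pig:
        offending = ordered.loc[
            (np.arange(len(pig)) > first_unpig) & pig, "index"].tolist()
        raise ContiguityError(
            "pigmented cells do not form a contiguous basal block",
            offending_rows=offending)
    mid = float((ordered.loc[last_pig, "pos_pd"]
                 + ordered.loc[first_unpig, "pos_pd"]) / 2)
    return BoundaryEstimate(mid, "pigment_transition", len(pig), stage, replicate)


def edu_pdf(nuclei: pd.DataFrame, bandwidth=None, grid_size: int = 201,
            n_hist_bins: int = 10):
    """PDF of EdU-labeled nucleus positions along the PD axis.

    Gaussian KDE (Silverman bandwidth by default) with reflection at the
    0 and 1 boundaries so the density integrates to 1 on [0, 1]. Returns
    (grid, density, histogram) where ``histogram`` is the per-bin count
    vector usable for chi-square-style comparisons.
    """
    pos = np.asarray(nuclei["pos_pd"], dtype=float)
    if pos.size < 5:
        raise ValueError("need at least 5 nuclei for a density estimate")
    kde = gaussian_kde(pos, bw_method=bandwidth)
    grid = np.linspace(0.0, 1.0, grid_size)
    dens = kde(grid) + kde(-grid) + kde(2.0 - grid)  # boundary reflection
    dens /= np.trapezoid(dens, grid)
    hist, _ = np.histogram(pos, bins=n_hist_bins, range=(0.0, 1.0))
    return grid, dens, hist


def region_summary(records: pd.DataFrame, boundary: float,
                   value_col: str = "area") -> pd.DataFrame:
    """Split cells at a PD boundary and summarise the two regions.

    Returns two rows (proximal = below boundary, distal = above) with the
    cell count, median of ``value_col`` and region total, plus the
    proximal/distal ratios in ``DataFrame.attrs`` (keys ``length_ratio``,
    ``count_ratio``).
    """
    if not 0 < boundary < 1:
        raise ValueError("boundary must be inside (0, 1)")
    prox = records[records["pos_pd"] < boundary]
    dist = records[records["pos_pd"] >= boundary]
    if prox.empty or dist.empty:
        raise UndefinedRatioError("a region is empty at this boundary")
    rows = []
    for name, sub in (("proximal", prox), ("distal", dist)):
        rows.append({"region": name, "n_cells": len(sub),
                     "median_value": float(sub[value_col].median()),
                     "total_value": float(sub[value_col].sum())})
    out = pd.DataFrame(rows)
    med = out.set_index("region")["median_value"]
    n = out.set_index("region")["n_cells"]
    out.attrs["length_ratio"] = float(med["proximal"] / med["distal"])
    out.attrs["count_ratio"] = float(n["proximal"] / n["distal"])
    return out


def bullseye_proportion(pigmented_area: float, total_area: float) -> float:
    """Pigmented fraction of the petal surface, in percent."""
    if total_area <= 0 or not 0 <= pigmented_area <= total_area:
        raise ValueError("need 0 <= pigmented_area <= total_area, total > 0")
    return 100.0 * pigmented_area / total_area
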