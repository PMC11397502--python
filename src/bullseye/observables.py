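"""Observables over simulated trajectories, ensembles and ratio-grid scans.

Per snapshot the model exposes four aggregates: cell counts per fate
(nc0 distal, nc1 proximal) and total region lengths (tl0, tl1). From these:

* boundary position  = tl1 / (tl0 + tl1)
* length ratio       = (tl1 / nc1) / (tl0 / nc0)   (proximal/distal mean length)
* cell-number ratio  = nc1 / nc0

Time series are binned into 100 equal windows of simulation time and, since
petal length rather than time is the natural developmental coordinate, also
resampled at the windows whose total length is closest to each 10% of the
final length. The mean-percentage-error objective compares two such
length-resampled frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedRatioError, UndefinedSensitivityError
from .tissue import InitialState, ModelParams, Trajectory, simulate

__all__ = [
    "ObservableFrame",
    "ScanResult",
    "compute_observables",
    "ensemble_average",
    "run_ensemble",
    "scan_ratios",
    "maintenance_contour",
    "sensitivity",
    "objective_distance",
]

N_BINS = 100
N_RESAMPLE = 10
OBSERVABLE_NAMES = ("boundary", "length_ratio", "ncell_ratio")

#: default grids for mapping the boundary-maintenance contour: the boundary
#: responds ~30x more strongly to the expansion ratio than to the division
#: ratio, so the expansion axis needs fine resolution around 1 while the
#: division axis can span a broad log range.
MAINTENANCE_RG_GRID = np.geomspace(0.90, 1.12, 9)
MAINTENANCE_RD_GRID = np.geomspace(0.5, 2.0, 5)
#: preset sub-grid for the upward boundary-shift experiment
SHIFT_RG_GRID = np.linspace(1.0, 2.0, 5)
SHIFT_RD_GRID = np.linspace(1.0, 2.0, 5)


@dataclass
class ObservableFrame:
    """Time-binned (and length-resampled) observable series.

    ``binned`` has ``N_BINS`` rows with columns time, nc0, nc1, tl0, tl1,
    total_length, boundary, length_ratio, ncell_ratio. ``resampled`` has
    ``N_RESAMPLE`` rows (one per 10% of final length) with the same
    observable columns plus ``target_length``. ``n`` counts the replicates
    averaged into the frame.
    """

    binned: pd.DataFrame
    resampled: pd.DataFrame
    n: int = 1

    @property
    def final_boundary(self) -> float:
        return float(self.binned["boundary"].iloc[-1])


def _derive(df: pd.DataFrame) -> pd.DataFrame:
    if (df["nc0"] <= 0).any() or (df["nc1"] <= 0).any():
        raise UndefinedRatioError("a fate region has no cells; ratios undefined")
    df = df.copy()
    df["total_length"] = df["tl0"] + df["tl1"]
    df["boundary"] = df["tl1"] / df["total_length"]
    df["length_ratio"] = (df["tl1"] / df["nc1"]) / (df["tl0"] / df["nc0"])
    df["ncell_ratio"] = df["nc1"] / df["nc0"]
    return df


def _resample_by_length(binned: pd.DataFrame) -> pd.DataFrame:
    """Pick, per 10% of final length, the time bin of nearest total length.

    Ties break toward the earlier bin.
    """
    L_final = float(binned["total_length"].iloc[-1])
    rows = []
    lengths = binned["total_length"].to_numpy()
    for k in range(1, N_RESAMPLE + 1):
        target = k * L_final / N_RESAMPLE
        i = int(np.argmin(np.abs(lengths - target)))  # argmin → earliest on tie
        row = binned.iloc[i][list(OBSERVABLE_NAMES) + ["total_length", "time"]].copy()
        row["target_length"] = target
        rows.append(row)
    out = pd.DataFrame(rows).reset_index(drop=True)
    out.index = pd.RangeIndex(1, N_RESAMPLE + 1, name="length_decile")
    return out


def compute_observables(traj: Trajectory, n_bins: int = N_BINS) -> ObservableFrame:
    """Bin a trajectory's aggregates into equal simulation-time windows.

    Window means are taken per bin; windows without a snapshot (possible
    only for runs shorter than ``n_bins`` steps) are filled by linear
    interpolation between neighbouring windows.
    """
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    t_final = traj.times[-1]
    if t_final <= 0:
        raise ValueError("trajectory never advanced in time")
    idx = np.minimum((traj.times / t_final * n_bins).astype(int), n_bins - 1)
    raw = pd.DataFrame({
        "bin": idx, "time": traj.times,
        "nc0": traj.nc0, "nc1": traj.nc1, "tl0": traj.tl0, "tl1": traj.tl1,
    })
    binned = raw.groupby("bin").mean()
    binned = binned.reindex(pd.RangeIndex(n_bins, name="bin"))
    if binned["time"].isna().any():
        binned = binned.interpolate(method="linear", limit_direction="both")
    binned = _derive(binned)
    return ObservableFrame(binned=binned, resampled=_resample_by_length(binned), n=1)


def ensemble_average(frames: list[ObservableFrame]) -> ObservableFrame:
    """Bin-wise mean across replicate frames (boundary and ratios recomputed
    from averaged raw aggregates; the resampled view is rebuilt)."""
    if not frames:
        raise ValueError("need at least one frame")
    shapes = {f.binned.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError("frames have mismatched binning")
    raw_cols = ["time", "nc0", "nc1", "tl0", "tl1"]
    mean_raw = sum(f.binned[raw_cols] for f in frames) / len(frames)
    binned = _derive(mean_raw)
    n = sum(f.n for f in frames)
    return ObservableFrame(binned=binned, resampled=_resample_by_length(binned), n=n)


def run_ensemble(params: ModelParams, init: InitialState = InitialState(),
                 n_reps: int = 50, base_seed: int | None = None) -> ObservableFrame:
    """Simulate ``n_reps`` replicates (replicate i seeded base_seed+i) and
    average their observable frames."""
    base = params.seed if base_seed is None else base_seed
    frames = [compute_observables(simulate(params, init, seed=base + i))
              for i in range(n_reps)]
    return ensemble_average(frames)


@dataclass
class ScanResult:
    """Grid scan over (r_g_ratio, r_d_ratio) with per-point ensemble means.

    ``table`` is long-format with columns rg_ratio, rd_ratio, n_replicates,
    deviation (mean final boundary − initial boundary; positive = tipward),
    length_ratio, ncell_ratio (final-state ensemble means) and sem_deviation.
    """

    table: pd.DataFrame
    initial_boundary: float
    base_params: ModelParams
    seeds: tuple[int, ...]

    def max_deviation(self) -> float:
        return float(self.table["deviation"].max())

    def at(self, rg_ratio: float, rd_ratio: float) -> pd.Series:
        t = self.table
        match = t[(np.isclose(t["rg_ratio"], rg_ratio))
                  & (np.isclose(t["rd_ratio"], rd_ratio))]
        if match.empty:
            raise KeyError(f"grid point ({rg_ratio}, {rd_ratio}) not in scan")
        return match.iloc[0]


def _final_state_stats(params, init, seeds):
    bounds, lratios, nratios = [], [], []
    for s in seeds:
        traj = simulate(params, init, seed=s)
        nc0, nc1, tl0, tl1 = traj.final_tissue.counts_and_lengths()
        if nc0 == 0 or nc1 == 0:
            raise UndefinedRatioError("a fate region emptied during simulation")
        bounds.append(tl1 / (tl0 + tl1))
        lratios.append((tl1 / nc1) / (tl0 / nc0))
        nratios.append(nc1 / nc0)
    return (np.mean(bounds), np.std(bounds, ddof=1) / np.sqrt(len(seeds)),
            np.mean(lratios), np.mean(nratios))


def scan_ratios(base: ModelParams,
                rg_ratios, rd_ratios,
                n_reps: int = 20,
                init: InitialState = InitialState(),
                base_seed: int = 0) -> ScanResult:
    """Ensemble-run every (rg_ratio, rd_ratio) grid point.

    Each point uses the same replicate seeds ``base_seed .. base_seed+n_reps-1``
    so points differ only through parameters.
    """
    rg_ratios = np.atleast_1d(np.asarray(rg_ratios, dtype=float))
    rd_ratios = np.atleast_1d(np.asarray(rd_ratios, dtype=float))
    if np.any(rg_ratios <= 0) or np.any(rd_ratios <= 0):
        raise ValueError("ratio grids must be strictly positive")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seeds = tuple(range(base_seed, base_seed + n_reps))
    b0 = init.boundary
    rows = []
    for rg in rg_ratios:
        for rd in rd_ratios:
            params = base.with_ratios(rg, rd)
            try:
                mb, sem, lr, nr = _final_state_stats(params, init, seeds)
            except Exception as exc:
                raise type(exc)(
                    f"{exc} [at grid point rg_ratio={rg:g}, rd_ratio={rd:g}]"
                ) from exc
            rows.append({
                "rg_ratio": rg, "rd_ratio": rd, "n_replicates": n_reps,
                "deviation": mb - b0, "sem_deviation": sem,
                "length_ratio": lr, "ncell_ratio": nr,
            })
    return ScanResult(table=pd.DataFrame(rows), initial_boundary=b0,
                      base_params=base, seeds=seeds)


@dataclass
class MaintenanceContour:
    """Grid points whose |boundary deviation| stays within tolerance."""

    points: pd.DataFrame
    tol: float
    spearman_rho: float
    spearman_p: float


def maintenance_contour(scan: ScanResult, tol: float = 0.05) -> MaintenanceContour:
    """Extract the boundary-maintenance region of a scan.

    Returns the grid points with |deviation| <= tol together with the
    Spearman correlation of log rg_ratio vs log rd_ratio over that set —
    negative when higher proximal expansion must be offset by lower
    proximal division to hold the boundary.
    """
    pts = scan.table[scan.table["deviation"].abs() <= tol].reset_index(drop=True)
    if len(pts) >= 3 and pts["rg_ratio"].nunique() > 1 and pts["rd_ratio"].nunique() > 1:
        rho, p = stats.spearmanr(np.log(pts["rg_ratio"]), np.log(pts["rd_ratio"]))
    else:
        rho, p = np.nan, np.nan
    return MaintenanceContour(points=pts, tol=tol,
                              spearman_rho=float(rho), spearman_p=float(p))


_FINAL_OBSERVABLES = {
    "boundary": lambda f: f.final_boundary,
    "length_ratio": lambda f: float(f.binned["length_ratio"].iloc[-1]),
    "ncell_ratio": lambda f: float(f.binned["ncell_ratio"].iloc[-1]),
}


def sensitivity_from_values(obs_base: float, obs_pert: float,
                            theta_base: float, theta_pert: float) -> float:
    """|Δobs|/obs divided by |Δθ|/θ. < 1 ⇒ observable under-responds."""
    if obs_base == 0:
        raise UndefinedSensitivityError("baseline observable is zero")
    if theta_pert == theta_base:
        raise ValueError("parameter perturbation is zero")
    return (abs(obs_pert - obs_base) / abs(obs_base)) / (
        abs(theta_pert - theta_base) / abs(theta_base))


def sensitivity(base: ModelParams, param_name: str, delta_fraction: float,
                observable_name: str, n_reps: int = 20,
                init: InitialState = InitialState(),
                base_seed: int = 0) -> float:
    """Relative-change ratio of a final-state observable to a ±fraction
    change of one model parameter, on ensemble means."""
    if delta_fraction == 0:
        raise ValueError("delta_fraction must be non-zero")
    if observable_name not in _FINAL_OBSERVABLES:
        raise KeyError(f"unknown observable {observable_name!r}; "
                       f"choose from {sorted(_FINAL_OBSERVABLES)}")
    theta = getattr(base, param_name)
    pert = replace(base, **{param_name: theta * (1 + delta_fraction)})
    f0 = run_ensemble(base, init, n_reps, base_seed)
    f1 = run_ensemble(pert, init, n_reps, base_seed)
    getter = _FINAL_OBSERVABLES[observable_name]
    return sensitivity_from_values(getter(f0), getter(f1),
                                   theta, theta * (1 + delta_fraction))


def objective_distance(sim: ObservableFrame, ref: ObservableFrame) -> float:
    """Mean percentage error between two length-resampled frames.

    Per observable, mean over the 10 relative-length samples of
    |sim − ref| / |ref|; the total is the unweighted average over boundary,
    length ratio and cell-number ratio. Returned as a fraction (0.2 = 20%).
    """
    if len(sim.resampled) != len(ref.resampled):
        raise ValueError("frames resampled at different numbers of points")
    errs = []
    for name in OBSERVABLE_NAMES:
        r = ref.resampled[name].to_numpy(dtype=float)
        s = sim.resampled[name].to_numpy(dtype=float)
        if np.any(r == 0):
            raise ZeroDivisionError(f"reference {name} is zero at a sample point")
        errs.append(np.mean(np.abs(s - r) / np.abs(r)))
    return float(np.mean(errs))
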