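"""Stochastic 1D two-fate cell-array model of petal growth.

The petal is a file of cells from base to tip. Each cell carries a fixed
fate — proximal (the future pigmented bullseye centre) or distal (the white
periphery) — a length in μm, and an id. Cells grow logistically towards a
maximum cell length ``l_max`` and divide at a rate that decays exponentially
with the *total* tissue length, so divisions dominate early and expansion
late, reproducing the two-phase development seen in staged petals.

Growth rule (deterministic):  dl/dt = r_g(f) · l · (1 − l / l_max)
Division rule (stochastic):   d(f, L) = r_d(f) · exp(−L / L0(f))

where f is the fate, L the current total tissue length, and L0(f) sets the
fate-specific timing of the exit from the division-heavy phase. A division
replaces the mother by two daughters of half its length placed side by side,
so divisions conserve total length exactly; the boundary position
tl1/(tl0+tl1) therefore moves only through differential growth and through
the size structure that divisions create.

The default engine is a fixed-step hybrid: per step of ``dt`` days, lengths
are advanced deterministically from start-of-step values and every cell
divides independently with probability 1 − exp(−d(f, L_start)·dt). An exact
event-driven alternative (closed-form logistic advance between events plus
thinning, valid because d only decreases as L grows) is available via
:func:`simulate_exact`.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import (
    CellNotFoundError,
    CoarseStepWarning,
    InvalidStateError,
    NoProgressError,
)

__all__ = [
    "Fate",
    "ModelParams",
    "InitialState",
    "Cell",
    "Tissue",
    "Trajectory",
    "growth_increment",
    "division_propensity",
    "divide_cell",
    "step",
    "simulate",
    "simulate_exact",
]

#: sentinel right-neighbour id of the tip-most cell
NO_NEIGHBOR = -1


class Fate(enum.IntEnum):
    """Cell fate. Distal is coded 0 and proximal 1."""

    DISTAL = 0
    PROXIMAL = 1


@dataclass(frozen=True)
class ModelParams:
    """All rates and thresholds of the growth/division model.

    Defaults are the wild-type *H. trionum* values: distal base rates with
    proximal rates expressed as proximal:distal ratios.

    Parameters
    ----------
    r_g_distal : base relative growth rate of distal cells, per day.
    r_g_ratio : proximal:distal expansion-rate ratio; r_g(1) = ratio · r_g(0).
    r_d_distal : base division rate of distal cells, per day.
    r_d_ratio : proximal:distal division-rate ratio; r_d(1) = ratio · r_d(0).
    l_max : maximum cell length, μm.
    L_max : threshold total petal length ending the simulation, μm.
    L0_distal : division slow-down length scale of distal cells, μm
        (default 0.1 · L_max).
    L0_ratio : L0(distal) / L0(proximal); < 1 means proximal cells exit the
        division-heavy phase later.
    dt : engine step, days.
    seed : base RNG seed; replicate i of an ensemble uses seed + i.
    """

    r_g_distal: float = 0.91
    r_g_ratio: float = 1.0
    r_d_distal: float = 1.1
    r_d_ratio: float = 1.0
    l_max: float = 20.0
    L_max: float = 300.0
    L0_distal: float = 30.0
    L0_ratio: float = 0.6
    dt: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in ("r_g_ratio", "r_d_ratio", "l_max", "L_max",
                     "L0_distal", "L0_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        # base rates of zero are legal degenerate inputs (pure-division or
        # pure-growth runs); negatives are not
        if self.r_g_distal < 0 or self.r_d_distal < 0:
            raise ValueError("base rates must be non-negative")
        if not 0 < self.dt <= 0.05:
            raise ValueError("dt must be in (0, 0.05] days")

    def r_g(self, fate: int) -> float:
        """Relative growth rate for a fate, per day."""
        return self.r_g_distal * (self.r_g_ratio if fate == Fate.PROXIMAL else 1.0)

    def r_d(self, fate: int) -> float:
        """Base division rate for a fate, per day."""
        return self.r_d_distal * (self.r_d_ratio if fate == Fate.PROXIMAL else 1.0)

    def L0(self, fate: int) -> float:
        """Division slow-down length scale for a fate, μm."""
        if fate == Fate.PROXIMAL:
            return self.L0_distal / self.L0_ratio
        return self.L0_distal

    def with_ratios(self, r_g_ratio: float, r_d_ratio: float) -> "ModelParams":
        return replace(self, r_g_ratio=r_g_ratio, r_d_ratio=r_d_ratio)

    def to_dict(self) -> dict:
        return {
            "r_g_distal": self.r_g_distal, "r_g_ratio": self.r_g_ratio,
            "r_d_distal": self.r_d_distal, "r_d_ratio": self.r_d_ratio,
            "l_max": self.l_max, "L_max": self.L_max,
            "L0_distal": self.L0_distal, "L0_ratio": self.L0_ratio,
            "dt": self.dt, "seed": self.seed,
        }

    @classmethod
    def from_file(cls, path) -> "ModelParams":
        """Load parameters from a YAML/JSON mapping; unknown keys rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        init_keys = {"n_cells", "cell_length", "n_proximal"}
        raw = {k: v for k, v in raw.items() if k not in init_keys}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass(frozen=True)
class InitialState:
    """Initial tissue: n_cells of equal length, a basal proximal block."""

    n_cells: int = 21
    cell_length: float = 0.1
    n_proximal: int = 7

    def __post_init__(self):
        if not 0 < self.n_proximal < self.n_cells:
            raise ValueError("need 0 < n_proximal < n_cells")
        if self.cell_length <= 0:
            raise ValueError("cell_length must be positive")

    @property
    def boundary(self) -> float:
        """Initial relative boundary position (proximal fraction)."""
        return self.n_proximal / self.n_cells

    @classmethod
    def from_file(cls, path) -> "InitialState":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        keys = set(cls.__dataclass_fields__)
        return cls(**{k: v for k, v in raw.items() if k in keys})


@dataclass(frozen=True)
class Cell:
    """One cell: id, right-neighbour id (NO_NEIGHBOR at the tip), fate, length."""

    cid: int
    neigh: int
    fate: Fate
    length: float


class Tissue:
    """Ordered cell file from base (index 0) to tip, stored as arrays."""

    __slots__ = ("cids", "fates", "lengths", "time")

    def __init__(self, cids, fates, lengths, time=0.0):
        self.cids = np.asarray(cids, dtype=np.int64)
        self.fates = np.asarray(fates, dtype=np.int8)
        self.lengths = np.asarray(lengths, dtype=np.float64)
        self.time = float(time)

    @classmethod
    def from_initial(cls, init: InitialState = InitialState()) -> "Tissue":
        n = init.n_cells
        fates = np.where(np.arange(n) < init.n_proximal,
                         int(Fate.PROXIMAL), int(Fate.DISTAL))
        return cls(np.arange(1, n + 1), fates,
                   np.full(n, init.cell_length), time=0.0)

    # -- aggregates (the model's observables) --------------------------------

    @property
    def n_cells(self) -> int:
        return self.lengths.size

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def counts_and_lengths(self) -> tuple[int, int, float, float]:
        """(nc0, nc1, tl0, tl1): per-fate cell counts and total lengths."""
        prox = self.fates == Fate.PROXIMAL
        tl1 = float(self.lengths[prox].sum())
        tl0 = float(self.lengths.sum() - tl1)
        nc1 = int(prox.sum())
        return self.n_cells - nc1, nc1, tl0, tl1

    @property
    def boundary_position(self) -> float:
        """Proximal fraction of total length, tl1/(tl0+tl1)."""
        _, _, tl0, tl1 = self.counts_and_lengths()
        return tl1 / (tl0 + tl1)

    # -- structure -----------------------------------------------------------

    @property
    def cells(self) -> list[Cell]:
        neighs = np.append(self.cids[1:], NO_NEIGHBOR)
        return [Cell(int(c), int(n), Fate(int(f)), float(l))
                for c, n, f, l in zip(self.cids, neighs, self.fates, self.lengths)]

    def copy(self) -> "Tissue":
        return Tissue(self.cids.copy(), self.fates.copy(),
                      self.lengths.copy(), self.time)

    def validate(self, l_max: float | None = None) -> None:
        """Raise InvalidStateError on any violated structural invariant."""
        if self.n_cells == 0:
            raise InvalidStateError("empty tissue")
        if np.any(self.lengths <= 0):
            raise InvalidStateError("non-positive cell length")
        if l_max is not None and np.any(self.lengths > l_max * (1 + 1e-12)):
            raise InvalidStateError("cell length exceeds l_max")
        if np.unique(self.cids).size != self.n_cells:
            raise InvalidStateError("duplicate cell ids")
        # proximal cells basal, distal cells apical, one switch at most
        switches = np.count_nonzero(np.diff(self.fates.astype(int)))
        if switches > 1 or (switches == 1 and self.fates[0] != Fate.PROXIMAL):
            raise InvalidStateError("fate blocks are not contiguous (proximal base, distal tip)")


@dataclass
class Trajectory:
    """Per-step aggregate time series of one simulation run.

    ``snapshots`` holds full :class:`Tissue` copies only when the run was
    recorded with ``record_cells=True``.
    """

    times: np.ndarray
    nc0: np.ndarray
    nc1: np.ndarray
    tl0: np.ndarray
    tl1: np.ndarray
    params: ModelParams
    init: InitialState
    snapshots: list[Tissue] | None = None
    final_tissue: Tissue | None = None

    @property
    def total_length(self) -> np.ndarray:
        return self.tl0 + self.tl1

    @property
    def boundary(self) -> np.ndarray:
        return self.tl1 / (self.tl0 + self.tl1)

    @property
    def final_boundary(self) -> float:
        return float(self.boundary[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_days": self.times,
            "n_cells": self.nc0 + self.nc1,
            "nc0": self.nc0, "nc1": self.nc1,
            "tl0": self.tl0, "tl1": self.tl1,
            "L": self.total_length,
            "boundary": self.boundary,
        })

    def to_cell_frame(self) -> pd.DataFrame:
        """Long per-cell table (requires record_cells=True)."""
        if self.snapshots is None:
            raise ValueError("trajectory was recorded without cell snapshots")
        rows = []
        for t in self.snapshots:
            pos = np.cumsum(t.lengths) - t.lengths / 2
            rows.append(pd.DataFrame({
                "time_days": t.time, "cid": t.cids, "fate": t.fates,
                "length": t.lengths, "position": pos,
            }))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# rules

def growth_increment(length, fate, params: ModelParams, dt: float | None = None):
    """Logistic length increment over one step, clipped so length ≤ l_max.

    Accepts scalars or arrays of lengths (with matching fates).
    """
    dt = params.dt if dt is None else dt
    length = np.asarray(length, dtype=float)
    if np.any(length <= 0):
        raise InvalidStateError("cell length must be positive")
    if np.any(length > params.l_max * (1 + 1e-12)):
        raise InvalidStateError("cell length exceeds l_max")
    rg = np.where(np.asarray(fate) == Fate.PROXIMAL,
                  params.r_g(Fate.PROXIMAL), params.r_g(Fate.DISTAL))
    inc = rg * length * (1.0 - length / params.l_max) * dt
    inc = np.minimum(inc, params.l_max - length)
    inc = np.maximum(inc, 0.0)
    return float(inc) if inc.ndim == 0 else inc


def division_propensity(fate, L, params: ModelParams):
    """Division rate d(f, L) = r_d(f)·exp(−L/L0(f)), per day."""
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("total length must be non-negative")
    rd = np.where(np.asarray(fate) == Fate.PROXIMAL,
                  params.r_d(Fate.PROXIMAL), params.r_d(Fate.DISTAL))
    L0 = np.where(np.asarray(fate) == Fate.PROXIMAL,
                  params.L0(Fate.PROXIMAL), params.L0(Fate.DISTAL))
    out = rd * np.exp(-L / L0)
    return float(out) if out.ndim == 0 else out


def divide_cell(tissue: Tissue, cid: int) -> Tissue:
    """Divide the cell ``cid``: two half-length daughters, same fate.

    The new cell is inserted immediately to the mother's right and receives
    the fresh id (cell count)+1. Returns a new Tissue; total length is
    conserved exactly.
    """
    idx = np.flatnonzero(tissue.cids == cid)
    if idx.size == 0:
        raise CellNotFoundError(f"no cell with cid={cid}")
    i = int(idx[0])
    if tissue.lengths[i] <= 0:
        raise InvalidStateError("cannot divide a cell of non-positive length")
    half = tissue.lengths[i] / 2.0
    new_cid = tissue.n_cells + 1
    cids = np.insert(tissue.cids, i + 1, new_cid)
    fates = np.insert(tissue.fates, i + 1, tissue.fates[i])
    lengths = np.insert(tissue.lengths, i + 1, half)
    lengths[i] = half
    return Tissue(cids, fates, lengths, tissue.time)


def _apply_divisions(tissue: Tissue, divide_mask: np.ndarray) -> None:
    """Apply simultaneous divisions in base-to-tip order, in place."""
    if not divide_mask.any():
        return
    n = tissue.n_cells
    reps = 1 + divide_mask.astype(np.int64)
    new_lengths = np.repeat(
        np.where(divide_mask, tissue.lengths / 2.0, tissue.lengths), reps)
    new_fates = np.repeat(tissue.fates, reps)
    new_cids = np.repeat(tissue.cids, reps)
    # daughters sit right of their mothers; fresh ids base-to-tip
    daughter_pos = np.cumsum(reps) - 1
    daughter_pos = daughter_pos[divide_mask]
    new_cids[daughter_pos] = n + 1 + np.arange(daughter_pos.size)
    tissue.cids, tissue.fates, tissue.lengths = new_cids, new_fates, new_lengths


def step(tissue: Tissue, params: ModelParams, rng: np.random.Generator) -> Tissue:
    """Advance the tissue by one engine step of ``params.dt`` days, in place.

    Growth uses start-of-step lengths; each cell then divides independently
    with probability 1 − exp(−d(f, L_start)·dt), divisions applied at the end
    of the step in base-to-tip order.
    """
    dt = params.dt
    L_start = tissue.total_length
    prop = division_propensity(tissue.fates, L_start, params)
    max_prop = float(np.max(prop)) if tissue.n_cells else 0.0
    if dt * max_prop > 0.5:
        warnings.warn(
            f"dt*max propensity = {dt * max_prop:.2f} > 0.5; step too coarse",
            CoarseStepWarning, stacklevel=2)
    inc = growth_increment(tissue.lengths, tissue.fates, params, dt)
    p_div = -np.expm1(-prop * dt)
    divide_mask = rng.random(tissue.n_cells) < p_div
    tissue.lengths = tissue.lengths + inc
    _apply_divisions(tissue, divide_mask)
    tissue.time += dt
    return tissue


def simulate(params: ModelParams = ModelParams(),
             init: InitialState = InitialState(),
             seed: int | None = None,
             record_cells: bool = False,
             max_steps: int = 500_000) -> Trajectory:
    """Run the hybrid engine until total length reaches ``params.L_max``.

    Parameters
    ----------
    seed : overrides ``params.seed`` when given.
    record_cells : keep a full Tissue copy per step (memory-heavy).
    max_steps : raise :class:`NoProgressError` beyond this step count
        (guards degenerate parameter sets, e.g. zero growth).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    tissue = Tissue.from_initial(init)
    times, nc0s, nc1s, tl0s, tl1s = [], [], [], [], []
    snaps = [] if record_cells else None

    def record():
        nc0, nc1, tl0, tl1 = tissue.counts_and_lengths()
        times.append(tissue.time)
        nc0s.append(nc0); nc1s.append(nc1); tl0s.append(tl0); tl1s.append(tl1)
        if snaps is not None:
            snaps.append(tissue.copy())

    record()
    n_steps = 0
    while tissue.total_length < params.L_max:
        if n_steps >= max_steps:
            raise NoProgressError(
                f"no termination after {max_steps} steps "
                f"(L = {tissue.total_length:.3g} < L_max = {params.L_max:g})")
        step(tissue, params, rng)
        record()
        n_steps += 1

    return Trajectory(
        times=np.asarray(times), nc0=np.asarray(nc0s), nc1=np.asarray(nc1s),
        tl0=np.asarray(tl0s), tl1=np.asarray(tl1s),
        params=params, init=init, snapshots=snaps, final_tissue=tissue)


# ---------------------------------------------------------------------------
# exact event-driven engine

def _advance_logistic(lengths, fates, params: ModelParams, tau: float):
    """Closed-form logistic advance of all lengths by tau days."""
    out = np.empty_like(lengths)
    for f in (Fate.DISTAL, Fate.PROXIMAL):
        m = fates == f
        if not m.any():
            continue
        l0 = lengths[m]
        e = np.exp(params.r_g(f) * tau)
        out[m] = params.l_max * l0 * e / (params.l_max + l0 * (e - 1.0))
    return out


def simulate_exact(params: ModelParams = ModelParams(),
                   init: InitialState = InitialState(),
                   seed: int | None = None,
                   max_events: int = 1_000_000) -> Trajectory:
    """Event-driven simulation: exact division times by thinning.

    Between divisions, lengths follow the logistic growth law in closed form.
    Division propensities only decrease as L grows, so the start-of-interval
    total propensity is a valid thinning bound. Snapshot aggregates are
    recorded at every accepted event and at termination.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    tissue = Tissue.from_initial(init)
    times, nc0s, nc1s, tl0s, tl1s = [], [], [], [], []

    def record():
        nc0, nc1, tl0, tl1 = tissue.counts_and_lengths()
        times.append(tissue.time)
        nc0s.append(nc0); nc1s.append(nc1); tl0s.append(tl0); tl1s.append(tl1)

    def _cap_tau_at_threshold(tau):
        # bisect the time at which L crosses L_max, if within tau
        Lt = _advance_logistic(tissue.lengths, tissue.fates, params, tau).sum()
        if Lt < params.L_max:
            return tau, False
        lo, hi = 0.0, tau
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if _advance_logistic(tissue.lengths, tissue.fates, params, mid).sum() < params.L_max:
                lo = mid
            else:
                hi = mid
        return hi, True

    record()
    for _ in range(max_events):
        L = tissue.total_length
        if L >= params.L_max:
            break
        per_cell = division_propensity(tissue.fates, L, params)
        D0 = float(per_cell.sum())
        tau = rng.exponential(1.0 / D0) if D0 > 1e-300 else np.inf
        if not np.isfinite(tau):
            tau = 1.0  # pure-growth stretch; propensity may rise never, L still grows
        tau, crossed = _cap_tau_at_threshold(tau)
        tissue.lengths = _advance_logistic(tissue.lengths, tissue.fates, params, tau)
        tissue.time += tau
        if crossed:
            record()
            break
        L_new = tissue.total_length
        per_cell_new = division_propensity(tissue.fates, L_new, params)
        D_new = float(per_cell_new.sum())
        if D0 > 0 and rng.random() < D_new / D0:
            i = rng.choice(tissue.n_cells, p=per_cell_new / D_new)
            divided = divide_cell(tissue, int(tissue.cids[i]))
            tissue.cids, tissue.fates, tissue.lengths = (
                divided.cids, divided.fates, divided.lengths)
            record()
    else:
        raise NoProgressError(f"no termination after {max_events} events")

    return Trajectory(
        times=np.asarray(times), nc0=np.asarray(nc0s), nc1=np.asarray(nc1s),
        tl0=np.asarray(tl0s), tl1=np.asarray(tl1s),
        params=params, init=init, snapshots=None, final_tissue=tissue)
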