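"""Seeded generators emulating the measured petal datasets.

Every input the measurement pipeline consumes can be produced here with a
known ground truth: segmented-cell tables with a planted cell-area peak (or
plateau) along the PD axis, EdU nucleus positions with a distal division
bias or not, stage-summary trajectories forward-simulated from the tissue
model with known rates, and bee choice sequences with a planted learning
curve. Generators are pure functions of their spec and seed.

Species/genotype presets encode the qualitative geometry of the three
studied lines: wild-type *H. trionum* (area peak near one-third, distal
EdU bias, mature proximal cells about twice as long and distal cells about
five times as numerous), *H. richardsonii* (peak near 0.15, small bullseye)
and the *HtTCP4.1* overexpressor (early peak at one-third, then a broad
plateau and an upward-shifted boundary near 0.4–0.5, uniform EdU at S0a,
mature count ratio near 0.35).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rates import StageTiming
from .tissue import Fate, InitialState, ModelParams, simulate

__all__ = [
    "STAGES",
    "SPECIES_PRESETS",
    "GeneratorSpec",
    "gen_cell_table",
    "gen_edu",
    "gen_stage_series",
    "gen_choices",
]

STAGES = ["S0a", "S0b", "S0c", "S1", "S2E", "S2L", "S3", "S4", "S5"]

#: default cells per replicate petal, growing across stages
DEFAULT_N_CELLS = {"S0a": 300, "S0b": 400, "S0c": 600, "S1": 900,
                   "S2E": 1500, "S2L": 1800, "S3": 2000, "S4": 2000, "S5": 2000}

_THIRD = 1.0 / 3.0


@dataclass(frozen=True)
class SpeciesPreset:
    """Stage-resolved geometry of one genotype's area/EdU/pigment pattern.

    ``peak_position`` maps stage → peak centre (float), plateau (lo, hi)
    tuple, or None for a flat profile. ``pigment_boundary`` applies from
    S2L on. Ratios describe the mature proximal:distal contrast.
    """

    name: str
    peak_position: dict
    base_area: dict
    peak_amplitude: float
    edu_mode: dict
    pigment_boundary: dict
    length_ratio_mature: float
    count_ratio_mature: float


def _wt_like_edu():
    return {s: ("distal_biased" if s in ("S0a", "S0b", "S0c", "S1") else "uniform")
            for s in STAGES}


SPECIES_PRESETS = {
    "trionum_wt": SpeciesPreset(
        name="trionum_wt",
        peak_position={"S0a": None, "S0b": _THIRD, "S0c": _THIRD, "S1": _THIRD,
                       "S2E": _THIRD, "S2L": 0.4, "S3": 0.37,
                       "S4": _THIRD, "S5": _THIRD},
        base_area={s: a for s, a in zip(
            STAGES, [30, 40, 55, 75, 110, 160, 250, 400, 600])},
        peak_amplitude=1.0,
        edu_mode=_wt_like_edu(),
        pigment_boundary={"S2L": 0.4, "S3": 0.37, "S4": _THIRD, "S5": _THIRD},
        length_ratio_mature=2.0,
        count_ratio_mature=0.2,
    ),
    "richardsonii": SpeciesPreset(
        name="richardsonii",
        peak_position={"S0a": None, "S0b": 0.2, "S0c": 0.2, "S1": 0.18,
                       "S2E": 0.18, "S2L": 0.17, "S3": 0.16,
                       "S4": 0.15, "S5": 0.15},
        base_area={s: a for s, a in zip(
            STAGES, [28, 36, 50, 68, 100, 140, 220, 340, 500])},
        peak_amplitude=1.0,
        edu_mode=_wt_like_edu(),
        pigment_boundary={"S2L": 0.17, "S3": 0.16, "S4": 0.15, "S5": 0.15},
        length_ratio_mature=2.0,
        count_ratio_mature=0.2,
    ),
    "tcp4_oe": SpeciesPreset(
        name="tcp4_oe",
        peak_position={"S0a": None, "S0b": _THIRD, "S0c": _THIRD, "S1": _THIRD,
                       "S2E": (0.2, 0.5), "S2L": 0.5, "S3": 0.45,
                       "S4": 0.4, "S5": 0.4},
        base_area={s: a for s, a in zip(
            STAGES, [30, 40, 55, 75, 115, 170, 270, 450, 700])},
        peak_amplitude=1.0,
        edu_mode={**_wt_like_edu(), "S0a": "uniform"},
        pigment_boundary={"S2L": 0.5, "S3": 0.45, "S4": 0.4, "S5": 0.4},
        length_ratio_mature=2.0,
        count_ratio_mature=0.35,
    ),
}

#: stages where the measured boundary comes from pigment, not the area peak
PIGMENTED_STAGES = ("S2L", "S3", "S4", "S5")
#: stages with mature region contrast baked into position density and areas
_MATURE_STAGES = ("S3", "S4", "S5")


@dataclass(frozen=True)
class GeneratorSpec:
    """Bundle of preset, stage and sampling parameters for the generators."""

    preset: str = "trionum_wt"
    stage: str = "S1"
    n_replicates: int = 5
    n_cells: int | None = None  # per replicate; default scaled by stage
    sigma: float = 0.15  # lognormal multiplicative noise on areas
    seed: int = 0
    croissant: bool = False  # lateral phase shift of the early peak

    def __post_init__(self):
        if self.preset not in SPECIES_PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; "
                             f"choose from {sorted(SPECIES_PRESETS)}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def species(self) -> SpeciesPreset:
        return SPECIES_PRESETS[self.preset]

    @property
    def cells_per_replicate(self) -> int:
        return self.n_cells if self.n_cells is not None else DEFAULT_N_CELLS[self.stage]


def _sigmoid(x, scale=0.02):
    return 1.0 / (1.0 + np.exp(-x / scale))


def area_profile(pos: np.ndarray, spec: GeneratorSpec,
                 lat_shift: np.ndarray | float = 0.0) -> np.ndarray:
    """Noise-free cell-area curve along the PD axis for a preset and stage."""
    sp = spec.species
    base = sp.base_area[spec.stage]
    peak = sp.peak_position[spec.stage]
    out = np.full_like(pos, float(base))
    if peak is not None:
        if isinstance(peak, tuple):  # plateau of large cells
            lo, hi = peak
            bump = _sigmoid(pos - (lo + lat_shift)) * _sigmoid((hi + lat_shift) - pos)
        else:
            bump = np.exp(-0.5 * ((pos - (peak + lat_shift)) / 0.08) ** 2)
        out = base * (1.0 + sp.peak_amplitude * bump)
    if spec.stage in _MATURE_STAGES:
        # mature proximal cells are larger by the preset length ratio
        b = sp.pigment_boundary[spec.stage]
        out = out * (1.0 + (sp.length_ratio_mature - 1.0) * _sigmoid(b - pos))
    return out


def _sample_pd(rng, n: int, spec: GeneratorSpec) -> np.ndarray:
    """PD positions: uniform early; at mature stages the distal region is
    denser in cells by the preset count ratio."""
    sp = spec.species
    if spec.stage not in _MATURE_STAGES:
        return rng.uniform(0.0, 1.0, n)
    b = sp.pigment_boundary[spec.stage]
    cr = sp.count_ratio_mature  # n_prox / n_dist
    w_prox = cr / (1.0 + cr)
    in_prox = rng.random(n) < w_prox
    pos = np.where(in_prox,
                   rng.uniform(0.0, b, n),
                   rng.uniform(b, 1.0, n))
    return pos


def gen_cell_table(spec: GeneratorSpec) -> pd.DataFrame:
    """Synthetic segmented-cell table (one row per epidermal cell).

    Columns match the measurement pipeline's reader: stage, replicate,
    pos_pd, pos_lat, area, aspect_ratio, circularity, pigmented. With
    ``sigma = 0`` the area column equals the preset profile exactly.
    """
    sp = spec.species
    frames = []
    for rep in range(1, spec.n_replicates + 1):
        rng = np.random.default_rng([spec.seed, rep])
        n = spec.cells_per_replicate
        pos_pd = _sample_pd(rng, n, spec)
        pos_lat = rng.uniform(0.0, 1.0, n)
        lat_shift = 0.0
        if spec.croissant and spec.stage in ("S0b", "S0c"):
            # croissant-shaped early domain: peak sits higher near margins
            lat_shift = 0.08 * (2.0 * np.abs(pos_lat - 0.5))
        area = area_profile(pos_pd, spec, lat_shift)
        if spec.sigma > 0:
            area = area * np.exp(spec.sigma * rng.standard_normal(n))
        b = sp.pigment_boundary.get(spec.stage)
        basal = _sigmoid((b if b is not None else 0.0) - pos_pd, scale=0.01)
        aspect = 1.0 + 2.0 * basal + np.abs(0.1 * rng.standard_normal(n))
        circ = np.clip(1.0 / aspect + 0.05 * rng.standard_normal(n), 0.05, 1.0)
        pigmented = (pos_pd < b) if (spec.stage in PIGMENTED_STAGES) \
            else np.zeros(n, dtype=bool)
        frames.append(pd.DataFrame({
            "stage": spec.stage, "replicate": rep,
            "pos_pd": pos_pd, "pos_lat": pos_lat, "area": area,
            "aspect_ratio": aspect, "circularity": circ,
            "pigmented": pigmented,
        }))
    return pd.concat(frames, ignore_index=True)


#: tip-skewed law for distally biased division positions
_DISTAL_BETA = (3.0, 1.5)


def gen_edu(spec: GeneratorSpec, n_nuclei: int = 200) -> pd.DataFrame:
    """Synthetic EdU-labeled nucleus table.

    ``distal_biased`` stages draw PD positions from a Beta law with mass
    towards the tip (median > 0.5); ``uniform`` stages draw uniformly.
    """
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    mode = spec.species.edu_mode[spec.stage]
    frames = []
    for rep in range(1, spec.n_replicates + 1):
        rng = np.random.default_rng([spec.seed, 1000 + rep])
        if mode == "distal_biased":
            pos_pd = rng.beta(*_DISTAL_BETA, n_nuclei)
        else:
            pos_pd = rng.uniform(0.0, 1.0, n_nuclei)
        frames.append(pd.DataFrame({
            "stage": spec.stage, "replicate": rep,
            "pos_pd": pos_pd, "pos_lat": rng.uniform(0.0, 1.0, n_nuclei),
        }))
    return pd.concat(frames, ignore_index=True)


def gen_stage_series(params: ModelParams = ModelParams(),
                     timings: StageTiming = StageTiming(),
                     seed: int = 0,
                     init: InitialState = InitialState()) -> pd.DataFrame:
    """Forward-simulate the tissue model and summarise it at stage times.

    Stage times (hours) are rescaled affinely onto the simulation duration,
    and the nearest snapshot to each rescaled time is summarised per region
    (cell count, median cell length, total petal length). The ground-truth
    parameters are attached in ``DataFrame.attrs['ground_truth']`` so rate
    estimates can be checked against them.
    """
    traj = simulate(params, init, seed=seed, record_cells=True)
    hours = np.array([timings.hours[s] for s in timings.stages])
    h0, h1 = hours[0], hours[-1]
    t_final = traj.times[-1]
    targets = (hours - h0) / (h1 - h0) * t_final
    rows = []
    for stage, h, t_target in zip(timings.stages, hours, targets):
        i = int(np.argmin(np.abs(traj.times - t_target)))
        snap = traj.snapshots[i]
        L = snap.total_length
        for region, fate in (("proximal", Fate.PROXIMAL), ("distal", Fate.DISTAL)):
            lens = snap.lengths[snap.fates == fate]
            rows.append({
                "stage": stage, "region": region, "time_hours": h,
                "n_cells": int(lens.size),
                "median_length": float(np.median(lens)),
                "total_length": L,
            })
    out = pd.DataFrame(rows)
    out.attrs["ground_truth"] = params.to_dict()
    out.attrs["seed"] = seed
    return out


def recovery_orderings(params: ModelParams,
                       timings: StageTiming = StageTiming(),
                       seed: int = 0, n_petals: int = 5
                       ) -> tuple[float, float]:
    """End-to-end rate-recovery experiment for one pseudo-experiment seed.

    Simulates ``n_petals`` replicate stage series (seeds ``n_petals·seed + r``),
    median-pools counts and median lengths per stage and region as done with
    real staged petals, then contrasts effective exponential rates:

    * division contrast: distal − proximal cell-count rate over the
      division-dominated window (S0a → S2E), per day;
    * expansion contrast: proximal − distal median-length rate over the
      expansion phase (S2E → S5), per day.

    Positive values mean the recovered ordering matches a ground truth with
    more frequent distal division and faster proximal expansion.
    """
    from .rates import estimate_rate  # local import keeps module load light

    series = [gen_stage_series(params, timings, seed=n_petals * seed + r)
              for r in range(n_petals)]
    pooled = (pd.concat(series)
              .groupby(["stage", "region"], as_index=False)
              .median(numeric_only=True))
    n = pooled.pivot(index="stage", columns="region", values="n_cells")
    l = pooled.pivot(index="stage", columns="region", values="median_length")
    h = timings.hours
    k_div = {r: estimate_rate(n.loc["S0a", r], n.loc["S2E", r],
                              h["S0a"], h["S2E"]).k for r in ("distal", "proximal")}
    k_grow = {r: estimate_rate(l.loc["S2E", r], l.loc["S5", r],
                               h["S2E"], h["S5"], quantity="cell_length").k
              for r in ("distal", "proximal")}
    return (k_div["distal"] - k_div["proximal"],
            k_grow["proximal"] - k_grow["distal"])


def gen_choices(p0: float, p_final: float, n_bees: int = 20,
                n_visits: int = 80, seed: int = 0) -> pd.DataFrame:
    """Synthetic bee choice sequences with a logistic-in-visit learning curve.

    Each bee makes ``n_visits`` Bernoulli choices whose success probability
    interpolates on the logit scale from ``p0`` (first visit) to ``p_final``
    (last visit). Columns: bee, visit, correct.
    """
    for p in (p0, p_final):
        if not 0 < p < 1:
            raise ValueError("probabilities must be in (0, 1)")
    if n_bees < 1 or n_visits < 2:
        raise ValueError("need n_bees >= 1 and n_visits >= 2")
    logit = lambda p: np.log(p / (1 - p))
    eta = logit(p0) + (logit(p_final) - logit(p0)) * \
        (np.arange(n_visits) / (n_visits - 1))
    prob = 1.0 / (1.0 + np.exp(-eta))
    rng = np.random.default_rng(seed)
    rows = []
    for bee in range(1, n_bees + 1):
        correct = rng.random(n_visits) < prob
        rows.append(pd.DataFrame({
            "bee": bee, "visit": np.arange(1, n_visits + 1),
            "correct": correct.astype(int),
        }))
    return pd.concat(rows, ignore_index=True)
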