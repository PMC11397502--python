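"""Stage-wise growth/division rate estimation and ratio-of-variables statistics.

Between consecutive developmental stages, cell numbers and cell sizes are
treated as growing exponentially, so the effective rate over a stage interval
is the log-difference divided by the interval duration. Plotting per-interval
division rates against petal length and fitting an exponential decay
recovers the division-rule parameters (r_d, L0). Genotype comparisons use
the first-two-moment formulas for the mean and variance of a ratio of two
independent random variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy import optimize

__all__ = [
    "StageTiming",
    "RateEstimate",
    "DivisionDecayFit",
    "estimate_rate",
    "estimate_stage_rates",
    "fit_division_decay",
    "ratio_stats",
    "ratio_stats_from_samples",
]

HOURS_PER_DAY = 24.0

#: stage onset times in hours (S0a through S5)
DEFAULT_STAGE_HOURS = {
    "S0a": 1.0, "S0b": 31.0, "S0c": 62.0, "S1": 93.0, "S2E": 152.0,
    "S2L": 211.0, "S3": 309.0, "S4": 404.0, "S5": 416.0,
}


@dataclass(frozen=True)
class StageTiming:
    """Ordered stage → time-in-hours mapping; times must strictly increase."""

    hours: dict = None

    def __post_init__(self):
        object.__setattr__(self, "hours",
                           dict(DEFAULT_STAGE_HOURS if self.hours is None else self.hours))
        ts = list(self.hours.values())
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("stage times must be strictly increasing")

    @property
    def stages(self) -> list[str]:
        return list(self.hours)

    def days(self, stage: str) -> float:
        return self.hours[stage] / HOURS_PER_DAY

    @classmethod
    def from_file(cls, path) -> "StageTiming":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


@dataclass(frozen=True)
class RateEstimate:
    """Effective exponential rate over one stage interval, per day."""

    interval: tuple[str, str]
    k: float
    quantity: str  # "cell_count" or "cell_length"


def estimate_rate(v_prev: float, v_next: float,
                  t_prev_hours: float, t_next_hours: float,
                  interval: tuple[str, str] = ("", ""),
                  quantity: str = "cell_count") -> RateEstimate:
    """Exponential rate k = (ln v_next − ln v_prev) / Δt, reported per day."""
    if v_prev <= 0 or v_next <= 0:
        raise ValueError("values must be strictly positive")
    if t_next_hours <= t_prev_hours:
        raise ValueError("t_next must exceed t_prev")
    dt_days = (t_next_hours - t_prev_hours) / HOURS_PER_DAY
    k = (np.log(v_next) - np.log(v_prev)) / dt_days
    return RateEstimate(interval=interval, k=float(k), quantity=quantity)


def estimate_stage_rates(summary: pd.DataFrame, timing: StageTiming,
                         value_col: str = "n_cells",
                         quantity: str = "cell_count") -> pd.DataFrame:
    """Per-region, per-interval rates from a stage-summary table.

    ``summary`` needs columns stage, region and ``value_col``. No rate is
    computed into the first stage. Returns a long table with columns
    region, stage_from, stage_to, k_per_day, L (mean total_length over the
    interval, when a total_length column is present).
    """
    rows = []
    stages = [s for s in timing.stages if s in set(summary["stage"])]
    for region, sub in summary.groupby("region"):
        sub = sub.set_index("stage")
        for s_prev, s_next in zip(stages, stages[1:]):
            if s_prev not in sub.index or s_next not in sub.index:
                continue
            est = estimate_rate(
                float(sub.loc[s_prev, value_col]), float(sub.loc[s_next, value_col]),
                timing.hours[s_prev], timing.hours[s_next],
                interval=(s_prev, s_next), quantity=quantity)
            row = {"region": region, "stage_from": s_prev, "stage_to": s_next,
                   "k_per_day": est.k}
            if "total_length" in sub.columns:
                row["L"] = float((sub.loc[s_prev, "total_length"]
                                  + sub.loc[s_next, "total_length"]) / 2)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DivisionDecayFit:
    """Exponential-decay fit k(L) = r_d · exp(−L/L0)."""

    r_d: float
    L0: float
    log_residuals: np.ndarray
    rss: float
    leverage_warning: bool = False


def fit_division_decay(L, k, refine: bool = False) -> DivisionDecayFit:
    """Fit division rates against petal length with k = r_d·exp(−L/L0).

    Linear least squares on log k (exact on noise-free inputs); set
    ``refine=True`` for a nonlinear refinement on the original scale.
    """
    L = np.asarray(L, dtype=float)
    k = np.asarray(k, dtype=float)
    if L.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(k <= 0):
        raise ValueError("rates must be strictly positive")
    leverage = np.unique(L).size < L.size
    if np.unique(L).size < 2:
        raise ValueError("degenerate design: all lengths identical")
    if leverage:
        warnings.warn("repeated length values; fit has high-leverage points",
                      UserWarning, stacklevel=2)
    slope, intercept = np.polyfit(L, np.log(k), 1)
    if slope >= 0:
        raise ValueError("rates do not decay with length; cannot fit e^(−L/L0)")
    r_d, L0 = float(np.exp(intercept)), float(-1.0 / slope)
    if refine:
        popt, _ = optimize.curve_fit(
            lambda x, a, b: a * np.exp(-x / b), L, k, p0=(r_d, L0), maxfev=10_000)
        r_d, L0 = float(popt[0]), float(popt[1])
    resid = np.log(k) - (np.log(r_d) - L / L0)
    return DivisionDecayFit(r_d=r_d, L0=L0, log_residuals=resid,
                            rss=float(np.sum(resid**2)),
                            leverage_warning=leverage)


def ratio_stats(mean_x: float, mean_x2: float,
                mean_invy: float, mean_invy2: float) -> tuple[float, float]:
    """Mean and variance of X/Y for independent X, Y from raw moments.

    E(X/Y) = E(X)·E(1/Y);  Var(X/Y) = E(X²)·E(1/Y²) − E²(X)·E²(1/Y).
    Error bars on genotype-comparison plots are sqrt of the variance.
    """
    mean_ratio = mean_x * mean_invy
    var_ratio = mean_x2 * mean_invy2 - mean_x**2 * mean_invy**2
    if var_ratio < -1e-12 * max(1.0, abs(mean_x2 * mean_invy2)):
        raise ValueError("negative ratio variance: inconsistent input moments")
    return float(mean_ratio), float(max(var_ratio, 0.0))


def ratio_stats_from_samples(x, y) -> tuple[float, float]:
    """Moment-based ratio statistics from independent samples of X and Y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y == 0):
        raise ZeroDivisionError("Y samples must be bounded away from zero")
    return ratio_stats(x.mean(), np.mean(x**2),
                       np.mean(1.0 / y), np.mean(1.0 / y**2))
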