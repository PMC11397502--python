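"""Artificial flower-disc geometry and bumblebee choice analyses.

Artificial flowers are flat bicoloured discs: an inner purple circle (the
"bullseye") on a white background, with the bullseye size expressed as the
percentage of total disc area. Preference tests compare first-landing
counts between two disc types; differential-conditioning sequences are
analysed with a pooled binomial-logistic learning curve over visit index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DiscDesign",
    "disc_area_fraction",
    "preference_test",
    "learning_curve",
    "LearningCurveFit",
]


@dataclass(frozen=True)
class DiscDesign:
    """A bicoloured disc: inner bullseye circle on an outer disc, in cm."""

    outer_diameter: float = 6.0
    inner_diameter: float = 2.4

    def __post_init__(self):
        if not 0 < self.inner_diameter < self.outer_diameter:
            raise ValueError("need 0 < inner_diameter < outer_diameter")

    @property
    def area_fraction(self) -> float:
        return disc_area_fraction(self.inner_diameter, self.outer_diameter)


def disc_area_fraction(inner: float, outer: float) -> float:
    """Percent of disc area covered by the inner circle: 100·(inner/outer)²."""
    if not 0 < inner < outer:
        raise ValueError("need 0 < inner < outer")
    return 100.0 * (inner / outer) ** 2


def preference_test(a: int, b: int, ttest: bool = False):
    """First-choice preference between two disc types.

    Returns (proportion choosing type A, two-sided p-value against 0.5).
    The default test is the exact binomial; ``ttest=True`` additionally
    returns the one-sample t-test p-value on the 0/1 choices.
    """
    if a < 0 or b < 0 or a + b < 1:
        raise ValueError("need non-negative counts with a + b >= 1")
    n = a + b
    prop = a / n
    p_binom = stats.binomtest(a, n, 0.5, alternative="two-sided").pvalue
    if ttest:
        choices = np.r_[np.ones(a), np.zeros(b)]
        p_t = float(stats.ttest_1samp(choices, 0.5).pvalue) if 0 < a < n else 0.0
        return prop, float(p_binom), p_t
    return prop, float(p_binom)


@dataclass
class LearningCurveFit:
    """Pooled binomial-logistic fit of correct choice on visit index."""

    curve: pd.DataFrame  # visit, p_hat, ci_low, ci_high
    intercept: float
    slope: float
    lr_chi2: float
    lr_pvalue: float
    separation_fallback: bool = False

    @property
    def p_first(self) -> float:
        return float(self.curve["p_hat"].iloc[0])

    @property
    def p_last(self) -> float:
        return float(self.curve["p_hat"].iloc[-1])


def learning_curve(choices: pd.DataFrame) -> LearningCurveFit:
    """Fit the pooled learning curve of a differential-conditioning assay.

    ``choices`` needs columns visit (1..N) and correct (0/1); bees are
    pooled. Fits a binomial GLM with logit link of correct on visit index,
    and reports the likelihood-ratio chi-square against the intercept-only
    model (does the success probability change with experience?) plus
    pointwise 95% Wald bands computed on the link scale. Complete
    separation falls back to a small-L2-penalised fit, flagged on the
    result.
    """
    if choices["visit"].nunique() < 2:
        raise ValueError("need at least 2 distinct visit indices")
    y = choices["correct"].to_numpy(dtype=float)
    X = sm.add_constant(choices["visit"].to_numpy(dtype=float))
    model = sm.GLM(y, X, family=sm.families.Binomial())
    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = model.fit()
            params, cov = res.params, res.cov_params()
            llf_full = res.llf
        except Exception:
            fallback = True
    if fallback:
        res = model.fit_regularized(alpha=1e-4, L1_wt=0.0)
        params = np.asarray(res.params)
        cov = None
        mu = model.predict(params, X)
        llf_full = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
    null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial()).fit()
    lr = 2.0 * (llf_full - null.llf)
    lr_p = float(stats.chi2.sf(max(lr, 0.0), df=1))

    visits = np.sort(choices["visit"].unique()).astype(float)
    Xg = sm.add_constant(visits)
    eta = Xg @ params
    if cov is not None:
        se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, cov, Xg))
    else:
        se = np.zeros_like(eta)
    expit = lambda z: 1.0 / (1.0 + np.exp(-z))
    curve = pd.DataFrame({
        "visit": visits.astype(int),
        "p_hat": expit(eta),
        "ci_low": expit(eta - 1.96 * se),
        "ci_high": expit(eta + 1.96 * se),
    })
    return LearningCurveFit(curve=curve, intercept=float(params[0]),
                            slope=float(params[1]), lr_chi2=float(lr),
                            lr_pvalue=lr_p, separation_fallback=fallback)
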