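"""Linear response of the S/M partition ratio to initial sulfate.

If the partition of substrate carbon between sulfate reduction and
methanogenesis is set by the initial sulfate concentration and stays
constant through the production phase, the net-sulfate-reduced to
net-methane-produced ratio S/M regressed on initial sulfate (mM) should
give the same straight line at every sampling day.  This module fits
that regression per day (ordinary least squares, via statsmodels) and
summarizes how stable the fitted slope is across days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["SulfateResponseFit", "fit_sm_regression", "slope_stability"]


@dataclass(frozen=True)
class SulfateResponseFit:
    """OLS fit of S/M against initial sulfate at one sampling day."""

    day: float
    n_points: int
    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    p_value: float


def fit_sm_regression(
    initial_sulfate_mM: np.ndarray,
    sm_ratio: np.ndarray,
    day: float = float("nan"),
) -> SulfateResponseFit:
    """Regress the S/M ratio on initial sulfate concentration.

    OLS with an estimated intercept (the line is not forced through the
    origin); R^2 is the squared Pearson correlation and the p-value is
    the two-sided t-test on the slope with n-2 degrees of freedom.
    Needs at least 3 points with non-degenerate x.
    """
    x = np.asarray(initial_sulfate_mM, dtype=float)
    y = np.asarray(sm_ratio, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("regression inputs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in initial sulfate: degenerate design")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return SulfateResponseFit(
        day=day,
        n_points=int(x.size),
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_se=float(model.bse[1]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
    )


def slope_stability(
    fits: list[SulfateResponseFit],
    max_ratio: float = 1.5,
) -> dict:
    """Summarize slope constancy across per-day regressions.

    Returns the slope range, the maximum pairwise slope difference, a
    per-day table, and ``stable`` — False when max/min slope exceeds
    ``max_ratio`` (sign changes are always unstable).
    """
    if len(fits) < 2:
        raise ValueError("slope stability needs at least 2 per-day fits")
    slopes = np.array([f.slope for f in fits], dtype=float)
    smin, smax = float(np.min(slopes)), float(np.max(slopes))
    if smin <= 0 <= smax and smin != smax and smin < 0:
        stable = False
    elif smin == 0:
        stable = smax == 0
    else:
        stable = (smax / smin if smin > 0 else smin / smax) <= max_ratio
    table = pd.DataFrame(
        {
            "day": [f.day for f in fits],
            "n_points": [f.n_points for f in fits],
            "slope": slopes,
            "intercept": [f.intercept for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "p_value": [f.p_value for f in fits],
        }
    )
    return {
        "slope_min": smin,
        "slope_max": smax,
        "max_pairwise_difference": smax - smin,
        "stable": bool(stable),
        "per_day": table,
    }
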