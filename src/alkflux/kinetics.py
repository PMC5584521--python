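"""Logistic fitting of cumulative methane production curves.

Cumulative headspace methane y(t) from a batch culture typically shows
a lag phase followed by roughly exponential acceleration and a plateau,
and is well described by the three-parameter logistic

    y(t) = a / (1 + exp(-k * (t - t_c)))

with asymptote ``a`` (mmol), midpoint ``t_c`` (days) and rate constant
``k``.  The maximum specific methane production rate mu_max is taken to
be ``k``: for the logistic the per-capita rate (1/y) dy/dt equals
k * (1 - y/a), whose supremum (the y -> 0 limit) is k.  Time is
converted from days to months (1 month = 30.4375 days, a Julian
year/12) before fitting so that k — and hence mu_max — is reported in
month^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["LogisticFit", "DAYS_PER_MONTH", "fit_logistic", "predict_logistic"]

#: Days per month used for the days -> months conversion (Julian year / 12).
DAYS_PER_MONTH = 30.4375


@dataclass(frozen=True)
class LogisticFit:
    """Result of a logistic fit to a cumulative production curve.

    ``amplitude`` is in mmol, ``midpoint_day`` in days, ``rate`` (= k)
    and ``mu_max`` in month^-1; ``rss`` is the residual sum of squares
    in mmol^2.
    """

    amplitude: float
    midpoint_day: float
    rate: float
    rss: float
    converged: bool
    n_points: int
    message: str = ""

    @property
    def mu_max(self) -> float:
        """Maximum specific production rate; equals the logistic k."""
        return self.rate


def _logistic(t_months: np.ndarray, a: float, k: float, tc_months: float) -> np.ndarray:
    return a / (1.0 + np.exp(-k * (t_months - tc_months)))


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Deterministic starting point: amplitude from the max, midpoint from
    the half-maximum crossing, rate from a logit-linear regression."""
    a0 = 1.05 * float(np.max(y))
    above = np.nonzero(y > a0 / 2)[0]
    tc0 = float(t[above[0]]) if above.size else float(np.median(t))
    frac = np.clip(y / a0, 1e-9, 1 - 1e-9)
    interior = (frac > 1e-6) & (frac < 1 - 1e-6)
    if interior.sum() >= 2 and np.ptp(t[interior]) > 0:
        slope, _ = np.polyfit(t[interior], np.log(frac[interior] / (1 - frac[interior])), 1)
        k0 = float(slope) if slope > 0 else 0.1
    else:
        k0 = 0.1
    return a0, k0, tc0


def fit_logistic(
    days: np.ndarray,
    methane_mmol: np.ndarray,
    restarts: int = 0,
    seed: int | None = None,
    days_per_month: float = DAYS_PER_MONTH,
) -> LogisticFit:
    """Least-squares logistic fit of cumulative methane versus time.

    Parameters
    ----------
    days, methane_mmol
        Sampling days and cumulative methane; at least 4 distinct time
        points are required and methane must be non-negative.
    restarts
        Number of additional fits from seeded, jittered starting points;
        the best RSS wins.  The default 0 is fully deterministic.
    seed
        RNG seed for the restart jitter.

    Non-convergence (including degenerate flat series) is reported via
    ``converged=False`` with a diagnostic message, not an exception.
    """
    t_days = np.asarray(days, dtype=float)
    y = np.asarray(methane_mmol, dtype=float)
    if t_days.shape != y.shape or t_days.ndim != 1:
        raise ValueError("days and methane must be 1-d vectors of equal length")
    if np.unique(t_days).size < 4:
        raise ValueError("logistic fit needs at least 4 distinct time points")
    if np.any(y < 0):
        raise ValueError("methane amounts must be non-negative")

    n = y.size
    if np.ptp(y) <= 1e-12 * max(1.0, float(np.max(np.abs(y)))):
        return LogisticFit(
            amplitude=float(np.mean(y)), midpoint_day=float("nan"), rate=float("nan"),
            rss=0.0, converged=False, n_points=n,
            message="no growth signal: series is constant",
        )

    t = t_days / days_per_month
    a0, k0, tc0 = _initial_guess(t, y)
    starts = [(a0, k0, tc0)]
    if restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(restarts):
            jitter = rng.lognormal(0.0, 0.3, size=3)
            starts.append((a0 * jitter[0], k0 * jitter[1], tc0 * jitter[2]))

    def residuals(p: np.ndarray) -> np.ndarray:
        return _logistic(t, *p) - y

    best = None
    for start in starts:
        try:
            sol = least_squares(
                residuals, x0=np.asarray(start), ftol=1e-12, xtol=1e-12, gtol=1e-12,
                max_nfev=10_000,
                bounds=([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            )
        except Exception:  # pragma: no cover - scipy failures are rare
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        return LogisticFit(
            amplitude=float("nan"), midpoint_day=float("nan"), rate=float("nan"),
            rss=float("inf"), converged=False, n_points=n,
            message="optimizer did not converge",
        )
    a, k, tc = best.x
    return LogisticFit(
        amplitude=float(a),
        midpoint_day=float(tc * days_per_month),
        rate=float(k),
        rss=float(2 * best.cost),
        converged=True,
        n_points=n,
        message=best.message,
    )


def predict_logistic(
    fit: LogisticFit, days: np.ndarray, days_per_month: float = DAYS_PER_MONTH
) -> np.ndarray:
    """Evaluate a fitted logistic curve at ``days``."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    t = np.asarray(days, dtype=float) / days_per_month
    return _logistic(t, fit.amplitude, fit.rate, fit.midpoint_day / days_per_month)
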