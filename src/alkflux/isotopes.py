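"""Apparent carbon-isotope fractionation between CO2 and CH4.

The apparent methanogenesis fractionation factor

    alpha_app = (d13CO2 + 1000) / (d13CH4 + 1000)

(deltas in per-mil vs VPDB) is a coarse index of the dominant
methanogenic pathway: CO2 reduction with H2 discriminates strongly
against 13C (large alpha), while aceticlastic methanogenesis transmits
the acetate methyl carbon with little fractionation (alpha close to 1).
Literature thresholds place hydrogenotrophic-dominated systems above
1.065 and aceticlastic-dominated systems below 1.025; values between
are mixed/intermediate.  Headspace CO2 (not DIC) deltas are assumed
throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PathwayClass",
    "AlphaRecord",
    "DEFAULT_ACETICLASTIC_THRESHOLD",
    "DEFAULT_HYDROGENOTROPHIC_THRESHOLD",
    "alpha_app",
    "classify_pathway",
    "plateau_estimate",
    "alpha_table",
]

DEFAULT_ACETICLASTIC_THRESHOLD = 1.025
DEFAULT_HYDROGENOTROPHIC_THRESHOLD = 1.065


class PathwayClass(str, enum.Enum):
    ACETICLASTIC_DOMINATED = "aceticlastic_dominated"
    INTERMEDIATE = "intermediate"
    HYDROGENOTROPHIC_DOMINATED = "hydrogenotrophic_dominated"


@dataclass(frozen=True)
class AlphaRecord:
    treatment_id: str
    day: float
    d13ch4: float
    d13co2: float
    alpha_app: float
    pathway_class: PathwayClass


def alpha_app(d13co2, d13ch4):
    """Apparent fractionation factor (d13CO2 + 1000)/(d13CH4 + 1000).

    Accepts scalars or arrays (per-mil vs VPDB).  Deltas at or below
    -1000 permil are nonphysical (they would imply zero or negative 13C)
    and raise :class:`ValueError`.
    """
    co2 = np.asarray(d13co2, dtype=float)
    ch4 = np.asarray(d13ch4, dtype=float)
    if np.any(co2 <= -1000) or np.any(ch4 <= -1000):
        raise ValueError("delta values must be > -1000 permil")
    out = (co2 + 1000.0) / (ch4 + 1000.0)
    return float(out) if out.ndim == 0 else out


def classify_pathway(
    alpha: float,
    aceticlastic_threshold: float = DEFAULT_ACETICLASTIC_THRESHOLD,
    hydrogenotrophic_threshold: float = DEFAULT_HYDROGENOTROPHIC_THRESHOLD,
) -> PathwayClass:
    """Classify the dominant methanogenic pathway from alpha_app."""
    if alpha <= 0:
        raise ValueError("alpha_app must be positive")
    if aceticlastic_threshold >= hydrogenotrophic_threshold:
        raise ValueError("thresholds must satisfy aceticlastic < hydrogenotrophic")
    if alpha < aceticlastic_threshold:
        return PathwayClass.ACETICLASTIC_DOMINATED
    if alpha > hydrogenotrophic_threshold:
        return PathwayClass.HYDROGENOTROPHIC_DOMINATED
    return PathwayClass.INTERMEDIATE


def plateau_estimate(
    values: np.ndarray,
    window: int = 3,
    slope_tolerance: float = 1e-3,
) -> tuple[float, float, bool]:
    """Mean ± SE of the final ``window`` points of a time series, with a
    plateau flag.

    Returns ``(mean, se, is_plateau)``.  The series is judged to have
    plateaued when the OLS slope over the final window (per sampling
    step) does not exceed ``slope_tolerance`` in magnitude.  The plateau
    procedure — mean of the last few sampled points — is a pragmatic
    summary of an asymptoting trajectory, not a fitted asymptote.
    """
    v = np.asarray(values, dtype=float)
    if window < 2:
        raise ValueError("window must be at least 2")
    if v.size < window:
        raise ValueError(f"series of length {v.size} shorter than window {window}")
    tail = v[-window:]
    mean = float(np.mean(tail))
    se = float(np.std(tail, ddof=1) / np.sqrt(window))
    slope = float(np.polyfit(np.arange(window, dtype=float), tail, 1)[0])
    return mean, se, abs(slope) <= slope_tolerance


def alpha_table(
    observations: pd.DataFrame,
    aceticlastic_threshold: float = DEFAULT_ACETICLASTIC_THRESHOLD,
    hydrogenotrophic_threshold: float = DEFAULT_HYDROGENOTROPHIC_THRESHOLD,
) -> pd.DataFrame:
    """Per treatment × day summary of delta13C values and alpha_app.

    alpha_app is computed per replicate first, then averaged within the
    treatment × day cell (consistent with the replicate-first convention
    of the mass balance); delta columns are replicate means.
    Observations lacking either delta are dropped.
    """
    required = {"treatment_id", "day", "d13ch4_permil", "d13co2_permil"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observation table is missing columns: {sorted(missing)}")
    obs = observations.dropna(subset=["d13ch4_permil", "d13co2_permil"]).copy()
    obs["alpha_app"] = alpha_app(obs["d13co2_permil"], obs["d13ch4_permil"])
    grouped = obs.groupby(["treatment_id", "day"], sort=True)
    table = grouped.agg(
        d13ch4_mean=("d13ch4_permil", "mean"),
        d13co2_mean=("d13co2_permil", "mean"),
        alpha_app=("alpha_app", "mean"),
        n_replicates=("alpha_app", "size"),
    ).reset_index()
    table["pathway_class"] = [
        classify_pathway(a, aceticlastic_threshold, hydrogenotrophic_threshold).value
        for a in table["alpha_app"]
    ]
    return table
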