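"""Observation-table I/O and packaged reference data.

The standard long-format observation schema has one row per
treatment × replicate × sampling day:

================== ===========================================================
column             meaning
================== ===========================================================
treatment_id       treatment label
initial_sulfate_mM initial sulfate concentration (mM)
replicate_id       replicate label
day                days since inoculation
methane_mmol       cumulative headspace methane (mmol)
sulfate_mmol       sulfate remaining (mmol); alternatively ``sulfate_mM``,
                   converted on ingest using the liquid volume
d13ch4_permil      delta13C of CH4 (permil vs VPDB, optional)
d13co2_permil      delta13C of CO2 (permil vs VPDB, optional)
hexadecane_mmol    residual alkane (mmol, endpoint only, optional)
================== ===========================================================

Two small reference tables ship with the package so that the worked
examples and offline checks need no download: treatment-level endpoint
summaries (mean ± SE over 2-3 replicates) from a 421-day hexadecane
enrichment across a 0.5-25 mM sulfate gradient, and the plateau
delta13C pairs of its low- and high-sulfate groups.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "read_observations",
    "write_observations",
    "load_reference_endpoints",
    "load_reference_isotope_plateaus",
]

REQUIRED_COLUMNS = ("treatment_id", "initial_sulfate_mM", "replicate_id", "day", "methane_mmol")
OPTIONAL_COLUMNS = ("sulfate_mmol", "sulfate_mM", "d13ch4_permil", "d13co2_permil", "hexadecane_mmol")


def read_observations(path: str | Path, liquid_volume_l: float = 0.2) -> pd.DataFrame:
    """Read and validate an observation CSV.

    ``sulfate_mM`` is converted to ``sulfate_mmol`` with
    ``liquid_volume_l`` when the mmol column is absent.  Schema
    violations raise :class:`ValueError` naming the offending column,
    with row numbers for value errors.
    """
    obs = pd.read_csv(path)
    return validate_observations(obs, liquid_volume_l=liquid_volume_l)


def validate_observations(obs: pd.DataFrame, liquid_volume_l: float = 0.2) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table is missing required column(s): {missing}")
    obs = obs.copy()
    if "sulfate_mmol" not in obs.columns:
        if "sulfate_mM" in obs.columns:
            if liquid_volume_l <= 0:
                raise ValueError("liquid volume must be positive to convert sulfate_mM")
            obs["sulfate_mmol"] = obs["sulfate_mM"] * liquid_volume_l
        else:
            raise ValueError("observation table needs either sulfate_mmol or sulfate_mM")
    for col in ("day", "methane_mmol", "sulfate_mmol"):
        values = pd.to_numeric(obs[col], errors="coerce")
        bad = obs.index[values.isna() & obs[col].notna() | (values < 0)].tolist()
        if obs[col].isna().any():
            bad += obs.index[obs[col].isna()].tolist()
        if bad:
            raise ValueError(f"column {col!r} has missing/negative values at rows {sorted(set(bad))[:10]}")
        obs[col] = values
    return obs


def write_observations(obs: pd.DataFrame, path: str | Path) -> None:
    obs.to_csv(path, index=False)


def _load_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("alkflux.data").joinpath(name).open("r") as handle:
        return pd.read_csv(handle)


def load_reference_endpoints() -> pd.DataFrame:
    """Treatment-level endpoint summary of the reference hexadecane culture.

    Columns: ``initial_sulfate_mM``, then mean/SE pairs for hexadecane
    consumed (mmol), sulfate consumed (mmol, background-corrected),
    methane produced (mmol, background-corrected), carbon recovery (%),
    mu_max (month^-1) and the combined (M+S)/hexadecane ratio.  All
    statistics were computed replicate-first over n = 2-3 replicates.
    """
    return _load_packaged_csv("reference_endpoints.csv")


def load_reference_isotope_plateaus() -> pd.DataFrame:
    """Plateau delta13C values (permil vs VPDB) of the reference culture.

    One row per sulfate group (low = 0.5-4 mM, high = 10-25 mM) with the
    plateau delta13CH4 and delta13CO2 means and SEs after 421 days.
    """
    return _load_packaged_csv("reference_isotope_plateaus.csv")
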