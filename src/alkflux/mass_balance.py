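"""Background-corrected mass balance and pathway partition statistics.

Endpoint measurements from an alkane-degrading culture are converted
into net methane produced (M, mmol), net sulfate reduced (S, mmol) and
alkane consumed, from which the partition of substrate carbon and
electrons between methanogenesis and sulfate reduction is derived.

Two partition conventions coexist in the literature and both are
computed here:

* the electron-flow split of Isa and co-workers, 100·M/(M+S) and
  100·S/(M+S), which always sums to 100 %;
* substrate-normalized pathway contributions E_M = 100·M/(Y·hex) and
  E_S = 100·S/(Y·hex), where Y = (3n+1)/4 is the combined stoichiometric
  yield.  These sum to the carbon recovery, not to 100 %.

Ratio statistics are computed per replicate first and then averaged
("replicate-first"); the mean of per-replicate ratios is generally not
the ratio of means, and reported culture tables are only reproducible
under the replicate-first order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .stoichiometry import StoichiometricYields

__all__ = [
    "DataQualityWarning",
    "NetBalance",
    "DEFAULT_BACKGROUND_METHANE_MMOL",
    "DEFAULT_BACKGROUND_SULFATE_MMOL",
    "net_methane",
    "net_sulfate",
    "combined_ratio",
    "carbon_recovery",
    "pathway_contributions",
    "electron_flow_split",
    "sm_ratio",
    "replicate_balances",
    "summarize_treatment",
]

#: Default background constants: methane accumulated and sulfate drawn
#: down by a substrate-free control culture over a full incubation.
DEFAULT_BACKGROUND_METHANE_MMOL = 0.66
DEFAULT_BACKGROUND_SULFATE_MMOL = 0.096


class DataQualityWarning(UserWarning):
    """Non-fatal data issue (negative net value, non-monotone series)."""


def net_methane(detected_mmol: float, background_mmol: float = DEFAULT_BACKGROUND_METHANE_MMOL) -> float:
    """Net methane M = detected endpoint methane minus control background.

    Negative results are returned as-is with a :class:`DataQualityWarning`
    so that QC problems stay visible; clip downstream if desired.
    """
    if detected_mmol < 0 or background_mmol < 0:
        raise ValueError("methane amounts must be non-negative")
    net = detected_mmol - background_mmol
    if net < 0:
        warnings.warn(
            f"net methane is negative ({net:.3g} mmol): detected below background",
            DataQualityWarning,
            stacklevel=2,
        )
    return net


def net_sulfate(consumed_raw_mmol: float, background_mmol: float = DEFAULT_BACKGROUND_SULFATE_MMOL) -> float:
    """Net sulfate reduced S = raw consumption minus control consumption."""
    if consumed_raw_mmol < 0 or background_mmol < 0:
        raise ValueError("sulfate amounts must be non-negative")
    net = consumed_raw_mmol - background_mmol
    if net < 0:
        warnings.warn(
            f"net sulfate is negative ({net:.3g} mmol): consumption below background",
            DataQualityWarning,
            stacklevel=2,
        )
    return net


def combined_ratio(m_mmol: float, s_mmol: float, alkane_consumed_mmol: float) -> float:
    """(M + S) / alkane consumed — the pathway-independent yield observed.

    At complete recovery this equals the stoichiometric combined yield
    (3n+1)/4, i.e. 12.25 for hexadecane.
    """
    if alkane_consumed_mmol <= 0:
        raise ValueError("alkane consumed must be positive")
    return (m_mmol + s_mmol) / alkane_consumed_mmol


def carbon_recovery(ratio: float, yields: StoichiometricYields) -> float:
    """Percent of consumed alkane carbon recovered as CH4 + sulfate equivalents.

    ``100 * ratio / Y`` with Y the combined stoichiometric yield.
    """
    y = float(yields.combined_yield)
    if y <= 0:
        raise ValueError("combined stoichiometric yield must be positive")
    return 100.0 * ratio / y


def pathway_contributions(
    m_mmol: float,
    s_mmol: float,
    alkane_consumed_mmol: float,
    yields: StoichiometricYields,
) -> tuple[float, float]:
    """Substrate-normalized contributions (E_M %, E_S %).

    E_M + E_S equals the carbon recovery exactly.
    """
    if alkane_consumed_mmol <= 0:
        raise ValueError("alkane consumed must be positive")
    denom = float(yields.combined_yield) * alkane_consumed_mmol
    return 100.0 * m_mmol / denom, 100.0 * s_mmol / denom


def electron_flow_split(m_mmol: float, s_mmol: float) -> tuple[float, float]:
    """Percent electron flow via methanogenesis and via sulfate reduction.

    (100·M/(M+S), 100·S/(M+S)); the two shares sum to 100.  Undefined
    when M + S is zero.
    """
    total = m_mmol + s_mmol
    if total <= 0:
        raise ValueError("electron-flow split undefined for M + S <= 0")
    return 100.0 * m_mmol / total, 100.0 * s_mmol / total


def sm_ratio(m_mmol: float, s_mmol: float) -> float:
    """Sulfate-reduction to methane-production ratio S/M."""
    if m_mmol <= 0:
        raise ValueError("S/M undefined for non-positive methane")
    return s_mmol / m_mmol


@dataclass
class NetBalance:
    """Background-corrected balance and partition statistics for one replicate."""

    treatment_id: str
    replicate_id: str
    initial_sulfate_mM: float
    M: float
    S: float
    hexadecane_consumed: float
    combined_ratio: float
    recovery: float
    contribution_methanogenesis: float
    contribution_sulfidogenesis: float
    electron_flow_M: float
    electron_flow_S: float
    sm_ratio: float
    flags: list[str] = field(default_factory=list)

    @classmethod
    def compute(
        cls,
        treatment_id: str,
        replicate_id: str,
        initial_sulfate_mM: float,
        methane_detected: float,
        sulfate_consumed_raw: float,
        hexadecane_consumed: float,
        yields: StoichiometricYields,
        background_methane: float = DEFAULT_BACKGROUND_METHANE_MMOL,
        background_sulfate: float = DEFAULT_BACKGROUND_SULFATE_MMOL,
        clip_negative: bool = False,
    ) -> "NetBalance":
        flags: list[str] = []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", DataQualityWarning)
            m = net_methane(methane_detected, background_methane)
            s = net_sulfate(sulfate_consumed_raw, background_sulfate)
        flags.extend(str(w.message) for w in caught)
        if clip_negative:
            m, s = max(m, 0.0), max(s, 0.0)
        ratio = combined_ratio(m, s, hexadecane_consumed)
        e_m, e_s = pathway_contributions(m, s, hexadecane_consumed, yields)
        if m + s > 0:
            f_m, f_s = electron_flow_split(m, s)
        else:
            f_m = f_s = float("nan")
            flags.append("electron-flow split undefined (M + S = 0)")
        return cls(
            treatment_id=treatment_id,
            replicate_id=replicate_id,
            initial_sulfate_mM=initial_sulfate_mM,
            M=m,
            S=s,
            hexadecane_consumed=hexadecane_consumed,
            combined_ratio=ratio,
            recovery=carbon_recovery(ratio, yields),
            contribution_methanogenesis=e_m,
            contribution_sulfidogenesis=e_s,
            electron_flow_M=f_m,
            electron_flow_S=f_s,
            sm_ratio=sm_ratio(m, s) if m > 0 else float("nan"),
            flags=flags,
        )


_STAT_COLUMNS = [
    "hexadecane_consumed",
    "S",
    "M",
    "recovery",
    "combined_ratio",
    "contribution_methanogenesis",
    "contribution_sulfidogenesis",
    "electron_flow_M",
    "electron_flow_S",
    "sm_ratio",
]


def replicate_balances(
    observations: pd.DataFrame,
    yields: StoichiometricYields,
    hexadecane_initial_mmol: float,
    background_methane: float = DEFAULT_BACKGROUND_METHANE_MMOL,
    background_sulfate: float = DEFAULT_BACKGROUND_SULFATE_MMOL,
    liquid_volume_l: float = 0.2,
    clip_negative: bool = False,
) -> pd.DataFrame:
    """Per-replicate endpoint balances from a long observation table.

    ``observations`` follows the standard schema (see :mod:`alkflux.io`):
    one row per treatment × replicate × day with cumulative headspace
    methane (mmol), sulfate remaining (mmol, or mM converted on ingest)
    and, at the endpoint, residual hexadecane (mmol).  The last sampled
    day of each replicate is taken as the endpoint.  Sulfate consumption
    is ``initial_sulfate_mM · V − sulfate_remaining``; hexadecane
    consumption is ``hexadecane_initial_mmol − residual``.
    """
    required = {"treatment_id", "initial_sulfate_mM", "replicate_id", "day", "methane_mmol", "sulfate_mmol"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observation table is missing columns: {sorted(missing)}")
    rows = []
    for (treatment, replicate), group in observations.groupby(
        ["treatment_id", "replicate_id"], sort=True
    ):
        group = group.sort_values("day")
        if (group["methane_mmol"].diff().dropna() < -1e-9).any():
            warnings.warn(
                f"methane series not non-decreasing for {treatment}/{replicate}",
                DataQualityWarning,
                stacklevel=2,
            )
        end = group.iloc[-1]
        initial_sulfate_mmol = end["initial_sulfate_mM"] * liquid_volume_l
        consumed_raw = initial_sulfate_mmol - end["sulfate_mmol"]
        if "hexadecane_mmol" in group.columns and np.isfinite(end.get("hexadecane_mmol", np.nan)):
            hex_consumed = hexadecane_initial_mmol - end["hexadecane_mmol"]
        else:
            raise ValueError(
                f"no endpoint residual hexadecane for {treatment}/{replicate}; "
                "cannot close the balance"
            )
        bal = NetBalance.compute(
            treatment_id=str(treatment),
            replicate_id=str(replicate),
            initial_sulfate_mM=float(end["initial_sulfate_mM"]),
            methane_detected=float(end["methane_mmol"]),
            sulfate_consumed_raw=float(consumed_raw),
            hexadecane_consumed=float(hex_consumed),
            yields=yields,
            background_methane=background_methane,
            background_sulfate=background_sulfate,
            clip_negative=clip_negative,
        )
        row = {f.name: getattr(bal, f.name) for f in fields(bal) if f.name != "flags"}
        row["flags"] = "; ".join(bal.flags)
        rows.append(row)
    if not rows:
        raise ValueError("empty observation table")
    return pd.DataFrame(rows)


def summarize_treatment(balances: pd.DataFrame) -> pd.DataFrame:
    """Treatment-level mean ± standard error of each partition statistic.

    Statistics are averaged replicate-first: every ratio is computed per
    replicate in :func:`replicate_balances` and only then averaged here.
    SE = sd/sqrt(n) with ddof = 1 (NaN for a single replicate).
    """
    if balances.empty:
        raise ValueError("no replicate balances to summarize")
    grouped = balances.groupby(["treatment_id", "initial_sulfate_mM"], sort=True)
    out = {}
    for col in _STAT_COLUMNS:
        out[f"{col}_mean"] = grouped[col].mean()
        out[f"{col}_se"] = grouped[col].sem(ddof=1)
    summary = pd.DataFrame(out)
    summary["n_replicates"] = grouped.size()
    return summary.reset_index().sort_values("initial_sulfate_mM").reset_index(drop=True)
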