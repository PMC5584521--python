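"""End-to-end report: ingest -> balance -> kinetics -> isotopes -> regression.

``run_report`` turns a standard observation table into a bundle of
tab-separated outputs: a treatment-level balance table (endpoint mass
balance and partition statistics), per-replicate logistic kinetics, the
alpha_app trajectory table, and the per-day S/M-versus-sulfate
regression with a slope-stability summary.  Outputs are deterministic
for a given input + configuration (+ seed, where a stochastic option is
enabled) and are written into a fresh versioned subdirectory
(``run_0001``, ``run_0002``, ...) so re-running never corrupts earlier
results.

Full precision is kept internally; rounding (recovery and contributions
to 1 dp, ratios to 2 dp, rates to 3 dp) is applied only when the tables
are serialized.
"""

from __future__ import annotations

import dataclasses
import hashlib
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import read_observations
from .isotopes import (
    DEFAULT_ACETICLASTIC_THRESHOLD,
    DEFAULT_HYDROGENOTROPHIC_THRESHOLD,
    alpha_table,
)
from .kinetics import DAYS_PER_MONTH, fit_logistic
from .mass_balance import (
    DEFAULT_BACKGROUND_METHANE_MMOL,
    DEFAULT_BACKGROUND_SULFATE_MMOL,
    replicate_balances,
    summarize_treatment,
)
from .stoichiometry import methanogenic_yields, parse_alkane_formula
from .sulfate_response import fit_sm_regression, slope_stability

__all__ = ["RunConfig", "run_report"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one report run; defaults reproduce the package's
    standard conventions for a 0.34 mmol hexadecane dose in 0.2 l."""

    input_path: str
    output_dir: str
    alkane_formula: str = "C16H34"
    liquid_volume_l: float = 0.2
    hexadecane_initial_mmol: float = 0.34
    background_methane: float = DEFAULT_BACKGROUND_METHANE_MMOL
    background_sulfate: float = DEFAULT_BACKGROUND_SULFATE_MMOL
    days_per_month: float = DAYS_PER_MONTH
    aceticlastic_threshold: float = DEFAULT_ACETICLASTIC_THRESHOLD
    hydrogenotrophic_threshold: float = DEFAULT_HYDROGENOTROPHIC_THRESHOLD
    regression_days: tuple[float, ...] | None = None
    regression_on_means: bool = False
    subtract_background_before_fit: bool = False
    clip_negative: bool = False
    restarts: int = 0
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "rb") as handle:
            raw = tomllib.load(handle)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        if "regression_days" in raw and raw["regression_days"] is not None:
            raw["regression_days"] = tuple(float(d) for d in raw["regression_days"])
        raw.update(overrides)
        return cls(**raw)

    def config_hash(self) -> str:
        payload = repr(sorted(dataclasses.asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _next_run_dir(output_dir: Path) -> Path:
    output_dir.mkdir(parents=True, exist_ok=True)
    index = 1
    while (output_dir / f"run_{index:04d}").exists():
        index += 1
    run_dir = output_dir / f"run_{index:04d}"
    run_dir.mkdir()
    return run_dir


def _round_columns(frame: pd.DataFrame, rules: dict[str, int]) -> pd.DataFrame:
    out = frame.copy()
    for pattern, digits in rules.items():
        for col in out.columns:
            if pattern in col and pd.api.types.is_float_dtype(out[col]):
                out[col] = out[col].round(digits)
    return out


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _net_series(obs: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Per-row net methane M(t) and net sulfate reduced S(t)."""
    out = obs.copy()
    out["M"] = out["methane_mmol"] - config.background_methane
    out["S"] = (
        out["initial_sulfate_mM"] * config.liquid_volume_l
        - out["sulfate_mmol"]
        - config.background_sulfate
    )
    return out


def run_report(config: RunConfig) -> dict:
    """Run the full pipeline and write the report bundle.

    Returns a dict with the run directory and every table (also kept
    in memory for programmatic use).  Input schema violations raise
    before anything is written; partial bundles are never left behind
    silently.
    """
    obs = read_observations(config.input_path, liquid_volume_l=config.liquid_volume_l)
    alkane = parse_alkane_formula(config.alkane_formula)
    yields = methanogenic_yields(alkane)
    log_lines = [
        f"alkflux {__version__}",
        f"input: {config.input_path}",
        f"config hash: {config.config_hash()}",
        f"alkane: {alkane.formula} (combined yield {float(yields.combined_yield)})",
        f"observations: {len(obs)} rows, "
        f"{obs['treatment_id'].nunique()} treatments, "
        f"{obs.groupby('treatment_id')['replicate_id'].nunique().max()} replicates max",
    ]

    # --- endpoint mass balance -------------------------------------------
    balances = replicate_balances(
        obs,
        yields,
        hexadecane_initial_mmol=config.hexadecane_initial_mmol,
        background_methane=config.background_methane,
        background_sulfate=config.background_sulfate,
        liquid_volume_l=config.liquid_volume_l,
        clip_negative=config.clip_negative,
    )
    summary = summarize_treatment(balances)

    # --- logistic kinetics ------------------------------------------------
    kin_rows = []
    for (treatment, replicate), group in obs.groupby(["treatment_id", "replicate_id"], sort=True):
        group = group.sort_values("day")
        y = group["methane_mmol"].to_numpy(dtype=float)
        if config.subtract_background_before_fit:
            y = np.maximum(y - config.background_methane, 0.0)
        fit = fit_logistic(
            group["day"].to_numpy(dtype=float), y,
            restarts=config.restarts, seed=config.seed,
            days_per_month=config.days_per_month,
        )
        kin_rows.append(
            {
                "treatment_id": treatment,
                "replicate_id": replicate,
                "amplitude_mmol": fit.amplitude,
                "midpoint_day": fit.midpoint_day,
                "mu_max_per_month": fit.mu_max,
                "rss": fit.rss,
                "converged": fit.converged,
                "n_points": fit.n_points,
            }
        )
    kin_table = pd.DataFrame(kin_rows)
    n_failed = int((~kin_table["converged"]).sum())
    if n_failed:
        log_lines.append(f"kinetics: {n_failed} non-converged fit(s)")

    # --- isotopes ----------------------------------------------------------
    has_deltas = obs[["d13ch4_permil", "d13co2_permil"]].notna().all(axis=1).any() if {
        "d13ch4_permil", "d13co2_permil"
    } <= set(obs.columns) else False
    if has_deltas:
        alpha = alpha_table(
            obs,
            aceticlastic_threshold=config.aceticlastic_threshold,
            hydrogenotrophic_threshold=config.hydrogenotrophic_threshold,
        )
    else:
        alpha = pd.DataFrame()
        log_lines.append("isotopes: no complete delta13C pairs; alpha table empty")

    # --- per-day S/M regression -------------------------------------------
    nets = _net_series(obs, config)
    days = (
        sorted(config.regression_days)
        if config.regression_days is not None
        else sorted(nets["day"].unique())
    )
    fits = []
    for day in days:
        at_day = nets[nets["day"] == day]
        if at_day.empty:
            log_lines.append(f"regression: day {day:g} not sampled; skipped")
            continue
        if (at_day["M"] <= 0).any():
            log_lines.append(f"regression: day {day:g} skipped (pre-lag, some M <= 0)")
            continue
        points = at_day.assign(sm=at_day["S"] / at_day["M"])
        if config.regression_on_means:
            points = points.groupby("initial_sulfate_mM", as_index=False)["sm"].mean()
        if points["initial_sulfate_mM"].nunique() < 3:
            log_lines.append(f"regression: day {day:g} skipped (<3 sulfate levels)")
            continue
        fits.append(
            fit_sm_regression(
                points["initial_sulfate_mM"].to_numpy(dtype=float),
                points["sm"].to_numpy(dtype=float),
                day=float(day),
            )
        )
    if len(fits) >= 2:
        stability = slope_stability(fits)
        sm_table = stability["per_day"]
        log_lines.append(
            "regression: slope range "
            f"[{stability['slope_min']:.4f}, {stability['slope_max']:.4f}], "
            f"{'stable' if stability['stable'] else 'UNSTABLE'}"
        )
    else:
        stability = None
        sm_table = pd.DataFrame([dataclasses.asdict(f) for f in fits])
        log_lines.append("regression: fewer than 2 usable days; no stability summary")

    # --- serialize ----------------------------------------------------------
    run_dir = _next_run_dir(Path(config.output_dir))
    _write_tsv(
        _round_columns(summary, {"recovery": 1, "contribution": 1, "electron_flow": 1,
                                 "combined_ratio": 2, "sm_ratio": 2, "M_": 3, "S_": 3,
                                 "hexadecane": 3}),
        run_dir / "balance.tsv",
    )
    _write_tsv(_round_columns(kin_table, {"mu_max": 3, "amplitude": 3, "midpoint": 1, "rss": 6}),
               run_dir / "kinetics.tsv")
    if not alpha.empty:
        _write_tsv(_round_columns(alpha, {"alpha_app": 4, "d13": 2}), run_dir / "alpha.tsv")
    _write_tsv(_round_columns(sm_table, {"slope": 4, "intercept": 4, "r_squared": 4, "p_value": 6}),
               run_dir / "sm_regression.tsv")
    (run_dir / "run.log").write_text("\n".join(log_lines) + "\n")

    return {
        "run_dir": run_dir,
        "balances": balances,
        "summary": summary,
        "kinetics": kin_table,
        "alpha": alpha,
        "sm_regression": sm_table,
        "stability": stability,
        "log": log_lines,
    }
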