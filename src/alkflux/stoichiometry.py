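"""Balanced stoichiometry of complete anaerobic n-alkane oxidation.

A saturated alkane CnH(2n+2) can be completely mineralized either
methanogenically,

    CnH(2n+2) + (n-1)/2 H2O  ->  (3n+1)/4 CH4 + (n-1)/4 CO2

or coupled to sulfate reduction,

    CnH(2n+2) + (3n+1)/4 SO4^2- + (3n+1)/2 H+
        ->  (3n+1)/4 H2S + n CO2 + (n+1) H2O

Both routes transfer the same 6n+2 electron equivalents per mole of
alkane (8 e- per CH4 formed or per SO4^2- reduced), which is what makes
"moles CH4 produced + moles sulfate reduced" a pathway-independent
currency for mass-balance accounting.  For hexadecane (n = 16) the
common coefficient is 49/4 = 12.25.

Coefficients are kept as exact :class:`fractions.Fraction` values (they
are quarters for every n), so element-balance checks close to exactly
zero rather than to float round-off.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from fractions import Fraction

__all__ = [
    "Pathway",
    "AlkaneFormula",
    "StoichiometricYields",
    "parse_alkane_formula",
    "methanogenic_yields",
    "sulfidogenic_yields",
    "sulfate_demand",
    "alkane_molar_mass",
    "dose_to_mmol",
    "ELECTRONS_PER_CH4",
    "ELECTRONS_PER_SULFATE",
]

#: Electron equivalents carried per mole of product: 8 e- to reduce CO2
#: to CH4, 8 e- to reduce SO4^2- to H2S.
ELECTRONS_PER_CH4 = 8
ELECTRONS_PER_SULFATE = 8

# IUPAC 2021 standard atomic weights.
_ATOMIC_WEIGHT_C = 12.011
_ATOMIC_WEIGHT_H = 1.008

_FORMULA_RE = re.compile(r"^C(?P<c>\d*)H(?P<h>\d+)$")


class Pathway(str, enum.Enum):
    """Terminal route of complete alkane oxidation."""

    METHANOGENIC = "methanogenic"
    SULFIDOGENIC = "sulfidogenic"


@dataclass(frozen=True)
class AlkaneFormula:
    """Elemental composition of a saturated acyclic alkane CnH(2n+2).

    Parameters
    ----------
    n_carbon
        Number of carbon atoms (>= 1).
    n_hydrogen
        Number of hydrogen atoms; must equal ``2 * n_carbon + 2``.
    """

    n_carbon: int
    n_hydrogen: int

    def __post_init__(self) -> None:
        if self.n_carbon < 1:
            raise ValueError("alkane must have at least one carbon atom")
        if self.n_hydrogen != 2 * self.n_carbon + 2:
            raise ValueError(
                f"C{self.n_carbon}H{self.n_hydrogen} is not a saturated "
                f"n-alkane: expected H = 2n+2 = {2 * self.n_carbon + 2}"
            )

    @property
    def formula(self) -> str:
        return f"C{self.n_carbon}H{self.n_hydrogen}"


#: Hexadecane, the reference substrate.
HEXADECANE = AlkaneFormula(16, 34)


@dataclass(frozen=True)
class StoichiometricYields:
    """Per-mole coefficients for one complete-oxidation pathway.

    Sign convention: positive = produced, negative = consumed.  All
    values are exact rationals; use :meth:`as_floats` for decimal
    export.  ``h_plus_per_alkane`` is the proton consumption that
    balances the sulfate charge (zero for the methanogenic route).
    """

    pathway: Pathway
    alkane: AlkaneFormula
    ch4_per_alkane: Fraction
    co2_per_alkane: Fraction
    h2o_per_alkane: Fraction
    sulfate_per_alkane: Fraction
    h2s_per_alkane: Fraction
    h_plus_per_alkane: Fraction
    electron_equivalents: Fraction

    @property
    def combined_yield(self) -> Fraction:
        """Pathway-independent yield (3n+1)/4: CH4 or sulfate per alkane."""
        return self.ch4_per_alkane + self.sulfate_per_alkane

    def element_imbalance(self) -> dict[str, Fraction]:
        """Products-minus-reactants residual per element (and charge).

        All entries are exactly zero for a balanced equation.  Reactant
        side: 1 alkane, consumed water/protons/sulfate; product side:
        CH4, CO2, H2S, produced water.
        """
        n = self.alkane.n_carbon
        ch4, co2 = self.ch4_per_alkane, self.co2_per_alkane
        so4, h2s = self.sulfate_per_alkane, self.h2s_per_alkane
        h2o, h = self.h2o_per_alkane, self.h_plus_per_alkane
        return {
            "C": ch4 + co2 - Fraction(n),
            "H": 4 * ch4 + 2 * h2s + 2 * h2o - Fraction(self.alkane.n_hydrogen) - h,
            "O": 2 * co2 + h2o - 4 * so4,
            "S": h2s - so4,
            "charge": Fraction(0) - (-2 * so4 + h),
        }

    def as_floats(self) -> dict[str, float]:
        return {
            "ch4_per_alkane": float(self.ch4_per_alkane),
            "co2_per_alkane": float(self.co2_per_alkane),
            "h2o_per_alkane": float(self.h2o_per_alkane),
            "sulfate_per_alkane": float(self.sulfate_per_alkane),
            "h2s_per_alkane": float(self.h2s_per_alkane),
            "h_plus_per_alkane": float(self.h_plus_per_alkane),
            "electron_equivalents": float(self.electron_equivalents),
        }


def parse_alkane_formula(text: str) -> AlkaneFormula:
    """Parse a molecular formula like ``"C16H34"`` into an :class:`AlkaneFormula`.

    ``"CH4"`` is accepted as shorthand for ``"C1H4"``.  Raises
    :class:`ValueError` for malformed strings and for formulas that are
    not saturated acyclic alkanes (H != 2C+2) — general hydrocarbons
    are rejected rather than silently computed.
    """
    match = _FORMULA_RE.match(text.strip())
    if match is None:
        raise ValueError(f"cannot parse alkane formula {text!r}: expected C<n>H<m>")
    n_c = int(match.group("c") or 1)
    n_h = int(match.group("h"))
    return AlkaneFormula(n_c, n_h)


def methanogenic_yields(alkane: AlkaneFormula) -> StoichiometricYields:
    """Coefficients for complete methanogenic oxidation of ``alkane``.

    CnH(2n+2) + (n-1)/2 H2O -> (3n+1)/4 CH4 + (n-1)/4 CO2.  Water is
    reported with a negative sign (consumed).
    """
    n = alkane.n_carbon
    ch4 = Fraction(3 * n + 1, 4)
    return StoichiometricYields(
        pathway=Pathway.METHANOGENIC,
        alkane=alkane,
        ch4_per_alkane=ch4,
        co2_per_alkane=Fraction(n - 1, 4),
        h2o_per_alkane=-Fraction(n - 1, 2),
        sulfate_per_alkane=Fraction(0),
        h2s_per_alkane=Fraction(0),
        h_plus_per_alkane=Fraction(0),
        electron_equivalents=ELECTRONS_PER_CH4 * ch4,
    )


def sulfidogenic_yields(alkane: AlkaneFormula) -> StoichiometricYields:
    """Coefficients for complete sulfate-coupled oxidation of ``alkane``.

    CnH(2n+2) + (3n+1)/4 SO4^2- + (3n+1)/2 H+
        -> (3n+1)/4 H2S + n CO2 + (n+1) H2O.
    """
    n = alkane.n_carbon
    so4 = Fraction(3 * n + 1, 4)
    return StoichiometricYields(
        pathway=Pathway.SULFIDOGENIC,
        alkane=alkane,
        ch4_per_alkane=Fraction(0),
        co2_per_alkane=Fraction(n),
        h2o_per_alkane=Fraction(n + 1),
        sulfate_per_alkane=so4,
        h2s_per_alkane=so4,
        h_plus_per_alkane=2 * so4,
        electron_equivalents=ELECTRONS_PER_SULFATE * so4,
    )


def sulfate_demand(
    alkane_amount_mmol: float,
    alkane: AlkaneFormula = HEXADECANE,
    liquid_volume_l: float = 0.2,
) -> float:
    """Sulfate concentration (mM) needed to oxidize ``alkane_amount_mmol``
    completely through sulfate reduction in ``liquid_volume_l`` litres.

    The 0.2 l default liquid volume is the package's working assumption
    for a 600 ml culture vial with 20 % (vol/vol) inoculum-scale medium;
    it makes a 0.34 mmol hexadecane dose demand ~21 mM sulfate.
    """
    if alkane_amount_mmol <= 0:
        raise ValueError("alkane amount must be positive")
    if liquid_volume_l <= 0:
        raise ValueError("liquid volume must be positive")
    so4 = sulfidogenic_yields(alkane).sulfate_per_alkane
    return float(so4) * alkane_amount_mmol / liquid_volume_l


def alkane_molar_mass(alkane: AlkaneFormula) -> float:
    """Molar mass in g/mol from standard atomic weights."""
    return alkane.n_carbon * _ATOMIC_WEIGHT_C + alkane.n_hydrogen * _ATOMIC_WEIGHT_H


def dose_to_mmol(
    volume_ul: float,
    alkane: AlkaneFormula = HEXADECANE,
    density_g_per_ml: float = 0.773,
) -> float:
    """Convert a liquid alkane dose (µl) to mmol.

    Default density 0.773 g/ml is hexadecane at ~20 °C; a 100 µl dose is
    0.34 mmol.
    """
    if volume_ul <= 0 or density_g_per_ml <= 0:
        raise ValueError("volume and density must be positive")
    grams = volume_ul * 1e-3 * density_g_per_ml
    return grams / alkane_molar_mass(alkane) * 1e3
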