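"""Dose-metric conversions for metal oxide / metal salt exposures.

Exposure concentrations of particles are conventionally reported as the mass
of the whole compound per volume of medium (µg/mL).  For cross-material
potency comparison three further metrics are used: the mass of the
constituent metal (µg/mL Me), the molar metal concentration (µM Me), and --
for particles -- the surface-area concentration (cm²/mL) obtained from the
specific surface area (SSA, m²/g) of the powder.

Molar masses are built from IUPAC 2021 standard atomic weights stored to
four decimals in a packaged table; hydrate salts convert via the hydrate
molar mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "CompoundFormula",
    "SSASpec",
    "formula_table",
    "lookup_formula",
    "metal_molar_conc",
    "metal_mass_conc",
    "ssa_conc",
    "mean_ssa",
]


@dataclass(frozen=True)
class CompoundFormula:
    """Stoichiometry needed to convert compound mass to constituent metal.

    ``metal_atoms`` is the number of metal atoms per formula unit (2 for
    Al2O3, 1 otherwise); molar masses are in g/mol.
    """

    compound: str
    metal: str
    metal_atoms: int
    molar_mass_compound: float
    molar_mass_metal: float

    def __post_init__(self) -> None:
        if self.metal_atoms < 1:
            raise ValueError("metal_atoms must be >= 1")
        if self.molar_mass_compound <= 0 or self.molar_mass_metal <= 0:
            raise ValueError("molar masses must be positive")


@dataclass(frozen=True)
class SSASpec:
    """Specific surface area, either a scalar or a manufacturer range."""

    min: float
    max: float

    def __post_init__(self) -> None:
        if self.min <= 0 or self.max <= 0:
            raise ValueError("SSA must be positive")
        if self.min > self.max:
            raise ValueError("SSA range requires min <= max")


_TABLE: dict[str, CompoundFormula] | None = None


def formula_table() -> dict[str, CompoundFormula]:
    """Load the packaged compound-formula table (cached)."""
    global _TABLE
    if _TABLE is None:
        path = resources.files("toxpod").joinpath("data/compound_formulas.tsv")
        with resources.as_file(path) as p:
            df = pd.read_csv(p, sep="\t")
        _TABLE = {
            row.compound: CompoundFormula(
                compound=row.compound,
                metal=row.metal,
                metal_atoms=int(row.metal_atoms),
                molar_mass_compound=float(row.molar_mass_compound),
                molar_mass_metal=float(row.molar_mass_metal),
            )
            for row in df.itertuples()
        }
    return _TABLE


def lookup_formula(compound: str) -> CompoundFormula:
    """Fetch a built-in formula by compound name (e.g. ``"ZnO"``)."""
    table = formula_table()
    try:
        return table[compound]
    except KeyError:
        raise KeyError(
            f"unknown compound {compound!r}; known: {sorted(table)}"
        ) from None


def _resolve(formula: CompoundFormula | str) -> CompoundFormula:
    if isinstance(formula, str):
        return lookup_formula(formula)
    return formula


def metal_molar_conc(conc: float, formula: CompoundFormula | str) -> float:
    """Molar concentration of constituent metal (µM) from compound µg/mL.

    conc [µg/mL] / M_compound [g/mol] gives mmol/L of compound; × 1000 to µM
    and × metal_atoms to metal.
    """
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    f = _resolve(formula)
    return conc / f.molar_mass_compound * f.metal_atoms * 1000.0


def metal_mass_conc(conc: float, formula: CompoundFormula | str) -> float:
    """Mass concentration of constituent metal (µg/mL) from compound µg/mL."""
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    f = _resolve(formula)
    return conc * f.metal_atoms * f.molar_mass_metal / f.molar_mass_compound


def ssa_conc(conc: float, ssa: float) -> float:
    """Surface-area concentration (cm²/mL) from mass concentration and SSA.

    conc [µg/mL] × ssa [m²/g] = conc × ssa × 1e-6 g/mL × 1e4 cm²/g
    = conc × ssa × 0.01 cm²/mL.
    """
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    if ssa <= 0:
        raise ValueError("SSA must be positive")
    return conc * ssa * 0.01


def mean_ssa(spec: SSASpec | float | tuple[float, float]) -> float:
    """Average SSA from a manufacturer range, or identity on a scalar."""
    if isinstance(spec, (int, float)):
        if spec <= 0:
            raise ValueError("SSA must be positive")
        return float(spec)
    if isinstance(spec, tuple):
        spec = SSASpec(*spec)
    return (spec.min + spec.max) / 2.0
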