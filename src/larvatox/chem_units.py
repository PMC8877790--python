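"""Molar/mass concentration conversions and exposure-design validation.

Exposure concentrations in this assay are specified in nanomolar (nM); the
ecotoxicology literature usually reports mass concentrations (µg/L). The
conversion is linear in the molar mass:

    µg/L = c[nmol/L] × M[g/mol] × 10⁻³

Molar masses for the three study chemicals are computed from their molecular
formulas with 2020 IUPAC conventional atomic weights and stored as constants
(validated against the formula in the test suite).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .exceptions import ConfigurationError, ValidationError

# 2020 IUPAC conventional atomic weights (g/mol), elements needed for the
# built-in registry plus common organics.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Br": 79.904,
    "I": 126.904,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def molar_mass_from_formula(formula: str) -> float:
    """Molar mass (g/mol) of a simple molecular formula like ``C12H7Cl3O2``."""
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise ValidationError(f"malformed molecular formula: {formula!r}")
    mass = 0.0
    for element, count in _FORMULA_TOKEN.findall(formula):
        if element not in ATOMIC_WEIGHTS:
            raise ValidationError(f"unknown element {element!r} in {formula!r}")
        mass += ATOMIC_WEIGHTS[element] * (int(count) if count else 1)
    return mass


@dataclass(frozen=True)
class ChemicalSpec:
    """Identity and molar mass of one exposure chemical."""

    name: str
    cas: str
    formula: str
    molar_mass: float  # g/mol

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValidationError("molar_mass must be positive")
        computed = molar_mass_from_formula(self.formula)
        if abs(computed - self.molar_mass) > 0.01:
            raise ValidationError(
                f"molar_mass {self.molar_mass} inconsistent with formula "
                f"{self.formula} ({computed:.3f} g/mol)"
            )


#: Built-in registry for the three study chemicals.
REGISTRY: dict[str, ChemicalSpec] = {
    spec.name: spec
    for spec in (
        ChemicalSpec("triclosan", "3380-34-5", "C12H7Cl3O2", 289.536),
        ChemicalSpec("triclocarban", "101-20-2", "C13H9Cl3N2O", 315.578),
        ChemicalSpec("4-nonylphenol", "104-40-5", "C15H24O", 220.356),
    )
}

_ALIASES = {
    "tcs": "triclosan",
    "tcc": "triclocarban",
    "4np": "4-nonylphenol",
    "nonylphenol": "4-nonylphenol",
}


def get_chemical(name: str, registry: dict[str, ChemicalSpec] | None = None) -> ChemicalSpec:
    """Look up a chemical by name (case-insensitive; common abbreviations ok)."""
    registry = REGISTRY if registry is None else registry
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    if key not in registry:
        raise ValidationError(f"unknown chemical {name!r}; known: {sorted(registry)}")
    return registry[key]


def load_registry(path: str | Path) -> dict[str, ChemicalSpec]:
    """Read a user registry TSV with columns name, cas, formula, molar_mass."""
    registry = dict(REGISTRY)
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines):
        if not line.strip() or (i == 0 and line.lower().startswith("name")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 4:
            raise ValidationError(f"registry line {i + 1}: expected 4 tab-separated fields")
        name, cas, formula, mass = parts
        registry[name.strip().lower()] = ChemicalSpec(
            name.strip().lower(), cas.strip(), formula.strip(), float(mass)
        )
    return registry


def nM_to_ugL(chem: ChemicalSpec, concentration_nM: float) -> float:
    """Convert a nanomolar concentration to µg/L for the given chemical."""
    if concentration_nM < 0:
        raise ValidationError("concentration must be non-negative")
    return concentration_nM * chem.molar_mass * 1e-3


def ugL_to_nM(chem: ChemicalSpec, concentration_ugL: float) -> float:
    """Inverse of :func:`nM_to_ugL`; round-trips to machine precision."""
    if concentration_ugL < 0:
        raise ValidationError("concentration must be non-negative")
    return concentration_ugL / (chem.molar_mass * 1e-3)


DURATION_LABELS = ("24h", "120h")


@dataclass(frozen=True)
class ExposureDesign:
    """Planned concentrations/durations for one chemical, plus the vehicle label."""

    chemical: str
    concentrations_nM: tuple[float, ...]
    durations: tuple[str, ...] = DURATION_LABELS
    vehicle: str = "vehicle"

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.concentrations_nM):
            raise ConfigurationError("design concentrations must be strictly positive")
        if list(self.concentrations_nM) != sorted(self.concentrations_nM):
            raise ConfigurationError("design concentrations must be sorted ascending")
        unknown = set(self.durations) - set(DURATION_LABELS)
        if unknown:
            raise ConfigurationError(f"unknown duration labels: {sorted(unknown)}")


@dataclass
class DesignReport:
    """Discrepancies between a planned design and observed condition labels."""

    design_not_observed: list[float] = field(default_factory=list)
    observed_not_in_design: list[float] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return not self.design_not_observed and not self.observed_not_in_design


def validate_design(
    design: ExposureDesign, observed_concentrations_nM: Iterable[float]
) -> DesignReport:
    """Flag concentrations present in only one of design/observations.

    Catches, e.g., a results table whose column headers do not match the
    stated exposure design.
    """
    observed = {float(c) for c in observed_concentrations_nM}
    planned = {float(c) for c in design.concentrations_nM}
    return DesignReport(
        design_not_observed=sorted(planned - observed),
        observed_not_in_design=sorted(observed - planned),
    )
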