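"""Domain types, unit handling, and shared constants.

All internal arithmetic is carried out in canonical units: mg/L for
concentrations and mg/kg bw/day for doses.  Presentation layers convert
to ng/L or µg/L (or µg/kg bw/day) for reporting only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "UnitError",
    "ValidationError",
    "Concentration",
    "Dose",
    "ChemicalRecord",
    "HazardProfile",
    "ExposureDefaults",
    "convert",
    "cramer_ttc",
    "CRAMER_TTC_UG_PER_KG_DAY",
    "round_sig",
]


class UnitError(ValueError):
    """Raised when a unit is not a member of the closed unit set."""


class ValidationError(ValueError):
    """Raised when a domain value violates a type invariant."""


# factors to mg/L
_CONC_TO_MG_L = {
    "ng/L": 1e-6,
    "ug/L": 1e-3,
    "µg/L": 1e-3,
    "mg/L": 1.0,
}

# factors to mg/kg bw/day
_DOSE_TO_MG_KG_DAY = {
    "ug/kg bw/day": 1e-3,
    "µg/kg bw/day": 1e-3,
    "mg/kg bw/day": 1.0,
}


def _normalise_conc_unit(unit: str) -> str:
    if unit not in _CONC_TO_MG_L:
        raise UnitError(
            f"unknown concentration unit {unit!r}; expected one of ng/L, µg/L, mg/L"
        )
    return "µg/L" if unit == "ug/L" else unit


def _normalise_dose_unit(unit: str) -> str:
    if unit not in _DOSE_TO_MG_KG_DAY:
        raise UnitError(
            f"unknown dose unit {unit!r}; expected µg/kg bw/day or mg/kg bw/day"
        )
    return "µg/kg bw/day" if unit == "ug/kg bw/day" else unit


@dataclass(frozen=True)
class Concentration:
    """A non-negative aqueous concentration with an explicit unit."""

    value: float
    unit: str = "mg/L"

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", _normalise_conc_unit(self.unit))
        if not math.isfinite(self.value) or self.value < 0:
            raise ValidationError(f"concentration must be finite and >= 0, got {self.value}")

    def to(self, target_unit: str) -> "Concentration":
        target_unit = _normalise_conc_unit(target_unit)
        factor = _CONC_TO_MG_L[self.unit] / _CONC_TO_MG_L[target_unit]
        return Concentration(self.value * factor, target_unit)

    @property
    def mg_per_l(self) -> float:
        return self.value * _CONC_TO_MG_L[self.unit]


@dataclass(frozen=True)
class Dose:
    """A non-negative oral dose with an explicit unit."""

    value: float
    unit: str = "mg/kg bw/day"

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", _normalise_dose_unit(self.unit))
        if not math.isfinite(self.value) or self.value < 0:
            raise ValidationError(f"dose must be finite and >= 0, got {self.value}")

    def to(self, target_unit: str) -> "Dose":
        target_unit = _normalise_dose_unit(target_unit)
        factor = _DOSE_TO_MG_KG_DAY[self.unit] / _DOSE_TO_MG_KG_DAY[target_unit]
        return Dose(self.value * factor, target_unit)

    @property
    def mg_per_kg_day(self) -> float:
        return self.value * _DOSE_TO_MG_KG_DAY[self.unit]


def convert(c: Concentration, target_unit: str) -> Concentration:
    """Re-express ``c`` in ``target_unit`` (ng/L, µg/L or mg/L)."""
    return c.to(target_unit)


@dataclass(frozen=True)
class ChemicalRecord:
    """Identity and classification of one chemical.

    Carcinogen status is operational: a chemical is flagged as carcinogenic
    iff an oral slope factor or an explicit cancer drinking-water
    concentration is supplied — never from a name lookup.
    """

    cas: str
    name: str = ""
    smiles: Optional[str] = None
    verhaar_class: Optional[int] = None
    cramer_class: Optional[int] = None
    oral_slope_factor: Optional[float] = None
    cancer_dw_conc: Optional[Concentration] = None

    def __post_init__(self) -> None:
        if self.verhaar_class is not None and self.verhaar_class not in {1, 2, 3, 4, 5}:
            raise ValidationError(f"verhaar_class must be in 1..5, got {self.verhaar_class}")
        if self.cramer_class is not None and self.cramer_class not in {1, 2, 3}:
            raise ValidationError(f"cramer_class must be in 1..3, got {self.cramer_class}")
        if self.oral_slope_factor is not None and self.oral_slope_factor <= 0:
            raise ValidationError("oral_slope_factor must be > 0 when present")

    @property
    def is_carcinogen(self) -> bool:
        return self.oral_slope_factor is not None or self.cancer_dw_conc is not None


@dataclass(frozen=True)
class HazardProfile:
    """Per-chemical hazard values feeding the human and eco branches."""

    noael: Optional[Dose] = None
    adi: Optional[Dose] = None
    tdi: Optional[Dose] = None
    rfd: Optional[Dose] = None
    bmd: Optional[Dose] = None
    oral_slope_factor: Optional[float] = None  # per (mg/kg bw/day)
    cancer_dw_conc: Optional[Concentration] = None
    pnec: Optional[Concentration] = None

    def __post_init__(self) -> None:
        for name in ("noael", "adi", "tdi", "rfd", "bmd"):
            d = getattr(self, name)
            if d is not None and d.value <= 0:
                raise ValidationError(f"{name} must be strictly positive when present")
        if self.oral_slope_factor is not None and self.oral_slope_factor <= 0:
            raise ValidationError("oral_slope_factor must be strictly positive when present")
        for name in ("cancer_dw_conc", "pnec"):
            c = getattr(self, name)
            if c is not None and c.value <= 0:
                raise ValidationError(f"{name} must be strictly positive when present")

    @property
    def is_carcinogen(self) -> bool:
        return self.oral_slope_factor is not None or self.cancer_dw_conc is not None

    def human_fields_present(self) -> list[str]:
        return [
            f
            for f in ("adi", "tdi", "rfd", "bmd", "noael", "oral_slope_factor", "cancer_dw_conc")
            if getattr(self, f) is not None
        ]


@dataclass(frozen=True)
class ExposureDefaults:
    """Drinking-water exposure scenario parameters.

    bw: body weight (kg); wu: daily water uptake (L/day);
    allocation: fraction of the tolerable dose allotted to drinking water;
    risk_level: acceptable additional cancer risk.
    """

    bw: float = 70.0
    wu: float = 2.0
    allocation: float = 0.1
    risk_level: float = 1e-6

    def __post_init__(self) -> None:
        if self.bw <= 0 or self.wu <= 0 or self.risk_level <= 0:
            raise ValidationError("bw, wu and risk_level must be strictly positive")
        if not (0 < self.allocation <= 1):
            raise ValidationError("allocation must lie in (0, 1]")


# class -> TTC dose, µg/kg bw/day
CRAMER_TTC_UG_PER_KG_DAY = {1: 30.0, 2: 9.0, 3: 1.5}


def cramer_ttc(cramer_class: int) -> Dose:
    """TTC dose for a Cramer structural class (µg/kg bw/day)."""
    if cramer_class not in CRAMER_TTC_UG_PER_KG_DAY:
        raise ValidationError(f"cramer_class must be 1, 2 or 3, got {cramer_class}")
    return Dose(CRAMER_TTC_UG_PER_KG_DAY[cramer_class], "µg/kg bw/day")


def round_sig(x: float, digits: int = 4) -> float:
    """Round to ``digits`` significant figures (display only)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)
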