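"""Drinking-water quality standards from human toxicological values.

Non-cancer route: QS = allocation * TL * bw / wu, with TL a TTC dose, an
ADI/TDI/RfD/BMD taken directly, or NOAEL/100.  Cancer route: either a
supplied drinking-water concentration at the stated risk level, or
QS = (risk_level / SF) * bw / wu from the oral slope factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core import (
    Concentration,
    Dose,
    ExposureDefaults,
    HazardProfile,
    ValidationError,
    cramer_ttc,
)

__all__ = [
    "HumanQs",
    "qs_from_tl",
    "qs_from_cramer_class",
    "tl_from_noael",
    "qs_carcinogen",
    "compound_qs",
    "NOAEL_UNCERTAINTY_FACTOR",
    "TL_PRECEDENCE",
]

NOAEL_UNCERTAINTY_FACTOR = 100.0

# fixed-precedence order for the non-cancer TL when several fields exist
TL_PRECEDENCE = ("adi", "tdi", "rfd", "bmd", "noael")


@dataclass(frozen=True)
class HumanQs:
    """A water quality standard and the toxicological basis producing it."""

    value: Concentration  # mg/L
    basis: str  # cramer_ttc | adi | tdi | rfd | bmd | noael | slope_factor | cancer_dw_conc
    tl: Optional[Dose] = None  # absent for cancer routes
    bw: float = 70.0
    wu: float = 2.0
    allocation: Optional[float] = None
    risk_level: Optional[float] = None  # cancer routes only

    def __post_init__(self) -> None:
        if self.value.value <= 0:
            raise ValidationError("quality standard must be strictly positive")


def qs_from_tl(
    tl: Dose, defaults: ExposureDefaults = ExposureDefaults(), basis: str = "cramer_ttc"
) -> HumanQs:
    """QS = allocation * TL * bw / wu, in mg/L."""
    tl_mg = tl.mg_per_kg_day
    if tl_mg <= 0:
        raise ValidationError("TL must be strictly positive")
    value = defaults.allocation * tl_mg * defaults.bw / defaults.wu
    return HumanQs(
        value=Concentration(value, "mg/L"),
        basis=basis,
        tl=tl,
        bw=defaults.bw,
        wu=defaults.wu,
        allocation=defaults.allocation,
    )


def qs_from_cramer_class(
    cramer_class: int, defaults: ExposureDefaults = ExposureDefaults()
) -> HumanQs:
    """Quality standard from the class TTC dose."""
    return qs_from_tl(cramer_ttc(cramer_class), defaults, basis="cramer_ttc")


def tl_from_noael(noael: Dose) -> Dose:
    """TL = NOAEL / 100."""
    if noael.value <= 0:
        raise ValidationError("NOAEL must be strictly positive")
    return Dose(noael.mg_per_kg_day / NOAEL_UNCERTAINTY_FACTOR, "mg/kg bw/day")


def qs_carcinogen(sf: float, defaults: ExposureDefaults = ExposureDefaults()) -> HumanQs:
    """QS = (risk_level / SF) * bw / wu, in mg/L."""
    if sf <= 0:
        raise ValidationError("oral slope factor must be strictly positive")
    value = (defaults.risk_level / sf) * defaults.bw / defaults.wu
    return HumanQs(
        value=Concentration(value, "mg/L"),
        basis="slope_factor",
        bw=defaults.bw,
        wu=defaults.wu,
        risk_level=defaults.risk_level,
    )


def compound_qs(
    profile: HazardProfile,
    defaults: ExposureDefaults = ExposureDefaults(),
    tl_mode: str = "conservative",
) -> HumanQs:
    """Compound-specific quality standard from a hazard profile.

    Carcinogens (slope factor or cancer drinking-water concentration
    present) take the cancer route, which overrides any non-cancer field.
    Otherwise the TL is chosen either conservatively (lowest resulting QS
    among all available fields, the default) or by the fixed precedence
    ADI > TDI > RfD > BMD > NOAEL (``tl_mode="precedence"``).
    """
    fields = profile.human_fields_present()
    if not fields:
        raise ValidationError(
            "hazard profile has no human-branch field; need one of "
            "adi, tdi, rfd, bmd, noael, oral_slope_factor, cancer_dw_conc"
        )
    if tl_mode not in ("conservative", "precedence"):
        raise ValidationError(f"unknown tl_mode {tl_mode!r}")

    if profile.is_carcinogen:
        if profile.cancer_dw_conc is not None:
            # pass-through of a database-supplied risk-level concentration
            return HumanQs(
                value=profile.cancer_dw_conc.to("mg/L"),
                basis="cancer_dw_conc",
                bw=defaults.bw,
                wu=defaults.wu,
                risk_level=defaults.risk_level,
            )
        return qs_carcinogen(profile.oral_slope_factor, defaults)

    candidates: list[HumanQs] = []
    for name in TL_PRECEDENCE:
        dose = getattr(profile, name)
        if dose is None:
            continue
        tl = tl_from_noael(dose) if name == "noael" else dose
        candidates.append(qs_from_tl(tl, defaults, basis=name))

    if tl_mode == "precedence":
        return candidates[0]
    return min(candidates, key=lambda q: q.value.mg_per_l)
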