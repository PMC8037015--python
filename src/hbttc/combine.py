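"""Combine the ecological and human branches by the minimum rule."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .core import Concentration, ValidationError
from .ecottc import EcoTtc
from .human_qs import HumanQs

__all__ = ["HbTtcResult", "generic_hbttc", "compound_hbttc"]

VERHAAR_CLASSES = (1, 2, 3, 4, 5)
CRAMER_CLASSES = (1, 2, 3)


@dataclass(frozen=True)
class HbTtcResult:
    """A combined threshold and the branch that set it.

    Exactly equal branches are labelled eco-limited.
    """

    scope: str  # generic | compound
    value: Concentration  # mg/L
    limiting_branch: str  # eco | human
    eco_input: Concentration
    human_input: Concentration
    verhaar_class: Optional[int] = None
    cramer_class: Optional[int] = None
    chemical_id: Optional[str] = None
    eco_method: Optional[str] = None  # empirical | normal | logistic, generic scope

    def __post_init__(self) -> None:
        if self.scope not in ("generic", "compound"):
            raise ValidationError(f"unknown scope {self.scope!r}")


def _min_branch(eco: Concentration, human: Concentration) -> tuple[Concentration, str]:
    e, h = eco.mg_per_l, human.mg_per_l
    if e <= h:  # tie labelled eco
        return Concentration(e, "mg/L"), "eco"
    return Concentration(h, "mg/L"), "human"


def generic_hbttc(
    ecottcs: Mapping[int, EcoTtc], qs_table: Mapping[int, HumanQs]
) -> list[HbTtcResult]:
    """One combined threshold per (Verhaar, Cramer) pair — 15 results."""
    missing = [f"Verhaar class {v}" for v in VERHAAR_CLASSES if v not in ecottcs]
    missing += [f"Cramer class {c}" for c in CRAMER_CLASSES if c not in qs_table]
    if missing:
        raise ValidationError("missing inputs for generic combination: " + ", ".join(missing))

    results = []
    for v in VERHAAR_CLASSES:
        eco = ecottcs[v]
        for c in CRAMER_CLASSES:
            human = qs_table[c]
            value, branch = _min_branch(eco.value, human.value)
            results.append(
                HbTtcResult(
                    scope="generic",
                    verhaar_class=v,
                    cramer_class=c,
                    value=value,
                    limiting_branch=branch,
                    eco_input=eco.value.to("mg/L"),
                    human_input=human.value.to("mg/L"),
                    eco_method=eco.method,
                )
            )
    return results


def compound_hbttc(pnec: Concentration, qs: HumanQs, chemical_id: str) -> HbTtcResult:
    """Compound-specific threshold: min(PNEC, QS)."""
    if pnec.value <= 0:
        raise ValidationError("PNEC must be strictly positive")
    value, branch = _min_branch(pnec, qs.value)
    return HbTtcResult(
        scope="compound",
        chemical_id=chemical_id,
        value=value,
        limiting_branch=branch,
        eco_input=pnec.to("mg/L"),
        human_input=qs.value.to("mg/L"),
    )
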