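"""PNEC derivation from aquatic toxicity endpoints.

Endpoints are aggregated into per-(trophic group, duration class)
geometric means; an assessment factor is then selected from the data
availability pattern and applied to the basis cell that pattern
designates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Tuple

from .core import Concentration, ValidationError

__all__ = [
    "TROPHIC_GROUPS",
    "DURATION_CLASSES",
    "ToxEndpointRecord",
    "EndpointMatrix",
    "PnecResult",
    "geometric_mean",
    "build_matrix",
    "select_af",
    "derive_pnec",
]

TROPHIC_GROUPS = ("algae", "invertebrate", "fish")
DURATION_CLASSES = ("acute", "chronic")

Cell = Tuple[str, str]  # (trophic_group, duration_class)

# AF selected when >10 chronic records are available ("1 to 5" range);
# the conservative end of the range is the default.
DEFAULT_RICH_CHRONIC_AF = 5.0


@dataclass(frozen=True)
class ToxEndpointRecord:
    """One aquatic toxicity measurement."""

    chemical_id: str
    trophic_group: str
    duration_class: str
    value: Concentration
    endpoint_label: str = ""

    def __post_init__(self) -> None:
        if self.trophic_group not in TROPHIC_GROUPS:
            raise ValidationError(
                f"trophic_group must be one of {TROPHIC_GROUPS}, got {self.trophic_group!r}"
            )
        if self.duration_class not in DURATION_CLASSES:
            raise ValidationError(
                f"duration_class must be one of {DURATION_CLASSES}, got {self.duration_class!r}"
            )
        if self.value.value <= 0:
            raise ValidationError("endpoint value must be strictly positive")


@dataclass(frozen=True)
class EndpointMatrix:
    """Per-cell geometric means for one chemical.

    ``cells`` maps (trophic_group, duration_class) to (geometric mean in
    mg/L, contributing record count).  ``chronic_records`` keeps the raw
    chronic record count, needed by the data-rich AF rule.
    """

    chemical_id: str
    cells: Mapping[Cell, Tuple[float, int]]
    chronic_records: int

    def acute_groups(self) -> tuple[str, ...]:
        return tuple(g for g in TROPHIC_GROUPS if (g, "acute") in self.cells)

    def chronic_groups(self) -> tuple[str, ...]:
        return tuple(g for g in TROPHIC_GROUPS if (g, "chronic") in self.cells)

    def geomean(self, cell: Cell) -> float:
        return self.cells[cell][0]

    def lowest_cell(self, duration_class: str) -> Cell:
        """Cell with the lowest geomean for a duration class.

        Ties broken by the fixed trophic order algae < invertebrate < fish.
        """
        candidates = [
            ((g, duration_class), self.cells[(g, duration_class)][0])
            for g in TROPHIC_GROUPS
            if (g, duration_class) in self.cells
        ]
        if not candidates:
            raise ValidationError(f"no {duration_class} cells populated")
        return min(candidates, key=lambda cv: (cv[1], TROPHIC_GROUPS.index(cv[0][0])))[0]


@dataclass(frozen=True)
class PnecResult:
    chemical_id: str
    pnec: Concentration  # mg/L
    af: float
    basis_value: Concentration  # mg/L
    basis_cell: Cell
    rule_id: str
    fallback: bool = False

    def __post_init__(self) -> None:
        if self.af < 1:
            raise ValidationError("assessment factor must be >= 1")


def geometric_mean(values: Iterable[float]) -> float:
    """exp(mean(log values)); rejects empty or non-positive input."""
    vals = list(values)
    if not vals:
        raise ValidationError("geometric mean of an empty list")
    if any(v <= 0 for v in vals):
        raise ValidationError("geometric mean requires strictly positive values")
    return math.exp(sum(math.log(v) for v in vals) / len(vals))


def build_matrix(records: Iterable[ToxEndpointRecord]) -> EndpointMatrix:
    """Aggregate one chemical's records into per-cell geometric means (mg/L)."""
    recs = list(records)
    if not recs:
        raise ValidationError("no endpoint records supplied")
    ids = {r.chemical_id for r in recs}
    if len(ids) > 1:
        raise ValidationError(f"records mix chemical_ids: {sorted(ids)}")

    grouped: dict[Cell, list[float]] = {}
    for r in recs:
        grouped.setdefault((r.trophic_group, r.duration_class), []).append(r.value.mg_per_l)
    cells = {cell: (geometric_mean(vs), len(vs)) for cell, vs in grouped.items()}
    n_chronic = sum(1 for r in recs if r.duration_class == "chronic")
    return EndpointMatrix(chemical_id=recs[0].chemical_id, cells=cells, chronic_records=n_chronic)


def select_af(
    matrix: EndpointMatrix, rich_chronic_af: float = DEFAULT_RICH_CHRONIC_AF
) -> tuple[float, str, Cell, bool]:
    """Select the assessment factor for a data availability pattern.

    Returns ``(af, rule_id, basis_cell, fallback)``.  The rule ladder, from
    sparse to rich data:

    ======================================================  ======
    1 trophic acute level                                    10000
    2 trophic acute levels                                    5000
    3 trophic acute levels                                    1000
    3 acute + 1 chronic NOT on most sensitive acute taxon     1000
    3 acute + 1 chronic ON most sensitive acute taxon          100
    3 acute + 2 chronic incl. most sensitive acute taxon        50
    3 acute + 3 chronic                                         10
    more than 10 chronic records                            1 to 5
    ======================================================  ======

    Basis-cell semantics: acute-driven rules divide the lowest acute
    geometric mean; chronic-driven rules divide the lowest available
    chronic geometric mean.  Patterns outside the ladder (e.g. chronic
    data with fewer than three acute groups) fall back to the most
    conservative rule licensed by the acute coverage alone and are
    flagged.
    """
    if not (1 <= rich_chronic_af <= 5):
        raise ValidationError("rich_chronic_af must lie in [1, 5]")
    if not matrix.cells:
        raise ValidationError("cannot select an assessment factor from an empty matrix")

    acute = matrix.acute_groups()
    chronic = matrix.chronic_groups()
    n_a, n_c = len(acute), len(chronic)

    if matrix.chronic_records > 10:
        return rich_chronic_af, "chronic-rich", matrix.lowest_cell("chronic"), False

    if n_a == 3:
        most_sensitive = matrix.lowest_cell("acute")[0]
        if n_c == 3:
            return 10.0, "3+3", matrix.lowest_cell("chronic"), False
        if n_c == 2:
            if most_sensitive in chronic:
                return 50.0, "3+2-incl-ms", matrix.lowest_cell("chronic"), False
            # 2 chronic without the most sensitive taxon: not in the ladder
            return 1000.0, "fallback-3-acute", matrix.lowest_cell("acute"), True
        if n_c == 1:
            if chronic[0] == most_sensitive:
                return 100.0, "3+1-on-ms", (chronic[0], "chronic"), False
            return 1000.0, "3+1-not-ms", matrix.lowest_cell("acute"), False
        return 1000.0, "3-acute", matrix.lowest_cell("acute"), False

    if n_a == 2:
        rule = "2-acute" if n_c == 0 else "fallback-2-acute"
        return 5000.0, rule, matrix.lowest_cell("acute"), n_c > 0

    if n_a == 1:
        rule = "1-acute" if n_c == 0 else "fallback-1-acute"
        return 10000.0, rule, matrix.lowest_cell("acute"), n_c > 0

    # chronic-only data with <= 10 records: no ladder row applies
    return 10000.0, "fallback-chronic-only", matrix.lowest_cell("chronic"), True


def derive_pnec(
    records: Iterable[ToxEndpointRecord], rich_chronic_af: float = DEFAULT_RICH_CHRONIC_AF
) -> PnecResult:
    """Derive the PNEC for one chemical from its endpoint records."""
    matrix = build_matrix(records)
    af, rule_id, basis_cell, fallback = select_af(matrix, rich_chronic_af=rich_chronic_af)
    basis = matrix.geomean(basis_cell)
    return PnecResult(
        chemical_id=matrix.chemical_id,
        pnec=Concentration(basis / af, "mg/L"),
        af=af,
        basis_value=Concentration(basis, "mg/L"),
        basis_cell=basis_cell,
        rule_id=rule_id,
        fallback=fallback,
    )
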