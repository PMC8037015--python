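"""Readers and writers for the tabular schemas, plus run configuration.

Dialect: comma-separated UTF-8 text with a required header row and "." as
the decimal mark.  Row-level validation failures are collected with their
line numbers instead of aborting the whole file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import csv

import yaml

from .core import Concentration, Dose, ExposureDefaults, ValidationError
from .ecottc import EcoTtc, QuantileCandidates, select_minimum
from .human_qs import HumanQs, qs_from_cramer_class
from .pnec import DEFAULT_RICH_CHRONIC_AF, ToxEndpointRecord

__all__ = [
    "RunConfig",
    "RowError",
    "load_builtin_tables",
    "builtin_ecottcs",
    "builtin_qs_table",
    "read_endpoints",
    "write_endpoints",
    "read_pnec_table",
    "read_hazard_table",
]

ENDPOINT_COLUMNS = ("chemical_id", "trophic_group", "duration_class", "value", "unit")


@dataclass(frozen=True)
class RowError:
    line: int
    message: str


@dataclass
class RunConfig:
    """Run-wide options, loadable from YAML and echoed back identically."""

    bw: float = 70.0
    wu: float = 2.0
    allocation: float = 0.1
    risk_level: float = 1e-6
    rich_chronic_af: float = DEFAULT_RICH_CHRONIC_AF
    tl_mode: str = "conservative"  # or "precedence"
    output_unit: str = "ng/L"
    verbosity: int = 0

    _FIELDS = (
        "bw",
        "wu",
        "allocation",
        "risk_level",
        "rich_chronic_af",
        "tl_mode",
        "output_unit",
        "verbosity",
    )

    def __post_init__(self) -> None:
        self.exposure_defaults()  # validates bw/wu/allocation/risk_level
        if not (1 <= self.rich_chronic_af <= 5):
            raise ValidationError("rich_chronic_af: must lie in [1, 5]")
        if self.tl_mode not in ("conservative", "precedence"):
            raise ValidationError(f"tl_mode: unknown value {self.tl_mode!r}")
        if self.output_unit not in ("ng/L", "µg/L", "ug/L", "mg/L"):
            raise ValidationError(f"output_unit: unknown unit {self.output_unit!r}")

    def exposure_defaults(self) -> ExposureDefaults:
        return ExposureDefaults(
            bw=self.bw, wu=self.wu, allocation=self.allocation, risk_level=self.risk_level
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValidationError("config file must contain a mapping")
        unknown = set(raw) - set(cls._FIELDS)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = {k: getattr(self, k) for k in self._FIELDS}
        Path(path).write_text(
            yaml.safe_dump(data, sort_keys=True, allow_unicode=True), encoding="utf-8"
        )


def load_builtin_tables() -> dict:
    """The versioned reference-constant file shipped with the package."""
    text = resources.files("hbttc").joinpath("data/builtin_tables.json").read_text("utf-8")
    return json.loads(text)


def builtin_candidates() -> dict[int, QuantileCandidates]:
    """Shipped per-class fifth-percentile candidates, converted to log10 mg/L."""
    import math

    tables = load_builtin_tables()
    out = {}
    for vclass, cand in tables["ecottc_candidates_ng_per_l"].items():
        if vclass == "comment":
            continue
        v = int(vclass)
        out[v] = QuantileCandidates(
            verhaar_class=v,
            empirical=math.log10(cand["empirical"] * 1e-6),
            normal=math.log10(cand["normal"] * 1e-6),
            logistic=math.log10(cand["logistic"] * 1e-6),
            n=0,
            small_sample=False,
        )
    return out


def builtin_ecottcs() -> dict[int, EcoTtc]:
    """Per-class thresholds selected from the shipped candidate triples."""
    return {v: select_minimum(c) for v, c in builtin_candidates().items()}


def builtin_qs_table(defaults: Optional[ExposureDefaults] = None) -> dict[int, HumanQs]:
    """Quality standards for the three Cramer classes."""
    defaults = defaults or ExposureDefaults()
    return {c: qs_from_cramer_class(c, defaults) for c in (1, 2, 3)}


def _require_columns(fieldnames: Sequence[str], required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in fieldnames]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def read_endpoints(path: Union[str, Path]) -> tuple[list[ToxEndpointRecord], list[RowError]]:
    """Parse an endpoint table; invalid rows are reported, valid rows kept."""
    path = Path(path)
    records: list[ToxEndpointRecord] = []
    errors: list[RowError] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file, header row required")
        _require_columns(reader.fieldnames, ENDPOINT_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    ToxEndpointRecord(
                        chemical_id=row["chemical_id"].strip(),
                        trophic_group=row["trophic_group"].strip(),
                        duration_class=row["duration_class"].strip(),
                        value=Concentration(float(row["value"]), row["unit"].strip()),
                        endpoint_label=(row.get("endpoint_label") or "").strip(),
                    )
                )
            except (ValueError, KeyError) as exc:
                errors.append(RowError(line=lineno, message=str(exc)))
    return records, errors


def write_endpoints(records: Iterable[ToxEndpointRecord], path: Union[str, Path]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ENDPOINT_COLUMNS + ("endpoint_label",))
        for r in records:
            writer.writerow(
                [
                    r.chemical_id,
                    r.trophic_group,
                    r.duration_class,
                    repr(r.value.value),
                    r.value.unit,
                    r.endpoint_label,
                ]
            )


def read_pnec_table(
    path: Union[str, Path],
) -> tuple[list[tuple[str, int, Concentration]], list[RowError]]:
    """Parse a PNEC table: chemical_id, verhaar_class, pnec, unit."""
    path = Path(path)
    rows: list[tuple[str, int, Concentration]] = []
    errors: list[RowError] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file, header row required")
        _require_columns(reader.fieldnames, ("chemical_id", "verhaar_class", "pnec", "unit"), path)
        for lineno, row in enumerate(reader, start=2):
            try:
                vclass = int(row["verhaar_class"])
                if vclass not in {1, 2, 3, 4, 5}:
                    raise ValidationError(f"verhaar_class out of range: {vclass}")
                conc = Concentration(float(row["pnec"]), row["unit"].strip())
                if conc.value <= 0:
                    raise ValidationError("pnec must be strictly positive")
                rows.append((row["chemical_id"].strip(), vclass, conc))
            except (ValueError, KeyError) as exc:
                errors.append(RowError(line=lineno, message=str(exc)))
    return rows, errors


_HAZARD_DOSE_FIELDS = ("noael", "adi", "tdi", "rfd", "bmd")


def read_hazard_table(path: Union[str, Path]) -> tuple[list[dict], list[RowError]]:
    """Parse a hazard table into per-chemical profile dicts.

    Columns: chemical_id, then any of noael/adi/tdi/rfd/bmd (mg/kg bw/day),
    slope_factor (per mg/kg bw/day), cancer_dw_conc + cancer_dw_unit.
    Blank cells mean "absent".
    """
    path = Path(path)
    rows: list[dict] = []
    errors: list[RowError] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file, header row required")
        _require_columns(reader.fieldnames, ("chemical_id",), path)
        for lineno, row in enumerate(reader, start=2):
            try:
                entry: dict = {"chemical_id": row["chemical_id"].strip()}
                for f in _HAZARD_DOSE_FIELDS:
                    raw = (row.get(f) or "").strip()
                    if raw:
                        entry[f] = Dose(float(raw), "mg/kg bw/day")
                sf = (row.get("slope_factor") or "").strip()
                if sf:
                    entry["oral_slope_factor"] = float(sf)
                cdw = (row.get("cancer_dw_conc") or "").strip()
                if cdw:
                    unit = (row.get("cancer_dw_unit") or "mg/L").strip()
                    entry["cancer_dw_conc"] = Concentration(float(cdw), unit)
                rows.append(entry)
            except (ValueError, KeyError) as exc:
                errors.append(RowError(line=lineno, message=str(exc)))
    return rows, errors
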