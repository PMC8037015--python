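"""Synthetic chemicals, endpoint designs, and PNEC populations.

Every generator takes an explicit seed and returns ground truth alongside
the sample so downstream estimators can be checked against analytic
values without any external dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import Concentration, ValidationError
from .ecottc import Z_05, PnecSample
from .pnec import DURATION_CLASSES, TROPHIC_GROUPS, Cell, ToxEndpointRecord

__all__ = [
    "SyntheticSpec",
    "PnecPopulation",
    "EndpointDataset",
    "gen_pnec_population",
    "gen_endpoint_records",
    "gen_chemical_table",
    "DEFAULT_CLASS_WEIGHTS",
    "DEFAULT_CRAMER_WEIGHTS",
]

# qualitative shape only: class 5 most frequent, then 1 and 3
DEFAULT_CLASS_WEIGHTS = {1: 0.20, 2: 0.07, 3: 0.15, 4: 0.08, 5: 0.50}
DEFAULT_CRAMER_WEIGHTS = {1: 0.20, 2: 0.10, 3: 0.70}

# per-Verhaar-class log10 PNEC (mg/L) location and spread
DEFAULT_LOG10_PNEC_MU = {1: -4.0, 2: -4.2, 3: -4.5, 4: -5.5, 5: -4.1}
DEFAULT_LOG10_PNEC_SIGMA = {1: 1.2, 2: 1.4, 3: 1.3, 4: 1.6, 5: 1.3}

FULL_DESIGN: dict[Cell, int] = {
    (g, d): 1 for g in TROPHIC_GROUPS for d in DURATION_CLASSES
}
ACUTE_ONLY_DESIGN: dict[Cell, int] = {(g, "acute"): 1 for g in TROPHIC_GROUPS}


def _check_weights(weights: Mapping[int, float], keys: Sequence[int], label: str) -> None:
    if set(weights) != set(keys):
        raise ValidationError(f"{label} must cover classes {tuple(keys)}")
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"{label} must sum to 1, got {total}")
    if any(w < 0 for w in weights.values()):
        raise ValidationError(f"{label} must be non-negative")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for a synthetic chemical batch."""

    n_chemicals: int = 100
    class_weights: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))
    cramer_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CRAMER_WEIGHTS)
    )
    log10_pnec_mu: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_LOG10_PNEC_MU))
    log10_pnec_sigma: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG10_PNEC_SIGMA)
    )
    endpoint_design: Mapping[Cell, int] = field(default_factory=lambda: dict(FULL_DESIGN))
    noise_sigma: float = 0.3  # lognormal within-cell spread, log10 units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chemicals < 1:
            raise ValidationError("n_chemicals must be >= 1")
        _check_weights(self.class_weights, (1, 2, 3, 4, 5), "class_weights")
        _check_weights(self.cramer_weights, (1, 2, 3), "cramer_weights")
        if not self.endpoint_design:
            raise ValidationError("endpoint_design must populate at least one cell")
        for cell, reps in self.endpoint_design.items():
            if cell[0] not in TROPHIC_GROUPS or cell[1] not in DURATION_CLASSES:
                raise ValidationError(f"invalid design cell {cell}")
            if reps < 1:
                raise ValidationError(f"replicate count must be >= 1 in cell {cell}")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if any(s <= 0 for s in self.log10_pnec_sigma.values()):
            raise ValidationError("log10_pnec_sigma values must be > 0")


@dataclass(frozen=True)
class PnecPopulation:
    """A lognormal PNEC sample with its analytic 5th percentile."""

    sample: PnecSample
    log10_mu: float
    log10_sigma: float
    analytic_p5_log10: float  # mu + z_0.05 * sigma

    @property
    def analytic_p5(self) -> Concentration:
        return Concentration(10.0**self.analytic_p5_log10, "mg/L")


def gen_pnec_population(
    log10_mu: float, log10_sigma: float, n: int, seed: int, verhaar_class: int = 1
) -> PnecPopulation:
    """Draw n PNECs with log10 values ~ Normal(mu, sigma)."""
    if n < 2:
        raise ValidationError("n must be >= 2")
    if log10_sigma < 0:
        raise ValidationError("log10_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    logs = log10_mu + log10_sigma * rng.standard_normal(n)
    sample = PnecSample(verhaar_class, tuple(10.0**logs))
    return PnecPopulation(
        sample=sample,
        log10_mu=log10_mu,
        log10_sigma=log10_sigma,
        analytic_p5_log10=log10_mu + Z_05 * log10_sigma,
    )


@dataclass(frozen=True)
class EndpointDataset:
    """Synthetic endpoint records plus the noise-free cell means."""

    records: tuple[ToxEndpointRecord, ...]
    true_cell_means: Mapping[tuple[str, Cell], float]  # (chemical_id, cell) -> mg/L


def gen_endpoint_records(
    spec: SyntheticSpec, chemical_ids: Optional[Sequence[str]] = None
) -> EndpointDataset:
    """Generate endpoint records following the spec's design.

    Each chemical gets a base sensitivity drawn from its class PNEC
    distribution; per-cell true means are offset from it (chronic cells a
    fixed factor below acute), and replicates add lognormal noise.
    """
    rng = np.random.default_rng(spec.seed)
    if chemical_ids is None:
        chemical_ids = [f"SYN-{i:05d}" for i in range(spec.n_chemicals)]

    classes = list(spec.class_weights)
    probs = np.array([spec.class_weights[c] for c in classes])

    records: list[ToxEndpointRecord] = []
    true_means: dict[tuple[str, Cell], float] = {}
    for cid in chemical_ids:
        vclass = int(rng.choice(classes, p=probs))
        base_log10 = spec.log10_pnec_mu[vclass] + spec.log10_pnec_sigma[vclass] * float(
            rng.standard_normal()
        )
        # endpoints sit well above the PNEC scale; chronic below acute
        for cell, reps in spec.endpoint_design.items():
            trophic, duration = cell
            offset = 3.0 if duration == "acute" else 2.0
            jitter = 0.2 * float(rng.standard_normal())
            cell_log10 = base_log10 + offset + jitter
            true_means[(cid, cell)] = 10.0**cell_log10
            for _ in range(reps):
                noisy = cell_log10 + spec.noise_sigma * float(rng.standard_normal())
                records.append(
                    ToxEndpointRecord(
                        chemical_id=cid,
                        trophic_group=trophic,
                        duration_class=duration,
                        value=Concentration(10.0**noisy, "mg/L"),
                        endpoint_label=f"synthetic-{duration}",
                    )
                )
    return EndpointDataset(records=tuple(records), true_cell_means=true_means)


def gen_chemical_table(spec: SyntheticSpec) -> list[dict]:
    """Synthetic chemical identity rows (placeholder SMILES tokens)."""
    rng = np.random.default_rng(spec.seed + 1)
    vclasses = list(spec.class_weights)
    vprobs = np.array([spec.class_weights[c] for c in vclasses])
    cclasses = list(spec.cramer_weights)
    cprobs = np.array([spec.cramer_weights[c] for c in cclasses])
    rows = []
    for i in range(spec.n_chemicals):
        rows.append(
            {
                "chemical_id": f"SYN-{i:05d}",
                "cas": f"{100000 + i}-00-{i % 10}",
                "name": f"synthetic compound {i}",
                "smiles": "*",
                "verhaar_class": int(rng.choice(vclasses, p=vprobs)),
                "cramer_class": int(rng.choice(cclasses, p=cprobs)),
            }
        )
    return rows
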