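"""Per-class ecological thresholds from PNEC distributions.

The class threshold is the fifth percentile of the log10-transformed PNEC
distribution, estimated three ways — empirically, by a fitted normal, and
by a fitted logistic — back-transformed, with the minimum candidate
selected as the class value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from .core import Concentration, ValidationError

__all__ = [
    "PnecSample",
    "QuantileCandidates",
    "EcoTtc",
    "FitError",
    "fifth_percentile_empirical",
    "fifth_percentile_normal",
    "fifth_percentile_logistic",
    "derive_ecottc",
]

P = 0.05
Z_05 = -1.6448536269514722  # standard normal 5th-percentile quantile
LOGIT_05 = math.log(P / (1 - P))  # = -2.9444389791664403
SMALL_SAMPLE_N = 30


class FitError(RuntimeError):
    """Raised when the logistic maximum-likelihood fit fails to converge."""


@dataclass(frozen=True)
class PnecSample:
    """PNEC values (canonical mg/L) for one Verhaar class."""

    verhaar_class: int
    values: tuple[float, ...]  # mg/L

    def __post_init__(self) -> None:
        if self.verhaar_class not in {1, 2, 3, 4, 5}:
            raise ValidationError(f"verhaar_class must be in 1..5, got {self.verhaar_class}")
        if len(self.values) < 2:
            raise ValidationError("at least 2 PNEC values are required for fitting")
        if any(v <= 0 for v in self.values):
            raise ValidationError("all PNEC values must be strictly positive")

    @classmethod
    def from_concentrations(
        cls, verhaar_class: int, concs: Iterable[Concentration]
    ) -> "PnecSample":
        return cls(verhaar_class, tuple(c.mg_per_l for c in concs))

    def log10_values(self) -> np.ndarray:
        return np.log10(np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class QuantileCandidates:
    """Three fifth-percentile estimates for one class, log10 and linear."""

    verhaar_class: int
    empirical: float  # log10 mg/L
    normal: float
    logistic: float
    n: int
    small_sample: bool

    @property
    def back_transformed(self) -> tuple[Concentration, Concentration, Concentration]:
        return (
            Concentration(10.0**self.empirical, "mg/L"),
            Concentration(10.0**self.normal, "mg/L"),
            Concentration(10.0**self.logistic, "mg/L"),
        )

    def as_dict(self) -> dict[str, float]:
        return {"empirical": self.empirical, "normal": self.normal, "logistic": self.logistic}


@dataclass(frozen=True)
class EcoTtc:
    verhaar_class: int
    value: Concentration  # mg/L
    method: str  # empirical | normal | logistic
    small_sample: bool = False


def _check_sample(log_values: Sequence[float]) -> np.ndarray:
    x = np.asarray(log_values, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite log values")
    return x


def fifth_percentile_empirical(log_values: Sequence[float]) -> float:
    """Sample 5th percentile by linear interpolation, h = (n-1)p + 1."""
    x = _check_sample(log_values)
    return float(np.quantile(x, P, method="linear"))


def fifth_percentile_normal(log_values: Sequence[float]) -> float:
    """mu + z_0.05 * sigma with maximum-likelihood estimates (sigma uses n)."""
    x = _check_sample(log_values)
    mu = float(np.mean(x))
    sigma = float(np.std(x, ddof=0))
    if sigma == 0.0:
        return mu  # degenerate
    return mu + Z_05 * sigma


def _logistic_nll(params: np.ndarray, x: np.ndarray) -> float:
    loc, log_s = params
    s = math.exp(log_s)
    z = (x - loc) / s
    # -log f = z + 2*softplus(-z) + log s, numerically stable softplus
    return float(np.sum(z + 2.0 * np.logaddexp(0.0, -z)) + x.size * log_s)


def fifth_percentile_logistic(log_values: Sequence[float]) -> float:
    """loc + s*ln(0.05/0.95) with (loc, s) fitted by maximum likelihood.

    The optimiser works on (loc, log s), started at the moment-matched
    point (median, sqrt(3)*sd/pi).
    """
    x = _check_sample(log_values)
    sd = float(np.std(x, ddof=0))
    if sd == 0.0:
        return float(x[0])  # degenerate
    s0 = math.sqrt(3.0) * sd / math.pi
    start = np.array([float(np.median(x)), math.log(s0)])
    res = minimize(
        _logistic_nll,
        start,
        args=(x,),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-8, "maxiter": 10_000},
    )
    if not res.success:
        raise FitError(f"logistic MLE failed to converge: {res.message}")
    loc, log_s = res.x
    return float(loc + math.exp(log_s) * LOGIT_05)


def derive_ecottc(sample: PnecSample) -> tuple[QuantileCandidates, EcoTtc]:
    """Compute the three candidates and select the class threshold.

    The class value is the minimum back-transformed candidate; ties are
    broken in the order empirical, normal, logistic.
    """
    x = sample.log10_values()
    cands = QuantileCandidates(
        verhaar_class=sample.verhaar_class,
        empirical=fifth_percentile_empirical(x),
        normal=fifth_percentile_normal(x),
        logistic=fifth_percentile_logistic(x),
        n=x.size,
        small_sample=x.size < SMALL_SAMPLE_N,
    )
    return cands, select_minimum(cands)


def select_minimum(cands: QuantileCandidates) -> EcoTtc:
    """Pick the lowest candidate; tie-break empirical > normal > logistic."""
    ordered = [
        ("empirical", cands.empirical),
        ("normal", cands.normal),
        ("logistic", cands.logistic),
    ]
    method, log_value = min(ordered, key=lambda mv: mv[1])
    return EcoTtc(
        verhaar_class=cands.verhaar_class,
        value=Concentration(10.0**log_value, "mg/L"),
        method=method,
        small_sample=cands.small_sample,
    )
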