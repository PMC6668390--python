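"""Instrument precision, detection limits, and method detection limits.

The detection limit of a measured quantity is DL = t(n-1, one-sided
0.95) x SD, with SD the between-batch standard deviation of repeated
reference-gas analyses.  The method detection limit (MDL) propagates a
ratio or concentration DL through the mixing model and the chamber
ideal-gas conversion to a minimum detectable flux in g N ha⁻¹ day⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import constants as c
from .errors import DomainError, InsufficientDataError
from .fluxes import ChamberGeometry, flux_from_slope

__all__ = [
    "ReferenceStats",
    "reference_sd",
    "t_value",
    "detection_limit",
    "mdl_n2_flux",
    "mdl_n2o_flux",
]


@dataclass(frozen=True)
class ReferenceStats:
    """Precision summary for one reference quantity.

    ``ratio_name`` is one of R29/R30/R45/R46/C_N2O; ``sd`` and ``dl``
    share units (dimensionless for ratios, mol fraction for C_N2O).
    """

    ratio_name: str
    n: int
    sd: float
    dl: float

    def __post_init__(self):
        if self.ratio_name not in ("R29", "R30", "R45", "R46", "C_N2O"):
            raise DomainError(f"unknown reference quantity {self.ratio_name!r}")
        if self.n < 2:
            raise DomainError("reference statistics require n >= 2")
        if self.sd < 0:
            raise DomainError("standard deviation must be non-negative")

    @classmethod
    def from_values(cls, ratio_name: str, values) -> "ReferenceStats":
        values = np.asarray(values, dtype=float)
        sd = reference_sd(values)
        return cls(ratio_name, int(values.size), sd, detection_limit(sd, values.size))


def reference_sd(values) -> float:
    """Sample standard deviation (n-1 denominator) of reference analyses."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError(
            f"need at least 2 reference analyses, got {values.size}"
        )
    return float(np.std(values, ddof=1))


def t_value(n: int, confidence: float = c.CONFIDENCE_LEVEL) -> float:
    """One-sided Student's t quantile at ``confidence``, n-1 df."""
    if n < 2:
        raise DomainError(f"t value requires n >= 2, got {n}")
    if not 0.0 < confidence < 1.0:
        raise DomainError("confidence must lie in (0, 1)")
    return float(stats.t.ppf(confidence, n - 1))


def detection_limit(sd: float, n: int, confidence: float = c.CONFIDENCE_LEVEL) -> float:
    """DL = t(n-1, one-sided ``confidence``) x SD."""
    if sd < 0:
        raise DomainError("standard deviation must be non-negative")
    return t_value(n, confidence) * sd


def mdl_n2_flux(
    dl_30r: float,
    a_pool: float = 0.5,
    geometry: ChamberGeometry | None = None,
    temperature_k: float = c.DEFAULT_TEMPERATURE_K,
    pressure_pa: float = c.DEFAULT_PRESSURE_PA,
    closure_minutes: float = c.SAMPLING_WINDOW_MIN,
) -> float:
    """Minimum detectable N2 flux from the 30R detection limit.

    The smallest resolvable pool-derived fraction is d_min = DL(30R) /
    a_pool²; times the 0.78084 atmospheric N2 mol fraction this is the
    smallest detectable headspace mol-fraction excess, accumulated over
    one closure and converted with the ideal-gas chamber factor.
    """
    if not 0.0 < a_pool <= 1.0:
        raise DomainError(f"pool enrichment must lie in (0, 1], got {a_pool}")
    if dl_30r < 0:
        raise DomainError("detection limit must be non-negative")
    if closure_minutes <= 0:
        raise DomainError("closure time must be positive")
    d_min = dl_30r / (a_pool * a_pool)
    slope = d_min * c.N2_AIR_FRACTION / closure_minutes
    return flux_from_slope(slope, geometry, temperature_k, pressure_pa)


def mdl_n2o_flux(
    dl_conc: float,
    geometry: ChamberGeometry | None = None,
    temperature_k: float = c.DEFAULT_TEMPERATURE_K,
    pressure_pa: float = c.DEFAULT_PRESSURE_PA,
    closure_minutes: float = c.SAMPLING_WINDOW_MIN,
) -> float:
    """Minimum detectable N2O flux from the concentration DL (mol fraction)."""
    if dl_conc < 0:
        raise DomainError("detection limit must be non-negative")
    if closure_minutes <= 0:
        raise DomainError("closure time must be positive")
    return flux_from_slope(
        dl_conc / closure_minutes, geometry, temperature_k, pressure_pa
    )
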