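"""Isotopologue arithmetic for the 15N gas-flux method.

The method applies highly 15N-enriched nitrate to soil and detects
denitrification-derived N2 and N2O in a closed chamber headspace as an
excess of heavy isotopologues over the atmospheric background.  Both
gases carry two N atoms, so a single source pool with atom fraction
``a`` of 15N produces its molecules in binomial (random-pairing)
proportions::

    f_light : f_mid : f_heavy = (1-a)^2 : 2a(1-a) : a^2

The headspace is modelled as a two-component mixture of background gas
and pool-derived gas, with ``d`` the mol fraction of the gas species
that is pool derived.  This module provides the forward model
(fractions, mixing, ion-current ratios) and its inversion from the
background-subtracted ratio excesses (Δ-ratios) back to the pool
enrichment — ``aD`` when measured on the N2O isotopologues (45R/46R),
``XN15`` when measured on the N2 isotopologues (29R/30R) — and to the
pool-derived fraction ``d``.

For N2O the measured 45R/46R ratios also carry 17O/18O contributions.
Because the oxygen isotope distribution is identical in background and
pool-derived N2O and independent of the N isotopes, those contributions
cancel exactly under background subtraction up to a closed-form
cross-term; :func:`oxygen_corrected_deltas` and
:func:`nitrogen_ratio_pair` reduce the N2O path to the same diatomic
binomial problem as the N2 path.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from .constants import NAT_15N, NAT_17O, NAT_18O
from .errors import (
    BelowDetectionError,
    DomainError,
    InconsistentInputError,
    InvalidRecordError,
)

__all__ = [
    "GasPath",
    "IonCurrentRecord",
    "RatioPair",
    "DeltaRatios",
    "IsotopologueFractions",
    "PoolEstimate",
    "ratios_from_currents",
    "fractions_from_atom_fraction",
    "fractions_from_ratio_pair",
    "ratio_pair_from_fractions",
    "natural_ratio_pair",
    "mix_pools",
    "delta_ratios",
    "oxygen_corrected_deltas",
    "nitrogen_ratio_pair",
    "estimate_pool_enrichment",
    "estimate_pool_fraction",
    "invert_mixing",
    "n2o_isotopologue_fractions",
    "n2o_mixture_fractions",
    "n2o_heavy_fraction",
]


class GasPath(str, Enum):
    """Analytical path of an injection.

    ``N2`` measures m/z 28/29/30 (N2, plus N2O reduced to N2 upstream);
    ``N2O`` measures m/z 44/45/46.
    """

    N2 = "N2"
    N2O = "N2O"


@dataclass(frozen=True)
class IonCurrentRecord:
    """One IRMS injection: three ion currents in consistent arbitrary units.

    ``time_min`` is minutes since closure start; ``None`` for reference
    injections, which are not tied to a chamber closure.
    """

    source_id: str
    path: GasPath
    i_light: float
    i_mid: float
    i_heavy: float
    time_min: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "path", GasPath(self.path))
        if self.i_mid < 0 or self.i_heavy < 0:
            raise InvalidRecordError(
                f"negative ion current in record from {self.source_id!r}"
            )


@dataclass(frozen=True)
class RatioPair:
    """Heavy-to-light ion-current ratios (29R/30R or 45R/46R)."""

    r_mid: float
    r_heavy: float

    def __post_init__(self):
        if self.r_mid < 0 or self.r_heavy < 0:
            raise DomainError("isotopologue ratios must be non-negative")


@dataclass(frozen=True)
class DeltaRatios:
    """Background-subtracted ratio excesses (Δ29R/Δ30R or Δ45R/Δ46R).

    May be negative at noise level; estimators raise
    :class:`~n15flux.errors.BelowDetectionError` in that case.
    """

    delta_mid: float
    delta_heavy: float

    def __post_init__(self):
        if not (np.isfinite(self.delta_mid) and np.isfinite(self.delta_heavy)):
            raise DomainError("delta ratios must be finite")


@dataclass(frozen=True)
class IsotopologueFractions:
    """Molecular fractions of the (light, mid, heavy) isotopologues."""

    f_light: float
    f_mid: float
    f_heavy: float

    def __post_init__(self):
        for f in (self.f_light, self.f_mid, self.f_heavy):
            if not 0.0 <= f <= 1.0:
                raise DomainError("isotopologue fractions must lie in [0, 1]")
        if abs(self.f_light + self.f_mid + self.f_heavy - 1.0) > 1e-12:
            raise DomainError("isotopologue fractions must sum to 1")


@dataclass(frozen=True)
class PoolEstimate:
    """Pool enrichment and pool-derived fraction inferred for one gas.

    ``basis`` records which isotopologue system produced the estimate:
    aD from N2O (45/46) or XN15 from N2 (29/30).
    """

    a_pool: float
    d: float
    basis: str  # "N2O_4546" or "N2_2930"

    def __post_init__(self):
        if not 0.0 <= self.a_pool <= 1.0:
            raise DomainError("pool enrichment must lie in [0, 1]")
        if not 0.0 <= self.d <= 1.0:
            raise DomainError("pool-derived fraction must lie in [0, 1]")
        if self.basis not in ("N2O_4546", "N2_2930"):
            raise DomainError(f"unknown estimate basis {self.basis!r}")


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def ratios_from_currents(rec: IonCurrentRecord) -> RatioPair:
    """Molecular ratios R_mid = I_mid/I_light and R_heavy = I_heavy/I_light."""
    if rec.i_light <= 0:
        raise InvalidRecordError(
            f"non-positive major-beam current in record from {rec.source_id!r}"
        )
    return RatioPair(rec.i_mid / rec.i_light, rec.i_heavy / rec.i_light)


def fractions_from_atom_fraction(a: float) -> IsotopologueFractions:
    """Binomial isotope pairing of a single pool at 15N atom fraction ``a``."""
    if not 0.0 <= a <= 1.0:
        raise DomainError(f"atom fraction must lie in [0, 1], got {a}")
    return IsotopologueFractions((1.0 - a) ** 2, 2.0 * a * (1.0 - a), a * a)


def fractions_from_ratio_pair(rp: RatioPair) -> IsotopologueFractions:
    """Convert (R_mid, R_heavy) to normalized molecular fractions."""
    f_light = 1.0 / (1.0 + rp.r_mid + rp.r_heavy)
    return IsotopologueFractions(f_light, rp.r_mid * f_light, rp.r_heavy * f_light)


def ratio_pair_from_fractions(f: IsotopologueFractions) -> RatioPair:
    if f.f_light <= 0:
        raise DomainError("cannot form ratios: light-isotopologue fraction is 0")
    return RatioPair(f.f_mid / f.f_light, f.f_heavy / f.f_light)


def natural_ratio_pair(a: float = NAT_15N) -> RatioPair:
    """Binomial (R_mid, R_heavy) of an unenriched diatomic-N gas."""
    return ratio_pair_from_fractions(fractions_from_atom_fraction(a))


def mix_pools(
    bg: IsotopologueFractions, pool: IsotopologueFractions, d: float
) -> IsotopologueFractions:
    """Two-source mixture: fraction ``d`` pool-derived, ``1-d`` background."""
    if not 0.0 <= d <= 1.0:
        raise DomainError(f"mixing fraction must lie in [0, 1], got {d}")
    return IsotopologueFractions(
        (1.0 - d) * bg.f_light + d * pool.f_light,
        (1.0 - d) * bg.f_mid + d * pool.f_mid,
        (1.0 - d) * bg.f_heavy + d * pool.f_heavy,
    )


def delta_ratios(sample: RatioPair, background: RatioPair) -> DeltaRatios:
    """Component-wise ratio excess of a sample over the ambient background."""
    return DeltaRatios(
        sample.r_mid - background.r_mid, sample.r_heavy - background.r_heavy
    )


# ---------------------------------------------------------------------------
# Oxygen-isotope handling for the N2O path
# ---------------------------------------------------------------------------
#
# Writing fN0/fN1/fN2 for the N-pair fractions and (p16, p17, p18) for the
# oxygen abundances, the measured N2O ratios are
#     45R = fN1/fN0 + p17/p16
#     46R = fN2/fN0 + (p17/p16) * (fN1/fN0) + p18/p16
# so Δ45R equals the nitrogen-only Δ(fN1/fN0) exactly, and the oxygen
# cross-term in Δ46R is (p17/p16)·Δ45R.


def oxygen_corrected_deltas(
    deltas: DeltaRatios, a17: float = NAT_17O, a18: float = NAT_18O
) -> DeltaRatios:
    """Remove the 17O cross-term from Δ46R, giving nitrogen-only deltas."""
    cross = a17 / (1.0 - a17 - a18)
    return DeltaRatios(deltas.delta_mid, deltas.delta_heavy - cross * deltas.delta_mid)


def nitrogen_ratio_pair(
    rp: RatioPair, a17: float = NAT_17O, a18: float = NAT_18O
) -> RatioPair:
    """Strip oxygen-isotope contributions from measured N2O (45R, 46R)."""
    cross = a17 / (1.0 - a17 - a18)
    r_mid_n = rp.r_mid - cross
    r_heavy_n = rp.r_heavy - cross * r_mid_n - a18 / (1.0 - a17 - a18)
    return RatioPair(max(r_mid_n, 0.0), max(r_heavy_n, 0.0))


# ---------------------------------------------------------------------------
# Inversion
# ---------------------------------------------------------------------------

def estimate_pool_enrichment(
    deltas: DeltaRatios, background_enrichment: float = NAT_15N
) -> float:
    """Pool 15N atom fraction from the Δ-ratio ratio x = Δheavy/Δmid.

    With an unlabelled background (``background_enrichment=0``) this is
    the classical closed form a = 2x/(1+2x).  With a background at atom
    fraction ``ab`` the corrected form

        a = (2x(1-ab) - ab) / (1 - 2ab + 2x(1-ab))

    is exact for any mixing fraction d, because both deltas share the
    same mixture denominator and the d-dependence cancels from x.

    Raises
    ------
    BelowDetectionError
        If either delta is non-positive (signal not above background) or
        the implied enrichment does not exceed the background.
    """
    if deltas.delta_mid <= 0 or deltas.delta_heavy <= 0:
        raise BelowDetectionError(
            "delta ratios at or below background; flag the closure instead of "
            "estimating enrichment"
        )
    ab = background_enrichment
    if not 0.0 <= ab < 1.0:
        raise DomainError(f"background enrichment must lie in [0, 1), got {ab}")
    x = deltas.delta_heavy / deltas.delta_mid
    a = (2.0 * x * (1.0 - ab) - ab) / (1.0 - 2.0 * ab + 2.0 * x * (1.0 - ab))
    if a <= 0.0:
        raise BelowDetectionError(
            "implied pool enrichment does not exceed the background"
        )
    if a >= 1.0:
        raise InconsistentInputError(
            f"implied pool enrichment {a:.4f} outside (0, 1)"
        )
    return a


def estimate_pool_fraction(
    deltas: DeltaRatios,
    a_pool: float,
    background: RatioPair | None = None,
    method: str = "simple",
    tol: float = 1e-9,
) -> float:
    """Fraction d of the gas species derived from the labelled pool.

    ``method="simple"`` uses d = Δheavy / a_pool²; ``method="exact"``
    solves the two-component mixing model for d given the background
    ratio pair (required).  The returned d may be slightly negative when
    the delta is negative at noise level — regression over a closure
    series stays unbiased that way.  Values above ``1 + tol`` raise;
    within the tolerance they are clipped to 1 (series processing sets a
    noise-sized tolerance because a true d near 1 can overshoot).
    """
    if not 0.0 < a_pool <= 1.0:
        raise DomainError(f"pool enrichment must lie in (0, 1], got {a_pool}")
    if method == "simple":
        d = deltas.delta_heavy / (a_pool * a_pool)
    elif method == "exact":
        if background is None:
            raise DomainError("exact pool-fraction estimate requires a background")
        bg = fractions_from_ratio_pair(background)
        rho = background.r_heavy + deltas.delta_heavy
        denom = (a_pool * a_pool - bg.f_heavy) - rho * (
            (1.0 - a_pool) ** 2 - bg.f_light
        )
        if denom == 0:
            raise InconsistentInputError("mixing model degenerate for these inputs")
        d = (rho * bg.f_light - bg.f_heavy) / denom
    else:
        raise DomainError(f"unknown method {method!r}")
    if d > 1.0 + tol:
        raise InconsistentInputError(
            f"implied pool-derived fraction {d:.4f} exceeds 1"
        )
    return min(d, 1.0)


def invert_mixing(deltas: DeltaRatios, background: RatioPair) -> tuple[float, float]:
    """Exact numerical inversion of the mixing model to (a_pool, d).

    Eliminates d via the heavy-isotopologue equation and solves the
    remaining one-dimensional equation in ``a`` by bracketing + Brent's
    method.  Serves as the exact counterpart of the closed-form
    estimators; the two agree to numerical precision on model-consistent
    inputs.
    """
    if deltas.delta_mid <= 0 or deltas.delta_heavy <= 0:
        raise BelowDetectionError("delta ratios at or below background")
    bg = fractions_from_ratio_pair(background)
    rho_h = background.r_heavy + deltas.delta_heavy
    rho_m = background.r_mid + deltas.delta_mid

    def d_of_a(a: float) -> float:
        denom = (a * a - bg.f_heavy) - rho_h * ((1.0 - a) ** 2 - bg.f_light)
        if denom == 0:
            return np.nan
        return (rho_h * bg.f_light - bg.f_heavy) / denom

    def residual(a: float) -> float:
        d = d_of_a(a)
        if not np.isfinite(d) or not 0.0 <= d <= 1.0:
            return np.nan
        f_light = (1.0 - d) * bg.f_light + d * (1.0 - a) ** 2
        f_mid = (1.0 - d) * bg.f_mid + d * 2.0 * a * (1.0 - a)
        return f_mid / f_light - rho_m

    grid = np.linspace(1e-6, 1.0 - 1e-6, 4001)
    res = np.array([residual(a) for a in grid])
    ok = np.isfinite(res)
    sign_change = np.where(ok[:-1] & ok[1:] & (res[:-1] * res[1:] <= 0))[0]
    if sign_change.size == 0:
        raise InconsistentInputError(
            "no mixing-model solution with 0 <= d <= 1 for these deltas"
        )
    i = sign_change[0]
    if res[i] == 0.0:
        a = float(grid[i])
    else:
        a = float(brentq(residual, grid[i], grid[i + 1], xtol=1e-15, rtol=1e-15))
    d = float(d_of_a(a))
    if not 0.0 <= d <= 1.0 + 1e-9:
        raise InconsistentInputError(f"inverted pool-derived fraction {d} invalid")
    return a, min(d, 1.0)


# ---------------------------------------------------------------------------
# Full N2O isotopologue distribution (masses 44-48)
# ---------------------------------------------------------------------------

def n2o_isotopologue_fractions(
    a15: float, a17: float = NAT_17O, a18: float = NAT_18O
) -> np.ndarray:
    """Molecular fractions of N2O at masses 44..48.

    Binomial in the two N positions at atom fraction ``a15``, single O
    at (16O, 17O, 18O) = (1-a17-a18, a17, a18).  Mass excess over 44 is
    the 15N count plus the O mass excess.
    """
    if not 0.0 <= a15 <= 1.0:
        raise DomainError(f"atom fraction must lie in [0, 1], got {a15}")
    p_n = ((1.0 - a15) ** 2, 2.0 * a15 * (1.0 - a15), a15 * a15)
    p_o = (1.0 - a17 - a18, a17, a18)
    f = np.zeros(5)
    for i, pn in enumerate(p_n):
        for j, po in enumerate(p_o):
            f[i + j] += pn * po
    return f


def n2o_mixture_fractions(
    a_pool: float,
    d: float,
    a_background: float = NAT_15N,
    a17: float = NAT_17O,
    a18: float = NAT_18O,
) -> np.ndarray:
    """Mass-44..48 fractions of a background/pool N2O mixture."""
    if not 0.0 <= d <= 1.0:
        raise DomainError(f"mixing fraction must lie in [0, 1], got {d}")
    return (1.0 - d) * n2o_isotopologue_fractions(a_background, a17, a18) + (
        d * n2o_isotopologue_fractions(a_pool, a17, a18)
    )


def n2o_heavy_fraction(fractions: np.ndarray) -> float:
    """Fraction of N2O molecules at masses 47 and 48 (not ion-monitored)."""
    return float(fractions[3] + fractions[4])
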