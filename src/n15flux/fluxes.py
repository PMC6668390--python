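"""Per-closure flux computation for static-chamber IRMS measurements.

One chamber closure yields four timed injections per analytical path.
This module turns them into: an N2O concentration series calibrated
against the 1 ppm reference standard, a pool-derived mol-fraction
series from the isotopologue excesses, an ordinary-least-squares slope
with an r² linearity check, and an ideal-gas conversion of the slope to
an area-scaled flux in g N ha⁻¹ day⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import constants as c
from .errors import (
    BelowDetectionError,
    DegenerateDesignError,
    DomainError,
    InsufficientDataError,
    InvalidRecordError,
    InvalidReferenceError,
)
from .isotope import (
    GasPath,
    IonCurrentRecord,
    RatioPair,
    delta_ratios,
    estimate_pool_enrichment,
    estimate_pool_fraction,
    invert_mixing,
    n2o_heavy_fraction,
    n2o_isotopologue_fractions,
    n2o_mixture_fractions,
    nitrogen_ratio_pair,
    oxygen_corrected_deltas,
    ratios_from_currents,
)

__all__ = [
    "ChamberGeometry",
    "ClosureSeries",
    "FluxResult",
    "QC_ACCEPTED",
    "QC_DISCARDED",
    "QC_BELOW_DETECTION",
    "n2o_concentration",
    "pool_derived_series",
    "fit_closure_slope",
    "qc_filter",
    "flux_from_slope",
    "closure_flux",
    "n2_flux",
]

QC_ACCEPTED = "accepted"
QC_DISCARDED = "discarded_low_r2"
QC_BELOW_DETECTION = "below_detection"


@dataclass(frozen=True)
class ChamberGeometry:
    """Static chamber headspace geometry (default 0.25 m² x 0.15 m)."""

    basal_area_m2: float = c.CHAMBER_AREA_M2
    height_m: float = c.CHAMBER_HEIGHT_M

    def __post_init__(self):
        if self.basal_area_m2 <= 0 or self.height_m <= 0:
            raise DomainError("chamber area and height must be positive")

    @property
    def headspace_volume_m3(self) -> float:
        return self.basal_area_m2 * self.height_m


@dataclass
class ClosureSeries:
    """Timed values for one chamber closure plus ambient state.

    ``values`` are mol fractions: measured gas concentration (N2O path)
    or pool-derived mol fraction d(t) x gas abundance (either path).
    """

    chamber_id: str
    gas: str  # "N2O" or "N2_plus_N2O"
    times_min: np.ndarray
    values: np.ndarray
    temperature_k: float = c.DEFAULT_TEMPERATURE_K
    pressure_pa: float = c.DEFAULT_PRESSURE_PA
    geometry: ChamberGeometry = field(default_factory=ChamberGeometry)
    # diagnostics populated by pool_derived_series
    a_pool: float | None = None
    a_basis: str | None = None
    d_values: np.ndarray | None = None
    final_delta_heavy: float | None = None
    n_dropped: int = 0
    below_detection: bool = False

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_min.size != self.values.size:
            raise DomainError("times and values must have equal length")
        if self.times_min.size and np.any(np.diff(self.times_min) <= 0):
            raise DomainError("closure sample times must be strictly increasing")
        if self.times_min.size and (
            self.times_min.max() - self.times_min.min() > c.CLOSURE_MINUTES
        ):
            raise DomainError(
                f"sample span exceeds the {c.CLOSURE_MINUTES} min closure window"
            )


@dataclass
class FluxResult:
    """Regression outcome and flux for one closure and gas.

    ``flux_g_n_ha_day`` is NaN for discarded closures; below-detection
    closures keep their numeric value but must not be interpreted as a
    resolved emission.
    """

    chamber_id: str
    gas: str
    slope: float
    intercept: float
    r2: float
    flux_g_n_ha_day: float
    qc: str
    a_pool: float | None = None
    a_basis: str | None = None
    d_mean: float | None = None


# ---------------------------------------------------------------------------
# Concentration against the 1 ppm reference
# ---------------------------------------------------------------------------

def n2o_concentration(
    sample: IonCurrentRecord,
    reference: IonCurrentRecord | float,
    ref_conc: float = c.N2O_STANDARD,
    sample_a: float = c.NAT_15N,
    sample_d: float | None = None,
) -> float:
    """N2O mol fraction of a sample against the reference standard.

    The IRMS monitors masses 44-46 only, so the summed currents miss the
    mass-47/48 isotopologues.  Both sums are rescaled by 1/(1 - f47 -
    f48) with f47/f48 computed from the full isotopologue distribution:
    binomial 15N at ``sample_a`` (mixed with natural background at
    fraction ``sample_d`` when given) and natural 17O/18O.  The
    reference is assumed to be at natural abundance.  ``reference`` may
    be a record or a pre-computed corrected current sum.
    """
    s_sum = sample.i_light + sample.i_mid + sample.i_heavy
    if s_sum <= 0:
        raise InvalidRecordError(
            f"non-positive summed currents in sample {sample.source_id!r}"
        )
    h_ref = n2o_heavy_fraction(n2o_isotopologue_fractions(c.NAT_15N))
    if isinstance(reference, IonCurrentRecord):
        r_sum = reference.i_light + reference.i_mid + reference.i_heavy
        if r_sum <= 0:
            raise InvalidReferenceError(
                f"reference {reference.source_id!r} has no signal"
            )
        ref_corrected = r_sum / (1.0 - h_ref)
    else:
        ref_corrected = float(reference)
        if ref_corrected <= 0:
            raise InvalidReferenceError("reference current sum must be positive")
    if sample_d is None:
        f_sample = n2o_isotopologue_fractions(sample_a)
    else:
        f_sample = n2o_mixture_fractions(sample_a, sample_d)
    h_sample = n2o_heavy_fraction(f_sample)
    return ref_conc * (s_sum / (1.0 - h_sample)) / ref_corrected


# ---------------------------------------------------------------------------
# Pool-derived series
# ---------------------------------------------------------------------------

def pool_derived_series(
    records: list[IonCurrentRecord],
    background: RatioPair,
    total_gas_fraction,
    a_pool: float | None = None,
    estimator: str = "closed_form",
    temperature_k: float = c.DEFAULT_TEMPERATURE_K,
    pressure_pa: float = c.DEFAULT_PRESSURE_PA,
    geometry: ChamberGeometry | None = None,
    min_delta: tuple[float, float] = (0.0, 0.0),
    d_tol: float = 0.5,
) -> ClosureSeries:
    """Pool-derived mol-fraction series for one closure.

    Per timepoint the Δ-ratios against ``background`` give a pool
    enrichment estimate (where both deltas are positive) and a
    pool-derived fraction d(t); the series value is d(t) times
    ``total_gas_fraction`` (scalar 0.78084 for the N2 path, or the
    per-timepoint measured N2O concentration).  The closure enrichment
    is the unweighted mean of per-timepoint estimates unless ``a_pool``
    is supplied (the N2 path conventionally reuses aD from the N2O
    path of the same closure).

    ``estimator``: ``"closed_form"`` (background-corrected closed form)
    or ``"exact"`` (numerical inversion of the mixing model).
    Timepoints whose deltas do not exceed ``min_delta`` (detection
    limits for the mid and heavy ratio) are excluded from the
    enrichment mean — a weak-signal timepoint yields an arbitrarily
    noisy delta ratio x.  ``d_tol`` is the allowed noise overshoot of
    d above 1 before the closure is declared inconsistent.
    """
    if not records:
        raise InsufficientDataError("no records for closure")
    path = records[0].path
    chamber = records[0].source_id
    if any(r.path != path or r.source_id != chamber for r in records):
        raise DomainError("closure records must share one chamber and path")
    if estimator not in ("closed_form", "exact"):
        raise DomainError(f"unknown estimator {estimator!r}")

    if path == GasPath.N2O:
        bg_n = nitrogen_ratio_pair(background)
    else:
        bg_n = background
    a_bg = bg_n.r_mid / (2.0 + bg_n.r_mid)  # invert R_mid = 2a/(1-a)

    times, deltas_n, dropped = [], [], 0
    for rec in sorted(records, key=lambda r: (r.time_min is None, r.time_min)):
        if rec.time_min is None:
            dropped += 1
            continue
        try:
            rp = ratios_from_currents(rec)
        except InvalidRecordError:
            dropped += 1
            continue
        dd = delta_ratios(rp, background)
        if path == GasPath.N2O:
            dd = oxygen_corrected_deltas(dd)
        times.append(float(rec.time_min))
        deltas_n.append(dd)
    if len(times) < 2:
        raise InsufficientDataError(
            f"closure for {chamber!r} has fewer than 2 usable timepoints"
        )

    # Closure-level pool enrichment
    a_estimates = []
    for dd in deltas_n:
        if dd.delta_mid <= min_delta[0] or dd.delta_heavy <= min_delta[1]:
            continue
        try:
            if estimator == "exact":
                a_i, _ = invert_mixing(dd, bg_n)
            else:
                a_i = estimate_pool_enrichment(dd, background_enrichment=a_bg)
        except BelowDetectionError:
            continue
        a_estimates.append(a_i)
    if a_pool is not None:
        a_closure, basis = float(a_pool), "external"
    elif a_estimates:
        a_closure = float(np.mean(a_estimates))
        basis = "N2O_4546" if path == GasPath.N2O else "N2_2930"
    else:
        a_closure, basis = None, None

    below = a_closure is None
    gas_frac = np.broadcast_to(
        np.asarray(total_gas_fraction, dtype=float), (len(times),)
    )
    if below:
        values = np.zeros(len(times))
        d_vals = np.zeros(len(times))
    else:
        # the simple d = Δheavy/a² form is a trace-signal approximation;
        # series can reach d ~ 0.9 on the N2O path, so always solve the
        # mixing model (closed form in d given a)
        method = "exact"
        d_vals = np.array(
            [
                estimate_pool_fraction(
                    dd, a_closure, background=bg_n, method=method, tol=d_tol
                )
                for dd in deltas_n
            ]
        )
        values = d_vals * gas_frac

    return ClosureSeries(
        chamber_id=chamber,
        gas="N2O" if path == GasPath.N2O else "N2_plus_N2O",
        times_min=np.array(times),
        values=values,
        temperature_k=temperature_k,
        pressure_pa=pressure_pa,
        geometry=geometry or ChamberGeometry(),
        a_pool=a_closure,
        a_basis=basis,
        d_values=d_vals,
        final_delta_heavy=deltas_n[-1].delta_heavy,
        n_dropped=dropped,
        below_detection=below,
    )


# ---------------------------------------------------------------------------
# Regression, QC and unit conversion
# ---------------------------------------------------------------------------

def fit_closure_slope(times_min, values) -> tuple[float, float, float]:
    """OLS with intercept; returns (slope, intercept, r²).

    r² is the squared Pearson correlation, defined as 0 for a
    zero-variance response (a flat series carries no linearity
    evidence either way).
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2:
        raise InsufficientDataError("need at least 2 points for a slope")
    if np.ptp(t) == 0:
        raise DegenerateDesignError("all sample times identical")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    fit = stats.linregress(t, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def qc_filter(r2: float, threshold: float = c.R2_THRESHOLD) -> str:
    """Linearity check: accepted iff r² >= threshold (boundary inclusive)."""
    if not 0.0 <= r2 <= 1.0 + 1e-12:
        raise DomainError(f"r² must lie in [0, 1], got {r2}")
    return QC_ACCEPTED if r2 >= threshold else QC_DISCARDED


def flux_from_slope(
    slope_per_min: float,
    geometry: ChamberGeometry | None = None,
    temperature_k: float = c.DEFAULT_TEMPERATURE_K,
    pressure_pa: float = c.DEFAULT_PRESSURE_PA,
) -> float:
    """Convert a mol-fraction slope (min⁻¹) to g N ha⁻¹ day⁻¹.

    Ideal-gas moles in the headspace PV/RT times the slope gives mol of
    gas accumulating per minute; 28.014 g N per mol (two N atoms in both
    N2 and N2O), scaled by inverse basal area to hectares and by 1440 to
    a day.
    """
    geometry = geometry or ChamberGeometry()
    if temperature_k <= 0 or pressure_pa <= 0:
        raise DomainError("temperature and pressure must be positive")
    mol_air = pressure_pa * geometry.headspace_volume_m3 / (c.R_GAS * temperature_k)
    return (
        slope_per_min
        * mol_air
        * c.GRAMS_N_PER_MOL
        / geometry.basal_area_m2
        * c.M2_PER_HA
        * c.MIN_PER_DAY
    )


def closure_flux(
    series: ClosureSeries,
    r2_threshold: float = c.R2_THRESHOLD,
    detection_delta: tuple[float, float] | None = None,
) -> FluxResult:
    """Fit a closure series and apply QC.

    ``detection_delta`` is an optional (observed, limit) pair — e.g. the
    final-timepoint Δ30R against DL(30R), or the closure concentration
    increase against the concentration DL.  Detection is judged before
    linearity: a closure with no signal above the limit is
    below-detection, not "non-linear".
    """
    below = series.below_detection
    if detection_delta is not None:
        observed, limit = detection_delta
        below = below or observed <= limit
    slope, intercept, r2 = fit_closure_slope(series.times_min, series.values)
    flux = flux_from_slope(
        slope, series.geometry, series.temperature_k, series.pressure_pa
    )
    if below:
        qc = QC_BELOW_DETECTION
    else:
        qc = qc_filter(r2, r2_threshold)
        if qc == QC_DISCARDED:
            flux = float("nan")
    d_mean = None
    if series.d_values is not None and series.d_values.size:
        d_mean = float(np.mean(series.d_values[series.d_values > 0])) if np.any(
            series.d_values > 0
        ) else 0.0
    return FluxResult(
        chamber_id=series.chamber_id,
        gas=series.gas,
        slope=slope,
        intercept=intercept,
        r2=r2,
        flux_g_n_ha_day=flux,
        qc=qc,
        a_pool=series.a_pool,
        a_basis=series.a_basis,
        d_mean=d_mean,
    )


def n2_flux(
    flux_total: FluxResult, flux_n2o: FluxResult, mdl: float = 0.0
) -> FluxResult:
    """N2 flux as the difference of the N2+N2O and N2O fluxes.

    Either input discarded propagates a discard; a total-path closure
    below detection keeps N2 below detection.  Differences at or below
    ``mdl`` (default 0) are flagged below detection rather than
    reported as resolved negative emissions.
    """
    if QC_DISCARDED in (flux_total.qc, flux_n2o.qc):
        qc, flux = QC_DISCARDED, float("nan")
    elif flux_total.qc == QC_BELOW_DETECTION:
        qc, flux = QC_BELOW_DETECTION, flux_total.flux_g_n_ha_day - (
            flux_n2o.flux_g_n_ha_day
        )
    else:
        flux = flux_total.flux_g_n_ha_day - flux_n2o.flux_g_n_ha_day
        qc = QC_ACCEPTED if flux > mdl else QC_BELOW_DETECTION
    return FluxResult(
        chamber_id=flux_total.chamber_id,
        gas="N2",
        slope=float("nan"),
        intercept=float("nan"),
        r2=min(flux_total.r2, flux_n2o.r2),
        flux_g_n_ha_day=flux,
        qc=qc,
        a_pool=flux_total.a_pool,
        a_basis=flux_total.a_basis,
        d_mean=flux_total.d_mean,
    )
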