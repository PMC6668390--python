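"""End-to-end processing: injection stream -> flux table -> summary.

The run is self-calibrating: ambient-air reference injections define
the N2 isotopic background and its between-batch precision; the 1 ppm
N2O standard defines the concentration scale, the N2O isotopic
background and the concentration precision.  Detection limits derived
from those references (Eq. DL = t x SD) gate the per-closure
below-detection flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as c
from .campaign import daily_chamber_fluxes, summarize_campaign
from .detection import ReferenceStats, detection_limit
from .errors import InsufficientDataError, N15FluxError
from .fluxes import (
    QC_ACCEPTED,
    QC_BELOW_DETECTION,
    QC_DISCARDED,
    ChamberGeometry,
    FluxResult,
    IonCurrentRecord,
    closure_flux,
    n2_flux,
    n2o_concentration,
    pool_derived_series,
)
from .isotope import (
    GasPath,
    RatioPair,
    n2o_heavy_fraction,
    n2o_isotopologue_fractions,
)

__all__ = ["ProcessOptions", "RunResult", "process_run"]


@dataclass
class ProcessOptions:
    """Thresholds, constants and fallbacks for one processing run."""

    r2_threshold: float = c.R2_THRESHOLD
    confidence: float = c.CONFIDENCE_LEVEL
    estimator: str = "closed_form"  # or "exact"
    ref_conc: float = c.N2O_STANDARD
    fertilizer_enrichment: float | None = None
    default_geometry: ChamberGeometry = field(default_factory=ChamberGeometry)
    default_temperature_k: float = c.DEFAULT_TEMPERATURE_K
    default_pressure_pa: float = c.DEFAULT_PRESSURE_PA
    air_reference_id: str = "REF_AIR"
    n2o_standard_id: str = "REF_N2O_STD"
    # override the self-calibrated detection limits (mol fraction / ratio)
    dl_30r: float | None = None
    dl_conc: float | None = None


@dataclass
class RunResult:
    flux: pd.DataFrame
    daily: pd.DataFrame
    summary: pd.DataFrame
    reference_stats: dict
    qc: dict


def _record(row) -> IonCurrentRecord:
    return IonCurrentRecord(
        source_id=row.source_id,
        path=GasPath(row.path),
        i_light=row.i_light,
        i_mid=row.i_mid,
        i_heavy=row.i_heavy,
        time_min=None
        if pd.isna(row.minutes_since_closure)
        else float(row.minutes_since_closure),
    )


def _reference_calibration(refs: pd.DataFrame, options: ProcessOptions):
    """Backgrounds, concentration scale and precision from reference rows."""
    air = refs[refs["path"] == "N2"]
    std = refs[refs["path"] == "N2O"]
    if len(air) < 2 or len(std) < 2:
        raise InsufficientDataError(
            "need at least 2 ambient-air and 2 N2O-standard reference injections"
        )
    r29 = air["i_mid"] / air["i_light"]
    r30 = air["i_heavy"] / air["i_light"]
    bg_n2 = RatioPair(float(r29.mean()), float(r30.mean()))
    r45 = std["i_mid"] / std["i_light"]
    r46 = std["i_heavy"] / std["i_light"]
    bg_n2o = RatioPair(float(r45.mean()), float(r46.mean()))
    h_nat = n2o_heavy_fraction(n2o_isotopologue_fractions(c.NAT_15N))
    sums = (std["i_light"] + std["i_mid"] + std["i_heavy"]) / (1.0 - h_nat)
    ref_sum = float(sums.mean())
    conc = options.ref_conc * sums / ref_sum
    stats = {
        "R29": ReferenceStats.from_values("R29", r29),
        "R30": ReferenceStats.from_values("R30", r30),
        "R45": ReferenceStats.from_values("R45", r45),
        "R46": ReferenceStats.from_values("R46", r46),
        "C_N2O": ReferenceStats.from_values("C_N2O", conc),
    }
    return bg_n2, bg_n2o, ref_sum, stats


def _chamber_state(chamber: str, chambers_df: pd.DataFrame | None, options):
    geometry = options.default_geometry
    temperature = options.default_temperature_k
    pressure = options.default_pressure_pa
    treatment = "all"
    if chambers_df is not None:
        row = chambers_df[chambers_df["chamber"] == chamber]
        if len(row):
            row = row.iloc[0]
            treatment = str(row["treatment"])
            if np.isfinite(row.get("basal_area_m2", np.nan)) and np.isfinite(
                row.get("height_m", np.nan)
            ):
                geometry = ChamberGeometry(
                    float(row["basal_area_m2"]), float(row["height_m"])
                )
            if np.isfinite(row.get("temperature_K", np.nan)):
                temperature = float(row["temperature_K"])
            if np.isfinite(row.get("pressure_Pa", np.nan)):
                pressure = float(row["pressure_Pa"])
    return geometry, temperature, pressure, treatment


def _process_closure(
    n2_rows,
    n2o_rows,
    bg_n2: RatioPair,
    bg_n2o: RatioPair,
    ref_sum: float,
    dls: dict,
    geometry,
    temperature,
    pressure,
    options: ProcessOptions,
) -> list[FluxResult]:
    """Flux results (N2O, N2O_d, N2+N2O, N2) for one chamber closure."""
    results: list[FluxResult] = []

    # --- N2O path: isotopologues, then concentration per timepoint
    n2o_records = [_record(r) for r in n2o_rows.itertuples()]
    series_n2o = pool_derived_series(
        n2o_records,
        bg_n2o,
        total_gas_fraction=1.0,  # rescaled to concentration below
        estimator=options.estimator,
        temperature_k=temperature,
        pressure_pa=pressure,
        geometry=geometry,
        min_delta=(dls["R45"], dls["R46"]),
    )
    a_d = series_n2o.a_pool
    concs = []
    for t, d_t in zip(series_n2o.times_min, series_n2o.d_values):
        rec = next(
            rec
            for rec in n2o_records
            if rec.time_min is not None and float(rec.time_min) == float(t)
        )
        concs.append(
            n2o_concentration(
                rec,
                ref_sum,
                options.ref_conc,
                sample_a=a_d if a_d is not None else c.NAT_15N,
                sample_d=max(d_t, 0.0) if a_d is not None else None,
            )
        )
    concs = np.asarray(concs)
    conc_rise = float(concs[-1] - concs[0])
    series_conc = series_n2o.__class__(
        chamber_id=series_n2o.chamber_id,
        gas="N2O",
        times_min=series_n2o.times_min,
        values=concs,
        temperature_k=temperature,
        pressure_pa=pressure,
        geometry=geometry,
        a_pool=a_d,
        a_basis=series_n2o.a_basis,
        d_values=series_n2o.d_values,
        n_dropped=series_n2o.n_dropped,
    )
    res_n2o = closure_flux(
        series_conc, options.r2_threshold, detection_delta=(conc_rise, dls["conc"])
    )
    results.append(res_n2o)

    # pool-derived N2O concentration series -> N2O_d flux
    series_n2o.values = series_n2o.d_values * concs
    series_n2o.gas = "N2O_d"
    series_n2o.below_detection = series_n2o.below_detection or (
        res_n2o.qc == QC_BELOW_DETECTION
    )
    res_n2o_d = closure_flux(series_n2o, options.r2_threshold)
    if res_n2o.qc == QC_DISCARDED:
        res_n2o_d.qc = QC_DISCARDED
        res_n2o_d.flux_g_n_ha_day = float("nan")
    results.append(res_n2o_d)

    # --- N2 path, using aD from the N2O path when available
    n2_records = [_record(r) for r in n2_rows.itertuples()]
    series_n2 = pool_derived_series(
        n2_records,
        bg_n2,
        total_gas_fraction=c.N2_AIR_FRACTION,
        a_pool=a_d,
        estimator=options.estimator,
        temperature_k=temperature,
        pressure_pa=pressure,
        geometry=geometry,
        min_delta=(dls["R29"], dls["R30"]),
    )
    if a_d is not None:
        series_n2.a_pool, series_n2.a_basis = a_d, "N2O_4546"
    res_total = closure_flux(
        series_n2,
        options.r2_threshold,
        detection_delta=(
            series_n2.final_delta_heavy
            if series_n2.final_delta_heavy is not None
            else -np.inf,
            dls["R30"],
        ),
    )
    res_total.gas = "N2_plus_N2O"
    results.append(res_total)
    results.append(n2_flux(res_total, res_n2o))
    return results


def process_run(
    injections: pd.DataFrame,
    chambers: pd.DataFrame | None = None,
    options: ProcessOptions | None = None,
) -> RunResult:
    """Process a full injection table into flux and summary tables.

    ``injections`` must be the cleaned table from
    :func:`n15flux.io.read_injections` (or the simulator output).
    Closures are identified by (chamber, closure start = timestamp
    minus minutes-since-closure); day indices count from the first
    closure date in the file.
    """
    options = options or ProcessOptions()
    df = injections.copy()
    df["iso_time"] = pd.to_datetime(df["iso_time"], format="ISO8601")
    is_ref = df["minutes_since_closure"].isna() | df["source_id"].isin(
        [options.air_reference_id, options.n2o_standard_id]
    )
    refs, samples = df[is_ref], df[~is_ref]
    if not len(samples):
        raise InsufficientDataError("no chamber sample injections in input")
    bg_n2, bg_n2o, ref_sum, ref_stats = _reference_calibration(refs, options)
    dls = {
        name: detection_limit(
            ref_stats[key].sd, ref_stats[key].n, options.confidence
        )
        for name, key in (
            ("R29", "R29"),
            ("R30", "R30"),
            ("R45", "R45"),
            ("R46", "R46"),
            ("conc", "C_N2O"),
        )
    }
    if options.dl_30r is not None:
        dls["R30"] = options.dl_30r
    if options.dl_conc is not None:
        dls["conc"] = options.dl_conc

    samples = samples.copy()
    # round to the minute: timestamps carry sub-second float residue from
    # fractional sampling minutes, and closures are minutes apart
    samples["closure_start"] = (
        samples["iso_time"]
        - pd.to_timedelta(samples["minutes_since_closure"], unit="m")
    ).dt.round("1min")
    campaign_start = samples["closure_start"].min().normalize()
    samples["day"] = (
        samples["closure_start"].dt.normalize() - campaign_start
    ).dt.days + 1

    flux_rows = []
    qc_counts = {QC_ACCEPTED: 0, QC_DISCARDED: 0, QC_BELOW_DETECTION: 0}
    n_failed_closures = 0
    for (chamber, closure_start), grp in samples.groupby(
        ["source_id", "closure_start"], sort=True
    ):
        geometry, temperature, pressure, treatment = _chamber_state(
            chamber, chambers, options
        )
        day = int(grp["day"].iloc[0])
        n2_rows = grp[grp["path"] == "N2"]
        n2o_rows = grp[grp["path"] == "N2O"]
        try:
            results = _process_closure(
                n2_rows,
                n2o_rows,
                bg_n2,
                bg_n2o,
                ref_sum,
                dls,
                geometry,
                temperature,
                pressure,
                options,
            )
        except (N15FluxError, StopIteration):
            n_failed_closures += 1
            continue
        for res in results:
            if res.gas == "N2_plus_N2O":
                qc_counts[res.qc] += 1
            flux_rows.append(
                {
                    "chamber": chamber,
                    "treatment": treatment,
                    "day": day,
                    "closure_start": closure_start.isoformat(),
                    "gas": res.gas,
                    "slope_molfrac_per_min": res.slope,
                    "r2": res.r2,
                    "qc": res.qc,
                    "flux_gN_ha_day": res.flux_g_n_ha_day,
                    "aD": res.a_pool,
                    "aD_basis": res.a_basis,
                    "d": res.d_mean,
                }
            )
    if not flux_rows:
        raise InsufficientDataError("no closures could be processed")
    flux_df = pd.DataFrame(flux_rows)

    daily = daily_chamber_fluxes(
        flux_df[flux_df["gas"].isin(["N2", "N2O", "N2O_d"])]
    )
    summary = summarize_campaign(daily, options.fertilizer_enrichment)

    n_closures = qc_counts[QC_ACCEPTED] + qc_counts[QC_DISCARDED] + qc_counts[
        QC_BELOW_DETECTION
    ]
    qc = {
        "n_closures": n_closures + n_failed_closures,
        "n_failed": n_failed_closures,
        "accepted": qc_counts[QC_ACCEPTED],
        "discarded_low_r2": qc_counts[QC_DISCARDED],
        "below_detection": qc_counts[QC_BELOW_DETECTION],
        "dl_30r": dls["R30"],
        "dl_conc_molfrac": dls["conc"],
    }
    return RunResult(
        flux=flux_df,
        daily=daily,
        summary=summary,
        reference_stats=ref_stats,
        qc=qc,
    )
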