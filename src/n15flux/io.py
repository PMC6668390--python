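"""CSV interchange for injection streams, chamber metadata and results.

The interchange format is plain CSV with a header row; numeric output
columns carry their units in the header name.  Injection rows that fail
to parse are dropped (and counted) rather than aborting a run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .simulate import INJECTION_COLUMNS

__all__ = [
    "INJECTION_COLUMNS",
    "CHAMBER_COLUMNS",
    "read_injections",
    "write_injections",
    "read_chambers",
    "write_chambers",
]

CHAMBER_COLUMNS = [
    "chamber",
    "treatment",
    "basal_area_m2",
    "height_m",
    "temperature_K",
    "pressure_Pa",
]


def read_injections(path) -> tuple[pd.DataFrame, int]:
    """Read an injection CSV, returning (clean table, n rows skipped).

    Malformed rows — short rows, unparsable numbers, non-positive major
    beam, unknown path — are skipped and counted.
    """
    raw = pd.read_csv(
        path,
        usecols=lambda name: name in INJECTION_COLUMNS,
        dtype=str,
        keep_default_na=False,
        on_bad_lines="skip",
        engine="python",
    )
    missing = set(INJECTION_COLUMNS) - set(raw.columns)
    if missing:
        raise InsufficientDataError(
            f"injection file missing columns {sorted(missing)}"
        )
    n_raw = len(raw)
    df = raw.copy()
    for col in ("i_light", "i_mid", "i_heavy", "minutes_since_closure"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["iso_time"] = pd.to_datetime(df["iso_time"], errors="coerce", format="ISO8601")
    ok = (
        df["i_light"].notna()
        & (df["i_light"] > 0)
        & df["i_mid"].notna()
        & (df["i_mid"] >= 0)
        & df["i_heavy"].notna()
        & (df["i_heavy"] >= 0)
        & df["iso_time"].notna()
        & df["path"].isin(["N2", "N2O"])
        & (df["source_id"].str.len() > 0)
    )
    clean = df[ok].reset_index(drop=True)
    return clean, n_raw - int(ok.sum())


def write_injections(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=INJECTION_COLUMNS)


def read_chambers(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"chamber", "treatment"} - set(df.columns)
    if missing:
        raise InsufficientDataError(
            f"chamber metadata missing columns {sorted(missing)}"
        )
    for col, default in (
        ("basal_area_m2", np.nan),
        ("height_m", np.nan),
        ("temperature_K", np.nan),
        ("pressure_Pa", np.nan),
    ):
        if col not in df.columns:
            df[col] = default
    return df


def write_chambers(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=[c for c in CHAMBER_COLUMNS if c in df])
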