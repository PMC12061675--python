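"""CSV readers/writers with schema validation.

All data interchange is plain CSV (UTF-8, "." decimal).  Readers validate
required columns and numeric types, naming the offending column or row in
the error; unknown columns are preserved but ignored.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .fitting import StemSeries
from .richards import Domain

__all__ = [
    "read_measurements",
    "read_weather",
    "read_metadata",
    "read_harvest",
    "measurements_to_series",
    "series_to_frame",
]

_SCHEMAS = {
    "measurements": {"plant_id": str, "year": int, "day": float, "length_cm": float},
    "measurements_thermal": {"plant_id": str, "year": int, "thermal_cd": float,
                             "length_cm": float},
    "weather": {"day": int, "tmax_c": float, "tmin_c": float},
    "metadata": {"plant_id": str, "genotype": str, "block": int, "species_group": str,
                 "lat": float, "lon": float, "alt_m": float},
    "harvest": {"plant_id": str, "year": int, "wet_g": float, "sub_wet_g": float,
                "sub_dry_g": float},
}


def _read_validated(path, schema_name: str) -> pd.DataFrame:
    schema = _SCHEMAS[schema_name]
    df = pd.read_csv(path)
    for col, typ in schema.items():
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
        if typ in (int, float):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise SchemaError(
                    f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                    f"'{col}' at data row {row + 1}"
                )
            df[col] = coerced.astype(float if typ is float else "int64")
        else:
            df[col] = df[col].astype(str)
    return df


def read_measurements(path, domain: Domain = Domain.julian_day) -> pd.DataFrame:
    """Long-format stem measurements (plant_id, year, day|thermal_cd, length_cm)."""
    name = "measurements" if domain == Domain.julian_day else "measurements_thermal"
    return _read_validated(path, name)


def read_weather(path) -> pd.DataFrame:
    return _read_validated(path, "weather")


def read_metadata(path) -> pd.DataFrame:
    return _read_validated(path, "metadata")


def read_harvest(path) -> pd.DataFrame:
    return _read_validated(path, "harvest")


def measurements_to_series(df: pd.DataFrame,
                           domain: Domain = Domain.julian_day) -> list[StemSeries]:
    """Group a long-format measurement table into per-plant-year series."""
    xcol = "day" if domain == Domain.julian_day else "thermal_cd"
    out = []
    for (pid, year), grp in df.groupby(["plant_id", "year"], sort=True):
        grp = grp.sort_values(xcol)
        out.append(StemSeries(str(pid), int(year), grp[xcol].to_numpy(float),
                              grp["length_cm"].to_numpy(float), domain))
    return out


def series_to_frame(series_list: list[StemSeries]) -> pd.DataFrame:
    """Inverse of :func:`measurements_to_series` (day-of-year domain)."""
    frames = []
    for s in series_list:
        xcol = "day" if s.domain == Domain.julian_day else "thermal_cd"
        frames.append(pd.DataFrame({
            "plant_id": s.plant_id, "year": s.year, xcol: s.x, "length_cm": s.length,
        }))
    return pd.concat(frames, ignore_index=True)


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
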