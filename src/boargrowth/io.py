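"""Delimited-text table schemas and readers/writers.

All inputs are plain CSV with exact header names:

* ``bags.csv``       — country,region,year,bag,area_km2
* ``climate.csv``    — region,year,month,tmean_c,precip_mm
* ``mast.csv``       — region,year,rank
* ``accidents.csv``  — country,year,accidents,vehicles
* ``bodymass.csv``   — region,sex,mass_kg,dressed,zone,longterm_winter_c
"""

from __future__ import annotations

import os

import pandas as pd

BAGS_COLUMNS = ["country", "region", "year", "bag", "area_km2"]
CLIMATE_COLUMNS = ["region", "year", "month", "tmean_c", "precip_mm"]
MAST_COLUMNS = ["region", "year", "rank"]
ACCIDENTS_COLUMNS = ["country", "year", "accidents", "vehicles"]
BODYMASS_COLUMNS = ["region", "sex", "mass_kg", "dressed", "zone", "longterm_winter_c"]

_SCHEMAS = {
    "bags": BAGS_COLUMNS,
    "climate": CLIMATE_COLUMNS,
    "mast": MAST_COLUMNS,
    "accidents": ACCIDENTS_COLUMNS,
    "bodymass": BODYMASS_COLUMNS,
}


def check_schema(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Verify that *df* carries the columns of table *kind* (extra columns pass)."""
    expected = _SCHEMAS[kind]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table is missing columns {missing}; expected {expected}")
    return df


def _read(path: str | os.PathLike, kind: str) -> pd.DataFrame:
    return check_schema(pd.read_csv(path), kind)


def read_bags(path):
    return _read(path, "bags")


def read_climate(path):
    return _read(path, "climate")


def read_mast(path):
    return _read(path, "mast")


def read_accidents(path):
    return _read(path, "accidents")


def read_bodymass(path):
    return _read(path, "bodymass")


def read_exclusion_list(path) -> set[tuple[str, int]]:
    """Read a (region,year) exclusion list CSV with headers ``region,year``."""
    df = pd.read_csv(path)
    if not {"region", "year"} <= set(df.columns):
        raise ValueError("exclusion list needs columns region,year")
    return {(str(r), int(y)) for r, y in zip(df["region"], df["year"])}


def write_table(df: pd.DataFrame, path) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, index=False)
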