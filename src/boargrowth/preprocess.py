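"""From raw tables to the analysis-ready growth-rate table.

The unit of observation is one region x census year with the annual
growth rate ``lam = bag_t / bag_{t-1}``, six day-weighted seasonal
temperatures, regional long-term (default 1973-2002) climate means, a
5-year density proxy, the previous-year beech-mast code, and
standardized copies of every predictor (continuous: mean 0, SD 0.5;
binary: centred only).

Exclusion rules are applied in a fixed, fully logged order:

1. bag densities below ``min_density`` (default 0.01 shot/km^2) are
   removed before growth rates are formed, so the removed year drops
   both the ratio using it as numerator and the one using it as
   denominator;
2. census years on a supplied exclusion list (e.g. war periods);
3. growth rates only across consecutive surviving years;
4. rows without 5 consecutive prior bag years (density proxy) and rows
   with incomplete seasonal climate are dropped and logged.
"""

from __future__ import annotations

import calendar
import warnings
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

#: months belonging to each season; winter straddles the year boundary and
#: is assigned to the census year of its January/February.
SEASON_MONTHS = {
    "winter": (12, 1, 2),
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
}

#: predictor column -> (season, year offset relative to the census year)
SEASONAL_PREDICTORS = {
    "winter_t": ("winter", 0),
    "spring_t": ("spring", 0),
    "summer_t": ("summer", 0),
    "prior_spring_t": ("spring", -1),
    "prior_summer_t": ("summer", -1),
    "prior_autumn_t": ("autumn", -1),
}

DEFAULT_LT_WINDOW = (1973, 2002)
DEFAULT_MIN_DENSITY = 0.01

#: live mass = dressed mass x zone factor
DRESSING_FACTORS = {"central": 1.25, "eastern": 1.15}


class StandardizeRecord(NamedTuple):
    """Parameters of a standardization transform, kept for back-conversion."""

    mean: float
    sd: float
    binary: bool

    def apply(self, x):
        if self.binary:
            return np.asarray(x, float) - self.mean
        return (np.asarray(x, float) - self.mean) / (2.0 * self.sd)

    def invert_slope(self, slope_std: float) -> float:
        """Raw-scale slope from a standardized-scale slope."""
        if self.binary:
            return slope_std
        return slope_std / (2.0 * self.sd)


def standardize(values, binary: bool = False, name: str = "") -> tuple[np.ndarray, StandardizeRecord]:
    """Standardize to mean 0 / SD 0.5 (continuous) or centre only (binary).

    Continuous predictors are divided by twice their sample SD, which
    puts them on a scale commensurable with centred binary predictors.
    """
    x = np.asarray(values, float)
    m = float(np.mean(x))
    if binary:
        rec = StandardizeRecord(m, 0.5, True)
        return x - m, rec
    s = float(np.std(x, ddof=1))
    if not s > 0:
        raise ValueError(f"cannot standardize zero-variance variable {name or 'x'!r}")
    rec = StandardizeRecord(m, s, False)
    return (x - m) / (2.0 * s), rec


# ---------------------------------------------------------------------------
# growth rates and exclusions


def compute_lambda(
    series: pd.DataFrame, min_density: float = DEFAULT_MIN_DENSITY
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annual growth rates per region after the low-density filter.

    Returns ``(rows, exclusions)`` where rows has one record per region
    and census year with ``lam = bag_t / bag_{t-1}`` computed only for
    consecutive years that survive the density filter.
    """
    excl: list[dict] = []
    out: list[dict] = []
    for (country, region), g in series.groupby(["country", "region"], sort=True):
        g = g.sort_values("year")
        dens = g["bag"].to_numpy(float) / g["area_km2"].to_numpy(float)
        keep = dens >= min_density
        for row, d in zip(g.loc[~keep].itertuples(), dens[~keep]):
            excl.append(
                dict(country=country, region=region, year=int(row.year), rule="low_density",
                     detail=f"{d:.4f} shot/km2 < {min_density}")
            )
        kept = g.loc[keep]
        years = kept["year"].to_numpy(int)
        bags = kept["bag"].to_numpy(float)
        areas = kept["area_km2"].to_numpy(float)
        for i in range(1, len(years)):
            if years[i] - years[i - 1] != 1:
                continue
            if bags[i - 1] == 0:  # possible only when min_density == 0
                excl.append(dict(country=country, region=region, year=int(years[i]),
                                 rule="zero_denominator", detail="previous bag is zero"))
                continue
            out.append(
                dict(country=country, region=region, year=int(years[i]),
                     lam=bags[i] / bags[i - 1], bag=bags[i], area_km2=areas[i])
            )
    rows = pd.DataFrame(out, columns=["country", "region", "year", "lam", "bag", "area_km2"])
    log = pd.DataFrame(excl, columns=["country", "region", "year", "rule", "detail"])
    return rows, log


def exclude_years(rows: pd.DataFrame, exclusion_list: Iterable[tuple[str, int]]) -> pd.DataFrame:
    """Drop listed (region, year) records; unknown entries warn but never fail."""
    excl = {(str(r), int(y)) for r, y in exclusion_list}
    if not excl:
        return rows
    key = list(zip(rows["region"].astype(str), rows["year"].astype(int)))
    mask = np.array([k in excl for k in key])
    matched = {k for k in key if k in excl}
    for miss in excl - matched:
        warnings.warn(f"exclusion list entry {miss} matched no row", stacklevel=2)
    return rows.loc[~mask]


# ---------------------------------------------------------------------------
# seasonal climate


def days_in_month(year: int, month: int) -> int:
    return calendar.monthrange(year, month)[1]


def seasonal_table(climate: pd.DataFrame) -> pd.DataFrame:
    """Day-weighted seasonal temperature means and precipitation sums.

    One row per (region, season-year, season); winter of season-year *t*
    covers Dec(t-1), Jan(t), Feb(t). Seasons with fewer than three
    months of data get NaN.
    """
    c = climate.copy()
    month = c["month"].to_numpy(int)
    year = c["year"].to_numpy(int)
    season = np.empty(len(c), dtype=object)
    for s, months in SEASON_MONTHS.items():
        season[np.isin(month, months)] = s
    c["season"] = season
    c["season_year"] = np.where(month == 12, year + 1, year)
    c["days"] = [days_in_month(y, m) for y, m in zip(year, month)]
    c["tw"] = c["tmean_c"] * c["days"]

    g = c.groupby(["region", "season_year", "season"], sort=True)
    agg = g.agg(
        tw=("tw", "sum"), days=("days", "sum"), precip=("precip_mm", "sum"),
        n_months=("month", "size"),
    ).reset_index()
    agg["tmean"] = np.where(agg["n_months"] == 3, agg["tw"] / agg["days"], np.nan)
    agg["precip"] = np.where(agg["n_months"] == 3, agg["precip"], np.nan)
    return agg.rename(columns={"season_year": "year"})[
        ["region", "year", "season", "tmean", "precip", "n_months"]
    ]


def _season_lookup(climate: pd.DataFrame):
    tab = seasonal_table(climate)
    tmean = {(r, int(y), s): v for r, y, s, v in zip(tab["region"], tab["year"], tab["season"], tab["tmean"])}
    precip = {(r, int(y), s): v for r, y, s, v in zip(tab["region"], tab["year"], tab["season"], tab["precip"])}
    return tmean, precip


def seasonal_mean(climate: pd.DataFrame, region, season: str, census_year: int) -> float:
    """Day-weighted mean temperature of one season of one census year."""
    if season not in SEASON_MONTHS:
        raise ValueError(f"unknown season {season!r}")
    tmean, _ = _season_lookup(climate)
    v = tmean.get((region, int(census_year), season), np.nan)
    if np.isnan(v):
        raise ValueError(f"incomplete months for {season} {census_year} in region {region}")
    return float(v)


def seasonal_precip_sum(climate: pd.DataFrame, region, season: str, census_year: int) -> float:
    """Precipitation sum of one season (same season windows as temperature)."""
    if season not in SEASON_MONTHS:
        raise ValueError(f"unknown season {season!r}")
    _, precip = _season_lookup(climate)
    v = precip.get((region, int(census_year), season), np.nan)
    if np.isnan(v):
        raise ValueError(f"incomplete months for {season} {census_year} in region {region}")
    return float(v)


_LT_VARIABLES = ("winter_t", "summer_t", "summer_precip", "yearly_precip")


def longterm_mean(
    climate: pd.DataFrame, region, variable: str, window: tuple[int, int] = DEFAULT_LT_WINDOW
) -> float:
    """Long-term mean of a seasonal temperature / precipitation summary.

    ``variable`` is one of ``winter_t``, ``summer_t``, ``summer_precip``
    or ``yearly_precip``; the mean is over the inclusive year *window*
    (default 1973-2002) and every year must be present.
    """
    if variable not in _LT_VARIABLES:
        raise ValueError(f"variable must be one of {_LT_VARIABLES}")
    y0, y1 = window
    years = np.arange(y0, y1 + 1)
    if variable == "yearly_precip":
        c = climate[climate["region"] == region]
        g = c.groupby("year")["precip_mm"].agg(["sum", "size"])
        vals = {int(y): (s if n == 12 else np.nan) for y, (s, n) in g.iterrows()}
    else:
        season = "winter" if variable == "winter_t" else "summer"
        tab = seasonal_table(climate[climate["region"] == region])
        tab = tab[tab["season"] == season]
        col = "tmean" if variable.endswith("_t") else "precip"
        vals = {int(y): v for y, v in zip(tab["year"], tab[col])}
    series = np.array([vals.get(int(y), np.nan) for y in years])
    if np.isnan(series).any():
        missing = [int(y) for y, v in zip(years, series) if np.isnan(v)]
        raise ValueError(
            f"long-term window {window} incomplete for {variable} in region {region}: missing {missing}"
        )
    return float(series.mean())


def longterm_table(climate: pd.DataFrame, window: tuple[int, int] = DEFAULT_LT_WINDOW) -> pd.DataFrame:
    """Per-region long-term climate means over *window* (vectorized).

    Columns: lt_winter_t, lt_summer_t, lt_summer_precip,
    lt_yearly_precip; raises if any region misses a year of the window.
    """
    y0, y1 = window
    tab = seasonal_table(climate)
    tab = tab[(tab["year"] >= y0) & (tab["year"] <= y1)]
    n_years = y1 - y0 + 1

    def seasonal_lt(season: str, col: str) -> pd.Series:
        sub = tab[tab["season"] == season]
        g = sub.groupby("region")[col].agg(["mean", "count"])  # count skips NaN seasons
        bad = g.index[g["count"] < n_years].tolist()
        if bad:
            raise ValueError(
                f"long-term window {window} incomplete for {season} {col} in regions {bad}")
        return g["mean"]

    yearly = climate[(climate["year"] >= y0) & (climate["year"] <= y1)]
    gy = yearly.groupby(["region", "year"])["precip_mm"].agg(["sum", "size"])
    if (gy["size"] != 12).any():
        bad = sorted({r for (r, _), n in gy["size"].items() if n != 12})
        raise ValueError(f"long-term window {window} has incomplete months in regions {bad}")
    lt_yearly = gy["sum"].groupby("region").agg(["mean", "count"])
    if (lt_yearly["count"] != n_years).any():
        bad = lt_yearly.index[lt_yearly["count"] != n_years].tolist()
        raise ValueError(f"long-term window {window} missing years in regions {bad}")

    out = pd.DataFrame({
        "lt_winter_t": seasonal_lt("winter", "tmean"),
        "lt_summer_t": seasonal_lt("summer", "tmean"),
        "lt_summer_precip": seasonal_lt("summer", "precip"),
        "lt_yearly_precip": lt_yearly["mean"],
    })
    return out


def resolve_lt_window(climate: pd.DataFrame, window: tuple[int, int] | None) -> tuple[int, int]:
    """Default long-term window, falling back to the common span if 1973-2002 is not covered."""
    if window is not None:
        return window
    y0 = int(climate["year"].min()) + 1  # first full winter needs the prior December
    y1 = int(climate["year"].max())
    if y0 <= DEFAULT_LT_WINDOW[0] and y1 >= DEFAULT_LT_WINDOW[1]:
        return DEFAULT_LT_WINDOW
    return (y0, y1)


# ---------------------------------------------------------------------------
# density proxy and mast coding


def density_proxy(series: pd.DataFrame, region, census_year: int) -> float:
    """Mean shot/km^2 over the five consecutive years preceding the census year."""
    g = series[series["region"] == region]
    dens = {int(y): b / a for y, b, a in zip(g["year"], g["bag"], g["area_km2"])}
    prior = [census_year - k for k in range(5, 0, -1)]
    if any(y not in dens for y in prior):
        missing = [y for y in prior if y not in dens]
        raise ValueError(f"density proxy needs 5 consecutive prior years; missing {missing}")
    return float(np.mean([dens[y] for y in prior]))


def mast_binary(rank: float) -> int:
    """1 for moderate or full mast (rank >= 3, pollination >= 70%), else 0."""
    if not 0 <= rank <= 4:
        raise ValueError(f"mast rank {rank} outside [0, 4]")
    return int(rank >= 3)


def mast_category(rank: float) -> str:
    """Trend outcome class: failure (<=1), moderate (1..3], full (>3)."""
    if not 0 <= rank <= 4:
        raise ValueError(f"mast rank {rank} outside [0, 4]")
    if rank <= 1:
        return "failure"
    if rank <= 3:
        return "moderate"
    return "full"


def code_mast(ranks: pd.DataFrame, census_year: int) -> pd.DataFrame:
    """Previous-year mast codes per region for one census year.

    Multiple measurements per (region, year) are averaged first. Returns
    region, the averaged previous-year rank, the binary code and the
    trend category label.
    """
    prev = ranks[ranks["year"] == census_year - 1]
    mean_rank = prev.groupby("region")["rank"].mean()
    out = pd.DataFrame({
        "region": mean_rank.index,
        "rank_prev": mean_rank.to_numpy(float),
    })
    out["mast_prev"] = [mast_binary(r) for r in out["rank_prev"]]
    out["category_prev"] = [mast_category(r) for r in out["rank_prev"]]
    return out.reset_index(drop=True)


def dressed_to_live(mass_kg: float, zone: str | None = None, dressed: bool = True) -> float:
    """Live body mass from dressed mass via the zone dressing factor."""
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    if not dressed:
        return float(mass_kg)
    if zone not in DRESSING_FACTORS:
        raise ValueError(f"unknown dressing zone {zone!r}; known: {sorted(DRESSING_FACTORS)}")
    return float(mass_kg) * DRESSING_FACTORS[zone]


# ---------------------------------------------------------------------------
# the analysis table

#: continuous predictor columns of the growth table
CONTINUOUS_PREDICTORS = [
    "winter_t", "spring_t", "summer_t",
    "prior_spring_t", "prior_summer_t", "prior_autumn_t",
    "lt_winter_t", "lt_summer_t", "lt_summer_precip", "lt_yearly_precip",
    "density5",
]
BINARY_PREDICTORS = ["mast_prev"]
CROP_PREDICTORS = ["corn_pct", "potato_pct"]


def build_growth_table(
    bags: pd.DataFrame,
    climate: pd.DataFrame,
    mast: pd.DataFrame | None = None,
    crops: pd.DataFrame | None = None,
    exclusion_list: Iterable[tuple[str, int]] = (),
    min_density: float = DEFAULT_MIN_DENSITY,
    lt_window: tuple[int, int] | None = None,
    standardize_binary_as_continuous: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, StandardizeRecord]]:
    """Assemble the analysis table.

    Returns ``(growth, exclusions, transforms)``: one row per retained
    region x census year with raw and standardized (``_z``) predictor
    columns, the exclusion ledger, and the standardization transforms.
    """
    logs: list[pd.DataFrame] = []

    work = bags.copy()
    if exclusion_list:
        excl = {(str(r), int(y)) for r, y in exclusion_list}
        key = list(zip(work["region"].astype(str), work["year"].astype(int)))
        mask = np.array([k in excl for k in key])
        dropped = work.loc[mask]
        logs.append(pd.DataFrame(dict(
            country=dropped["country"], region=dropped["region"], year=dropped["year"],
            rule="political_period", detail="listed census year",
        )))
        matched = {k for k, m in zip(key, mask) if m}
        for miss in excl - matched:
            warnings.warn(f"exclusion list entry {miss} matched no bag row", stacklevel=2)
        work = work.loc[~mask]

    rows, dens_log = compute_lambda(work, min_density=min_density)
    logs.append(dens_log)

    # seasonal predictors of the census year and the prior year
    tab = seasonal_table(climate)
    tmean = tab.pivot_table(index=["region", "year"], columns="season", values="tmean")
    for col, (season, off) in SEASONAL_PREDICTORS.items():
        key = pd.MultiIndex.from_arrays([rows["region"], rows["year"] + off])
        rows[col] = tmean.reindex(key)[season].to_numpy() if season in tmean else np.nan

    # long-term regional climate
    window = resolve_lt_window(climate, lt_window)
    lt = longterm_table(climate, window)
    for col in ("lt_winter_t", "lt_summer_t", "lt_summer_precip", "lt_yearly_precip"):
        rows[col] = lt[col].reindex(rows["region"]).to_numpy()

    # 5-year density proxy from the post-filter bag rows
    filtered = work.loc[work["bag"] / work["area_km2"] >= min_density]
    dens = {(r, int(y)): b / a for r, y, b, a in zip(
        filtered["region"], filtered["year"], filtered["bag"], filtered["area_km2"])}
    d5 = []
    for r, y in zip(rows["region"], rows["year"]):
        prior = [(r, y - k) for k in range(5, 0, -1)]
        d5.append(np.mean([dens[p] for p in prior]) if all(p in dens for p in prior) else np.nan)
    rows["density5"] = d5

    # previous-year mast
    if mast is not None:
        mr = mast.groupby(["region", "year"])["rank"].mean()
        if ((mr < 0) | (mr > 4)).any():
            raise ValueError("mast ranks outside [0, 4]")
        prev_key = pd.MultiIndex.from_arrays([rows["region"], rows["year"] - 1])
        rank_prev = mr.reindex(prev_key).to_numpy()
        rows["rank_prev"] = rank_prev
        rows["mast_prev"] = np.where(np.isnan(rank_prev), np.nan, (rank_prev >= 3).astype(float))

    # previous-year crop areas (% of region area)
    if crops is not None:
        ck = crops.set_index(["region", "year"])
        prev_key = pd.MultiIndex.from_arrays([rows["region"], rows["year"] - 1])
        for col in CROP_PREDICTORS:
            if col in ck.columns:
                rows[col] = ck[col].reindex(prev_key).to_numpy()

    # completeness-based exclusions
    needed = list(SEASONAL_PREDICTORS)
    incomplete = rows[needed].isna().any(axis=1)
    _log_rows(logs, rows.loc[incomplete], "climate_incomplete", "missing seasonal months")
    rows = rows.loc[~incomplete]

    no_dens = rows["density5"].isna()
    _log_rows(logs, rows.loc[no_dens], "density5_incomplete", "fewer than 5 consecutive prior years")
    rows = rows.loc[~no_dens]

    if mast is not None:
        no_mast = rows["mast_prev"].isna()
        _log_rows(logs, rows.loc[no_mast], "mast_missing", "no previous-year mast rank")
        rows = rows.loc[~no_mast]
    if crops is not None:
        present = [c for c in CROP_PREDICTORS if c in rows.columns]
        no_crop = rows[present].isna().any(axis=1)
        _log_rows(logs, rows.loc[no_crop], "crops_missing", "no previous-year crop areas")
        rows = rows.loc[~no_crop]

    rows = rows.reset_index(drop=True)

    # standardization
    transforms: dict[str, StandardizeRecord] = {}
    cont = [c for c in CONTINUOUS_PREDICTORS + CROP_PREDICTORS if c in rows.columns]
    for col in cont:
        z, rec = standardize(rows[col], binary=False, name=col)
        rows[col + "_z"] = z
        transforms[col] = rec
    for col in (c for c in BINARY_PREDICTORS if c in rows.columns):
        z, rec = standardize(
            rows[col], binary=not standardize_binary_as_continuous, name=col)
        rows[col + "_z"] = z
        transforms[col] = rec

    exclusions = (
        pd.concat([log for log in logs if len(log)], ignore_index=True)
        if any(len(log) for log in logs)
        else pd.DataFrame(columns=["country", "region", "year", "rule", "detail"])
    )
    return rows, exclusions, transforms


def _log_rows(logs: list, dropped: pd.DataFrame, rule: str, detail: str) -> None:
    if len(dropped):
        logs.append(pd.DataFrame(dict(
            country=dropped["country"], region=dropped["region"], year=dropped["year"],
            rule=rule, detail=detail,
        )))
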