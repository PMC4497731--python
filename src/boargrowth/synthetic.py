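"""Region-structured synthetic data with known ground truth.

Generates hunting-bag, climate, mast, traffic-accident, crop-area and
body-mass tables with the statistical structure the analysis pipeline
assumes, so that every downstream stage has a parameter-recovery test.
The generating model for the growth rate is, per region r in country c
and census year t,

    lambda_rt = 1 + sum_k beta_k x_krt + u_c + u_r + eps_rt,

with the predictors x on exactly the standardized scale the
preprocessing stage reconstructs (continuous: mean 0 / SD 0.5 over the
analysis rows; binary mast: centred), nested random intercepts u_c ~
N(0, country_sd^2), u_r ~ N(0, region_sd^2), Gaussian noise eps, a
floor of 0.05 on lambda, and bags updated multiplicatively
(``bag_t = round(bag_{t-1} * lambda_t)``, never below 1).

Because the 5-year density proxy is itself a function of the simulated
bags, its standardization is self-referential; the generator resolves
this with two passes (pass 1 uses reference centring, pass 2 re-runs
the identical noise stream with the empirical pass-1 mean/SD), leaving
only a second-order discrepancy between generating and recovered
scales.

The default coefficient sets are the significant terms of the European
and Austrian growth-rate analyses (e.g. winter temperature 0.180,
long-term winter temperature -0.252, mast x winter -0.926 on the
standardized scale); one seed governs the whole bundle through named,
independently derived substreams.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from . import preprocess

LAMBDA_FLOOR = 0.05
SUMMER_OFFSET_C = 15.0  # mean summer - winter climatology gap, degC

#: ground truth of the European growth-rate model (standardized scale)
EUROPE_TRUTH: dict[str, float] = {
    "winter_t": 0.180,
    "lt_winter_t": -0.252,
    "prior_autumn_t": 0.179,
    "density5": -0.065,
    "summer_t": -0.050,
    "winter_t:lt_winter_t": -0.059,
}

#: ground truth of the Austrian food-availability model (standardized scale)
AUSTRIA_TRUTH: dict[str, float] = {
    "winter_t": 0.237,
    "mast_prev": 0.284,
    "mast_prev:winter_t": -0.926,
    "prior_autumn_t": 0.173,
    "lt_winter_t": -0.172,
}

RECOGNIZED_MAINS = tuple(
    preprocess.CONTINUOUS_PREDICTORS + preprocess.BINARY_PREDICTORS + preprocess.CROP_PREDICTORS
)

#: ordinal cut offsets (relative to logit P(rank >= 3)) for ranks >= 1..4
_MAST_CUT_OFFSETS = np.array([2.2, 1.2, 0.0, -1.2])


def _rng(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible substream named *name* under one master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic bundle.

    Defaults emulate the European data set: 60 regions in 12 countries,
    bag series 1972-2013 (36 analysed growth rates per region after the
    5-year density burn-in), regional long-term winter means spanning
    -4..+6 degC, and the European ground-truth coefficients.
    """

    n_regions: int = 60
    n_countries: int = 12
    years: tuple[int, int] = (1972, 2013)
    longterm_winter_range: tuple[float, float] = (-4.0, 6.0)
    annual_temp_sd: float = 1.2
    coefficients: Mapping[str, float] = field(default_factory=lambda: dict(EUROPE_TRUTH))
    region_sd: float = 0.03
    country_sd: float = 0.02
    residual_sd: float = 0.25
    mast_base_prob: float = 0.30
    mast_trend: float = 0.05
    density_init: float = 1.0
    density_spread_sd: float = 1.5
    density_climate_corr: float = 0.5
    mean_log_growth: float = 0.0
    seed: int = 0
    longterm_window: tuple[int, int] | None = None
    lambda_baseline: float | None = None

    def baseline(self) -> float:
        """Generating baseline growth rate.

        A multiplicative bag update with mean-one lambda declines almost
        surely (E log lambda = -Var(lambda)/2), which would drive long
        series under the low-density exclusion threshold and select the
        retained rows on their own history.  The default baseline
        compensates that drift and adds ``mean_log_growth`` so that
        E[log lambda] is about +0.04/yr, emulating the era of
        exponential wild boar population growth the analysis targets
        (populations multiplying severalfold over the series).
        """
        if self.lambda_baseline is not None:
            return self.lambda_baseline
        var_beta = 0.25 * sum(b * b for b in self.coefficients.values())
        total = self.residual_sd**2 + self.region_sd**2 + self.country_sd**2 + var_beta
        return 1.0 + self.mean_log_growth + 0.5 * total

    def __post_init__(self):
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.n_countries < 1 or self.n_countries > self.n_regions:
            raise ValueError("n_countries must be in [1, n_regions]")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        y0, y1 = self.years
        if y1 - y0 < 8:
            raise ValueError("years must span at least 8 years (5-year density proxy + growth)")
        if not 0 < self.mast_base_prob < 1:
            raise ValueError("mast_base_prob must be in (0, 1)")
        if self.density_init <= 0:
            raise ValueError("density_init must be positive")
        if self.longterm_window is not None:
            w0, w1 = self.longterm_window
            if w0 < y0 + 1 or w1 > y1:
                raise ValueError(
                    f"long-term window {self.longterm_window} not covered by years {self.years}")
        validate_coefficients(self.coefficients)

    # -- derived structure ---------------------------------------------------

    @property
    def regions(self) -> list[str]:
        return [f"R{i + 1:03d}" for i in range(self.n_regions)]

    @property
    def region_country(self) -> dict[str, str]:
        return {
            r: f"C{(i * self.n_countries) // self.n_regions + 1:02d}"
            for i, r in enumerate(self.regions)
        }

    @property
    def census_years(self) -> np.ndarray:
        """Years entering the analysis (growth rate + 5 prior bag years)."""
        return np.arange(self.years[0] + 5, self.years[1] + 1)

    def lt_window(self) -> tuple[int, int]:
        if self.longterm_window is not None:
            return self.longterm_window
        y0, y1 = self.years
        if y0 <= preprocess.DEFAULT_LT_WINDOW[0] - 1 and y1 >= preprocess.DEFAULT_LT_WINDOW[1]:
            return preprocess.DEFAULT_LT_WINDOW
        return (y0 + 1, y1)


def validate_coefficients(coefficients: Mapping[str, float]) -> None:
    for term in coefficients:
        for part in term.split(":"):
            if part not in RECOGNIZED_MAINS:
                raise ValueError(
                    f"unrecognized term {term!r}; valid mains: {sorted(RECOGNIZED_MAINS)}")


@dataclass
class SyntheticBundle:
    """One coherent synthetic data set plus its generating configuration."""

    bags: pd.DataFrame
    climate: pd.DataFrame
    mast: pd.DataFrame | None
    accidents: pd.DataFrame | None
    bodymass: pd.DataFrame | None
    crops: pd.DataFrame | None
    truth: GeneratorConfig

    def validate(self) -> None:
        if (self.bags["bag"] < 0).any():
            raise AssertionError("negative bag")
        if self.mast is not None and not self.mast["rank"].between(0, 4).all():
            raise AssertionError("mast rank outside [0, 4]")
        have = set(zip(self.climate["region"], self.climate["year"]))
        for r, y in zip(self.bags["region"], self.bags["year"]):
            if (r, y) not in have:
                raise AssertionError(f"no climate for {(r, y)}")


# ---------------------------------------------------------------------------
# climate


def simulate_climate(cfg: GeneratorConfig) -> pd.DataFrame:
    """Monthly temperatures and precipitation per region.

    Temperature = regional climatology (winter level from the
    configured long-term range, smooth seasonal cycle up to summer) plus
    one i.i.d. N(0, annual_temp_sd) anomaly per region x season-year, so
    seasonal means equal climatology + anomaly exactly.  Precipitation
    is positive gamma noise, uncorrelated with the growth process.
    Monthly rows start the December before the first bag year so the
    first winter is complete.
    """
    rng = _rng(cfg.seed, "climate")
    R = cfg.n_regions
    lo, hi = cfg.longterm_winter_range
    winter = np.linspace(lo, hi, R)
    summer = winter + SUMMER_OFFSET_C + rng.normal(0.0, 1.0, R)
    precip_scale = rng.uniform(0.8, 1.2, R)

    y0, y1 = cfg.years
    cal_years = np.arange(y0 - 1, y1 + 1)
    months = np.arange(1, 13)
    # season keyed by (region, season-year, season)
    season_of = {12: "winter", 1: "winter", 2: "winter", 3: "spring", 4: "spring", 5: "spring",
                 6: "summer", 7: "summer", 8: "summer", 9: "autumn", 10: "autumn", 11: "autumn"}
    seasons = ("winter", "spring", "summer", "autumn")
    n_season_years = len(cal_years) + 1
    anomaly = rng.normal(0.0, cfg.annual_temp_sd, size=(R, n_season_years, 4))

    rows = []
    phase = (1.0 - np.cos(2.0 * np.pi * (months - 1.5) / 12.0)) / 2.0
    for i, region in enumerate(cfg.regions):
        clim = winter[i] + (summer[i] - winter[i]) * phase
        for y in cal_years:
            syear = np.where(months == 12, y + 1, y) - (y0 - 1)
            sidx = np.array([seasons.index(season_of[m]) for m in months])
            t = clim + anomaly[i, syear, sidx]
            p = precip_scale[i] * rng.gamma(4.0, 20.0, size=12)
            for m, tv, pv in zip(months, t, p):
                rows.append((region, int(y), int(m), float(tv), float(pv)))
    return pd.DataFrame(rows, columns=["region", "year", "month", "tmean_c", "precip_mm"])


# ---------------------------------------------------------------------------
# mast


def simulate_mast(cfg: GeneratorConfig) -> pd.DataFrame:
    """Beech-mast ranks 0-4 per region and year with a logistic time trend.

    Drawn from a proportional-odds scheme in which
    ``P(rank >= 3) = expit(logit(mast_base_prob) + mast_trend * (year - year0))``,
    so a positive trend makes mast failures rarer and full masts more
    frequent; ranks are independent across regions given the year.
    """
    rng = _rng(cfg.seed, "mast")
    y0, y1 = cfg.years
    years = np.arange(y0 - 1, y1 + 1)  # include the year before the first census
    base = logit(cfg.mast_base_prob)
    rows = []
    for region in cfg.regions:
        u = rng.uniform(size=len(years))
        for y, uu in zip(years, u):
            p_ge = expit(base + _MAST_CUT_OFFSETS + cfg.mast_trend * (y - y0))
            rank = int(np.sum(uu < p_ge))
            rows.append((region, int(y), rank))
    return pd.DataFrame(rows, columns=["region", "year", "rank"])


def simulate_crops(cfg: GeneratorConfig) -> pd.DataFrame:
    """Null crop-area covariates (% of region area), unrelated to growth."""
    rng = _rng(cfg.seed, "crops")
    y0, y1 = cfg.years
    years = np.arange(y0 - 1, y1 + 1)
    rows = []
    for region in cfg.regions:
        corn = np.clip(rng.normal(10.0, 2.0, len(years)), 0.1, None)
        potato = np.clip(rng.normal(5.0, 1.0, len(years)), 0.1, None)
        for y, c, p in zip(years, corn, potato):
            rows.append((region, int(y), float(c), float(p)))
    return pd.DataFrame(rows, columns=["region", "year", "corn_pct", "potato_pct"])


# ---------------------------------------------------------------------------
# population


def _raw_predictors(cfg: GeneratorConfig, climate, mast, crops):
    """Raw predictor arrays (region x simulated year), density excepted."""
    y0, y1 = cfg.years
    sim_years = np.arange(y0 + 1, y1 + 1)
    census = cfg.census_years
    regions = cfg.regions
    R, T = len(regions), len(sim_years)

    tab = preprocess.seasonal_table(climate)
    tmean = tab.pivot_table(index=["region", "year"], columns="season", values="tmean")

    raw: dict[str, np.ndarray] = {}
    for col, (season, off) in preprocess.SEASONAL_PREDICTORS.items():
        key = pd.MultiIndex.from_product([regions, (sim_years + off).tolist()])
        raw[col] = tmean[season].reindex(key).to_numpy().reshape(R, T)

    lt = preprocess.longterm_table(climate, cfg.lt_window())
    for col in ("lt_winter_t", "lt_summer_t", "lt_summer_precip", "lt_yearly_precip"):
        vals = lt[col].reindex(regions).to_numpy()
        raw[col] = np.repeat(vals[:, None], T, axis=1)

    binary: dict[str, bool] = {}
    prev_key = pd.MultiIndex.from_product([regions, (sim_years - 1).tolist()])
    if mast is not None:
        mr = mast.groupby(["region", "year"])["rank"].mean()
        raw["mast_prev"] = (mr.reindex(prev_key).to_numpy().reshape(R, T) >= 3).astype(float)
        binary["mast_prev"] = True
    if crops is not None:
        ck = crops.set_index(["region", "year"])
        for col in preprocess.CROP_PREDICTORS:
            raw[col] = ck[col].reindex(prev_key).to_numpy().reshape(R, T)

    return raw, binary, sim_years


def _standardize_over(raw, binary, retain_mask):
    """Standardize each raw predictor over the retained analysis cells."""
    z = {}
    for col, m in raw.items():
        vals = m[retain_mask]
        is_bin = binary.get(col, False)
        if not is_bin and np.std(vals, ddof=1) == 0:
            z[col] = np.zeros_like(m)  # degenerate under selection; centred out
            continue
        _, rec = preprocess.standardize(vals, binary=is_bin, name=col)
        z[col] = rec.apply(m)
    return z


def simulate_population(
    cfg: GeneratorConfig,
    climate: pd.DataFrame,
    mast: pd.DataFrame | None = None,
    crops: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Bag series driven by the configured coefficients (multi-pass scheme).

    Returns the bags table (country, region, year, bag, area_km2).
    Region areas are drawn once per region; the initial bag realises
    ``density_init`` animals shot per km^2.  Because the density proxy
    and the set of rows surviving the low-density exclusion both depend
    on the simulated bags, the generator runs three passes with an
    identical noise stream, each time re-standardizing every predictor
    (and re-centring the density proxy) over the rows the preprocessing
    stage will actually retain, so generating and recovered coefficients
    share one scale up to a second-order discrepancy.
    """
    validate_coefficients(cfg.coefficients)
    needs_mast = any("mast_prev" in t.split(":") for t in cfg.coefficients)
    if needs_mast and mast is None:
        raise ValueError("coefficients reference mast_prev but no mast series supplied")

    raw, binary, sim_years = _raw_predictors(cfg, climate, mast, crops)
    R, T = cfg.n_regions, len(sim_years)
    rng = _rng(cfg.seed, "population")
    areas = rng.uniform(500.0, 2000.0, R)
    # persistent regional density differences (log-normal around density_init),
    # partly tied to how mild the regional climate is: warm regions carry
    # denser populations, as in the emulated system
    s, rho = cfg.density_spread_sd, cfg.density_climate_corr
    ltw = raw["lt_winter_t"][:, 0]
    ltw_n = (ltw - ltw.mean()) / ltw.std() if ltw.std() > 0 else np.zeros(R)
    dens0 = cfg.density_init * np.exp(
        s * (rho * ltw_n + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=R)))
    u_country_by = {c: e for c, e in zip(
        sorted(set(cfg.region_country.values())),
        _rng(cfg.seed, "country_effects").normal(0.0, cfg.country_sd, cfg.n_countries))}
    u_region = _rng(cfg.seed, "region_effects").normal(0.0, cfg.region_sd, R)
    u = np.array([u_country_by[cfg.region_country[r]] for r in cfg.regions]) + u_region
    eps = rng.normal(0.0, cfg.residual_sd, size=(R, T))

    census_mask = sim_years - cfg.years[0] >= 5  # rows with a full density proxy
    retain = np.repeat(census_mask[None, :], R, axis=0)
    dens_ref = (float(dens0.mean()), float(dens0.std()) + 0.1 * cfg.density_init)
    bags = None
    for _ in range(3):
        z = _standardize_over(raw, binary, retain)
        bags, bag_matrix, d5 = _run_population_pass(
            cfg, z, sim_years, areas, dens0, u, eps, dens_ref)
        retain = _retained_rows(cfg, bag_matrix, areas, census_mask)
        if retain.sum() < 2:  # degenerate collapse; keep first-pass output
            break
        vals = d5[retain]
        if len(vals) >= 2 and np.std(vals, ddof=1) > 0:
            dens_ref = (float(np.mean(vals)), float(np.std(vals, ddof=1)))
    return bags


def _retained_rows(cfg, bag, areas, census_mask):
    """Mask of (region, sim-year) cells surviving the pipeline's exclusions:
    the census year and its five prior bag years all above the density floor."""
    dens_ok = (bag / areas[:, None]) >= preprocess.DEFAULT_MIN_DENSITY  # (R, T+1)
    R, T1 = dens_ok.shape
    retain = np.zeros((R, T1 - 1), dtype=bool)
    for j in range(T1 - 1):
        if not census_mask[j]:
            continue
        retain[:, j] = dens_ok[:, j - 4:j + 2].all(axis=1)  # 5 prior years + census year
    return retain


def _run_population_pass(cfg, z, sim_years, areas, dens0, u, eps, dens_ref):
    R, T = cfg.n_regions, len(sim_years)
    y0 = cfg.years[0]
    dmean, dsd = dens_ref
    bag = np.empty((R, T + 1))
    bag[:, 0] = np.maximum(1.0, np.round(dens0 * areas))
    coeff = dict(cfg.coefficients)
    for j, year in enumerate(sim_years):
        have_d5 = year - y0 >= 5
        if have_d5:
            # bag[:, j] is the bag of year-1; columns j-4..j are the 5 prior years
            d5 = bag[:, j - 4:j + 1].mean(axis=1) / areas
            zd = (d5 - dmean) / (2.0 * dsd)
        else:
            zd = np.zeros(R)
        lin = np.zeros(R)
        for term, beta in coeff.items():
            x = np.ones(R)
            for part in term.split(":"):
                x = x * (zd if part == "density5" else z[part][:, j])
            lin += beta * x
        lam = cfg.baseline() + lin + u + eps[:, j]
        lam = np.maximum(lam, LAMBDA_FLOOR)
        bag[:, j + 1] = np.maximum(1.0, np.round(bag[:, j] * lam))

    years_all = np.arange(y0, cfg.years[1] + 1)
    rows = []
    for i, r in enumerate(cfg.regions):
        country = cfg.region_country[r]
        for k, y in enumerate(years_all):
            rows.append((country, r, int(y), float(bag[i, k]), float(areas[i])))
    bags_df = pd.DataFrame(rows, columns=["country", "region", "year", "bag", "area_km2"])
    # raw (unstandardized) density-proxy values for recalibration
    d5_matrix = np.full((R, T), np.nan)
    for j, year in enumerate(sim_years):
        if year - y0 >= 5:
            d5_matrix[:, j] = bag[:, j - 4:j + 1].mean(axis=1) / areas
    return bags_df, bag, d5_matrix


# ---------------------------------------------------------------------------
# accidents and body mass


def simulate_accidents(
    bags: pd.DataFrame,
    detectability: float = 1e-3,
    noise_sd: float = 0.1,
    vehicle_growth: float = 0.02,
    seed: int = 0,
    vehicles0: float = 2_000_000.0,
) -> pd.DataFrame:
    """National traffic-accident counts proportional to bag totals.

    accidents = detectability x national bag total x (vehicles/vehicles0)
    x lognormal noise; registered vehicles grow geometrically.
    """
    if detectability <= 0:
        raise ValueError("detectability must be positive")
    rng = _rng(seed, "accidents")
    nat = bags.groupby(["country", "year"], as_index=False)["bag"].sum()
    out = []
    for country, g in nat.groupby("country"):
        g = g.sort_values("year")
        t = g["year"].to_numpy(int) - int(g["year"].min())
        vehicles = vehicles0 * (1.0 + vehicle_growth) ** t
        noise = np.exp(rng.normal(0.0, noise_sd, len(g))) if noise_sd > 0 else 1.0
        acc = detectability * g["bag"].to_numpy(float) * (vehicles / vehicles0) * noise
        for y, a, v in zip(g["year"], acc, vehicles):
            out.append((country, int(y), float(a), float(v)))
    return pd.DataFrame(out, columns=["country", "year", "accidents", "vehicles"])


def simulate_bodymass(
    cfg: GeneratorConfig,
    slope: float = -3.9,
    sex_offset: float = 25.7,
    noise_sd: float = 8.0,
    baseline: float = 75.0,
) -> pd.DataFrame:
    """Adult body mass declining with regional long-term winter temperature.

    mass = baseline + slope * long-term winter temp + sex_offset * male
    + N(0, noise_sd); one male and one female record per region; live
    masses (no dressing conversion needed).
    """
    if cfg.n_regions < 5:
        raise ValueError("need at least 5 regions for a meaningful body-mass fit")
    rng = _rng(cfg.seed, "bodymass")
    lo, hi = cfg.longterm_winter_range
    ltw = np.linspace(lo, hi, cfg.n_regions)
    rows = []
    for r, t in zip(cfg.regions, ltw):
        for sex, male in (("f", 0.0), ("m", 1.0)):
            mass = baseline + slope * t + sex_offset * male + rng.normal(0.0, noise_sd)
            rows.append((r, sex, float(mass), False, "central", float(t)))
    return pd.DataFrame(
        rows, columns=["region", "sex", "mass_kg", "dressed", "zone", "longterm_winter_c"])


# ---------------------------------------------------------------------------
# bundles


def europe_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """European study conditions: 60 regions x 12 countries, European ground truth."""
    return GeneratorConfig(seed=seed, **overrides)


def austria_config(seed: int = 0, n_census_years: int = 100, **overrides) -> GeneratorConfig:
    """Austrian food-availability conditions: 6 regions, mast-driven truth.

    ``n_census_years`` growth rates per region (default 100; 23 gives
    approximately the real subset's n = 135).
    """
    y1 = 2013
    y0 = y1 - n_census_years - 4
    defaults = dict(
        n_regions=6, n_countries=1, years=(y0, y1),
        longterm_winter_range=(-3.0, 3.0),
        coefficients=dict(AUSTRIA_TRUTH),
    )
    defaults.update(overrides)
    return GeneratorConfig(seed=seed, **defaults)


def generate_bundle(
    cfg: GeneratorConfig,
    with_accidents: bool = True,
    with_bodymass: bool = True,
    with_crops: bool = False,
) -> SyntheticBundle:
    """Generate a full coherent bundle under one seed."""
    climate = simulate_climate(cfg)
    needs_mast = any("mast_prev" in t.split(":") for t in cfg.coefficients)
    mast = simulate_mast(cfg) if needs_mast else None
    crops = simulate_crops(cfg) if with_crops else None
    bags = simulate_population(cfg, climate, mast=mast, crops=crops)
    accidents = simulate_accidents(bags, seed=cfg.seed) if with_accidents else None
    bodymass = simulate_bodymass(cfg) if with_bodymass else None
    bundle = SyntheticBundle(bags, climate, mast, accidents, bodymass, crops, cfg)
    bundle.validate()
    return bundle


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write the delimited tables plus a truth.yaml echoing the configuration."""
    import os

    os.makedirs(outdir, exist_ok=True)
    bundle.bags.to_csv(os.path.join(outdir, "bags.csv"), index=False)
    bundle.climate.to_csv(os.path.join(outdir, "climate.csv"), index=False)
    for name in ("mast", "accidents", "bodymass", "crops"):
        df = getattr(bundle, name)
        if df is not None:
            df.to_csv(os.path.join(outdir, f"{name}.csv"), index=False)
    truth = asdict(bundle.truth)
    truth["coefficients"] = dict(truth["coefficients"])
    truth["years"] = list(truth["years"])
    truth["longterm_winter_range"] = list(truth["longterm_winter_range"])
    with open(os.path.join(outdir, "truth.yaml"), "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)
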