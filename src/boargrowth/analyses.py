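"""End-to-end configured analyses.

Four named pipelines, each a thin orchestration over preprocess,
mixed_models, model_averaging and diagnostics:

* :func:`run_europe` — the European growth-rate model: six seasonal
  temperatures, long-term winter/summer temperature and their
  interactions with the current-year values, long-term precipitation,
  the 5-year density proxy and its interaction with winter temperature;
  nested country/region random intercepts.
* :func:`run_austria` — the Austrian food-availability model: the terms
  retained from the European analysis plus previous-year beech mast
  (binary), crop areas, the mast x winter interaction, and the
  census-year mast category as an extra random factor.
* :func:`run_mast_trends` — three binomial random-intercept models for
  the yearly frequencies of mast failure, moderate and full mast.
* :func:`run_bodymass` — the body-mass cline: mass ~ long-term winter
  temperature x sex, multi-model averaged ordinary regression (raw
  scale, so the slope is in kg per degC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, preprocess
from .mixed_models import FittedModel, ModelSpec, fit_glmm_binomial
from .model_averaging import (
    AveragingResult,
    ModelSet,
    average_all,
    build_table,
    conditional_average,
    fit_model_set,
)

#: term vocabulary of the European growth-rate model
EUROPE_TERMS = (
    "winter_t", "lt_winter_t", "prior_autumn_t", "density5", "summer_t",
    "prior_spring_t", "prior_summer_t", "lt_summer_t", "lt_summer_precip",
    "lt_yearly_precip", "spring_t",
    "winter_t:lt_winter_t", "winter_t:density5", "summer_t:lt_summer_t",
)

#: term vocabulary of the Austrian food-availability model
AUSTRIA_TERMS = (
    "winter_t", "mast_prev", "prior_autumn_t", "lt_winter_t", "density5",
    "potato_pct", "corn_pct", "summer_t", "prior_spring_t",
    "mast_prev:winter_t", "winter_t:lt_winter_t",
    "mast_prev:lt_winter_t", "mast_prev:density5",
)

DISPLAY_NAMES = {
    "winter_t": "winter temperature",
    "lt_winter_t": "long-term winter temperature",
    "prior_autumn_t": "prior autumn temperature",
    "density5": "population density",
    "summer_t": "summer temperature",
    "spring_t": "spring temperature",
    "prior_spring_t": "prior spring temperature",
    "prior_summer_t": "prior summer temperature",
    "lt_summer_t": "long-term summer temperature",
    "lt_summer_precip": "long-term summer precipitation",
    "lt_yearly_precip": "long-term yearly precipitation",
    "mast_prev": "mast",
    "corn_pct": "area under cultivation of corn",
    "potato_pct": "area under cultivation of potatoes",
    "ltw": "long-term winter temperature",
    "sex_male": "sex (male)",
}


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run (loadable from YAML)."""

    analysis: str = "europe"
    bags: str | None = None
    climate: str | None = None
    mast: str | None = None
    crops: str | None = None
    accidents: str | None = None
    bodymass: str | None = None
    exclusion_list: str | None = None
    terms: tuple[str, ...] | None = None
    longterm_window: tuple[int, int] | None = None
    alpha: float = 0.05
    min_density: float = preprocess.DEFAULT_MIN_DENSITY
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "terms" in raw and raw["terms"] is not None:
            raw["terms"] = tuple(raw["terms"])
        if "longterm_window" in raw and raw["longterm_window"] is not None:
            raw["longterm_window"] = tuple(raw["longterm_window"])
        return cls(**raw)


@dataclass
class GrowthAnalysisResult:
    """Everything a growth-rate pipeline run produces."""

    natural: AveragingResult
    zero: AveragingResult
    conditional: AveragingResult
    model_set: ModelSet
    growth: pd.DataFrame
    exclusions: pd.DataFrame
    transforms: dict
    n: int

    def report(self, alpha: float = 0.05) -> pd.DataFrame:
        return build_table(self.conditional, DISPLAY_NAMES, alpha=alpha)


def model_frame(growth: pd.DataFrame, terms: tuple[str, ...],
                extra_random: tuple[str, ...] = ()) -> pd.DataFrame:
    """Modelling frame: standardized predictors under their base names.

    Region labels are made unique within country so nesting is a plain
    pair of random-intercept factors.
    """
    mains = sorted({p for t in terms for p in t.split(":")})
    frame = pd.DataFrame({
        "lam": growth["lam"].to_numpy(float),
        "country": growth["country"].astype(str),
        "region": growth["country"].astype(str) + "/" + growth["region"].astype(str),
    })
    for m in mains:
        zcol = m + "_z"
        if zcol not in growth.columns:
            raise ValueError(f"predictor {m!r} missing from the growth table")
        frame[m] = growth[zcol].to_numpy(float)
    for col in extra_random:
        frame[col] = growth[col].to_numpy()
    return frame


def _run_growth(
    growth: pd.DataFrame, exclusions: pd.DataFrame, transforms: dict,
    terms: tuple[str, ...], random_groups: tuple[str, ...],
    extra_random: tuple[str, ...] = (), alpha: float = 0.05,
    max_models: int | None = 100_000,
) -> GrowthAnalysisResult:
    frame = model_frame(growth, terms, extra_random=extra_random)
    spec = ModelSpec("lam", terms, random_groups, "gaussian")
    model_set = fit_model_set(frame, spec, max_models=max_models)
    return GrowthAnalysisResult(
        natural=average_all(model_set, "natural"),
        zero=average_all(model_set, "zero"),
        conditional=conditional_average(model_set, alpha=alpha),
        model_set=model_set, growth=growth, exclusions=exclusions,
        transforms=transforms, n=len(frame),
    )


def run_europe(
    bags: pd.DataFrame,
    climate: pd.DataFrame,
    exclusion_list=(),
    terms: tuple[str, ...] = EUROPE_TERMS,
    alpha: float = 0.05,
    min_density: float = preprocess.DEFAULT_MIN_DENSITY,
    lt_window: tuple[int, int] | None = None,
    max_models: int | None = 100_000,
) -> GrowthAnalysisResult:
    """The European growth-rate multi-model average."""
    growth, excl, transforms = preprocess.build_growth_table(
        bags, climate, exclusion_list=exclusion_list,
        min_density=min_density, lt_window=lt_window)
    return _run_growth(growth, excl, transforms, tuple(terms),
                       ("country", "region"), alpha=alpha, max_models=max_models)


def run_austria(
    bags: pd.DataFrame,
    climate: pd.DataFrame,
    mast: pd.DataFrame,
    crops: pd.DataFrame | None = None,
    exclusion_list=(),
    terms: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    min_density: float = preprocess.DEFAULT_MIN_DENSITY,
    lt_window: tuple[int, int] | None = None,
    mast_random: bool = True,
    max_models: int | None = 100_000,
) -> GrowthAnalysisResult:
    """The Austrian food-availability multi-model average.

    Adds previous-year mast (binary), optional crop-area covariates and,
    when ``mast_random``, the census-year mast category as an extra
    random-intercept factor accounting for mast effects on hunting
    success.
    """
    if terms is None:
        terms = AUSTRIA_TERMS if crops is not None else tuple(
            t for t in AUSTRIA_TERMS if "pct" not in t)
    growth, excl, transforms = preprocess.build_growth_table(
        bags, climate, mast=mast, crops=crops, exclusion_list=exclusion_list,
        min_density=min_density, lt_window=lt_window)
    extra: tuple[str, ...] = ()
    random_groups: tuple[str, ...] = ("region",)
    if mast_random:
        mr = mast.groupby(["region", "year"])["rank"].mean()
        key = pd.MultiIndex.from_arrays([growth["region"], growth["year"]])
        growth = growth.copy()
        growth["mast_level"] = np.round(mr.reindex(key).to_numpy()).astype(int)
        extra = ("mast_level",)
        random_groups = ("region", "mast_level")
    return _run_growth(growth, excl, transforms, tuple(terms), random_groups,
                       extra_random=extra, alpha=alpha, max_models=max_models)


def run_mast_trends(mast: pd.DataFrame, since: int | None = 1976) -> dict[str, FittedModel]:
    """Binomial mixed-model time trends of the three mast outcome classes.

    For each of failure (rank <= 1), moderate (1 < rank <= 3) and full
    (rank > 3): outcome ~ year with a region random intercept.  Classes
    never observed are skipped with a message instead of a model.
    """
    mr = mast.groupby(["region", "year"], as_index=False)["rank"].mean()
    if since is not None:
        mr = mr[mr["year"] >= since]
    mr["category"] = [preprocess.mast_category(r) for r in mr["rank"]]
    # centred year keeps the intercept interpretable and the fit well-scaled
    mr["year_c"] = mr["year"] - mr["year"].mean()
    out: dict[str, FittedModel] = {}
    for cat in ("failure", "moderate", "full"):
        y = (mr["category"] == cat).astype(float)
        if y.sum() == 0 or y.sum() == len(y):
            out[cat] = None
            continue
        frame = pd.DataFrame(dict(outcome=y, year_c=mr["year_c"], region=mr["region"]))
        out[cat] = fit_glmm_binomial(
            frame, ModelSpec("outcome", ("year_c",), ("region",), "binomial"))
    return out


def run_bodymass(bodymass: pd.DataFrame, alpha: float = 0.05) -> tuple[AveragingResult, ModelSet]:
    """Multi-model averaged body-mass cline (kg per degC, raw scale).

    Dressed masses are converted to live mass by the zone factor; both
    sexes must be present for the interaction term to be retained.
    """
    bm = bodymass.copy()
    bm["mass_live"] = [
        preprocess.dressed_to_live(m, z, bool(d))
        for m, z, d in zip(bm["mass_kg"], bm["zone"], bm["dressed"])
    ]
    if bm["region"].nunique() < 2:
        raise ValueError("need body-mass data from more than one region")
    bm["ltw"] = bm["longterm_winter_c"].astype(float)
    bm["sex_male"] = (bm["sex"].astype(str).str.lower().str.startswith("m")).astype(float)
    terms: tuple[str, ...] = ("ltw", "sex_male", "ltw:sex_male")
    if bm["sex_male"].nunique() < 2:
        import warnings

        warnings.warn("only one sex present; dropping sex terms", stacklevel=2)
        terms = ("ltw",)
    spec = ModelSpec("mass_live", terms, (), "gaussian")
    ms = fit_model_set(bm, spec)
    return conditional_average(ms, alpha=alpha), ms


def run_validate(bags: pd.DataFrame, accidents: pd.DataFrame) -> pd.DataFrame:
    """Hunting-bag validity: correlations with corrected accident counts."""
    return diagnostics.validate_bags(bags, accidents)


def residual_semivariograms(
    result: GrowthAnalysisResult,
    station_lonlat: dict[str, tuple[float, float]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Temporal (and, given station coordinates, spatial) semivariograms
    of the model-averaged residuals."""
    from .model_averaging import averaged_residuals

    resid = averaged_residuals(result.model_set)
    g = result.growth
    out = {"temporal": diagnostics.empirical_semivariogram(
        resid, years=g["year"].to_numpy(), ids=g["region"].to_numpy())}
    if station_lonlat is not None:
        pts = np.array([station_lonlat[r] for r in g["region"]])
        out["spatial"] = diagnostics.empirical_semivariogram(
            resid, coords=diagnostics.lonlat_to_km(pts))
    return out
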