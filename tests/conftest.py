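import numpy as np
import pandas as pd
import pytest

from boargrowth import synthetic


@pytest.fixture(scope="session")
def small_cfg():
    """A small but fully structured European-style configuration."""
    return synthetic.GeneratorConfig(
        n_regions=12, n_countries=3, years=(1988, 2013), seed=42)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return synthetic.generate_bundle(small_cfg)


@pytest.fixture(scope="session")
def small_growth(small_bundle):
    from boargrowth import preprocess

    cfg = small_bundle.truth
    growth, excl, transforms = preprocess.build_growth_table(
        small_bundle.bags, small_bundle.climate, lt_window=cfg.lt_window())
    return growth, excl, transforms


@pytest.fixture(scope="session")
def small_model_set(small_growth):
    """A fitted candidate set over four terms on the small bundle."""
    from boargrowth import analyses
    from boargrowth.mixed_models import ModelSpec
    from boargrowth.model_averaging import fit_model_set

    growth, _, _ = small_growth
    terms = ("winter_t", "lt_winter_t", "density5", "winter_t:lt_winter_t")
    frame = analyses.model_frame(growth, terms)
    return fit_model_set(frame, ModelSpec("lam", terms, ("country", "region")))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def make_climate(region_months):
    """Small climate frame from {region: {(year, month): (t, p)}}."""
    rows = []
    for region, vals in region_months.items():
        for (y, m), (t, p) in vals.items():
            rows.append((region, y, m, t, p))
    return pd.DataFrame(rows, columns=["region", "year", "month", "tmean_c", "precip_mm"])
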