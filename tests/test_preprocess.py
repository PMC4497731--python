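"""Growth rates, exclusion rules, seasonal climate and standardization."""

import calendar

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boargrowth import preprocess as pp


def bags_frame(bags, area=1.0, years=None, region="R1", country="C1"):
    years = years if years is not None else range(2000, 2000 + len(bags))
    return pd.DataFrame(dict(
        country=country, region=region, year=list(years), bag=list(bags),
        area_km2=area))


class TestComputeLambda:
    def test_simple_ratios(self):
        rows, log = pp.compute_lambda(bags_frame([10, 20, 30]))
        assert np.allclose(rows["lam"], [2.0, 1.5])
        assert len(log) == 0

    def test_low_density_removal_propagates_to_both_ratios(self):
        # year-1 density 5/1000 = 0.005 < 0.01: both the ratio into and out
        # of that year must vanish, leaving only 60/40
        rows, log = pp.compute_lambda(bags_frame([5, 40, 60], area=1000.0))
        assert np.allclose(rows["lam"], [1.5])
        assert list(log["rule"]) == ["low_density"]

    def test_no_ratio_across_year_gaps(self):
        rows, _ = pp.compute_lambda(bags_frame([10, 20], years=[1990, 1992]))
        assert len(rows) == 0

    def test_accounting_bag_rows(self):
        df = bags_frame([5, 40, 60, 3, 50], area=1000.0)
        rows, log = pp.compute_lambda(df)
        kept = len(df) - len(log)
        assert kept == 3  # years 2001, 2002, 2004 survive the density filter
        assert len(rows) == 1  # only 2001->2002 is consecutive


class TestExcludeYears:
    def test_empty_list_is_identity(self):
        rows, _ = pp.compute_lambda(bags_frame([10, 20, 30]))
        assert pp.exclude_years(rows, []).equals(rows)

    def test_matching_rows_removed(self):
        df = bags_frame([10, 20, 30, 40])
        rows, _ = pp.compute_lambda(df)
        out = pp.exclude_years(rows, [("R1", 2001), ("R1", 2002), ("R1", 2003)])
        assert len(out) == len(rows) - 3

    def test_unmatched_entry_warns_not_fails(self):
        rows, _ = pp.compute_lambda(bags_frame([10, 20]))
        with pytest.warns(UserWarning, match="matched no row"):
            out = pp.exclude_years(rows, [("nowhere", 1900)])
        assert out.equals(rows)


def climate_one_winter(dec, jan, feb, year=2001, region="R1"):
    rows = [(region, year - 1, 12, dec, 0.0), (region, year, 1, jan, 0.0),
            (region, year, 2, feb, 0.0)]
    return pd.DataFrame(rows, columns=["region", "year", "month", "tmean_c", "precip_mm"])


class TestSeasonalClimate:
    def test_day_weighted_winter_mean(self):
        # (31*-2 + 31*-4 + 28*0)/90 for a non-leap February
        cl = climate_one_winter(-2.0, -4.0, 0.0, year=2001)
        got = pp.seasonal_mean(cl, "R1", "winter", 2001)
        assert got == pytest.approx((31 * -2 + 31 * -4) / 90, abs=1e-12)

    def test_constant_season_mean(self):
        cl = climate_one_winter(5.0, 5.0, 5.0)
        assert pp.seasonal_mean(cl, "R1", "winter", 2001) == pytest.approx(5.0)

    def test_leap_year_february_weight(self):
        # 2004 is a leap year: Feb weighs 29 of 91 days
        non_leap = pp.seasonal_mean(climate_one_winter(-2, -4, 0, year=2001), "R1", "winter", 2001)
        leap = pp.seasonal_mean(climate_one_winter(-2, -4, 0, year=2004), "R1", "winter", 2004)
        assert leap == pytest.approx((31 * -2 + 31 * -4) / 91, abs=1e-12)
        assert leap != non_leap

    def test_precip_sum_and_missing_month(self):
        cl = pd.DataFrame(
            [("R1", 2001, 3, 5.0, 10.0), ("R1", 2001, 4, 6.0, 20.0), ("R1", 2001, 5, 7.0, 30.0)],
            columns=["region", "year", "month", "tmean_c", "precip_mm"])
        assert pp.seasonal_precip_sum(cl, "R1", "spring", 2001) == pytest.approx(60.0)
        with pytest.raises(ValueError, match="incomplete"):
            pp.seasonal_mean(cl.iloc[:2], "R1", "spring", 2001)

    def test_season_day_weights_tile_the_year(self):
        # the four seasonal windows of census year t cover Dec(t-1)..Nov(t)
        for year in (2001, 2004):
            total = sum(
                pp.days_in_month(year - 1 if m == 12 else year, m)
                for months in pp.SEASON_MONTHS.values() for m in months)
            assert total == (366 if calendar.isleap(year) else 365)


class TestLongTermMean:
    def make(self, values, region="R1"):
        rows = []
        for y, v in values.items():
            for m in range(1, 13):
                rows.append((region, y, m, v, 50.0))
        return pd.DataFrame(rows, columns=["region", "year", "month", "tmean_c", "precip_mm"])

    def test_constant_series(self):
        cl = self.make({y: 3.0 for y in range(1972, 2004)})
        assert pp.longterm_mean(cl, "R1", "winter_t", (1973, 2002)) == pytest.approx(3.0)

    def test_alternating_series_averages_to_zero(self):
        cl = self.make({y: (1.0 if y % 2 else -1.0) for y in range(1972, 2004)})
        assert pp.longterm_mean(cl, "R1", "summer_t", (1973, 2002)) == pytest.approx(0.0)

    def test_incomplete_window_names_missing_years(self):
        cl = self.make({y: 3.0 for y in range(1990, 2003)})
        with pytest.raises(ValueError, match="missing"):
            pp.longterm_mean(cl, "R1", "winter_t", (1973, 2002))


class TestDensityProxy:
    def test_five_year_mean(self):
        df = bags_frame([1, 1, 1, 1, 2, 9], years=range(1995, 2001))
        assert pp.density_proxy(df, "R1", 2000) == pytest.approx(1.2)

    def test_constant_density(self):
        df = bags_frame([3] * 6, years=range(1995, 2001))
        assert pp.density_proxy(df, "R1", 2000) == pytest.approx(3.0)

    def test_missing_prior_year_raises(self):
        df = bags_frame([1, 1, 1, 1], years=[1995, 1996, 1998, 1999])
        with pytest.raises(ValueError, match="missing"):
            pp.density_proxy(df, "R1", 2000)


class TestMastCoding:
    @pytest.mark.parametrize("rank,binary,category", [
        (3.0, 1, "moderate"),
        (2.5, 0, "moderate"),
        (1.0, 0, "failure"),
        (4.0, 1, "full"),
        (0.0, 0, "failure"),
    ])
    def test_binary_and_category(self, rank, binary, category):
        assert pp.mast_binary(rank) == binary
        assert pp.mast_category(rank) == category

    def test_code_mast_uses_previous_year_and_averages(self):
        ranks = pd.DataFrame(dict(region=["R1", "R1", "R1"], year=[2000, 2000, 2001],
                                  rank=[2.0, 3.0, 4.0]))
        out = pp.code_mast(ranks, 2001)
        # 2000 measurements average to 2.5 -> binary 0, moderate
        assert out.loc[0, "rank_prev"] == pytest.approx(2.5)
        assert out.loc[0, "mast_prev"] == 0
        assert out.loc[0, "category_prev"] == "moderate"

    def test_rank_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pp.mast_binary(4.5)


class TestStandardize:
    def test_continuous_half_sd(self):
        z, rec = pp.standardize([1.0, 2.0, 3.0])
        assert np.allclose(z, [-0.5, 0.0, 0.5])
        assert rec.sd == pytest.approx(1.0)

    def test_binary_centred_only(self):
        z, rec = pp.standardize([0, 0, 0, 1], binary=True)
        assert set(np.round(z, 10)) == {-0.25, 0.75}

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pp.standardize([2.0, 2.0, 2.0], name="flat")

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.floats(-50, 50), min_size=4, max_size=30).filter(
        lambda v: np.std(v, ddof=1) > 1e-6))
    def test_standardized_sd_is_half_and_invertible(self, values):
        z, rec = pp.standardize(values)
        assert np.std(z, ddof=1) == pytest.approx(0.5, rel=1e-9)
        # a raw-scale slope survives the round trip through the z scale
        slope_raw = 1.7
        slope_std = slope_raw * (2.0 * rec.sd)
        assert rec.invert_slope(slope_std) == pytest.approx(slope_raw, rel=1e-9)


class TestDressedToLive:
    @pytest.mark.parametrize("mass,zone,dressed,expected", [
        (80.0, "central", True, 100.0),
        (80.0, "eastern", True, 92.0),
        (80.0, None, False, 80.0),
    ])
    def test_factors(self, mass, zone, dressed, expected):
        assert pp.dressed_to_live(mass, zone, dressed) == pytest.approx(expected)

    def test_unknown_zone_rejected(self):
        with pytest.raises(ValueError, match="zone"):
            pp.dressed_to_live(80.0, "atlantis", True)


class TestGrowthTable:
    def test_exclusion_accounting(self, small_bundle):
        from boargrowth import preprocess

        cfg = small_bundle.truth
        growth, excl, _ = preprocess.build_growth_table(
            small_bundle.bags, small_bundle.climate, lt_window=cfg.lt_window())
        # every retained row has a positive growth rate and full predictors
        assert (growth["lam"] > 0).all()
        assert not growth[[c for c in growth.columns if c.endswith("_z")]].isna().any().any()
        # the ledger never names a region unknown to the bags table
        assert set(excl["region"]) <= set(small_bundle.bags["region"])

    def test_lambda_matches_generator_up_to_rounding(self, small_bundle, small_growth):
        growth, _, _ = small_growth
        bags = small_bundle.bags.set_index(["region", "year"])["bag"]
        for _, row in growth.head(25).iterrows():
            expect = bags[(row["region"], row["year"])] / bags[(row["region"], row["year"] - 1)]
            assert row["lam"] == pytest.approx(expect, rel=1e-12)
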