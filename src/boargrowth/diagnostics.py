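"""Residual and data-validity diagnostics.

* empirical semivariograms (spatial, temporal, spatio-temporal) of
  model-averaged residuals, for checking that nothing structured is
  left over in space or time;
* great-circle distance matrices between climate stations;
* the hunting-bag validity check against vehicle-corrected wild boar
  traffic-accident counts (levels and year-to-year relative changes);
* an advisory normality summary of residuals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

EARTH_RADIUS_KM = 6371.0


def empirical_semivariogram(
    values,
    coords=None,
    years=None,
    ids=None,
    space_bin_km: float = 50.0,
    space_cutoff_km: float | None = None,
    max_time_lag: int | None = None,
) -> pd.DataFrame:
    """Binned empirical semivariogram gamma(h) = mean squared difference / 2.

    ``coords`` (n x 2, planar km) selects spatial binning, ``years``
    temporal binning (1-year lags); both together give the joint
    spatio-temporal variant.  With ``ids`` given, only pairs sharing an
    identifier are compared — the usual choice for purely temporal
    variograms of multi-region residual series, where cross-region
    pairs would sit at the sill for every lag and mask the structure.
    Spatial bins are ``space_bin_km`` wide up to ``space_cutoff_km``
    (default half the maximum pairwise distance).  Empty bins report
    NaN with pair count 0.
    """
    z = np.asarray(values, float)
    n = len(z)
    if n < 2:
        raise ValueError("need at least two observations")
    if coords is None and years is None:
        raise ValueError("supply coords (spatial) and/or years (temporal)")
    iu, ju = np.triu_indices(n, k=1)
    if ids is not None:
        ids = np.asarray(ids)
        same = ids[iu] == ids[ju]
        iu, ju = iu[same], ju[same]
    sq = (z[iu] - z[ju]) ** 2

    sdist = tlag = None
    if coords is not None:
        c = np.asarray(coords, float)
        sdist = np.hypot(c[iu, 0] - c[ju, 0], c[iu, 1] - c[ju, 1])
        cutoff = 0.5 * sdist.max() if space_cutoff_km is None else space_cutoff_km
        sedges = np.arange(0.0, cutoff + space_bin_km, space_bin_km)
        if len(sedges) < 2:
            sedges = np.array([0.0, max(cutoff, space_bin_km)])
    if years is not None:
        yr = np.asarray(years, float)
        tlag = np.rint(np.abs(yr[iu] - yr[ju])).astype(int)
        tmax = int(tlag.max()) if max_time_lag is None else max_time_lag

    rows = []
    if sdist is not None and tlag is not None:
        for k in range(len(sedges) - 1):
            smask = (sdist >= sedges[k]) & (sdist < sedges[k + 1])
            for lag in range(tmax + 1):
                m = smask & (tlag == lag)
                rows.append(dict(
                    space_lo=sedges[k], space_mid=0.5 * (sedges[k] + sedges[k + 1]),
                    space_hi=sedges[k + 1], time_lag=lag,
                    gamma=float(sq[m].mean() / 2.0) if m.any() else np.nan,
                    n_pairs=int(m.sum()), direction="spatiotemporal"))
    elif sdist is not None:
        for k in range(len(sedges) - 1):
            m = (sdist >= sedges[k]) & (sdist < sedges[k + 1])
            rows.append(dict(
                bin_lo=sedges[k], bin_mid=0.5 * (sedges[k] + sedges[k + 1]),
                bin_hi=sedges[k + 1],
                gamma=float(sq[m].mean() / 2.0) if m.any() else np.nan,
                n_pairs=int(m.sum()), direction="spatial"))
    else:
        for lag in range(tmax + 1):
            m = tlag == lag
            rows.append(dict(
                bin_lo=lag, bin_mid=lag, bin_hi=lag,
                gamma=float(sq[m].mean() / 2.0) if m.any() else np.nan,
                n_pairs=int(m.sum()), direction="temporal"))
    return pd.DataFrame(rows)


def variogram_trend(vgm: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlation of gamma with lag (monotone-trend screen)."""
    v = vgm.dropna(subset=["gamma"])
    lag = v["bin_mid"] if "bin_mid" in v else v["time_lag"]
    if len(v) < 3:
        return np.nan, np.nan
    rho, p = stats.spearmanr(lag, v["gamma"])
    return float(rho), float(p)


def station_distance_matrix(stations) -> np.ndarray:
    """Great-circle distances (km, spherical earth) between lon/lat points."""
    pts = np.asarray(stations, float)
    lon, lat = np.radians(pts[:, 0]), np.radians(pts[:, 1])
    if np.any(np.abs(pts[:, 1]) > 90) or np.any(np.abs(pts[:, 0]) > 180):
        raise ValueError("coordinates outside |lon|<=180, |lat|<=90")
    dlon = lon[:, None] - lon[None, :]
    dlat = lat[:, None] - lat[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def lonlat_to_km(stations) -> np.ndarray:
    """Project lon/lat to planar km about the centroid (for variogram bins)."""
    pts = np.asarray(stations, float)
    lat0 = np.radians(pts[:, 1].mean())
    kx = EARTH_RADIUS_KM * np.cos(lat0) * np.pi / 180.0
    ky = EARTH_RADIUS_KM * np.pi / 180.0
    return np.column_stack([(pts[:, 0] - pts[:, 0].mean()) * kx,
                            (pts[:, 1] - pts[:, 1].mean()) * ky])


def validate_bags(bags: pd.DataFrame, accidents: pd.DataFrame) -> pd.DataFrame:
    """Correlate national hunting bags with vehicle-corrected accident counts.

    Per country: Pearson r of levels (bag vs accidents/vehicles) and of
    year-to-year relative changes, with two-sided p-values.  Needs at
    least three overlapping years; zero-variance series report NaN.
    """
    nat = bags.groupby(["country", "year"], as_index=False)["bag"].sum()
    merged = nat.merge(accidents, on=["country", "year"]).sort_values(["country", "year"])
    out = []
    for country, g in merged.groupby("country"):
        if len(g) < 3:
            raise ValueError(f"need >= 3 overlapping years for {country}, got {len(g)}")
        bag = g["bag"].to_numpy(float)
        corr = g["accidents"].to_numpy(float) / g["vehicles"].to_numpy(float)
        r_lvl, p_lvl = _safe_pearson(bag, corr)
        yrs = g["year"].to_numpy(int)
        step = np.flatnonzero(np.diff(yrs) == 1)
        lam = bag[step + 1] / bag[step]
        dacc = corr[step + 1] / corr[step]
        r_chg, p_chg = _safe_pearson(lam, dacc)
        out.append(dict(country=country, n=len(g), r_levels=r_lvl, p_levels=p_lvl,
                        n_changes=len(lam), r_changes=r_chg, p_changes=p_chg))
    return pd.DataFrame(out)


def _safe_pearson(x, y):
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def normality_report(residuals) -> dict:
    """Skewness, excess kurtosis and a QQ-deviation statistic (advisory only)."""
    r = np.asarray(residuals, float)
    if len(r) < 10:
        raise ValueError("need at least 10 residuals")
    sd = r.std(ddof=1)
    if sd == 0:
        return dict(n=len(r), degenerate=True, skewness=np.nan,
                    excess_kurtosis=np.nan, qq_rmsd=np.nan)
    z = np.sort((r - r.mean()) / sd)
    theo = stats.norm.ppf((np.arange(1, len(r) + 1) - 0.5) / len(r))
    return dict(
        n=len(r), degenerate=False,
        skewness=float(stats.skew(r)),
        excess_kurtosis=float(stats.kurtosis(r)),
        qq_rmsd=float(np.sqrt(np.mean((z - theo) ** 2))),
    )
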