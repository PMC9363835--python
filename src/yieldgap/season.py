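"""Probabilistic growing-season delineation and per-season weather aggregates.

The growing season of a perennial forage crop is bounded by cold, not by
planting: growth effectively stops when mean daily temperature falls below
the crop's base temperature (5 deg C for alfalfa). For each county we
compute, per day of year (DOY), the across-year probability that the daily
growing-degree-day increment (Tmax+Tmin)/2 - Tbase is negative. That
probability is ~1 in winter, ~0 in midsummer, and descends/ascends through
spring/fall shoulders. A straight line is fit through each shoulder and the
season start (last cold day of spring) and end (first cold day of fall) are
read off where the fitted lines cross a probability threshold, 0.2 by
default: up to two sub-base days out of ten have negligible yield effect.

Two distinct uses of "GDD" coexist deliberately: the probability test uses
the UNtruncated increment (which can be negative — otherwise "GDD < 0"
would be impossible), while accumulated seasonal GDD truncates negative
days at zero, as thermal-time accounting always does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

TBASE_C = 5.0
P_THRESHOLD = 0.2


def daily_gdd(tmax, tmin, tbase: float = TBASE_C, truncate: bool = False):
    """Daily growing-degree-day increment (Tmax+Tmin)/2 - Tbase, deg C-day.

    With ``truncate`` the increment is floored at zero (thermal-time
    accumulation); without, it may be negative (cold-day probability test).
    Accepts scalars or arrays.
    """
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmax < tmin):
        raise ValidationError("tmax < tmin")
    g = (tmax + tmin) / 2.0 - tbase
    if truncate:
        g = np.maximum(g, 0.0)
    return g if g.ndim else float(g)


def doy_index(dates: pd.Series) -> np.ndarray:
    """DOY 1..365 with Feb 29 mapped to 0 (callers drop it).

    In leap years every date after Feb 29 is shifted down one so that
    Mar 1 is always DOY 60 and Dec 31 always DOY 365.
    """
    dates = pd.to_datetime(dates)
    doy = dates.dt.dayofyear.to_numpy().copy()
    leap = dates.dt.is_leap_year.to_numpy()
    feb29 = leap & (doy == 60)
    after = leap & (doy > 60)
    doy[after] -= 1
    doy[feb29] = 0
    return doy


@dataclass(frozen=True)
class DOYProbabilityProfile:
    """Per-DOY probability of a sub-base day, pooled over n_years years."""

    fips: str
    p: np.ndarray  # length 365, index d-1 holds DOY d
    n_years: int

    def __post_init__(self):
        if self.p.shape != (365,):
            raise ValidationError("profile must cover DOY 1..365")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValidationError("probabilities outside [0, 1]")


@dataclass(frozen=True)
class GrowingSeason:
    """Delineated season: start/end DOY and the shoulder regressions."""

    fips: str
    start_doy: int
    end_doy: int
    spring_fit: tuple[float, float] | None = None  # (slope, intercept), p on DOY
    fall_fit: tuple[float, float] | None = None
    status: str = "ok"  # ok | year_round | no_season

    @property
    def length(self) -> int:
        return self.end_doy - self.start_doy


def season_length(gs: GrowingSeason) -> int:
    """Season length in days, end_doy - start_doy."""
    return gs.end_doy - gs.start_doy


def doy_probability_profile(series: pd.DataFrame) -> DOYProbabilityProfile:
    """Pooled cold-day probability profile from >= 2 whole calendar years.

    p[d] = (# years whose untruncated GDD on DOY d is < 0) / n_years.
    Feb 29 rows are dropped; later leap-year days shift down one DOY.
    Raises if any (year, DOY) cell is missing.
    """
    if series["fips"].nunique() != 1:
        raise ValidationError("profile expects a single-county series")
    fips = series["fips"].iloc[0]
    dates = pd.to_datetime(series["date"])
    years = dates.dt.year.to_numpy()
    doy = doy_index(dates)
    keep = doy > 0  # drop Feb 29
    years, doy = years[keep], doy[keep]
    g = daily_gdd(series["tmax"].to_numpy()[keep], series["tmin"].to_numpy()[keep])

    year_list = np.unique(years)
    if len(year_list) < 2:
        raise ValidationError("need at least 2 whole years")
    # gap check: every year must contribute each of DOY 1..365 exactly once
    cells = pd.MultiIndex.from_arrays([years, doy])
    if cells.has_duplicates:
        raise ValidationError("duplicate county-days in series")
    counts = pd.Series(1, index=cells).unstack(fill_value=0)
    missing = counts.reindex(columns=range(1, 366), fill_value=0) == 0
    if missing.to_numpy().any():
        yr, d = np.argwhere(missing.to_numpy())[0]
        raise ValidationError(
            f"series has gaps, e.g. year {counts.index[yr]} DOY {d + 1}"
        )

    cold = np.asarray(g) < 0
    p = np.zeros(365)
    for d in range(1, 366):
        sel = doy == d
        p[d - 1] = cold[sel].sum() / len(year_list)
    return DOYProbabilityProfile(fips=fips, p=p, n_years=len(year_list))


def _longest_zero_run(p: np.ndarray) -> tuple[int, int]:
    """(first, last) 0-based indices of the longest run of p == 0.

    Ties break toward the earlier run — the agronomic season, not a false
    spring.
    """
    best = (-1, -1)
    best_len = 0
    i = 0
    n = len(p)
    while i < n:
        if p[i] == 0:
            j = i
            while j + 1 < n and p[j + 1] == 0:
                j += 1
            if j - i + 1 > best_len:
                best_len = j - i + 1
                best = (i, j)
            i = j + 1
        else:
            i += 1
    return best


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _limb_crossing(doys: np.ndarray, probs: np.ndarray, threshold: float):
    """Fit p ~ DOY over one shoulder; return (crossing DOY, slope, intercept).

    Falls back to linear interpolation between the days bracketing the
    threshold when the limb has fewer than two distinct probability values.
    """
    if len(np.unique(probs)) >= 2:
        slope, intercept = np.polyfit(doys, probs, 1)
        return (threshold - intercept) / slope, float(slope), float(intercept)
    # degenerate limb: interpolate between bracketing days
    order = np.argsort(doys)
    d, q = doys[order], probs[order]
    for k in range(len(d) - 1):
        lo, hi = sorted((q[k], q[k + 1]))
        if lo <= threshold <= hi and q[k] != q[k + 1]:
            frac = (threshold - q[k]) / (q[k + 1] - q[k])
            return d[k] + frac * (d[k + 1] - d[k]), None, None
    raise ValidationError("limb never brackets the probability threshold")


def delineate_season(
    profile: DOYProbabilityProfile, p_threshold: float = P_THRESHOLD
) -> GrowingSeason:
    """Locate season start/end where shoulder regressions cross p_threshold.

    The spring limb runs from the last certain-cold day (p = 1) before the
    longest midyear warm run (p = 0) to that run's first day; the fall limb
    from the run's last day to the first certain-cold day after it. Each
    limb is fit by least squares of p on DOY and the crossing DOY is
    rounded half-up.

    Degenerate profiles return sentinels rather than fits: a profile that
    never warms to p = 0 has no growing season (status ``no_season``); one
    that never reaches p = 1 is growing year-round (status ``year_round``,
    start 1 / end 365).
    """
    p = profile.p
    z0, z1 = _longest_zero_run(p)
    if z0 < 0:
        return GrowingSeason(profile.fips, 0, 0, status="no_season")
    ones_before = np.flatnonzero(p[:z0] == 1)
    ones_after = z1 + 1 + np.flatnonzero(p[z1 + 1 :] == 1)
    if len(ones_before) == 0 or len(ones_after) == 0:
        return GrowingSeason(profile.fips, 1, 365, status="year_round")

    s0 = ones_before[-1]  # last p=1 day before the warm run (0-based)
    f1 = ones_after[0]  # first p=1 day after it

    spring_doys = np.arange(s0, z0 + 1) + 1
    fall_doys = np.arange(z1, f1 + 1) + 1
    sx, s_slope, s_int = _limb_crossing(spring_doys, p[s0 : z0 + 1], p_threshold)
    fx, f_slope, f_int = _limb_crossing(fall_doys, p[z1 : f1 + 1], p_threshold)

    start = _round_half_up(sx)
    end = _round_half_up(fx)
    if not 1 <= start < end <= 365:
        raise ValidationError(
            f"inconsistent crossings: start {start}, end {end}"
        )
    return GrowingSeason(
        profile.fips,
        start,
        end,
        spring_fit=(s_slope, s_int) if s_slope is not None else None,
        fall_fit=(f_slope, f_int) if f_slope is not None else None,
    )


def summarize_season(series: pd.DataFrame, gs: GrowingSeason) -> pd.Series:
    """Aggregate one county-year of weather over [start_doy, end_doy].

    Returns gsr (mm, summed precipitation), mean Tmax/Tmin/Tav (deg C) and
    accumulated truncated GDD (deg C-day). The series must cover every
    season day of exactly one calendar year.
    """
    dates = pd.to_datetime(series["date"])
    years = dates.dt.year.unique()
    if len(years) != 1:
        raise ValidationError("summarize_season expects a single calendar year")
    doy = doy_index(dates)
    sel = (doy >= gs.start_doy) & (doy <= gs.end_doy)
    sub = series.loc[sel]
    present = set(doy[sel])
    expected = set(range(gs.start_doy, gs.end_doy + 1))
    gaps = sorted(expected - present)
    if gaps:
        raise ValidationError(f"missing season day(s), DOY {gaps[:10]}")

    tmax = sub["tmax"].to_numpy()
    tmin = sub["tmin"].to_numpy()
    return pd.Series(
        {
            "fips": series["fips"].iloc[0],
            "state": series["state"].iloc[0],
            "year": int(years[0]),
            "gsr": float(sub["prcp"].sum()),
            "tmax_mean": float(tmax.mean()),
            "tmin_mean": float(tmin.mean()),
            "tav_mean": float(((tmax + tmin) / 2).mean()),
            "gdd_sum": float(np.sum(daily_gdd(tmax, tmin, truncate=True))),
        }
    )


def summarize_panel(
    weather: pd.DataFrame,
    seasons: dict[str, GrowingSeason],
) -> pd.DataFrame:
    """Season summaries for every county-year in a multi-county panel."""
    rows = []
    for (fips, year), grp in weather.groupby(
        ["fips", pd.to_datetime(weather["date"]).dt.year], sort=True
    ):
        gs = seasons[fips]
        if gs.status == "no_season":
            continue
        rows.append(summarize_season(grp, gs))
    out = pd.DataFrame(rows).reset_index(drop=True)
    out["year"] = out["year"].astype(int)
    return out
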