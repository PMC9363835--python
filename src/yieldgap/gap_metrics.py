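"""Yield-gap bookkeeping: current yield, gaps, mean WUE and water shares.

Three yields anchor the analysis, all in Mg ha-1:

* Yc — current yield: the (area-weighted) mean survey yield actually
  achieved over the study decade;
* Ya — attainable yield: the frontier-envelope maximum at optimum rainfall;
* Yw — water-limited potential yield: the boundary line evaluated at the
  realised rainfall.

Gaps are differences (YGa = Ya - Yc, YGw = Yw - Yc), also expressed as a
percent of the respective ceiling. Internal values stay full precision;
rounding happens only when a report is serialized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NegativeGapWarning, ValidationError


@dataclass(frozen=True)
class GapSummary:
    region: str
    yc: float
    ya: float
    yw: float
    yga: float
    ygw: float
    yga_pct: float
    ygw_pct: float


def current_yield(records: pd.DataFrame, weight_by_area: bool = True) -> float:
    """Mean survey yield for one region, Mg ha-1.

    Within each year, counties are averaged weighted by harvested area when
    areas are present (and ``weight_by_area``); the yearly means are then
    averaged unweighted across years. Falls back to the plain mean when no
    areas are reported.
    """
    surveys = records[records["source"] == "survey"] if "source" in records else records
    if surveys.empty:
        raise ValidationError("no survey yield records")

    have_area = "area_ha" in surveys and surveys["area_ha"].notna().all()
    if weight_by_area and have_area:
        if not (surveys["area_ha"] > 0).any():
            raise ValidationError("weighting requested but total area is zero")

        def year_mean(g):
            w = g["area_ha"].to_numpy()
            if w.sum() == 0:
                raise ValidationError("weighting requested but total area is zero")
            return float(np.average(g["yield_mg_ha"], weights=w))

        yearly = surveys.groupby("year").apply(year_mean, include_groups=False)
        return float(yearly.mean())
    return float(surveys["yield_mg_ha"].mean())


def yield_gaps(region: str, yc: float, ya: float, yw: float) -> GapSummary:
    """Absolute and percent gaps against the attainable and water-limited
    ceilings. A current yield above either ceiling yields a negative gap
    and a warning — never a clamp."""
    if min(yc, ya, yw) <= 0:
        raise ValidationError("yields must be positive")
    yga, ygw = ya - yc, yw - yc
    if yga < 0 or ygw < 0:
        warnings.warn(
            f"{region}: current yield exceeds a ceiling "
            f"(YGa={yga:.2f}, YGw={ygw:.2f})",
            NegativeGapWarning,
            stacklevel=2,
        )
    return GapSummary(
        region=region,
        yc=yc,
        ya=ya,
        yw=yw,
        yga=yga,
        ygw=ygw,
        yga_pct=100.0 * yga / ya,
        ygw_pct=100.0 * ygw / yw,
    )


def mean_wue(pairs: pd.DataFrame) -> float:
    """Mean realised water-use efficiency, kg ha-1 mm-1.

    Average over county-years of 1000 * yield / gsr — the mean of ratios,
    not the ratio of means. Zero-gsr entries are excluded with a warning.
    """
    gsr = pairs["gsr"].to_numpy(dtype=float)
    yld = pairs["yield_mg_ha"].to_numpy(dtype=float)
    bad = gsr <= 0
    if bad.all():
        raise ValidationError("no positive-gsr observations")
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} zero-gsr observation(s)")
    return float(np.mean(1000.0 * yld[~bad] / gsr[~bad]))


def fraction_below_optimum(gsr_obs, x_star: float) -> float:
    """Percent of county-year GSR observations strictly below optimum."""
    g = np.asarray(gsr_obs, dtype=float)
    if g.size == 0:
        raise ValidationError("no observations")
    return float(100.0 * np.count_nonzero(g < x_star) / g.size)


def water_loss_fraction(wl: float, mean_gsr: float) -> float:
    """Minimum water loss as percent of mean seasonal rainfall."""
    if mean_gsr <= 0:
        raise ValidationError("mean_gsr must be positive")
    return float(100.0 * wl / mean_gsr)


def round_half_up(x, decimals: int = 0):
    """Report rounding (0.5 always rounds away from zero toward +inf)."""
    f = 10.0**decimals
    return np.floor(np.asarray(x, dtype=float) * f + 0.5) / f


def gap_report(summaries: list[GapSummary]) -> pd.DataFrame:
    """Serialize gap summaries with report-level rounding: yields to one
    decimal, percentages half-up to integers."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "region": s.region,
                "yc": float(round_half_up(s.yc, 1)),
                "ya": float(round_half_up(s.ya, 1)),
                "yw": float(round_half_up(s.yw, 1)),
                "yga": float(round_half_up(s.yga, 1)),
                "ygw": float(round_half_up(s.ygw, 1)),
                "yga_pct": float(round_half_up(s.yga_pct)),
                "ygw_pct": float(round_half_up(s.ygw_pct)),
            }
        )
    return pd.DataFrame(rows)
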