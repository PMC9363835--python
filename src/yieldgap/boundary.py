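"""Water-limited potential yield via the linear boundary function.

Over the rainfall range where yield still responds to extra water, the
upper envelope of yield vs growing-season rainfall (GSR) is taken as
linear:

    Yw = WUE_pot * (GSR - WL)

The slope is the potential water-use efficiency (reported in
kg ha-1 mm-1 = 1000 x the Mg-scale slope) and the x-intercept WL is the
minimum non-productive water loss — rainfall lost to runoff, evaporation
and percolation before any of it becomes forage. The envelope is fit
through per-bin maximum yields, optionally augmented with variety-trial
points (high-management yields that extend the envelope upward).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import NegativeInterceptWarning, NoWaterResponseError, ValidationError
from .frontier import DEFAULT_BIN_WIDTH_MM, BinnedMaxima, bin_maxima


@dataclass(frozen=True)
class BoundaryFit:
    slope: float  # Mg ha-1 mm-1
    intercept: float  # Mg ha-1
    wue_potential: float  # kg ha-1 mm-1 = 1000 * slope
    wl: float  # mm, clamped at 0
    wl_raw: float  # unclamped x-intercept, for diagnostics
    responsive_max_gsr: float  # mm
    n_support: int
    r2: float


def select_responsive_range(
    points: pd.DataFrame,
    bin_width: float = DEFAULT_BIN_WIDTH_MM,
    min_points: int = 10,
) -> float:
    """Upper GSR edge of the water-responsive range, mm.

    Yield responds to water only up to the rainfall bin holding the
    globally maximal yield; wetter bins sit on the flat (or declining) part
    of the envelope and would bias the boundary slope downward. Bins are
    anchored at 0 mm with the given width, so the cutoff is the upper edge
    of the bin containing the best yield.
    """
    pts = points[["gsr", "yield_mg_ha"]].dropna()
    if len(pts) < min_points:
        raise ValidationError(f"need >= {min_points} points, got {len(pts)}")
    best_gsr = float(pts.loc[pts["yield_mg_ha"].idxmax(), "gsr"])
    return (np.floor(best_gsr / bin_width) + 1) * bin_width


def fit_boundary(
    support: BinnedMaxima | pd.DataFrame,
    extra: pd.DataFrame | None = None,
    responsive_max_gsr: float | None = None,
) -> BoundaryFit:
    """Least-squares line through responsive-range bin maxima plus trials.

    ``support`` is a :class:`BinnedMaxima` (or its support frame) already
    restricted to the responsive range; ``extra`` adds variety-trial
    (gsr, yield) points unbinned. A nonpositive slope raises
    :class:`NoWaterResponseError`. A negative x-intercept (line above the
    origin) is physically impossible for a water loss; it is clamped to 0
    with a warning and the raw value kept in ``wl_raw``.
    """
    pts = support.support if isinstance(support, BinnedMaxima) else support
    pts = pts[["gsr", "yield_mg_ha"]].copy()
    if extra is not None and len(extra):
        pts = pd.concat(
            [pts, extra[["gsr", "yield_mg_ha"]]], ignore_index=True
        )
    if pts["gsr"].nunique() < 2:
        raise ValidationError("need >= 2 points with distinct gsr")

    X = sm.add_constant(pts["gsr"].to_numpy())
    res = sm.OLS(pts["yield_mg_ha"].to_numpy(), X).fit()
    intercept, slope = (float(c) for c in res.params)
    if slope <= 1e-9:  # flat envelopes fit slopes at float-noise level
        raise NoWaterResponseError(
            f"boundary slope {slope:.4g} <= 0: no water response detected"
        )
    wl_raw = -intercept / slope
    wl = wl_raw
    if wl < 0:
        warnings.warn(
            f"negative x-intercept ({wl_raw:.1f} mm) clamped to 0",
            NegativeInterceptWarning,
            stacklevel=2,
        )
        wl = 0.0
    return BoundaryFit(
        slope=slope,
        intercept=intercept,
        wue_potential=1000.0 * slope,
        wl=wl,
        wl_raw=wl_raw,
        responsive_max_gsr=(
            float(responsive_max_gsr)
            if responsive_max_gsr is not None
            else float(pts["gsr"].max())
        ),
        n_support=len(pts),
        r2=float(res.rsquared),
    )


def fit_boundary_from_points(
    points: pd.DataFrame,
    extra: pd.DataFrame | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH_MM,
) -> BoundaryFit:
    """Full boundary pipeline: responsive range -> bin maxima -> line fit."""
    cutoff = select_responsive_range(points, bin_width=bin_width)
    responsive = points[points["gsr"] <= cutoff]
    support = bin_maxima(responsive, bin_width=bin_width)
    return fit_boundary(support, extra=extra, responsive_max_gsr=cutoff)


def water_limited_yield(fit_or_slope, gsr, wl: float | None = None):
    """Yw(gsr) = max(0, slope * (gsr - WL)), Mg ha-1.

    Accepts either a :class:`BoundaryFit`, or a potential WUE in
    kg ha-1 mm-1 together with ``wl`` in mm (the reported-units form used
    when evaluating published coefficients).
    """
    if isinstance(fit_or_slope, BoundaryFit):
        slope, wl_ = fit_or_slope.slope, fit_or_slope.wl
    else:
        if wl is None:
            raise ValidationError("wl is required when passing a WUE value")
        slope, wl_ = float(fit_or_slope) / 1000.0, float(wl)
    g = np.asarray(gsr, dtype=float)
    if np.any(g < 0):
        raise ValidationError("gsr must be nonnegative")
    out = np.maximum(0.0, slope * (g - wl_))
    return out if out.ndim else float(out)
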