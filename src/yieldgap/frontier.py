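"""Attainable yield via a log-quadratic frontier on binned maximum yields.

Attainable yield Ya(X) at growing-season rainfall X is the upper envelope
of the county-year yield cloud: the best any county ever did at that water
supply. Operationally the GSR range is cut into equally spaced bins, the
maximum-yield point in each bin is kept, and

    ln Ya = b0 + b1 ln X + b2 (ln X)^2

is fit through those support points by ordinary least squares in log space.
With b2 < 0 the curve has an interior maximum at X* = exp(-b1 / (2 b2)) —
the optimum GSR — beyond which excess water (waterlogging, harvest losses)
depresses the envelope. No inefficiency distribution is estimated: the
binned-maxima envelope IS the frontier here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import NoInteriorOptimumError, ValidationError

DEFAULT_BIN_WIDTH_MM = 50.0


@dataclass(frozen=True)
class BinnedMaxima:
    """Per-bin maximum-yield support points for envelope fitting."""

    bin_edges: np.ndarray  # ascending, len = n_bins + 1
    support: pd.DataFrame  # columns gsr, yield_mg_ha; one row per non-empty bin
    n_input: int


@dataclass(frozen=True)
class FrontierFit:
    """Fitted log-quadratic frontier and its interior optimum."""

    beta0: float
    beta1: float
    beta2: float
    optimum_gsr: float  # mm; nan when beta2 >= 0
    ya_max: float  # Mg ha-1 at the optimum; nan when beta2 >= 0
    r2: float
    n_support: int
    bin_width: float
    has_interior_optimum: bool


def bin_maxima(
    points: pd.DataFrame, bin_width: float = DEFAULT_BIN_WIDTH_MM
) -> BinnedMaxima:
    """Keep the maximum-yield point per equal-width GSR bin.

    ``points`` needs columns ``gsr`` and ``yield_mg_ha``. Bins span
    [min gsr, max gsr]; the top edge is inclusive. Yield ties within a bin
    keep the point with the larger gsr.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    pts = points[["gsr", "yield_mg_ha"]].dropna()
    if pts["gsr"].nunique() < 2:
        raise ValidationError("need >= 2 points with distinct gsr")
    lo, hi = pts["gsr"].min(), pts["gsr"].max()
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    if n_bins < 2:
        raise ValidationError(
            "all points fall in one bin; choose a smaller bin_width"
        )
    edges = lo + bin_width * np.arange(n_bins + 1)

    idx = np.minimum(
        ((pts["gsr"].to_numpy() - lo) // bin_width).astype(int), n_bins - 1
    )
    rows = []
    for b in range(n_bins):
        sub = pts[idx == b]
        if sub.empty:
            continue
        best = sub.sort_values(["yield_mg_ha", "gsr"], kind="mergesort").iloc[-1]
        rows.append({"gsr": float(best["gsr"]), "yield_mg_ha": float(best["yield_mg_ha"])})
    support = pd.DataFrame(rows)
    return BinnedMaxima(bin_edges=edges, support=support, n_input=len(pts))


def fit_frontier(
    support: BinnedMaxima, bin_width: float | None = None
) -> FrontierFit:
    """OLS of ln(yield) on [1, ln(gsr), ln(gsr)^2] over support points.

    Zero-yield support points are excluded (log undefined) with a warning.
    A fitted b2 >= 0 is returned but flagged: the envelope then has no
    interior optimum and ``optimum_gsr``/``ya_max`` are NaN.
    """
    pts = support.support
    zero = pts["yield_mg_ha"] <= 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} nonpositive-yield support point(s) "
            "before log transform"
        )
        pts = pts[~zero]
    if len(pts) < 3:
        raise ValidationError("need >= 3 positive support points")
    if (pts["gsr"] <= 0).any():
        raise ValidationError("support gsr must be positive")

    lx = np.log(pts["gsr"].to_numpy())
    ly = np.log(pts["yield_mg_ha"].to_numpy())
    X = sm.add_constant(np.column_stack([lx, lx**2]))
    if np.linalg.matrix_rank(X) < 3:
        raise ValidationError("singular design: support gsr values too alike")
    res = sm.OLS(ly, X).fit()
    b0, b1, b2 = (float(c) for c in res.params)

    if b2 < 0:
        xstar = float(np.exp(-b1 / (2 * b2)))
        ya = float(np.exp(b0 + b1 * np.log(xstar) + b2 * np.log(xstar) ** 2))
        interior = True
    else:
        xstar, ya, interior = float("nan"), float("nan"), False
    width = bin_width if bin_width is not None else float(np.diff(support.bin_edges)[0])
    return FrontierFit(
        beta0=b0,
        beta1=b1,
        beta2=b2,
        optimum_gsr=xstar,
        ya_max=ya,
        r2=float(res.rsquared),
        n_support=len(pts),
        bin_width=width,
        has_interior_optimum=interior,
    )


def optimum_gsr(fit: FrontierFit) -> float:
    """Rainfall at which the frontier peaks: exp(-b1 / (2 b2)), mm."""
    if not fit.beta2 < 0:
        raise NoInteriorOptimumError(
            f"beta2 = {fit.beta2:.4g} >= 0: frontier has no interior optimum"
        )
    return float(np.exp(-fit.beta1 / (2 * fit.beta2)))


def attainable_yield(fit: FrontierFit, gsr) -> float | np.ndarray:
    """Frontier yield Ya(gsr) = exp(b0 + b1 ln gsr + b2 (ln gsr)^2), Mg ha-1."""
    g = np.asarray(gsr, dtype=float)
    if np.any(g <= 0):
        raise ValidationError("gsr must be positive")
    lg = np.log(g)
    out = np.exp(fit.beta0 + fit.beta1 * lg + fit.beta2 * lg**2)
    return out if out.ndim else float(out)


def effective_optimum(
    fit: FrontierFit, gsr_min: float, gsr_max: float
) -> tuple[float, float, bool]:
    """(x_star, ya, is_interior) with edge handling.

    The analytic optimum is used when it is interior to the observed GSR
    range; otherwise the fitted envelope is maximized over that range on a
    1-mm grid (a monotone envelope peaks at the data edge — common when
    the true water response is linear with no wet-end decline).
    """
    if (
        fit.has_interior_optimum
        and gsr_min <= fit.optimum_gsr <= gsr_max
    ):
        return fit.optimum_gsr, fit.ya_max, True
    grid = np.arange(gsr_min, gsr_max + 1.0, 1.0)
    ya = attainable_yield(fit, grid)
    k = int(np.argmax(ya))
    return float(grid[k]), float(ya[k]), False


def fit_frontier_from_points(
    points: pd.DataFrame, bin_width: float = DEFAULT_BIN_WIDTH_MM
) -> FrontierFit:
    """Convenience: bin county-year points, then fit the frontier."""
    return fit_frontier(bin_maxima(points, bin_width), bin_width=bin_width)


def optimum_sensitivity(
    points: pd.DataFrame, widths=(25.0, 50.0, 100.0)
) -> pd.DataFrame:
    """Optimum GSR across bin widths — a robustness report, since the bin
    width is a free constant of the procedure."""
    rows = []
    for w in widths:
        try:
            fit = fit_frontier_from_points(points, bin_width=w)
            rows.append(
                {
                    "bin_width": w,
                    "optimum_gsr": fit.optimum_gsr,
                    "ya_max": fit.ya_max,
                    "n_support": fit.n_support,
                }
            )
        except (ValidationError, NoInteriorOptimumError) as exc:
            rows.append(
                {
                    "bin_width": w,
                    "optimum_gsr": float("nan"),
                    "ya_max": float("nan"),
                    "n_support": 0,
                    "note": str(exc),
                }
            )
    return pd.DataFrame(rows)
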