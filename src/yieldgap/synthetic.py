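"""Synthetic multi-county weather and yield panels with known ground truth.

The generator reproduces the statistical structure the analysis assumes,
so every stage can be exercised and checked against truth without any
download:

* temperature — a sinusoidal annual cycle (coldest in mid-January) plus
  AR(1) day-to-day noise, split into Tmax/Tmin by a fixed diurnal range.
  Defaults give a humid-continental climate whose 5 deg C-based growing
  season runs roughly DOY 85-310;
* rainfall — a two-state Markov occurrence chain (wet spells persist) with
  gamma-distributed wet-day amounts, tuned so seasonal totals average
  about 670 mm;
* yields — a linear water production function with multiplicative
  inefficiency: potential = min(ceiling, WUE/1000 * max(0, GSR - WL)),
  observed = potential * efficiency, efficiency ~ Beta rescaled into
  (0, 1], with a seeded fraction of county-years forced to >= 0.98 so the
  upper envelope is informative.

Everything is a pure function of (params, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_panel
from .errors import ValidationError
from .io_panel import WEATHER_COLUMNS


@dataclass(frozen=True)
class ClimateParams:
    t_mean_annual: float = 12.0  # deg C
    t_amplitude: float = 15.0  # deg C
    t_phase_doy: float = 15.0  # DOY of the coldest day
    t_noise_sd: float = 2.0  # marginal SD of the AR(1) noise, deg C
    t_noise_phi: float = 0.7  # AR(1) persistence
    diurnal_range: float = 10.0  # Tmax - Tmin, deg C
    rain_prob_wet: float = 0.25  # P(wet | yesterday dry)
    rain_persistence: float = 0.25  # added to get P(wet | yesterday wet)
    rain_shape: float = 0.7  # gamma shape of wet-day mm
    rain_scale: float = 13.0  # gamma scale of wet-day mm

    def __post_init__(self):
        if self.t_amplitude <= 0:
            raise ValidationError("t_amplitude must be positive")
        for p in (self.rain_prob_wet, self.rain_persistence):
            if not 0 <= p <= 1:
                raise ValidationError("rain probabilities must be in [0, 1]")
        if self.rain_shape <= 0 or self.rain_scale <= 0:
            raise ValidationError("gamma parameters must be positive")


@dataclass(frozen=True)
class ProductionParams:
    wue_true: float = 28.0  # kg ha-1 mm-1
    wl_true: float = 150.0  # mm
    yield_ceiling: float = 25.0  # Mg ha-1
    efficiency_alpha: float = 4.0
    efficiency_beta: float = 2.0  # 0 collapses efficiency to exactly 1
    frontier_frac: float = 0.05  # share forced to efficiency >= 0.98

    def __post_init__(self):
        if self.wue_true <= 0 or self.wl_true < 0:
            raise ValidationError("wue_true > 0 and wl_true >= 0 required")
        if not 0 < self.frontier_frac < 1:
            raise ValidationError("frontier_frac must be in (0, 1)")


def mean_temperature(doy, params: ClimateParams):
    """Noise-free annual cycle: mean - amplitude * cos(2 pi (d - phase)/365)."""
    d = np.asarray(doy, dtype=float)
    return params.t_mean_annual - params.t_amplitude * np.cos(
        2 * np.pi * (d - params.t_phase_doy) / 365.0
    )


def _county_params(base: ClimateParams, rng: np.random.Generator) -> ClimateParams:
    """Small seeded per-county perturbations of climate normals."""
    wet = base.rain_prob_wet
    if wet > 0:  # a rain-free climate stays rain-free
        wet = float(np.clip(wet + rng.uniform(-0.03, 0.03), 0.01, 0.9))
    return replace(
        base,
        t_mean_annual=base.t_mean_annual + rng.uniform(-1.5, 1.5),
        rain_prob_wet=wet,
        rain_scale=base.rain_scale * rng.uniform(0.9, 1.1),
    )


def generate_weather(
    params: ClimateParams | None = None,
    counties: int = 3,
    years: int = 10,
    seed: int = 0,
    start_year: int = 2009,
    state: str = "XX",
) -> pd.DataFrame:
    """Daily weather panel for ``counties`` x ``years`` in the canonical
    io_panel schema. Counties get FIPS 99001, 99002, ... and small seeded
    offsets in temperature and rainfall normals."""
    if counties < 1 or years < 1:
        raise ValidationError("counties and years must be >= 1")
    params = params or ClimateParams()
    rng = np.random.default_rng(seed)
    dates = pd.date_range(
        f"{start_year}-01-01", f"{start_year + years - 1}-12-31", freq="D"
    )
    # noise-free DOY with Feb 29 sharing Feb 28's position in the cycle
    doy = np.minimum(dates.dayofyear.to_numpy(), 365)

    frames = []
    for c in range(counties):
        cp = _county_params(params, rng)
        n = len(dates)
        mu = mean_temperature(doy, cp)
        if cp.t_noise_sd > 0:
            innov_sd = cp.t_noise_sd * np.sqrt(1 - cp.t_noise_phi**2)
            eps = rng.normal(0.0, innov_sd, size=n)
            noise = np.empty(n)
            noise[0] = rng.normal(0.0, cp.t_noise_sd)
            for t in range(1, n):
                noise[t] = cp.t_noise_phi * noise[t - 1] + eps[t]
        else:
            noise = np.zeros(n)
        tmean = mu + noise
        tmax = tmean + cp.diurnal_range / 2.0
        tmin = tmean - cp.diurnal_range / 2.0

        p01, p11 = cp.rain_prob_wet, min(1.0, cp.rain_prob_wet + cp.rain_persistence)
        u = rng.random(n)
        wet = np.empty(n, dtype=bool)
        wet[0] = u[0] < p01 / max(1e-12, 1.0 + p01 - p11)  # stationary start
        for t in range(1, n):
            wet[t] = u[t] < (p11 if wet[t - 1] else p01)
        prcp = np.zeros(n)
        n_wet = int(wet.sum())
        if n_wet:
            prcp[wet] = rng.gamma(cp.rain_shape, cp.rain_scale, size=n_wet)

        frames.append(
            pd.DataFrame(
                {
                    "fips": f"{99000 + c + 1:05d}",
                    "state": state,
                    "date": dates,
                    "tmax": tmax,
                    "tmin": tmin,
                    "prcp": prcp,
                    "filled": False,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out[WEATHER_COLUMNS]


def stationary_wet_probability(params: ClimateParams) -> float:
    """Long-run wet-day probability of the occurrence chain."""
    p01 = params.rain_prob_wet
    p11 = min(1.0, params.rain_prob_wet + params.rain_persistence)
    return p01 / (1.0 + p01 - p11)


def expected_daily_rain(params: ClimateParams) -> float:
    """Expected mm per day: stationary wet prob x mean wet-day amount."""
    return stationary_wet_probability(params) * params.rain_shape * params.rain_scale


def generate_yield_panel(
    params: ProductionParams | None = None,
    summaries: pd.DataFrame | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Observed yields for each county-year season summary, plus truth.

    Observed yield is the water-limited potential times a Beta-distributed
    efficiency; a seeded ``frontier_frac`` subset is forced to efficiency
    in [0.98, 1] so that bin maxima trace the true production frontier.
    County-years with GSR below the minimum water loss have zero potential;
    they are emitted with yield 0 and a ``zero_potential`` flag so callers
    can drop them before feeding survey readers (which require yield > 0).
    """
    params = params or ProductionParams()
    if summaries is None or summaries.empty:
        raise ValidationError("summaries must be a nonempty SeasonSummary frame")
    rng = np.random.default_rng(seed)
    n = len(summaries)
    gsr = summaries["gsr"].to_numpy(dtype=float)
    potential = np.minimum(
        params.yield_ceiling,
        params.wue_true / 1000.0 * np.maximum(0.0, gsr - params.wl_true),
    )
    if params.efficiency_beta == 0:
        eff = np.ones(n)
        front_idx = np.arange(n)  # everything already sits on the frontier
    else:
        eff = np.clip(
            rng.beta(params.efficiency_alpha, params.efficiency_beta, size=n),
            1e-6,
            1.0,
        )
        n_front = max(1, int(round(params.frontier_frac * n)))
        front_idx = rng.choice(n, size=n_front, replace=False)
        eff[front_idx] = rng.uniform(0.98, 1.0, size=n_front)

    observed = potential * eff
    zero_pot = potential <= 0
    if zero_pot.any():
        warnings.warn(
            f"{int(zero_pot.sum())} county-year(s) with GSR below the minimum "
            "water loss: zero potential yield"
        )

    yields = pd.DataFrame(
        {
            "fips": summaries["fips"].to_numpy(),
            "state": summaries.get("state", pd.Series(["XX"] * n)).to_numpy(),
            "year": summaries["year"].to_numpy(dtype=int),
            "yield_mg_ha": observed,
            "area_ha": np.nan,
            "source": "survey",
            "zero_potential": zero_pot,
        }
    )
    truth = {
        "wue_true": params.wue_true,
        "wl_true": params.wl_true,
        "yield_ceiling": params.yield_ceiling,
        "efficiency": eff.tolist(),
        "potential": potential.tolist(),
        "frontier_rows": sorted(int(i) for i in front_idx),
        "zero_potential_rows": sorted(int(i) for i in np.flatnonzero(zero_pot)),
    }
    return yields, truth


def generate_log_quadratic_yields(
    beta0: float,
    beta1: float,
    beta2: float,
    gsr,
    efficiency_alpha: float = 4.0,
    efficiency_beta: float = 2.0,
    frontier_frac: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """County-year points whose true upper envelope is log-quadratic in GSR
    (used to test frontier recovery; the optimum is exp(-b1/(2 b2)))."""
    rng = np.random.default_rng(seed)
    g = np.asarray(gsr, dtype=float)
    if np.any(g <= 0):
        raise ValidationError("gsr must be positive")
    lg = np.log(g)
    envelope = np.exp(beta0 + beta1 * lg + beta2 * lg**2)
    eff = np.clip(rng.beta(efficiency_alpha, efficiency_beta, size=len(g)), 1e-6, 1.0)
    n_front = max(1, int(round(frontier_frac * len(g))))
    idx = rng.choice(len(g), size=n_front, replace=False)
    eff[idx] = rng.uniform(0.98, 1.0, size=n_front)
    return pd.DataFrame({"gsr": g, "yield_mg_ha": envelope * eff})


def make_fixture_suite(dest, seed: int = 0) -> dict[str, Path]:
    """Write a small self-contained fixture bundle (3 counties x 10 years).

    Files: weather.csv and yields.csv in the io_panel schemas, trials.csv
    with 5 variety-trial points near the production frontier, and
    truth.json with the generating parameters. Regenerating with the same
    seed is byte-identical.
    """
    from . import season  # local import: season depends on nothing here

    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    weather = generate_weather(counties=3, years=10, seed=seed)

    seasons = {}
    for fips, grp in weather.groupby("fips"):
        prof = season.doy_probability_profile(grp)
        seasons[fips] = season.delineate_season(prof)
    summaries = season.summarize_panel(weather, seasons)

    prod = ProductionParams()
    yields, truth = generate_yield_panel(prod, summaries, seed=seed + 1)

    rng = np.random.default_rng(seed + 2)
    trial_gsr = rng.uniform(450.0, 900.0, size=5)
    trial_yield = (
        prod.wue_true / 1000.0 * np.maximum(0.0, trial_gsr - prod.wl_true)
    ) * rng.uniform(0.97, 1.0, size=5)
    trials = pd.DataFrame(
        {
            "county_fips": "99001",
            "state": "XX",
            "year": 2018,
            "yield": np.round(trial_yield, 4),
            "gsr": np.round(trial_gsr, 1),
            "source": "variety_trial",
        }
    )

    paths = {
        "weather": dest / "weather.csv",
        "yields": dest / "yields.csv",
        "trials": dest / "trials.csv",
        "truth": dest / "truth.json",
    }
    w = weather.copy()
    w["date"] = w["date"].dt.strftime("%Y-%m-%d")
    for col in ("tmax", "tmin", "prcp"):
        w[col] = w[col].round(4)
    w.to_csv(paths["weather"], index=False)

    y = (
        yields[~yields["zero_potential"]]
        .drop(columns="zero_potential")
        .rename(columns={"fips": "county_fips", "yield_mg_ha": "yield"})
        .copy()
    )
    y["yield"] = y["yield"].round(4)
    y.to_csv(paths["yields"], index=False)
    trials.to_csv(paths["trials"], index=False)

    truth_out = {
        k: truth[k]
        for k in ("wue_true", "wl_true", "yield_ceiling", "frontier_rows")
    }
    truth_out["seasons"] = {
        f: {"start_doy": s.start_doy, "end_doy": s.end_doy, "status": s.status}
        for f, s in seasons.items()
    }
    paths["truth"].write_text(json.dumps(truth_out, indent=1, sort_keys=True))
    return paths
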