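"""End-to-end orchestration: weather -> seasons -> envelopes -> gaps -> tree.

The pipeline joins a daily weather panel and an annual yield panel on the
county key, delineates each county's growing season, summarizes weather
over it, fits the frontier (attainable yield) and boundary (water-limited
yield) envelopes per region, computes gap metrics, and fits the
conditional-inference tree on the pooled county-year panel. Every stage
writes a delimited report; a JSON manifest records counts and effective
parameters. All randomness flows from the single configured seed, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import boundary, cit, frontier, gap_metrics, io_panel, season, synthetic
from .errors import ConfigurationError

log = logging.getLogger("yieldgap")

CIT_COVARIATES = ["gsr", "tmax_mean", "tmin_mean", "gdd_sum"]


@dataclass
class PipelineConfig:
    weather: str | None = None
    yields: str | None = None
    trials: str | None = None
    outdir: str = "yieldgap_out"
    tbase: float = season.TBASE_C
    p_threshold: float = season.P_THRESHOLD
    bin_width: float = frontier.DEFAULT_BIN_WIDTH_MM
    weight_by_area: bool = True
    fit_pooled: bool = False  # one region pooling all states
    cit_config: cit.CITConfig = field(default_factory=cit.CITConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cit_raw = raw.pop("cit", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if cit_raw:
            cfg.cit_config = cit.CITConfig(**cit_raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cit"] = d.pop("cit_config")
        return d


def delineate_counties(weather: pd.DataFrame, p_threshold: float):
    """Per-county probability profiles and seasons for a weather panel."""
    seasons = {}
    for fips, grp in weather.groupby("fips", sort=True):
        profile = season.doy_probability_profile(grp)
        seasons[fips] = season.delineate_season(profile, p_threshold=p_threshold)
    return seasons


def seasons_frame(seasons: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "county_fips": f,
                "start_doy": s.start_doy,
                "end_doy": s.end_doy,
                "length": s.length,
                "status": s.status,
            }
            for f, s in sorted(seasons.items())
        ]
    )


def analyze_region(
    region: str,
    panel: pd.DataFrame,
    trials: pd.DataFrame | None,
    bin_width: float,
    weight_by_area: bool,
) -> dict:
    """Frontier + boundary + gap metrics for one region's county-year panel.

    ``panel`` holds merged rows with yield_mg_ha, area_ha, source, gsr.
    """
    points = panel[["gsr", "yield_mg_ha"]]
    ffit = frontier.fit_frontier_from_points(points, bin_width=bin_width)
    bfit = boundary.fit_boundary_from_points(points, extra=trials, bin_width=bin_width)

    x_star, ya, interior = frontier.effective_optimum(
        ffit, float(points["gsr"].min()), float(points["gsr"].max())
    )
    if not interior:
        log.warning(
            "region %s: frontier has no interior optimum; using edge "
            "optimum at %.0f mm",
            region,
            x_star,
        )
    yc = gap_metrics.current_yield(panel, weight_by_area=weight_by_area)
    mean_gsr = float(panel["gsr"].mean())
    yw = boundary.water_limited_yield(bfit, mean_gsr)
    gaps = gap_metrics.yield_gaps(region, yc, ya, yw)
    return {
        "region": region,
        "frontier": ffit,
        "boundary": bfit,
        "gaps": gaps,
        "optimum_gsr": x_star,
        "ya_max": ya,
        "interior_optimum": interior,
        "mean_gsr": mean_gsr,
        "mean_wue": gap_metrics.mean_wue(panel),
        "pct_below_optimum": gap_metrics.fraction_below_optimum(
            panel["gsr"], x_star
        ),
        "wl_pct_of_gsr": gap_metrics.water_loss_fraction(bfit.wl, mean_gsr),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle into config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.weather is None:
        raise ConfigurationError("config.weather is required (csv path)")
    for name in ("weather", "yields"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise ConfigurationError(f"config.{name} not found: {p}")

    log.info("stage io: reading weather %s", config.weather)
    weather = io_panel.read_weather_table(config.weather)
    yields = io_panel.read_yield_table(config.yields)
    trials = io_panel.read_trial_table(config.trials) if config.trials else None
    log.info(
        "stage io: %d weather rows, %d counties, %d yield rows",
        len(weather),
        weather["fips"].nunique(),
        len(yields),
    )

    log.info("stage season: delineating at p = %.2f", config.p_threshold)
    seasons = delineate_counties(weather, config.p_threshold)
    sframe = seasons_frame(seasons)
    sframe.to_csv(outdir / "seasons.csv", index=False)
    summaries = season.summarize_panel(weather, seasons)
    out_sum = summaries.rename(
        columns={
            "fips": "county_fips",
            "gsr": "gsr_mm",
            "tmax_mean": "tmax_c",
            "tmin_mean": "tmin_c",
            "tav_mean": "tav_c",
            "gdd_sum": "gdd_c_day",
        }
    )
    out_sum.to_csv(outdir / "season_summaries.csv", index=False)

    panel = summaries.merge(
        yields[yields["source"] == "survey"],
        on=["fips", "year"],
        suffixes=("", "_y"),
    )
    if panel.empty:
        raise ConfigurationError("weather and yield panels share no county-years")
    log.info("stage merge: %d county-year observations", len(panel))

    regions = (
        {"ALL": panel}
        if config.fit_pooled
        else {st: grp for st, grp in panel.groupby("state", sort=True)}
    )
    frontier_rows, boundary_rows, gap_rows, gaps_list = [], [], [], []
    for region, grp in regions.items():
        tr = None
        if trials is not None and len(trials):
            tr = trials if config.fit_pooled else trials[trials["state"] == region]
            if not len(tr):
                tr = None
        res = analyze_region(
            region, grp, tr, config.bin_width, config.weight_by_area
        )
        f, b, g = res["frontier"], res["boundary"], res["gaps"]
        frontier_rows.append(
            {
                "region": region,
                "beta0": f.beta0,
                "beta1": f.beta1,
                "beta2": f.beta2,
                "optimum_gsr_mm": res["optimum_gsr"],
                "ya_max_mg_ha": res["ya_max"],
                "interior_optimum": res["interior_optimum"],
                "r2": f.r2,
                "n_support": f.n_support,
                "bin_width_mm": f.bin_width,
            }
        )
        boundary_rows.append(
            {
                "region": region,
                "slope": b.slope,
                "intercept": b.intercept,
                "wue_potential_kg_ha_mm": b.wue_potential,
                "wl_mm": b.wl,
                "responsive_max_gsr_mm": b.responsive_max_gsr,
                "n_support": b.n_support,
            }
        )
        gap_rows.append(
            {
                "region": region,
                "mean_gsr_mm": res["mean_gsr"],
                "mean_wue_kg_ha_mm": res["mean_wue"],
                "pct_below_optimum": res["pct_below_optimum"],
                "wl_pct_of_gsr": res["wl_pct_of_gsr"],
            }
        )
        gaps_list.append(g)
        log.info(
            "stage envelopes[%s]: X*=%.0f mm, WUEpot=%.1f, WL=%.0f mm",
            region,
            res["optimum_gsr"],
            b.wue_potential,
            b.wl,
        )

    pd.DataFrame(frontier_rows).to_csv(outdir / "frontier.csv", index=False)
    pd.DataFrame(boundary_rows).to_csv(outdir / "boundary.csv", index=False)
    report = gap_metrics.gap_report(gaps_list).merge(
        pd.DataFrame(gap_rows), on="region"
    )
    report.to_csv(outdir / "gaps.csv", index=False)

    log.info("stage cit: %d rows, covariates %s", len(panel), CIT_COVARIATES)
    X = panel[CIT_COVARIATES]
    y = panel["yield_mg_ha"].to_numpy()
    cfg = dataclasses.replace(config.cit_config, seed=config.seed)
    tree = cit.grow_tree(X, y, cfg)
    (outdir / "tree.json").write_text(tree.to_json(indent=1))
    (outdir / "tree.txt").write_text(tree.render())

    manifest = {
        "config": config.to_dict(),
        "n_weather_rows": int(len(weather)),
        "n_counties": int(weather["fips"].nunique()),
        "n_county_years": int(len(panel)),
        "regions": sorted(regions),
        "tree_leaves": tree.n_leaves(),
        "tree_r2": cit.r_squared(tree, X, y),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (outdir / "effective_config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    return {
        "seasons": sframe,
        "summaries": summaries,
        "frontier": pd.DataFrame(frontier_rows),
        "boundary": pd.DataFrame(boundary_rows),
        "gaps": report,
        "tree": tree,
        "manifest": manifest,
    }
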