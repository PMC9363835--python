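"""Reading, validation and gap-filling of daily weather and annual yield panels.

The canonical in-memory containers are pandas DataFrames:

* weather frame — columns ``fips`` (5-digit string), ``state`` (2-letter
  code), ``date`` (datetime64), ``tmax``/``tmin`` (deg C), ``prcp`` (mm),
  ``filled`` (bool); one row per county-day, sorted by county then date.
* yield frame — columns ``fips``, ``state``, ``year`` (int), ``yield_mg_ha``
  (Mg ha-1), ``area_ha`` (float, NaN when unreported), ``source``
  (``survey`` or ``variety_trial``); at most one survey row per county-year.

All internal units are fixed (deg C, mm, Mg ha-1, ha); unit conversion
happens only here, at the I/O boundary.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    MissingDataWarning,
    UnfillableGapError,
    ValidationError,
)

#: Mg ha-1 per (short) ton acre-1: 0.90718474 Mg / 0.40468564 ha
TONS_ACRE_TO_MG_HA = 2.2417

WEATHER_COLUMNS = ["fips", "state", "date", "tmax", "tmin", "prcp", "filled"]
YIELD_COLUMNS = ["fips", "state", "year", "yield_mg_ha", "area_ha", "source"]

#: share of gap-filled days above which a series is flagged as unreliable
FILL_WARN_FRACTION = 0.10


@dataclass(frozen=True)
class CountyKey:
    """A US county: 5-digit FIPS code plus 2-letter state abbreviation."""

    fips: str
    state: str = "XX"

    def __post_init__(self):
        if not re.fullmatch(r"\d{5}", self.fips):
            raise ValidationError(f"FIPS must be exactly 5 digits, got {self.fips!r}")
        if not re.fullmatch(r"[A-Z]{2}", self.state):
            raise ValidationError(
                f"state must be 2 uppercase letters, got {self.state!r}"
            )


def _normalize_fips(values) -> pd.Series:
    s = pd.Series(values).astype(str).str.strip()
    # tolerate numeric FIPS that lost leading zeros on the way through a spreadsheet
    s = s.str.replace(r"\.0$", "", regex=True).str.zfill(5)
    bad = ~s.str.fullmatch(r"\d{5}")
    if bad.any():
        raise ValidationError(
            f"invalid FIPS code(s): {sorted(s[bad].unique())[:5]}"
        )
    return s


def read_weather_table(source, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a delimited weather table into the canonical weather frame.

    Parameters
    ----------
    source : path or text stream
        CSV/TSV with one row per station-day.
    dialect : mapping, optional
        Maps canonical names (``date``, ``tmax``, ``tmin``, ``prcp``,
        ``fips``, optionally ``state``, ``filled``) to the column names
        actually present. Unmapped canonical names are looked up verbatim.

    Raises
    ------
    ConfigurationError
        if a mandatory column cannot be located.
    ValidationError
        if any row has tmax < tmin, negative precipitation, or an
        unparseable date — the offending rows are listed, never dropped.
    """
    raw = pd.read_csv(source, sep=None, engine="python")
    dialect = dict(dialect or {})
    mandatory = ["date", "tmax", "tmin", "prcp", "fips"]
    colmap = {}
    for canon in mandatory + ["state", "filled"]:
        actual = dialect.get(canon, canon)
        if actual in raw.columns:
            colmap[canon] = actual
        elif canon in mandatory:
            raise ConfigurationError(
                f"weather table is missing mandatory column {canon!r} "
                f"(looked for {actual!r}; have {list(raw.columns)})"
            )

    df = pd.DataFrame({c: raw[a] for c, a in colmap.items()})
    df["fips"] = _normalize_fips(df["fips"])
    if "state" not in df:
        df["state"] = "XX"
    df["state"] = df["state"].astype(str).str.upper()

    dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    if dates.isna().any():
        rows = df.index[dates.isna()].tolist()
        raise ValidationError(f"unparseable date(s) in rows {rows[:10]}")
    df["date"] = dates

    for col in ("tmax", "tmin", "prcp"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any():
            rows = df.index[df[col].isna()].tolist()
            raise ValidationError(f"non-numeric {col} in rows {rows[:10]}")

    bad = df["tmax"] < df["tmin"]
    if bad.any():
        raise ValidationError(
            f"tmax < tmin in rows {df.index[bad].tolist()[:10]}"
        )
    neg = df["prcp"] < 0
    if neg.any():
        raise ValidationError(
            f"negative precipitation in rows {df.index[neg].tolist()[:10]}"
        )

    if "filled" not in df:
        df["filled"] = False
    df["filled"] = df["filled"].astype(bool)

    df = df[WEATHER_COLUMNS].sort_values(["fips", "date"], kind="mergesort")
    return df.reset_index(drop=True)


def write_weather_table(df: pd.DataFrame, dest) -> None:
    """Write the canonical weather frame as CSV (ISO dates, full precision)."""
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(dest, index=False)


def read_yield_table(source) -> pd.DataFrame:
    """Read an annual yield table into the canonical yield frame.

    Recognised columns: ``county_fips`` (or ``fips``), ``year``, ``yield``
    (or ``yield_mg_ha``), optional ``unit`` (``mg_ha`` default or
    ``tons_acre``), ``area`` (ha), ``state``, ``source``. Yields reported in
    short tons per acre are converted to Mg ha-1 (x 2.2417). Duplicate
    survey county-years and nonpositive yields raise ValidationError.
    """
    raw = pd.read_csv(source, sep=None, engine="python")
    cols = {c.lower(): c for c in raw.columns}

    def pick(*names, required=False):
        for n in names:
            if n in cols:
                return raw[cols[n]]
        if required:
            raise ConfigurationError(
                f"yield table is missing a column named one of {names}"
            )
        return None

    fips = pick("county_fips", "fips", required=True)
    year = pick("year", required=True)
    yld = pick("yield", "yield_mg_ha", required=True)

    df = pd.DataFrame(
        {
            "fips": _normalize_fips(fips),
            "year": pd.to_numeric(year).astype(int),
            "yield_mg_ha": pd.to_numeric(yld, errors="coerce"),
        }
    )
    state = pick("state")
    df["state"] = state.astype(str).str.upper() if state is not None else "XX"

    unit = pick("unit")
    if unit is not None:
        unit = unit.astype(str).str.lower().str.strip()
        known = {"mg_ha", "mg/ha", "tons_acre", "tons/acre", "ton_acre"}
        unknown = set(unit.unique()) - known
        if unknown:
            raise ConfigurationError(f"unknown yield unit(s): {sorted(unknown)}")
        in_tons = unit.str.startswith("ton")
        df.loc[in_tons, "yield_mg_ha"] *= TONS_ACRE_TO_MG_HA

    if df["yield_mg_ha"].isna().any() or (df["yield_mg_ha"] <= 0).any():
        bad = df.index[~(df["yield_mg_ha"] > 0)].tolist()
        raise ValidationError(f"nonpositive or missing yield in rows {bad[:10]}")

    area = pick("area", "area_ha")
    df["area_ha"] = pd.to_numeric(area, errors="coerce") if area is not None else np.nan
    if (df["area_ha"] < 0).any():
        raise ValidationError("negative harvested area")

    src = pick("source")
    df["source"] = (
        src.astype(str).str.lower() if src is not None else "survey"
    )
    bad_src = ~df["source"].isin(["survey", "variety_trial"])
    if bad_src.any():
        raise ValidationError(
            f"unknown source value(s): {sorted(df.loc[bad_src, 'source'].unique())}"
        )

    surveys = df[df["source"] == "survey"]
    dup = surveys.duplicated(["fips", "year"], keep=False)
    if dup.any():
        keys = surveys.loc[dup, ["fips", "year"]].drop_duplicates()
        raise ValidationError(
            "duplicate survey county-year(s): "
            + ", ".join(f"{r.fips}/{r.year}" for r in keys.itertuples())
        )

    df = df[YIELD_COLUMNS].sort_values(["fips", "year"], kind="mergesort")
    return df.reset_index(drop=True)


def read_trial_table(source) -> pd.DataFrame:
    """Read variety-trial points: columns mappable to fips/state/year plus
    ``gsr`` (mm) and ``yield`` (Mg ha-1). These augment the boundary fit's
    upper envelope and are never merged into the survey panel."""
    raw = pd.read_csv(source, sep=None, engine="python")
    cols = {c.lower(): c for c in raw.columns}
    needed = {"gsr": ("gsr",), "yield_mg_ha": ("yield", "yield_mg_ha")}
    out = {}
    for canon, names in needed.items():
        for n in names:
            if n in cols:
                out[canon] = pd.to_numeric(raw[cols[n]], errors="coerce")
                break
        else:
            raise ConfigurationError(f"trial table missing column {names[0]!r}")
    df = pd.DataFrame(out)
    for n in ("county_fips", "fips"):
        if n in cols:
            df["fips"] = _normalize_fips(raw[cols[n]])
            break
    df["state"] = (
        raw[cols["state"]].astype(str).str.upper() if "state" in cols else "XX"
    )
    if df[["gsr", "yield_mg_ha"]].isna().any().any() or (df["yield_mg_ha"] <= 0).any():
        raise ValidationError("trial rows must have positive yield and numeric gsr")
    return df


def write_yield_table(df: pd.DataFrame, dest) -> None:
    out = df.rename(columns={"fips": "county_fips", "yield_mg_ha": "yield"})
    out.to_csv(dest, index=False)


def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Haversine distance in km (donor ranking only; no GIS ambitions)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * 6371.0 * math.asin(math.sqrt(a))


def fill_missing_days(
    series: pd.DataFrame,
    donors: Sequence[pd.DataFrame] = (),
    start=None,
    end=None,
    coords: Mapping[str, tuple[float, float]] | None = None,
    warn_fraction: float = FILL_WARN_FRACTION,
) -> tuple[pd.DataFrame, float]:
    """Fill calendar gaps in one county's weather series from donor series.

    Donors are tried nearest-first when ``coords`` gives (lat, lon) per FIPS;
    otherwise in the order supplied. Substituted rows carry ``filled=True``
    and keep the target county's identity. Returns the gap-free frame and
    the fill fraction (filled rows / total rows). A fraction above
    ``warn_fraction`` (default 10%) emits :class:`MissingDataWarning` but is
    never an error — exclusion is the caller's decision.

    Raises :class:`UnfillableGapError` listing dates no donor covers.
    """
    if series.empty:
        raise ValidationError("empty weather series")
    if series["fips"].nunique() != 1:
        raise ValidationError("fill_missing_days expects a single-county series")
    fips = series["fips"].iloc[0]
    state = series["state"].iloc[0]

    start = pd.Timestamp(start) if start is not None else series["date"].min()
    end = pd.Timestamp(end) if end is not None else series["date"].max()
    full = pd.date_range(start, end, freq="D")

    have = series.set_index("date")
    missing = full.difference(have.index)
    if len(missing) == 0:
        out = series.sort_values("date").reset_index(drop=True)
        frac = float(out["filled"].mean())
        return out, frac

    donor_list = list(donors)
    if coords is not None and fips in coords and donor_list:
        lat0, lon0 = coords[fips]

        def dist(d):
            f = d["fips"].iloc[0]
            if f not in coords:
                return float("inf")
            return great_circle_km(lat0, lon0, *coords[f])

        donor_list = sorted(donor_list, key=dist)

    donor_idx = [d.set_index("date") for d in donor_list]
    rows = []
    unfillable = []
    for day in missing:
        for d in donor_idx:
            if day in d.index:
                r = d.loc[day]
                rows.append(
                    {
                        "fips": fips,
                        "state": state,
                        "date": day,
                        "tmax": float(r["tmax"]),
                        "tmin": float(r["tmin"]),
                        "prcp": float(r["prcp"]),
                        "filled": True,
                    }
                )
                break
        else:
            unfillable.append(day.date())
    if unfillable:
        raise UnfillableGapError(unfillable)

    out = (
        pd.concat([series, pd.DataFrame(rows)], ignore_index=True)
        .sort_values("date", kind="mergesort")
        .reset_index(drop=True)
    )
    frac = float(out["filled"].mean())
    if frac > warn_fraction:
        warnings.warn(
            f"county {fips}: {frac:.1%} of days gap-filled (> {warn_fraction:.0%})",
            MissingDataWarning,
            stacklevel=2,
        )
    return out, frac


def iter_counties(weather: pd.DataFrame) -> Iterable[tuple[str, pd.DataFrame]]:
    """Yield (fips, single-county frame) pairs in sorted FIPS order."""
    for fips, grp in weather.groupby("fips", sort=True):
        yield fips, grp.reset_index(drop=True)
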