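import io

import numpy as np
import pandas as pd
import pytest

from yieldgap import pipeline, season, synthetic


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Self-contained synthetic weather/yield/trial bundle (3 counties x 10 y)."""
    dest = tmp_path_factory.mktemp("fixture")
    synthetic.make_fixture_suite(dest, seed=11)
    return dest


@pytest.fixture(scope="session")
def weather_panel():
    """Seeded 4-county x 10-year daily weather panel."""
    return synthetic.generate_weather(counties=4, years=10, seed=5)


@pytest.fixture(scope="session")
def season_summaries(weather_panel):
    seasons = pipeline.delineate_counties(weather_panel, season.P_THRESHOLD)
    return season.summarize_panel(weather_panel, seasons)


def weather_csv(rows: str) -> io.StringIO:
    """Inline CSV helper for io tests."""
    return io.StringIO(rows.strip() + "\n")


@pytest.fixture
def toy_weather_csv():
    return weather_csv(
        """
date,tmax,tmin,prcp,fips,state
2015-01-01,5.0,-2.0,0.0,17001,IL
2015-01-02,6.5,-1.0,3.2,17001,IL
2015-01-03,4.0,-3.0,0.5,17001,IL
"""
    )


def make_year(fips="99001", year=2015, tmax=20.0, tmin=10.0, prcp=1.0):
    """One gap-free calendar year of constant weather."""
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    return pd.DataFrame(
        {
            "fips": fips,
            "state": "XX",
            "date": dates,
            "tmax": float(tmax),
            "tmin": float(tmin),
            "prcp": float(prcp),
            "filled": False,
        }
    )
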