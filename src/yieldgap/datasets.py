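"""Packaged reference datasets.

``load_state_summary`` returns published state-level estimates for rainfed
alfalfa in 12 US states over 2009-2018: growing-season delineation (start/
end DOY, length, season temperatures, accumulated GDD), rainfall statistics
(mean and optimum GSR, minimum water loss, realised and potential WUE,
share of seasons below the optimum), and the yield ladder (Yc, Ya, Yw) with
absolute and percent gaps. It is the worked-example input for the gap
arithmetic — small enough to check every number by hand.

Two obvious misprints in the source table are corrected: the Ohio
season length is stored as end - start = 215 (printed as "21"), and the
column-mean Tmin is treated as 11.0 (printed as "110").
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_state_summary() -> pd.DataFrame:
    """State-level season, rainfall, WUE and yield-gap estimates (n = 12)."""
    with resources.files(__package__).joinpath("data/state_summary.csv").open() as fh:
        return pd.read_csv(fh)
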