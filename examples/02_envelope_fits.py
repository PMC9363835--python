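"""Fit the attainable-yield frontier and water-limited boundary envelopes.

Builds a 400-observation county-year panel whose yields follow a linear
water production function (true potential WUE 28 kg/ha/mm, minimum water
loss 150 mm) degraded by multiplicative inefficiency, then recovers those
parameters from the upper envelope of the yield-vs-rainfall cloud.
"""

import numpy as np
import pandas as pd

from yieldgap import boundary, frontier, synthetic

rng = np.random.default_rng(7)
summaries = pd.DataFrame(
    {
        "fips": "99001",
        "state": "XX",
        "year": 2009,
        "gsr": rng.uniform(250, 1150, 400),
    }
)
yields, truth = synthetic.generate_yield_panel(summaries=summaries, seed=7)
panel = pd.DataFrame({"gsr": summaries["gsr"], "yield_mg_ha": yields["yield_mg_ha"]})

bfit = boundary.fit_boundary_from_points(panel, bin_width=50)
print("linear boundary (upper envelope over the water-responsive range):")
print(f"  potential WUE : {bfit.wue_potential:5.1f} kg/ha/mm   (truth {truth['wue_true']})")
print(f"  min water loss: {bfit.wl:5.0f} mm          (truth {truth['wl_true']:.0f})")
print(f"  support points: {bfit.n_support}")

pts = synthetic.generate_log_quadratic_yields(-18.0, 6.5, -0.5, summaries["gsr"], seed=8)
ffit = frontier.fit_frontier_from_points(pts, bin_width=50)
true_opt = float(np.exp(6.5 / 1.0))
print("\nlog-quadratic frontier (on a panel with a true interior optimum):")
print(f"  optimum GSR   : {ffit.optimum_gsr:5.0f} mm          (truth {true_opt:.0f})")
print(f"  attainable Ya : {ffit.ya_max:5.1f} Mg/ha at the optimum")
print(
    "\nThe boundary slope is the best yield an extra mm of seasonal rain "
    "can buy; its x-intercept is rain lost before any yield forms. The "
    "frontier's peak marks the rainfall beyond which more water no longer "
    "raises the attainable yield."
)
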