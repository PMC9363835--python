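"""Explain yield variation with a conditional-inference tree.

Builds a county-year panel where yield truly depends on seasonal rainfall
through a step at 478 mm, plus three inert weather covariates, and lets
the permutation-tested tree find that structure. Splits happen only where
a covariate shows a Bonferroni-adjusted permutation p-value below 0.05, so
the tree stays small on noise.
"""

import numpy as np
import pandas as pd

from yieldgap import cit

rng = np.random.default_rng(99)
n = 800
X = pd.DataFrame(
    {
        "gsr": rng.uniform(250, 900, n),
        "tmax_mean": rng.uniform(20, 26, n),
        "tmin_mean": rng.uniform(8, 14, n),
        "gdd_sum": rng.uniform(1800, 3300, n),
    }
)
y = 4.0 + 3.0 * (X["gsr"].to_numpy() > 478.0) + rng.normal(0, 0.4, n)

tree = cit.grow_tree(X, y, cit.CITConfig(n_perm=1999, seed=99))
print(tree.render())
print(f"leaves: {tree.n_leaves()}   R^2: {cit.r_squared(tree, X, y):.3f}")

noise_tree = cit.grow_tree(X, rng.normal(size=n), cit.CITConfig(n_perm=1999, seed=100))
print(f"\nsame covariates, pure-noise response -> leaves: {noise_tree.n_leaves()}")
print(
    "\nThe fitted tree splits once, on rainfall near the true 478 mm step, "
    "and predicts each leaf's mean yield; with no real signal the "
    "significance gate leaves the tree as a single node."
)
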