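"""Conditional-inference regression tree with permutation split tests.

Recursive binary partitioning in which a split is only made when at least
one covariate shows a statistically significant association with the
response, so tree size is controlled by hypothesis tests instead of
post-hoc pruning. At each node:

1. every covariate is tested against the response with a permutation test
   of |Pearson r| and the p-values are Bonferroni-adjusted for the number
   of covariates;
2. if the smallest adjusted p-value is below ``alpha``, the node splits on
   that covariate at the cut point maximizing the standardized two-sample
   mean difference, subject to minimum-bucket constraints;
3. recurse into the two children.

The association test is the exact-style permutation p-value

    p = (1 + #{permutations with |r*| >= |r|}) / (1 + n_perm),

which can never be 0 and is uniform on its lattice under the null. Rows
whose covariate equals the threshold go LEFT (the <= convention).

Parsimony selection refits the tree over a grid of minimum-bucket sizes
and keeps the smallest tree whose training R^2 is within a tolerance
(default 5%) of the most permissive tree's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: permutations processed per block to bound peak memory
_PERM_BLOCK = 2048


@dataclass(frozen=True)
class CITConfig:
    alpha: float = 0.05
    n_perm: int = 9999
    min_node_frac: float = 0.05  # smallest node that may still be split
    min_leaf_frac: float = 0.01  # smallest allowed terminal node
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.n_perm < 99:
            raise ValidationError("n_perm must be >= 99")
        if self.min_leaf_frac > self.min_node_frac:
            raise ValidationError("min_leaf_frac must be <= min_node_frac")


@dataclass
class CITNode:
    n: int
    prediction: float
    split_var: str | None = None
    threshold: float | None = None
    adj_p: float | None = None
    children: tuple["CITNode", "CITNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return sum(c.n_leaves() for c in self.children)

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(c.depth() for c in self.children)

    def to_dict(self) -> dict:
        d = {"n": self.n, "prediction": self.prediction}
        if not self.is_leaf:
            d.update(
                split_var=self.split_var,
                threshold=self.threshold,
                adj_p=self.adj_p,
                children=[c.to_dict() for c in self.children],
            )
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def render(self, indent: int = 0) -> str:
        """Plain-text indented rendering of the tree."""
        pad = "  " * indent
        if self.is_leaf:
            return f"{pad}leaf: n={self.n}, mean={self.prediction:.3f}\n"
        out = (
            f"{pad}{self.split_var} <= {self.threshold:.3f} "
            f"(adj p={self.adj_p:.4g}, n={self.n})\n"
        )
        return out + "".join(c.render(indent + 1) for c in self.children)


def association_test(x, y, n_perm: int = 9999, seed: int = 0) -> float:
    """Permutation p-value of |Pearson correlation| between x and y.

    Deterministic for a fixed seed. Constant x or y returns p = 1 (no
    association is testable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise ValidationError("x and y must be equal-length 1-d, n >= 4")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        return 1.0
    r_obs = abs(float(np.dot(xc, yc) / (sx * sy)))

    rng = np.random.default_rng(seed)
    n = len(x)
    exceed = 0
    done = 0
    while done < n_perm:
        block = min(_PERM_BLOCK, n_perm - done)
        # permute y against fixed x; |r*| via one matmul per block
        perm = np.argsort(rng.random((block, n)), axis=1)
        r_perm = np.abs(yc[perm] @ xc) / (sx * sy)
        exceed += int(np.count_nonzero(r_perm >= r_obs - 1e-12))
        done += block
    return (1 + exceed) / (1 + n_perm)


def best_split(x, y, min_leaf: int = 1) -> tuple[float, float] | None:
    """Cut point maximizing the standardized two-sample mean difference.

    Candidate thresholds are midpoints between consecutive sorted unique x
    values; both sides must hold >= ``min_leaf`` rows (the <= convention
    sends threshold-equal rows left). The statistic is
    |mean_L - mean_R| / (s_pooled * sqrt(1/n_L + 1/n_R)); a zero pooled SD
    with unequal means scores infinity (perfect separation). Ties keep the
    smaller threshold. Returns (threshold, statistic), or None when no
    feasible split exists.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    uniq = np.unique(xs)
    if len(uniq) < 2:
        return None

    best = None
    for k in range(len(uniq) - 1):
        thr = (uniq[k] + uniq[k + 1]) / 2.0
        left = xs <= thr
        n_l = int(left.sum())
        n_r = len(xs) - n_l
        if n_l < min_leaf or n_r < min_leaf:
            continue
        yl, yr = ys[left], ys[~left]
        diff = abs(yl.mean() - yr.mean())
        ssq = np.sum((yl - yl.mean()) ** 2) + np.sum((yr - yr.mean()) ** 2)
        dof = n_l + n_r - 2
        sp = np.sqrt(ssq / dof) if dof > 0 else 0.0
        if sp == 0:
            stat = np.inf if diff > 0 else 0.0
        else:
            stat = diff / (sp * np.sqrt(1.0 / n_l + 1.0 / n_r))
        if best is None or stat > best[1]:
            best = (float(thr), float(stat))
    return best


def _grow(
    X: pd.DataFrame,
    y: np.ndarray,
    rows: np.ndarray,
    config: CITConfig,
    n_total: int,
    seed_seq: np.random.SeedSequence,
) -> CITNode:
    node = CITNode(n=len(rows), prediction=float(y[rows].mean()))
    min_node = int(np.ceil(config.min_node_frac * n_total))
    min_leaf = max(1, int(np.ceil(config.min_leaf_frac * n_total)))
    if len(rows) < max(min_node, 2 * min_leaf):
        return node

    covars = list(X.columns)
    # one child seed per covariate test + two for the children, all drawn
    # deterministically from this node's sequence
    seeds = seed_seq.spawn(len(covars) + 2)
    pvals = {}
    for cov, s in zip(covars, seeds):
        p = association_test(
            X[cov].to_numpy()[rows],
            y[rows],
            n_perm=config.n_perm,
            seed=s.generate_state(1)[0] % (2**31),
        )
        pvals[cov] = min(1.0, p * len(covars))  # Bonferroni
    best_cov = min(pvals, key=lambda c: (pvals[c], covars.index(c)))
    if pvals[best_cov] >= config.alpha:
        return node

    split = best_split(X[best_cov].to_numpy()[rows], y[rows], min_leaf=min_leaf)
    if split is None:
        return node
    thr, _stat = split

    mask = X[best_cov].to_numpy()[rows] <= thr
    left_rows, right_rows = rows[mask], rows[~mask]
    node.split_var = best_cov
    node.threshold = thr
    node.adj_p = pvals[best_cov]
    node.children = (
        _grow(X, y, left_rows, config, n_total, seeds[-2]),
        _grow(X, y, right_rows, config, n_total, seeds[-1]),
    )
    return node


def grow_tree(X: pd.DataFrame, y, config: CITConfig | None = None) -> CITNode:
    """Fit the tree. Covariates must be numeric and complete (no NaN)."""
    config = config or CITConfig()
    y = np.asarray(y, dtype=float)
    if len(X) == 0 or len(X) != len(y):
        raise ValidationError("X and y must be nonempty and the same length")
    if X.isna().to_numpy().any() or np.isnan(y).any():
        raise ValidationError("missing values are not handled")
    rows = np.arange(len(y))
    return _grow(X, y, rows, config, len(y), np.random.SeedSequence(config.seed))


def predict(root: CITNode, row) -> float:
    """Route one observation (mapping or Series) to its leaf mean."""
    node = root
    while not node.is_leaf:
        if node.split_var not in row:
            raise ValidationError(f"row lacks covariate {node.split_var!r}")
        val = row[node.split_var]
        if pd.isna(val):
            raise ValidationError(f"missing value for {node.split_var!r}")
        node = node.children[0] if val <= node.threshold else node.children[1]
    return node.prediction


def predict_frame(root: CITNode, X: pd.DataFrame) -> np.ndarray:
    return np.array([predict(root, row) for _, row in X.iterrows()])


def r_squared(root: CITNode, X: pd.DataFrame, y) -> float:
    y = np.asarray(y, dtype=float)
    resid = y - predict_frame(root, X)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 1.0
    return 1.0 - float(np.sum(resid**2)) / tss


def rmse(root: CITNode, X: pd.DataFrame, y) -> float:
    y = np.asarray(y, dtype=float)
    return float(np.sqrt(np.mean((y - predict_frame(root, X)) ** 2)))


#: bucket-size grid walked by the parsimony search (fractions of n)
PARSIMONY_GRID = tuple(
    (node, leaf)
    for node in (0.05, 0.10, 0.20, 0.40)
    for leaf in (0.01, 0.05, 0.10)
    if leaf <= node
)


def select_parsimonious(
    X: pd.DataFrame,
    y,
    config: CITConfig | None = None,
    grid: Sequence[tuple[float, float]] = PARSIMONY_GRID,
    tolerance: float = 0.05,
) -> tuple[CITNode, pd.DataFrame]:
    """Smallest tree within ``tolerance`` of the baseline tree's R^2.

    The baseline is the most permissive grid point (0.05, 0.01). Candidates
    are ranked by leaf count; ties prefer the larger minimum-leaf fraction
    (the more conservative tree). Returns (tree, candidate table).
    """
    base = config or CITConfig()
    candidates = []
    for node_frac, leaf_frac in grid:
        cfg = CITConfig(
            alpha=base.alpha,
            n_perm=base.n_perm,
            min_node_frac=node_frac,
            min_leaf_frac=leaf_frac,
            seed=base.seed,
        )
        tree = grow_tree(X, y, cfg)
        candidates.append(
            {
                "min_node_frac": node_frac,
                "min_leaf_frac": leaf_frac,
                "n_leaves": tree.n_leaves(),
                "r2": r_squared(tree, X, y),
                "rmse": rmse(tree, X, y),
                "tree": tree,
            }
        )
    table = pd.DataFrame(candidates)
    baseline_r2 = float(
        table.loc[
            (table["min_node_frac"] == 0.05) & (table["min_leaf_frac"] == 0.01),
            "r2",
        ].iloc[0]
    )
    ok = table[table["r2"] >= (1.0 - tolerance) * baseline_r2]
    chosen = ok.sort_values(
        ["n_leaves", "min_leaf_frac"], ascending=[True, False], kind="mergesort"
    ).iloc[0]
    return chosen["tree"], table.drop(columns="tree")
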