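import json

import numpy as np
import pandas as pd
import pytest

from yieldgap import cit
from yieldgap.errors import ValidationError


def step_panel(n=300, threshold=478.0, noise=0.2, seed=10):
    """Yield = 4 + 3 * [gsr > threshold] + N(0, noise^2), 4 covariates."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "gsr": rng.uniform(250, 900, n),
            "tmax_mean": rng.uniform(20, 26, n),
            "tmin_mean": rng.uniform(8, 14, n),
            "gdd_sum": rng.uniform(1800, 3300, n),
        }
    )
    y = 4.0 + 3.0 * (X["gsr"].to_numpy() > threshold) + rng.normal(0, noise, n)
    return X, y


class TestAssociationTest:
    def test_perfect_association_minimum_p(self):
        x = np.arange(20.0)
        p = cit.association_test(x, x, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_constant_response_p_one(self):
        x = np.arange(10.0)
        assert cit.association_test(x, np.ones(10), n_perm=999, seed=0) == 1.0
        assert cit.association_test(np.ones(10), x, n_perm=999, seed=0) == 1.0

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        p1 = cit.association_test(x, y, n_perm=1999, seed=7)
        p2 = cit.association_test(x, y, n_perm=1999, seed=7)
        assert p1 == p2

    def test_sign_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = 2 * x + rng.normal(size=40)
        p_pos = cit.association_test(x, y, n_perm=999, seed=3)
        p_neg = cit.association_test(x, -y, n_perm=999, seed=3)
        assert p_pos == p_neg

    def test_too_short_input_rejected(self):
        with pytest.raises(ValidationError):
            cit.association_test([1.0, 2.0], [1.0, 2.0], seed=0)


class TestBestSplit:
    def test_perfect_separation_threshold(self):
        x = np.arange(1.0, 7.0)
        y = np.array([1.0, 1, 1, 9, 9, 9])
        thr, stat = cit.best_split(x, y, min_leaf=1)
        assert 3.0 < thr < 4.0
        assert stat == np.inf

    def test_infeasible_min_leaf_returns_none(self):
        x = np.arange(1.0, 7.0)
        y = np.array([1.0, 1, 1, 9, 9, 9])
        assert cit.best_split(x, y, min_leaf=4) is None

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(14)
        for trial in range(5):
            x = rng.uniform(0, 10, 40)
            y = rng.normal(size=40)
            got = cit.best_split(x, y, min_leaf=3)
            # brute-force oracle over every midpoint
            uniq = np.unique(x)
            best = None
            for k in range(len(uniq) - 1):
                thr = (uniq[k] + uniq[k + 1]) / 2
                l, r = y[x <= thr], y[x > thr]
                if len(l) < 3 or len(r) < 3:
                    continue
                sp = np.sqrt(
                    (np.sum((l - l.mean()) ** 2) + np.sum((r - r.mean()) ** 2))
                    / (len(l) + len(r) - 2)
                )
                stat = (
                    abs(l.mean() - r.mean()) / (sp * np.sqrt(1 / len(l) + 1 / len(r)))
                    if sp > 0
                    else np.inf
                )
                if best is None or stat > best[1]:
                    best = (thr, stat)
            assert got[0] == pytest.approx(best[0])
            assert got[1] == pytest.approx(best[1])


class TestGrowTree:
    def test_step_function_recovers_split(self):
        X, y = step_panel(n=300, seed=10)
        tree = cit.grow_tree(X, y, cit.CITConfig(n_perm=999, seed=1))
        assert tree.split_var == "gsr"
        assert abs(tree.threshold - 478.0) <= 15.0
        # descendants may only refine on gsr (nothing else carries signal)
        def split_vars(node):
            if node.is_leaf:
                return set()
            return {node.split_var} | split_vars(node.children[0]) | split_vars(node.children[1])
        assert split_vars(tree) == {"gsr"}

    def test_stopping_rule_makes_leaves(self):
        X, y = step_panel(n=40, seed=3)
        cfg = cit.CITConfig(n_perm=199, min_node_frac=0.6, min_leaf_frac=0.25, seed=2)
        tree = cit.grow_tree(X, y, cfg)
        if not tree.is_leaf:
            assert tree.children[0].is_leaf and tree.children[1].is_leaf

    def test_partition_property(self):
        X, y = step_panel(n=200, seed=4)
        tree = cit.grow_tree(X, y, cit.CITConfig(n_perm=499, seed=5))
        leaves = []
        def collect(node):
            if node.is_leaf:
                leaves.append(node)
            else:
                collect(node.children[0]); collect(node.children[1])
        collect(tree)
        assert sum(l.n for l in leaves) == len(y)

    def test_fixed_seed_bit_identical(self):
        X, y = step_panel(n=150, seed=6)
        cfg = cit.CITConfig(n_perm=499, seed=9)
        t1 = cit.grow_tree(X, y, cfg)
        t2 = cit.grow_tree(X, y, cfg)
        assert t1.to_json() == t2.to_json()

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            cit.grow_tree(pd.DataFrame({"a": []}), np.array([]))


class TestPredict:
    def test_single_leaf_returns_global_mean(self):
        X, y = step_panel(n=100, seed=7)
        leaf = cit.CITNode(n=len(y), prediction=float(np.mean(y)))
        assert cit.predict(leaf, {"anything": 1.0}) == pytest.approx(np.mean(y))

    def test_row_at_threshold_goes_left(self):
        left = cit.CITNode(n=1, prediction=1.0)
        right = cit.CITNode(n=1, prediction=2.0)
        root = cit.CITNode(
            n=2, prediction=1.5, split_var="gsr", threshold=400.0, children=(left, right)
        )
        assert cit.predict(root, {"gsr": 400.0}) == 1.0
        assert cit.predict(root, {"gsr": 400.0001}) == 2.0

    def test_training_predictions_are_leaf_means(self):
        X, y = step_panel(n=200, seed=8)
        tree = cit.grow_tree(X, y, cit.CITConfig(n_perm=499, seed=11))
        preds = cit.predict_frame(tree, X)
        # group-by oracle: rows sharing a prediction share a leaf mean
        df = pd.DataFrame({"pred": preds, "y": y})
        for pred, grp in df.groupby("pred"):
            assert pred == pytest.approx(grp["y"].mean())

    def test_missing_covariate_rejected(self):
        root = cit.CITNode(
            n=2, prediction=1.5, split_var="gsr", threshold=400.0,
            children=(cit.CITNode(n=1, prediction=1.0), cit.CITNode(n=1, prediction=2.0)),
        )
        with pytest.raises(ValidationError, match="gsr"):
            cit.predict(root, {"tmax_mean": 20.0})


class TestParsimony:
    def test_single_candidate_returned(self):
        X, y = step_panel(n=120, seed=12)
        cfg = cit.CITConfig(n_perm=199, seed=13)
        tree, table = cit.select_parsimonious(X, y, cfg, grid=[(0.05, 0.01)])
        assert len(table) == 1
        assert tree.n_leaves() == table["n_leaves"].iloc[0]

    def test_deeper_tree_never_loses_r2(self):
        X, y = step_panel(n=200, seed=14)
        permissive = cit.grow_tree(X, y, cit.CITConfig(n_perm=499, seed=15))
        restrictive = cit.grow_tree(
            X, y, cit.CITConfig(n_perm=499, min_node_frac=0.4, min_leaf_frac=0.1, seed=15)
        )
        assert cit.r_squared(permissive, X, y) >= cit.r_squared(restrictive, X, y) - 1e-12

    def test_step_function_selects_two_leaf_tree(self):
        # one clean step: extra splits add almost no R^2, so the smallest
        # candidate within 5% of baseline R^2 is the 2-leaf tree
        X, y = step_panel(n=400, noise=0.05, seed=16)
        cfg = cit.CITConfig(n_perm=499, seed=17)
        tree, table = cit.select_parsimonious(X, y, cfg)
        assert tree.n_leaves() == 2
        baseline = table.loc[
            (table["min_node_frac"] == 0.05) & (table["min_leaf_frac"] == 0.01), "r2"
        ].iloc[0]
        assert cit.r_squared(tree, X, y) >= 0.95 * baseline

    def test_equal_r2_prefers_fewer_leaves(self):
        X, y = step_panel(n=200, noise=0.01, seed=18)
        cfg = cit.CITConfig(n_perm=299, seed=19)
        tree, table = cit.select_parsimonious(X, y, cfg)
        near_best = table[table["r2"] >= 0.95 * table["r2"].max()]
        assert tree.n_leaves() == near_best["n_leaves"].min()


class TestSerialization:
    def test_json_round_trip_structure(self):
        X, y = step_panel(n=150, seed=20)
        tree = cit.grow_tree(X, y, cit.CITConfig(n_perm=499, seed=21))
        d = json.loads(tree.to_json())
        assert d["n"] == 150
        if "children" in d:
            assert len(d["children"]) == 2
            assert d["split_var"] == "gsr"
        assert "gsr" in tree.render()
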