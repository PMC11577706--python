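"""Tests of tree growth, bootstrap accounting, BOP extraction and OOB."""

import io

import numpy as np
import pytest

from cateforest.forest import (
    ForestConfig,
    build_forest,
    forest_from_jsonl,
    forest_to_jsonl,
    get_bop,
    oob_predict_mean,
)

from conftest import make_noiseless_step


def small_forest(n=200, seed=0, **kw):
    X, Y, G, _ = make_noiseless_step(n, seed=seed)
    defaults = dict(rule="HET", n_trees=5, min_node=20, seed=seed)
    defaults.update(kw)
    cfg = ForestConfig(**defaults)
    return build_forest(X, Y, G, cfg), X, Y, G


class TestBuild:
    def test_root_only_when_min_node_equals_n(self):
        f, X, Y, G = small_forest(n=100, min_node=100, n_trees=3)
        assert all(t.n_leaves == 1 for t in f.trees)
        bop = get_bop(f, X[0])
        assert bop.size == 3 * 100  # full bootstrap sample per tree

    def test_no_bootstrap_inbag_all_ones(self):
        f, *_ = small_forest(bootstrap=False, n_trees=2)
        for t in f.trees:
            assert np.array_equal(t.inbag_counts, np.ones(200, dtype=int))

    def test_step_effect_trees_split_on_x4_near_5(self):
        f, *_ = small_forest(n=300, n_trees=10, min_node=20)
        x4_thresholds = np.concatenate(
            [t.threshold[t.feature == 3] for t in f.trees]
        )
        assert x4_thresholds.size > 0
        assert np.any(np.abs(x4_thresholds - 5.0) < 1.0)

    def test_same_seed_identical_forest(self):
        f1, *_ = small_forest(seed=9)
        f2, *_ = small_forest(seed=9)
        for a, b in zip(f1.trees, f2.trees):
            assert np.array_equal(a.feature, b.feature)
            assert np.array_equal(a.threshold[a.feature >= 0], b.threshold[b.feature >= 0])
            assert np.array_equal(a.inbag_counts, b.inbag_counts)

    def test_terminal_nodes_respect_min_node(self):
        f, *_ = small_forest(n=300, n_trees=5, min_node=25)
        for t in f.trees:
            leaf_ids = np.flatnonzero(t.feature == -1)
            sizes = t.leaf_stats[leaf_ids, 0]
            assert (sizes >= 25).all()

    def test_bootstrap_oob_fraction_near_exp_minus_one(self):
        # root-only trees keep this cheap: only the bootstrap draw matters
        X = np.random.default_rng(0).uniform(0, 10, (1000, 2))
        Y = np.zeros(1000)
        G = np.linspace(0, 1, 1000)
        f = build_forest(X, Y, G, ForestConfig(rule="VAR", n_trees=100, min_node=1000, seed=2))
        oob = np.mean([t.inbag_counts == 0 for t in f.trees])
        assert oob == pytest.approx(np.exp(-1), rel=0.02)

    def test_swor_subsampling(self):
        f, *_ = small_forest(samptype="swor", n_trees=3)
        for t in f.trees:
            assert t.inbag_counts.max() == 1
            assert t.inbag_counts.sum() == round(0.632 * 200)


class TestBOP:
    def test_conservation_per_tree(self):
        f, X, *_ = small_forest(n=250, n_trees=4)
        for t in f.trees:
            leaf_ids = np.flatnonzero(t.feature == -1)
            assert t.leaf_stats[leaf_ids, 0].sum() == pytest.approx(250)
            member_total = sum(t.leaf_rows[i][1].sum() for i in leaf_ids)
            assert member_total == 250

    def test_multiplicity_matches_leaf_sizes(self):
        f, X, *_ = small_forest(n=150, n_trees=6)
        q = X[7]
        bop = get_bop(f, q)
        leaf_total = sum(
            int(t.leaf_stats[t.apply(q.reshape(1, -1))[0], 0]) for t in f.trees
        )
        assert bop.size == leaf_total
        assert (bop.multiplicities > 0).all()

    def test_same_leaf_queries_share_bop(self):
        f, X, *_ = small_forest(n=150, n_trees=4)
        q = X[3]
        b1 = get_bop(f, q)
        b2 = get_bop(f, q + 1e-9)
        assert np.array_equal(b1.indices, b2.indices)
        assert np.array_equal(b1.multiplicities, b2.multiplicities)

    def test_bop_is_x4_localized_on_step_data(self):
        for seed in (0, 1):
            X, Y, G, _ = make_noiseless_step(400, seed=seed)
            f = build_forest(X, Y, G, ForestConfig(rule="HET", n_trees=25, min_node=20, seed=7))
            q = np.array([5.0, 5.0, 5.0, 2.5, 5.0])
            bop = get_bop(f, q)
            same = X[bop.indices, 3] < 5
            purity = float((bop.multiplicities * same).sum() / bop.size)
            assert purity >= 0.9


class TestOOBPredict:
    def test_constant_target(self):
        X = np.random.default_rng(1).uniform(0, 10, (120, 3))
        target = np.full(120, 3.7)
        f = build_forest(X, target, np.zeros(120), ForestConfig(rule="VAR", n_trees=10, min_node=20, seed=3))
        pred, fallback = oob_predict_mean(f, X)
        assert np.allclose(pred, 3.7)
        assert not fallback.any()

    def test_single_tree_fallback_fraction(self):
        X = np.random.default_rng(2).uniform(0, 10, (1000, 2))
        f = build_forest(X, X[:, 0], np.zeros(1000), ForestConfig(rule="VAR", n_trees=1, min_node=1000, seed=4))
        _, fallback = oob_predict_mean(f, X)
        # in-bag fraction of one bootstrap sample ~ 1 - e^-1
        assert fallback.mean() == pytest.approx(1 - np.exp(-1), abs=0.05)

    def test_oob_tracks_smooth_signal(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 10, (800, 3))
        target = X[:, 0] + rng.normal(0, 0.3, 800)
        f = build_forest(X, target, np.zeros(800), ForestConfig(rule="VAR", n_trees=50, min_node=30, seed=5))
        pred, _ = oob_predict_mean(f, X)
        assert np.mean((pred - target) ** 2) < 0.3 * np.var(target)


class TestSerialization:
    def test_round_trip_lossless(self):
        f, X, *_ = small_forest(n=150, n_trees=3)
        buf = io.StringIO()
        forest_to_jsonl(f, buf)
        buf.seek(0)
        g = forest_from_jsonl(buf)
        assert g.n_trees == f.n_trees
        assert g.config == f.config
        queries = X[:20]
        assert np.array_equal(f.bop_suffstats(queries), g.bop_suffstats(queries))
        b1, b2 = get_bop(f, X[0]), get_bop(g, X[0])
        assert np.array_equal(b1.indices, b2.indices)
        assert np.array_equal(b1.multiplicities, b2.multiplicities)
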