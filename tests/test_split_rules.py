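"""Tests of the HET / CMB / VAR split criteria and the candidate search."""

import math

import numpy as np
import pytest

from cateforest.node_model import NodeModel, fit_node
from cateforest.split_rules import best_split, cmb_score, het_score, var_score

from conftest import brute_force_best, make_noiseless_step


def _nm(tau, n, sse=0.0, degenerate=False):
    return NodeModel(0.0, tau, sse, n, 0.1, degenerate)


class TestScores:
    def test_het_zero_when_children_agree(self):
        assert het_score(_nm(2.0, 30), _nm(2.0, 30)) == 0.0

    def test_het_product_and_sqrt_weights(self):
        left, right = _nm(1.0, 2), _nm(3.0, 2)
        assert het_score(left, right) == pytest.approx(8.0)  # 2*2*|1-3|
        assert het_score(left, right, weight="sqrt") == pytest.approx(4.0)

    def test_het_symmetric(self):
        left, right = _nm(1.5, 10), _nm(0.5, 25)
        assert het_score(left, right) == het_score(right, left)

    def test_het_degenerate_child_invalid(self):
        assert het_score(_nm(1.0, 5, degenerate=True), _nm(2.0, 5)) == -math.inf

    def test_het_unknown_weight(self):
        with pytest.raises(ValueError):
            het_score(_nm(1.0, 5), _nm(2.0, 5), weight="cubic")

    def test_cmb_additive(self):
        assert cmb_score(_nm(1.0, 5, sse=1.5), _nm(2.0, 5, sse=2.5)) == pytest.approx(4.0)
        assert cmb_score(_nm(1.0, 5), _nm(2.0, 5)) == 0.0
        assert cmb_score(_nm(1.0, 5, degenerate=True), _nm(2.0, 5)) == math.inf

    def test_var_score_hand_values(self):
        Y = np.array([0.0, 0.0, 10.0, 10.0])
        assert var_score(Y[:2], Y[2:]) == pytest.approx(0.0)
        # split off one point: right SS around mean 20/3 is 200/3
        assert var_score(Y[:1], Y[1:]) == pytest.approx(200 / 3)
        assert var_score(np.full(3, 2.0), np.full(4, 2.0)) == 0.0

    def test_var_defined_when_g_constant_but_cmb_invalid(self):
        Y = np.array([1.0, 2.0, 3.0, 4.0])
        G = np.full(4, 0.5)
        left = fit_node(Y[:2], G[:2], g_scale=1.0)
        right = fit_node(Y[2:], G[2:], g_scale=1.0)
        assert cmb_score(left, right) == math.inf
        assert math.isfinite(var_score(Y[:2], Y[2:]))


class TestBestSplit:
    def test_het_finds_step_boundary_on_noiseless_data(self, rng):
        X, Y, G, _ = make_noiseless_step(80, seed=3, flat_baseline=True, x4_gap=True)
        cand = best_split(
            X, Y, G, "HET", mtry=5, nsplit=None, min_child=5, rng=rng
        )
        assert cand is not None and cand.var_index == 3
        # the split separates the two effect regimes (at most 2 points
        # misplaced: slope leverage can favour a just-off-boundary cut)
        misplaced = int(((X[:, 3] < 5) & (X[:, 3] > cand.threshold)).sum()
                        + ((X[:, 3] >= 5) & (X[:, 3] <= cand.threshold)).sum())
        assert misplaced <= 2

    def test_cmb_prefers_prognostic_covariate_when_tau_constant(self, rng):
        n = 80
        r = np.random.default_rng(8)
        X = r.uniform(0, 10, (n, 3))
        G = r.uniform(0, 1, n)
        Y = 2.0 * (X[:, 0] > 5) + 1.0 * G  # pure prognostic step in X1
        cand = best_split(X, Y, G, "CMB", mtry=3, nsplit=None, min_child=5, rng=rng)
        assert cand is not None and cand.var_index == 0
        het = best_split(
            X, Y, G, "HET", mtry=3, nsplit=None, min_child=5,
            rng=np.random.default_rng(0),
        )
        # constant tau: the implied slope contrast |tau_L - tau_R| is
        # finite-sample leakage, below the prognostic jump of 2
        assert het is None or het.score / (het.n_left * het.n_right) < 2.0

    def test_min_child_larger_than_half_returns_none(self, rng):
        X, Y, G, _ = make_noiseless_step(30, seed=4)
        assert best_split(X, Y, G, "CMB", mtry=5, nsplit=10, min_child=16, rng=rng) is None

    @pytest.mark.parametrize("rule", ["HET", "CMB", "VAR"])
    def test_oracle_equivalence_exhaustive(self, rule):
        """Incremental search equals brute-force enumeration (30 nodes)."""
        for i in range(30):
            r = np.random.default_rng(1000 + i)
            m = int(r.integers(12, 50))
            X = r.uniform(0, 10, (m, 3))
            G = r.uniform(0, 1, m)
            Y = X[:, 0] / 4 + (1 + X[:, 1] / 5) * G + r.normal(0, 0.5, m)
            oracle_score, oracle = brute_force_best(X, Y, G, rule, min_child=3)
            cand = best_split(
                X, Y, G, rule, mtry=3, nsplit=None, min_child=3,
                rng=np.random.default_rng(i),
            )
            assert (cand is None) == (oracle is None)
            if cand is None:
                continue
            assert cand.score == pytest.approx(oracle_score, rel=1e-9, abs=1e-9)
            # the returned candidate achieves the oracle score
            mask = X[:, cand.var_index] <= cand.threshold
            g_scale = float(G.max() - G.min())
            left = fit_node(Y[mask], G[mask], g_scale=g_scale)
            right = fit_node(Y[~mask], G[~mask], g_scale=g_scale)
            if rule == "HET":
                achieved = het_score(left, right)
            elif rule == "CMB":
                achieved = cmb_score(left, right)
            else:
                achieved = var_score(Y[mask], Y[~mask])
            assert achieved == pytest.approx(oracle_score, rel=1e-9, abs=1e-9)

    def test_deterministic_given_rng_state(self):
        X, Y, G, _ = make_noiseless_step(60, seed=5)
        a = best_split(X, Y, G, "CMB", mtry=5, nsplit=10, min_child=5,
                       rng=np.random.default_rng(42))
        b = best_split(X, Y, G, "CMB", mtry=5, nsplit=10, min_child=5,
                       rng=np.random.default_rng(42))
        assert a == b
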