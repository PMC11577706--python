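import math

import numpy as np
import pytest

from cateforest.dgp import baseline
from cateforest.node_model import fit_node
from cateforest.split_rules import SplitRule, cmb_score, het_score, var_score


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_noiseless_step(n, seed, p=5, flat_baseline=False, x4_gap=False):
    """Noiseless varying-coefficient data with a step effect in X4.

    ``flat_baseline`` replaces the piecewise prognostic part by a
    constant so the treatment effect is the only signal; ``x4_gap``
    leaves (4, 6) empty in X4 so the two effect regimes are separated
    by a wide margin.
    """
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 10, (n, p))
    if x4_gap:
        x4 = X[:, 3]
        X[:, 3] = np.where(x4 < 5, x4 * 0.4, 6 + (x4 - 5) * 0.8)
    G = rng.uniform(0, 1, n)
    tau = np.where(X[:, 3] < 5, 1.0, 5.0)
    mu = 1.0 if flat_baseline else baseline(X[:, 0], X[:, 1], X[:, 2])
    Y = mu + tau * G
    return X, Y, G, tau


def brute_force_best(X, Y, G, rule, min_child, het_weight="product"):
    """Exhaustive split search over all covariates and midpoints.

    Independent oracle for best_split: O(p * m^2) direct fits, no
    shared code with the incremental implementation.
    """
    rule = SplitRule(rule)
    m, p = X.shape
    g_scale = float(G.max() - G.min())
    best_score, best = None, None
    for j in range(p):
        uniq = np.unique(X[:, j])
        for thr in (uniq[:-1] + uniq[1:]) / 2.0:
            mask = X[:, j] <= thr
            nl, nr = int(mask.sum()), int((~mask).sum())
            if nl < max(min_child, 2) or nr < max(min_child, 2):
                continue
            left = fit_node(Y[mask], G[mask], g_scale=g_scale)
            right = fit_node(Y[~mask], G[~mask], g_scale=g_scale)
            if rule is SplitRule.HET:
                s = het_score(left, right, het_weight)
                if not math.isfinite(s):
                    continue
                better = best_score is None or s > best_score
            elif rule is SplitRule.CMB:
                s = cmb_score(left, right)
                if not math.isfinite(s):
                    continue
                better = best_score is None or s < best_score
            else:
                s = var_score(Y[mask], Y[~mask])
                better = best_score is None or s < best_score
            if better:
                best_score, best = s, (j, float(thr), nl, nr)
    return best_score, best
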