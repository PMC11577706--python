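"""Split criteria for causal and auxiliary regression trees.

Three rules are provided:

* ``HET`` — maximize weighted treatment-effect heterogeneity,
  w(N_L, N_R) * |tau_L - tau_R|, the direct heterogeneity-seeking rule;
* ``CMB`` — minimize the pooled residual sum of squares of the
  within-child linear models Y = mu + tau*G, a CART-style counterpart
  of model-based recursive partitioning;
* ``VAR`` — classic least-squares regression-tree rule (pooled
  within-child SS around child means), used by the auxiliary centering
  forests that estimate E[Y|X] and the propensity E[G|X].

HET and CMB require both children to have non-constant G; VAR has no
such constraint.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .node_model import NodeModel, PrefixStats, g_var_tolerance

__all__ = ["SplitRule", "SplitCandidate", "het_score", "cmb_score", "var_score", "best_split"]


class SplitRule(str, enum.Enum):
    HET = "HET"
    CMB = "CMB"
    VAR = "VAR"


@dataclass(frozen=True)
class SplitCandidate:
    """A scored candidate split (rows with X[var] <= threshold go left)."""

    var_index: int
    threshold: float
    score: float
    rule: SplitRule
    n_left: int
    n_right: int
    valid: bool = True


def het_score(left: NodeModel, right: NodeModel, weight: str = "product") -> float:
    """Heterogeneity score w(N_L, N_R) * |tau_L - tau_R| (maximized).

    ``weight`` selects the size weight: ``"product"`` uses N_L * N_R
    (the default), ``"sqrt"`` uses sqrt(N_L * N_R).  A degenerate child
    (constant G) makes the candidate invalid: -inf.
    """
    if left.degenerate or right.degenerate:
        return -math.inf
    w = left.n * right.n
    if weight == "sqrt":
        w = math.sqrt(w)
    elif weight != "product":
        raise ValueError(f"unknown HET weight {weight!r}")
    return w * abs(left.tau_hat - right.tau_hat)


def cmb_score(left: NodeModel, right: NodeModel) -> float:
    """Pooled within-child SSE of the linear model (minimized)."""
    if left.degenerate or right.degenerate:
        return math.inf
    return left.sse + right.sse


def var_score(
    left_Y: np.ndarray,
    right_Y: np.ndarray,
    left_w: Optional[np.ndarray] = None,
    right_w: Optional[np.ndarray] = None,
) -> float:
    """Pooled within-child sum of squared deviations from child means."""
    total = 0.0
    for y, w in ((left_Y, left_w), (right_Y, right_w)):
        y = np.asarray(y, dtype=float)
        if y.size == 0:
            continue
        if w is None:
            total += float(((y - y.mean()) ** 2).sum())
        else:
            w = np.asarray(w, dtype=float)
            sw = w.sum()
            ybar = (w * y).sum() / sw
            total += float((w * (y - ybar) ** 2).sum())
    return total


def best_split(
    X: np.ndarray,
    Y: np.ndarray,
    G: np.ndarray,
    rule: SplitRule,
    *,
    mtry: int,
    nsplit: Optional[int],
    min_child: int,
    rng: np.random.Generator,
    het_weight: str = "product",
    g_scale: Optional[float] = None,
) -> Optional[SplitCandidate]:
    """Best candidate split of a node under the given rule, or None.

    ``mtry`` covariates are drawn without replacement; for each,
    ``nsplit`` thresholds are drawn uniformly between the node's min
    and max of that covariate (randomized splitting).  ``nsplit=None``
    enumerates all midpoints between consecutive distinct values
    (exhaustive search).  A candidate is valid only if both children
    hold at least ``min_child`` rows (with multiplicity) and — under
    HET/CMB — neither child has essentially constant G.  Ties are
    broken in favour of the first-drawn candidate, which makes the
    search deterministic given the node RNG.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    rule = SplitRule(rule)
    if het_weight not in ("product", "sqrt"):
        raise ValueError(f"unknown HET weight {het_weight!r}")
    m, p = X.shape
    min_child = max(int(min_child), 1)
    if m < 2 * min_child:
        return None
    if g_scale is None:
        g_scale = float(G.max() - G.min()) if m else 0.0
    g_var_tol = g_var_tolerance(g_scale)

    maximize = rule is SplitRule.HET
    best: Optional[SplitCandidate] = None
    best_goodness = -math.inf

    cols = rng.choice(p, size=min(mtry, p), replace=False)
    for j in cols:
        x = X[:, j]
        lo, hi = float(x.min()), float(x.max())
        if not hi > lo:
            continue
        if nsplit is None:
            uniq = np.unique(x)
            thresholds = (uniq[:-1] + uniq[1:]) / 2.0
        else:
            thresholds = rng.uniform(lo, hi, size=int(nsplit))
        if thresholds.size == 0:
            continue
        order = np.argsort(x, kind="stable")
        xs = x[order]
        ps = PrefixStats(Y[order], G[order], g_scale=g_scale)
        ks = np.searchsorted(xs, thresholds, side="right")

        swL = ps.cw[ks]
        swR = ps.cw[m] - swL
        sgL, syL = ps.cg[ks], ps.cy[ks]
        sgR, syR = ps.cg[m] - sgL, ps.cy[m] - syL
        with np.errstate(divide="ignore", invalid="ignore"):
            sggL = np.maximum(ps.cgg[ks] - sgL * sgL / swL, 0.0)
            sggR = np.maximum((ps.cgg[m] - ps.cgg[ks]) - sgR * sgR / swR, 0.0)
            sgyL = ps.cgy[ks] - sgL * syL / swL
            sgyR = (ps.cgy[m] - ps.cgy[ks]) - sgR * syR / swR
            syyL = np.maximum(ps.cyy[ks] - syL * syL / swL, 0.0)
            syyR = np.maximum((ps.cyy[m] - ps.cyy[ks]) - syR * syR / swR, 0.0)

        valid = (swL >= min_child) & (swR >= min_child) & (swL >= 2) & (swR >= 2)
        if rule in (SplitRule.HET, SplitRule.CMB):
            with np.errstate(divide="ignore", invalid="ignore"):
                valid &= (sggL / np.maximum(swL, 1.0) >= g_var_tol) & (
                    sggR / np.maximum(swR, 1.0) >= g_var_tol
                )

        with np.errstate(divide="ignore", invalid="ignore"):
            if rule is SplitRule.HET:
                dtau = np.abs(sgyL / sggL - sgyR / sggR)
                w = swL * swR if het_weight == "product" else np.sqrt(swL * swR)
                goodness = np.where(valid, w * dtau, -math.inf)
            elif rule is SplitRule.CMB:
                sse = (syyL - sgyL * sgyL / sggL) + (syyR - sgyR * sgyR / sggR)
                goodness = np.where(valid, -sse, -math.inf)
            else:
                goodness = np.where(valid, -(syyL + syyR), -math.inf)

        for t in range(thresholds.size):
            if goodness[t] > best_goodness:
                best_goodness = float(goodness[t])
                score = best_goodness if maximize else -best_goodness
                best = SplitCandidate(
                    var_index=int(j),
                    threshold=float(thresholds[t]),
                    score=score,
                    rule=rule,
                    n_left=int(round(swL[t])),
                    n_right=int(round(swR[t])),
                )
    return best
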