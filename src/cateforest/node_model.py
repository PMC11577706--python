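"""Within-node linear model Y = mu + tau * G fitted by least squares.

The slope tau of this simple regression, fitted on a node's (or a
BOP's) observations, is the local treatment-effect estimate.  All fits
support nonnegative integer multiplicity weights because bootstrap
resampling and BOP extraction produce multisets of training rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "NodeModel",
    "fit_node",
    "PrefixStats",
    "split_stats",
    "DEGENERACY_REL_TOL",
    "g_var_tolerance",
]

#: A node's G is treated as constant (slope undefined) when its variance
#: falls below this fraction of the squared training-range of G.
DEGENERACY_REL_TOL = 1e-12


def g_var_tolerance(g_scale: Optional[float]) -> float:
    """Variance threshold below which G counts as constant.

    Scale-aware: relative to the squared training-range of G.  A zero
    or unknown range means any variance is numerical noise, so the
    tolerance is infinite (everything degenerate).
    """
    if g_scale is None or not g_scale > 0.0:
        return float("inf")
    return DEGENERACY_REL_TOL * g_scale * g_scale


@dataclass(frozen=True)
class NodeModel:
    """OLS fit of Y = mu + tau*G on one index set.

    Attributes
    ----------
    mu_hat, tau_hat : float
        Intercept and slope estimates.  ``tau_hat`` is NaN when the fit
        is degenerate (fewer than two effective observations, or G
        essentially constant within the node).
    sse : float
        Residual sum of squares (multiplicity-weighted).
    n : int
        Effective number of observations (sum of weights).
    g_var : float
        Within-node variance of G (weighted, denominator n).
    degenerate : bool
        True when the slope is undefined.
    """

    mu_hat: float
    tau_hat: float
    sse: float
    n: int
    g_var: float
    degenerate: bool = False


def _from_sums(
    sw: float,
    sgg: float,
    sgy: float,
    syy: float,
    ybar: float,
    gbar: float,
    g_var_tol: float,
) -> NodeModel:
    """Build a NodeModel from centered second-moment sums."""
    n = int(round(sw))
    if sw < 2 or sgg <= 0.0 or sgg / max(sw, 1.0) < g_var_tol:
        mu = ybar if sw > 0 else float("nan")
        sse = max(syy, 0.0)
        return NodeModel(mu, float("nan"), sse, n, sgg / sw if sw > 0 else 0.0, True)
    tau = sgy / sgg
    mu = ybar - tau * gbar
    sse = max(syy - sgy * sgy / sgg, 0.0)
    return NodeModel(mu, tau, sse, n, sgg / sw, False)


def fit_node(
    Y: np.ndarray,
    G: np.ndarray,
    weights: Optional[np.ndarray] = None,
    g_scale: Optional[float] = None,
) -> NodeModel:
    """Weighted OLS of Y on G with an intercept.

    Parameters
    ----------
    Y, G : arrays of equal length
    weights : optional nonnegative multiplicities (default: all ones)
    g_scale : optional range of G in the *training set*; the degeneracy
        guard compares the node's Var(G) against
        ``DEGENERACY_REL_TOL * g_scale**2``.  Defaults to the range of
        the supplied G.

    A degenerate input (effective n < 2, or Var(G) below tolerance)
    returns a flagged NodeModel instead of raising: callers decide
    whether degeneracy invalidates a split or triggers a fallback.
    """
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    if Y.shape != G.shape:
        raise ValueError("Y and G must have the same length")
    if weights is None:
        w = np.ones_like(Y)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != Y.shape:
            raise ValueError("weights must match Y in length")
    sw = float(w.sum())
    if sw <= 0:
        return NodeModel(float("nan"), float("nan"), 0.0, 0, 0.0, True)
    gbar = float((w * G).sum() / sw)
    ybar = float((w * Y).sum() / sw)
    gc = G - gbar
    yc = Y - ybar
    sgg = float((w * gc * gc).sum())
    sgy = float((w * gc * yc).sum())
    syy = float((w * yc * yc).sum())
    if g_scale is None:
        g_scale = float(G.max() - G.min()) if G.size else 0.0
    return _from_sums(sw, sgg, sgy, syy, ybar, gbar, g_var_tolerance(g_scale))


class PrefixStats:
    """Cumulative sufficient statistics for O(1) left/right OLS fits.

    Built once on a node's data sorted by a candidate covariate; any
    split index then yields both child models without re-scanning.  Y
    and G are centered at the node mean before accumulation to keep the
    second-moment differences numerically stable.
    """

    def __init__(
        self,
        Y: np.ndarray,
        G: np.ndarray,
        weights: Optional[np.ndarray] = None,
        g_scale: Optional[float] = None,
    ) -> None:
        Y = np.asarray(Y, dtype=float)
        G = np.asarray(G, dtype=float)
        w = np.ones_like(Y) if weights is None else np.asarray(weights, dtype=float)
        self.m = Y.shape[0]
        sw = float(w.sum())
        self._gref = float((w * G).sum() / sw) if sw > 0 else 0.0
        self._yref = float((w * Y).sum() / sw) if sw > 0 else 0.0
        gc = G - self._gref
        yc = Y - self._yref
        z = np.zeros(1)
        self.cw = np.concatenate([z, np.cumsum(w)])
        self.cg = np.concatenate([z, np.cumsum(w * gc)])
        self.cy = np.concatenate([z, np.cumsum(w * yc)])
        self.cgg = np.concatenate([z, np.cumsum(w * gc * gc)])
        self.cgy = np.concatenate([z, np.cumsum(w * gc * yc)])
        self.cyy = np.concatenate([z, np.cumsum(w * yc * yc)])
        if g_scale is None:
            g_scale = float(G.max() - G.min()) if G.size else 0.0
        self.g_var_tol = g_var_tolerance(g_scale)

    def side_sums(self, lo: int, hi: int) -> Tuple[float, float, float, float]:
        """(sw, sgg_centered, sgy_centered, syy_centered) for rows [lo, hi).

        The second moments are recentered at the segment's own mean.
        """
        sw = self.cw[hi] - self.cw[lo]
        sg = self.cg[hi] - self.cg[lo]
        sy = self.cy[hi] - self.cy[lo]
        sgg = self.cgg[hi] - self.cgg[lo]
        sgy = self.cgy[hi] - self.cgy[lo]
        syy = self.cyy[hi] - self.cyy[lo]
        if sw > 0:
            sgg -= sg * sg / sw
            sgy -= sg * sy / sw
            syy -= sy * sy / sw
        return sw, max(sgg, 0.0), sgy, max(syy, 0.0)

    def model(self, lo: int, hi: int) -> NodeModel:
        sw, sgg, sgy, syy = self.side_sums(lo, hi)
        sg = self.cg[hi] - self.cg[lo]
        sy = self.cy[hi] - self.cy[lo]
        gbar = self._gref + (sg / sw if sw > 0 else 0.0)
        ybar = self._yref + (sy / sw if sw > 0 else 0.0)
        return _from_sums(sw, sgg, sgy, syy, ybar, gbar, self.g_var_tol)

    def models(self, k: int) -> Tuple[NodeModel, NodeModel]:
        """Child models for the split putting rows [0, k) left."""
        return self.model(0, k), self.model(k, self.m)


def split_stats(
    Y_sorted: np.ndarray,
    G_sorted: np.ndarray,
    split_index: int,
    weights: Optional[np.ndarray] = None,
    g_scale: Optional[float] = None,
) -> Tuple[NodeModel, NodeModel]:
    """Left/right NodeModels for a split of covariate-sorted node data.

    Rows ``[0, split_index)`` go left.  Equivalent to calling
    :func:`fit_node` on each side; implemented with prefix sums so a
    sweep over all split points is linear overall.
    """
    ps = PrefixStats(Y_sorted, G_sorted, weights, g_scale=g_scale)
    return ps.models(split_index)
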