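"""CATE prediction: local linear fits on the BOP of each query point.

Given a fitted causal forest, the treatment effect at a new point
x_new is the slope of the multiplicity-weighted OLS regression
Y = mu + tau*G run on BOP(x_new).  When the forest was trained on
locally centered variables, the same centered variables are used here —
the slope of the centered regression is the CATE estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .node_model import NodeModel, fit_node, g_var_tolerance
from .forest import CausalForest, get_bop

__all__ = ["CATEEstimate", "FittedCATE", "estimate_cate", "predict_batch", "predict_tau"]


@dataclass(frozen=True)
class CATEEstimate:
    """A single tau(x_new) estimate with diagnostics."""

    tau_hat: float
    bop_size: int
    degenerate: bool = False
    fallback_used: bool = False


@dataclass
class FittedCATE:
    """A causal forest together with the training arrays it regresses on.

    ``Y_used`` and ``G_used`` are the (possibly centered) response and
    treatment the forest was built on; BOP regressions reuse them.
    ``global_model`` is the full-training-sample OLS fit, the fallback
    for the (practically impossible) degenerate-BOP case.
    """

    forest: CausalForest
    X: np.ndarray
    Y_used: np.ndarray
    G_used: np.ndarray
    variant_label: str = "NoC"
    global_model: Optional[NodeModel] = None

    def __post_init__(self) -> None:
        if self.global_model is None:
            self.global_model = fit_node(self.Y_used, self.G_used)

    @property
    def g_scale(self) -> float:
        return self.forest.g_scale


def estimate_cate(fitted: FittedCATE, x_new: np.ndarray) -> CATEEstimate:
    """tau-hat at one query point via an explicit BOP regression.

    This is the reference path: it materializes the BOP multiset and
    fits the weighted node model on it.  :func:`predict_batch` computes
    the same slope from leaf-wise sufficient statistics; the two agree
    to numerical precision.
    """
    bop = get_bop(fitted.forest, x_new)
    model = fit_node(
        fitted.Y_used[bop.indices],
        fitted.G_used[bop.indices],
        weights=bop.multiplicities,
        g_scale=fitted.g_scale,
    )
    if model.degenerate:
        return CATEEstimate(
            tau_hat=float(fitted.global_model.tau_hat),
            bop_size=bop.size,
            degenerate=True,
            fallback_used=True,
        )
    return CATEEstimate(tau_hat=float(model.tau_hat), bop_size=bop.size)


def predict_batch(fitted: FittedCATE, X_test: np.ndarray) -> list[CATEEstimate]:
    """Row-wise CATE estimates for a test matrix (order-preserving).

    Uses per-leaf cached sufficient sums, so the cost per query is one
    tree descent per tree rather than a BOP materialization.
    """
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    stats = fitted.forest.bop_suffstats(X_test)
    sw, sg, sgg, sy, sgy = stats.T
    with np.errstate(divide="ignore", invalid="ignore"):
        sgg_c = sgg - sg * sg / sw
        sgy_c = sgy - sg * sy / sw
        tau = sgy_c / sgg_c
    tol = g_var_tolerance(fitted.g_scale)
    degenerate = (sw < 2) | (sgg_c <= 0) | (sgg_c / np.maximum(sw, 1.0) < tol)
    fallback_tau = float(fitted.global_model.tau_hat)
    out = []
    for i in range(X_test.shape[0]):
        if degenerate[i]:
            out.append(
                CATEEstimate(fallback_tau, int(round(sw[i])), True, True)
            )
        else:
            out.append(CATEEstimate(float(tau[i]), int(round(sw[i]))))
    return out


def predict_tau(fitted: FittedCATE, X_test: np.ndarray) -> np.ndarray:
    """Convenience: tau-hat estimates as a plain array."""
    return np.array([e.tau_hat for e in predict_batch(fitted, X_test)])
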