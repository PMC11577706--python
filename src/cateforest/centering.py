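"""Local centering (orthogonalization) of response and treatment.

Before building the causal forest, the response and/or the treatment
can be replaced by their residuals against out-of-bag regression-forest
estimates of the nuisance functions m(x) = E[Y|X] and the (generalized)
propensity pi(x) = E[G|X]:

    Y_c = Y - m_hat(x),      G_c = G - pi_hat(x).

The four combinations give the variants NoC (neither), Cy (response
only), Cg (treatment only) and Cyg (both).  Centering is a one-shot
preprocessing step: the centered variables feed both tree growth and
the BOP regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .dgp import Dataset
from .forest import ForestConfig, build_forest, oob_predict_mean
from .split_rules import SplitRule
from .cate_estimator import FittedCATE

__all__ = [
    "CenteringVariant",
    "CenteredData",
    "VARIANTS",
    "compute_nuisance",
    "center",
    "pipeline_fit",
]


@dataclass(frozen=True)
class CenteringVariant:
    """Which of Y and G get locally centered."""

    center_y: bool
    center_g: bool

    @property
    def label(self) -> str:
        return {
            (False, False): "NoC",
            (True, False): "Cy",
            (False, True): "Cg",
            (True, True): "Cyg",
        }[(self.center_y, self.center_g)]

    @classmethod
    def from_label(cls, label: str) -> "CenteringVariant":
        table = {
            "NoC": (False, False),
            "Cy": (True, False),
            "Cg": (False, True),
            "Cyg": (True, True),
        }
        if label not in table:
            raise ValueError(f"unknown centering variant {label!r}")
        return cls(*table[label])


VARIANTS = {lbl: CenteringVariant.from_label(lbl) for lbl in ("NoC", "Cy", "Cg", "Cyg")}


@dataclass
class CenteredData:
    """The working response/treatment after (possible) centering."""

    Y_used: np.ndarray
    G_used: np.ndarray
    m_hat: Optional[np.ndarray] = None
    pi_hat: Optional[np.ndarray] = None


@dataclass
class Nuisance:
    """Cached OOB nuisance estimates, shared across variants/methods.

    ``r2_m`` / ``r2_g`` are OOB R-squared diagnostics of the two
    auxiliary forests (1 - MSE_oob / Var(target)).
    """

    m_hat: np.ndarray
    pi_hat: np.ndarray
    r2_m: float
    r2_g: float
    n_fallback: int = 0


def _oob_r2(target: np.ndarray, pred: np.ndarray) -> float:
    var = float(np.var(target))
    if var <= 0:
        return 0.0
    return 1.0 - float(np.mean((target - pred) ** 2)) / var


def compute_nuisance(dataset: Dataset, config: Optional[ForestConfig] = None) -> Nuisance:
    """Fit the two auxiliary VAR-rule forests and return OOB estimates.

    The m(x) forest regresses Y on X; the pi(x) forest regresses G on
    X.  Both use out-of-bag predictions so each row's estimate never
    uses that row's own response.  Computed once per dataset and meant
    to be cached: all centering variants and both causal split rules
    share the same nuisance realizations.
    """
    if config is None:
        config = ForestConfig(rule=SplitRule.VAR)
    base = replace(config, rule=SplitRule.VAR, bootstrap=True)
    zeros = np.zeros(dataset.n)

    f_m = build_forest(dataset.X, dataset.Y, zeros, replace(base, seed=base.seed))
    m_hat, fb_m = oob_predict_mean(f_m, dataset.X)
    f_g = build_forest(dataset.X, dataset.G, zeros, replace(base, seed=base.seed + 1))
    pi_hat, fb_g = oob_predict_mean(f_g, dataset.X)

    return Nuisance(
        m_hat=m_hat,
        pi_hat=pi_hat,
        r2_m=_oob_r2(dataset.Y, m_hat),
        r2_g=_oob_r2(dataset.G, pi_hat),
        n_fallback=int(fb_m.sum() + fb_g.sum()),
    )


def center(
    dataset: Dataset,
    variant: CenteringVariant,
    centering_forest_config: Optional[ForestConfig] = None,
    nuisance: Optional[Nuisance] = None,
) -> CenteredData:
    """Apply a centering variant, fitting nuisance forests on demand.

    NoC fits no forests at all.  For the other variants a precomputed
    :class:`Nuisance` can be supplied to avoid refitting when several
    variants are evaluated on the same dataset.
    """
    if isinstance(variant, str):
        variant = CenteringVariant.from_label(variant)
    if not (variant.center_y or variant.center_g):
        return CenteredData(Y_used=dataset.Y.copy(), G_used=dataset.G.copy())
    if nuisance is None:
        nuisance = compute_nuisance(dataset, centering_forest_config)
    y = dataset.Y - nuisance.m_hat if variant.center_y else dataset.Y.copy()
    g = dataset.G - nuisance.pi_hat if variant.center_g else dataset.G.copy()
    return CenteredData(
        Y_used=y,
        G_used=g,
        m_hat=nuisance.m_hat if variant.center_y else None,
        pi_hat=nuisance.pi_hat if variant.center_g else None,
    )


def pipeline_fit(
    dataset: Dataset,
    variant: CenteringVariant,
    cate_forest_config: ForestConfig,
    centering_forest_config: Optional[ForestConfig] = None,
    nuisance: Optional[Nuisance] = None,
) -> FittedCATE:
    """Center, then build the causal forest on the working variables.

    By default the centering forests reuse the causal forest's
    hyperparameters (tree count, mtry, node size), differing only in
    their split rule (VAR).
    """
    if isinstance(variant, str):
        variant = CenteringVariant.from_label(variant)
    if centering_forest_config is None:
        centering_forest_config = replace(cate_forest_config, rule=SplitRule.VAR)
    cd = center(dataset, variant, centering_forest_config, nuisance)
    forest = build_forest(dataset.X, cd.Y_used, cd.G_used, cate_forest_config)
    return FittedCATE(
        forest=forest,
        X=dataset.X,
        Y_used=cd.Y_used,
        G_used=cd.G_used,
        variant_label=variant.label,
    )
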