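"""Synthetic data-generating processes for the confounder/collider benchmark.

The simulated world has five covariates X1..X5, a continuous treatment
(dose) G and a continuous response Y following the varying-coefficient
model

    E[Y | X = x, G = g] = mu(x) + tau(x) * g,

where ``mu`` is a piecewise-constant prognostic baseline on (X1, X2, X3)
and the treatment effect ``tau`` depends on X4 alone, through one of
three shapes (step, linear, quadratic).  Two optional distortions are
available:

* confounding — the treatment is generated as a decreasing function of
  X1 plus Gaussian noise, truncated to [0, 1], so X1 drives both the
  dose and the response;
* a collider — X5 is generated as the noiseless conditional mean of Y
  plus Gaussian noise, so conditioning on X5 opens a spurious path
  between treatment and response.

The full factorial grid (3 effect shapes x 3 confounding levels x
3 collider levels) yields 27 scenarios.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = [
    "EffectShape",
    "Level",
    "ScenarioConfig",
    "Dataset",
    "gen_covariates",
    "tau",
    "baseline",
    "gen_treatment",
    "gen_response",
    "gen_x5",
    "make_dataset",
    "scenario_grid",
    "RESPONSE_SD",
    "CONFOUNDING_SD",
    "COLLIDER_SD",
]

#: Standard deviation of the response noise epsilon.
RESPONSE_SD = 0.5

#: Treatment-noise standard deviation by confounding level.  Smaller
#: noise around the X1-driven mean means a *stronger* confounder.
CONFOUNDING_SD = {"weak": 0.17, "strong": 0.07}

#: Collider-noise standard deviation by collider level.  Smaller noise
#: means X5 tracks the signal more closely, i.e. a *stronger* collider.
COLLIDER_SD = {"weak": 4.0, "strong": 1.5}


class EffectShape(str, enum.Enum):
    """Shape of the treatment-effect function tau(X4)."""

    STEP = "step"
    LINEAR = "linear"
    QUADRATIC = "quadratic"


class Level(str, enum.Enum):
    """Strength level for confounding or collider distortion."""

    NONE = "none"
    WEAK = "weak"
    STRONG = "strong"


RngLike = Union[int, np.random.Generator, np.random.SeedSequence]


def _as_rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation grid.

    Parameters
    ----------
    effect_shape : EffectShape or str
        Shape of tau(X4): ``step``, ``linear`` or ``quadratic``.
    confounding : Level or str
        ``none`` (uniform G), ``weak`` (sigma_G = 0.17) or ``strong``
        (sigma_G = 0.07).
    collider : Level or str
        ``none`` (independent uniform X5), ``weak`` (sigma_X = 4.0) or
        ``strong`` (sigma_X = 1.5).
    n : int
        Sample size (training default in the benchmark: 1000).
    seed : int
        Master seed; expanded into independent substreams for
        covariates, treatment noise, response noise and collider noise.
    """

    effect_shape: EffectShape = EffectShape.LINEAR
    confounding: Level = Level.NONE
    collider: Level = Level.NONE
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_shape", EffectShape(self.effect_shape))
        object.__setattr__(self, "confounding", Level(self.confounding))
        object.__setattr__(self, "collider", Level(self.collider))
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def label(self) -> str:
        return (
            f"{self.effect_shape.value}/conf={self.confounding.value}"
            f"/coll={self.collider.value}"
        )


@dataclass
class Dataset:
    """A (Y, G, X) triplet, optionally with the true CATE attached.

    ``tau_true`` and ``h_true`` are populated for simulated data only;
    ``h_true`` is the noiseless conditional mean of Y (baseline plus
    treatment effect) which also serves as the signal component of the
    collider X5.
    """

    Y: np.ndarray
    G: np.ndarray
    X: np.ndarray
    tau_true: Optional[np.ndarray] = None
    h_true: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.Y.shape[0]
        if self.G.shape[0] != n or self.X.shape[0] != n:
            raise ValueError("Y, G and X must have the same number of rows")
        for name in ("tau_true", "h_true"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape[0] != n:
                    raise ValueError(f"{name} must have length n={n}")
                setattr(self, name, v)

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def gen_covariates(n: int, rng: RngLike) -> np.ndarray:
    """Draw the base covariates X1..X4, i.i.d. Uniform(0, 10).

    Returns an (n, 4) array.  X5 is generated separately because it may
    depend on the realized signal (collider scenarios).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return _as_rng(rng).uniform(0.0, 10.0, size=(n, 4))


def tau(effect_shape: Union[EffectShape, str], x4) -> np.ndarray:
    """True treatment effect tau(X4) under the given shape.

    step:      1 if X4 < 5 else 5
    linear:    X4 / 2
    quadratic: (X4 - 5)^2 / 5
    """
    shape = EffectShape(effect_shape)
    x4 = np.asarray(x4, dtype=float)
    if shape is EffectShape.STEP:
        return np.where(x4 < 5.0, 1.0, 5.0)
    if shape is EffectShape.LINEAR:
        return x4 / 2.0
    return (x4 - 5.0) ** 2 / 5.0


def baseline(x1, x2, x3) -> np.ndarray:
    """Piecewise-constant prognostic baseline mu(X1, X2, X3) in {1, 2, 3, 4}.

    Region rule: X1<=5 & X3<=5 -> 1; X1<=5 & X3>5 -> 2;
    X1>5 & X2<=5 -> 3; X1>5 & X2>5 -> 4.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x3 = np.asarray(x3, dtype=float)
    left = np.where(x3 <= 5.0, 1.0, 2.0)  # X1 <= 5 branch
    right = np.where(x2 <= 5.0, 3.0, 4.0)  # X1 > 5 branch
    return np.where(x1 <= 5.0, left, right)


def gen_treatment(
    confounding: Union[Level, str], x1: np.ndarray, rng: RngLike
) -> np.ndarray:
    """Draw the treatment G.

    Without confounding G ~ Uniform(0, 1) independent of everything.
    With confounding, G = 0.6 - X1/50 + eps_G with Gaussian noise of
    standard deviation 0.17 (weak) or 0.07 (strong), truncated to
    [0, 1].
    """
    level = Level(confounding)
    rng = _as_rng(rng)
    x1 = np.asarray(x1, dtype=float)
    n = x1.shape[0]
    if level is Level.NONE:
        return rng.uniform(0.0, 1.0, size=n)
    sigma = CONFOUNDING_SD[level.value]
    g = 0.6 - x1 / 50.0 + rng.normal(0.0, sigma, size=n)
    return np.clip(g, 0.0, 1.0)


def gen_response(h_true: np.ndarray, rng: RngLike) -> np.ndarray:
    """Y = h + eps with eps i.i.d. N(0, 0.5^2)."""
    h_true = np.asarray(h_true, dtype=float)
    return h_true + _as_rng(rng).normal(0.0, RESPONSE_SD, size=h_true.shape[0])


def gen_x5(
    collider: Union[Level, str], h_true: np.ndarray, rng: RngLike
) -> np.ndarray:
    """Draw X5: independent Uniform(0, 10), or h + collider noise.

    In collider scenarios X5 = h + eps_X with sigma_X = 4.0 (weak) or
    1.5 (strong), sharing the same realized h as the response so that
    X5 is a genuine common effect of treatment and covariates.
    """
    level = Level(collider)
    rng = _as_rng(rng)
    h_true = np.asarray(h_true, dtype=float)
    n = h_true.shape[0]
    if level is Level.NONE:
        return rng.uniform(0.0, 10.0, size=n)
    sigma = COLLIDER_SD[level.value]
    return h_true + rng.normal(0.0, sigma, size=n)


def make_dataset(config: ScenarioConfig) -> Dataset:
    """Generate a complete dataset for one scenario.

    The master seed is expanded into four independent substreams
    (covariates, treatment, response, collider) so that e.g. changing
    the collider level never perturbs the covariate draw.
    """
    streams = np.random.SeedSequence(config.seed).spawn(4)
    rng_cov, rng_treat, rng_resp, rng_coll = map(np.random.default_rng, streams)

    xb = gen_covariates(config.n, rng_cov)
    g = gen_treatment(config.confounding, xb[:, 0], rng_treat)
    tau_true = tau(config.effect_shape, xb[:, 3])
    h_true = baseline(xb[:, 0], xb[:, 1], xb[:, 2]) + tau_true * g
    y = gen_response(h_true, rng_resp)
    x5 = gen_x5(config.collider, h_true, rng_coll)
    x = np.column_stack([xb, x5])
    return Dataset(Y=y, G=g, X=x, tau_true=tau_true, h_true=h_true)


def scenario_grid(n: int = 1000, seed: int = 0) -> list[ScenarioConfig]:
    """Enumerate the 27-scenario factorial grid in a fixed order."""
    grid = []
    for shape, conf, coll in itertools.product(EffectShape, Level, Level):
        grid.append(
            ScenarioConfig(
                effect_shape=shape, confounding=conf, collider=coll, n=n, seed=seed
            )
        )
    return grid
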