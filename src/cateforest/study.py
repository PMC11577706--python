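"""Simulation benchmark: scenarios x methods x repetitions.

Each repetition draws an independent training set and test set from a
scenario, fits each (split rule, centering variant) method on the
training data, predicts the CATE on the test covariates and scores
against the known true effects.  Per-cell summaries feed rank tables
and paired t-test comparisons.

Pairing discipline: within a repetition, all methods share the same
train/test draw, the same nuisance-forest realizations and the same
causal-forest seed, so method contrasts are purely paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dgp import ScenarioConfig, make_dataset
from .forest import ForestConfig
from .split_rules import SplitRule
from .centering import CenteringVariant, compute_nuisance, pipeline_fit
from .cate_estimator import predict_tau

__all__ = [
    "MethodSpec",
    "StudyConfig",
    "mse_cate",
    "mae_cate",
    "concordance",
    "run_rep",
    "run_study",
    "rank_methods",
    "paired_t_compare",
    "default_methods",
]


@dataclass(frozen=True)
class MethodSpec:
    """One method: a causal split rule plus a centering variant."""

    rule: SplitRule
    variant: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "rule", SplitRule(self.rule))
        CenteringVariant.from_label(self.variant)  # validate

    @property
    def label(self) -> str:
        return f"{self.rule.value}-{self.variant}"


def default_methods() -> list[MethodSpec]:
    """The core grid: HET and CMB under all four centering variants."""
    return [
        MethodSpec(rule, v)
        for rule in (SplitRule.HET, SplitRule.CMB)
        for v in ("NoC", "Cy", "Cg", "Cyg")
    ]


@dataclass
class StudyConfig:
    """Full benchmark configuration.

    The benchmark defaults are 100 repetitions, 1000 training and 500
    test observations per repetition; scaled-down runs simply override
    these counts and the forest size.
    """

    scenarios: Sequence[ScenarioConfig]
    methods: Sequence[MethodSpec] = field(default_factory=default_methods)
    n_reps: int = 100
    n_train: int = 1000
    n_test: int = 500
    forest: ForestConfig = field(default_factory=ForestConfig)
    master_seed: int = 0


def mse_cate(tau_hat: np.ndarray, tau_true: np.ndarray) -> float:
    """Mean squared error of the estimated CATE over a test set."""
    tau_hat = np.asarray(tau_hat, dtype=float)
    tau_true = np.asarray(tau_true, dtype=float)
    if tau_hat.shape != tau_true.shape:
        raise ValueError("tau_hat and tau_true must have equal length")
    if tau_hat.size < 1:
        raise ValueError("need at least one test point")
    return float(np.mean((tau_hat - tau_true) ** 2))


def mae_cate(tau_hat: np.ndarray, tau_true: np.ndarray) -> float:
    """Mean absolute error companion metric."""
    tau_hat = np.asarray(tau_hat, dtype=float)
    tau_true = np.asarray(tau_true, dtype=float)
    if tau_hat.shape != tau_true.shape:
        raise ValueError("tau_hat and tau_true must have equal length")
    return float(np.mean(np.abs(tau_hat - tau_true)))


def concordance(tau_hat: np.ndarray, tau_true: np.ndarray) -> float:
    """Simple concordance between estimated and true effect orderings.

    Reported as (Kendall's tau-b + 1) / 2, i.e. 1 for a perfectly
    concordant ranking, 0.5 for an uninformative one.  NaN when either
    vector is constant.
    """
    tau_hat = np.asarray(tau_hat, dtype=float)
    tau_true = np.asarray(tau_true, dtype=float)
    if np.ptp(tau_hat) == 0 or np.ptp(tau_true) == 0:
        return float("nan")
    kt = sps.kendalltau(tau_hat, tau_true).statistic
    return float((kt + 1.0) / 2.0)


def _rep_seeds(master_seed: int, scenario_index: int, rep: int) -> np.ndarray:
    """Four independent sub-seeds (< 2^31) for one repetition."""
    ss = np.random.SeedSequence([master_seed, scenario_index, rep])
    return ss.generate_state(4) % (2**31)


def run_rep(
    scenario: ScenarioConfig,
    methods: Sequence[MethodSpec],
    rep: int,
    *,
    n_train: int,
    n_test: int,
    forest: ForestConfig,
    master_seed: int = 0,
    scenario_index: int = 0,
) -> list[dict]:
    """One repetition: shared data, one record per method."""
    train_seed, test_seed, nuis_seed, forest_seed = map(
        int, _rep_seeds(master_seed, scenario_index, rep)
    )
    train = make_dataset(replace(scenario, n=n_train, seed=train_seed))
    test = make_dataset(replace(scenario, n=n_test, seed=test_seed))

    needs_centering = any(v != "NoC" for v in (m.variant for m in methods))
    nuisance = None
    if needs_centering:
        nuisance = compute_nuisance(train, replace(forest, rule=SplitRule.VAR, seed=nuis_seed))

    records = []
    for method in methods:
        cfg = replace(forest, rule=method.rule, seed=forest_seed)
        fitted = pipeline_fit(train, method.variant, cfg, nuisance=nuisance)
        tau_hat = predict_tau(fitted, test.X)
        records.append(
            {
                "scenario": scenario.label,
                "method": method.label,
                "rep": rep,
                "mse": mse_cate(tau_hat, test.tau_true),
                "mae": mae_cate(tau_hat, test.tau_true),
                "concordance": concordance(tau_hat, test.tau_true),
            }
        )
    return records


def run_study(config: StudyConfig, progress: bool = False) -> pd.DataFrame:
    """Run the full grid; returns one tidy record per (scenario, method, rep)."""
    rows: list[dict] = []
    for si, scenario in enumerate(config.scenarios):
        for rep in range(config.n_reps):
            rows.extend(
                run_rep(
                    scenario,
                    config.methods,
                    rep,
                    n_train=config.n_train,
                    n_test=config.n_test,
                    forest=config.forest,
                    master_seed=config.master_seed,
                    scenario_index=si,
                )
            )
            if progress:
                print(f"[study] {scenario.label} rep {rep + 1}/{config.n_reps}", flush=True)
    return pd.DataFrame(rows)


def rank_methods(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Rank methods per scenario by median MSE (1 = best; ties averaged).

    Returns (rank-count table with one row per method and one column
    per rank, mean rank per method).
    """
    medians = records.groupby(["scenario", "method"])["mse"].median().unstack("method")
    if medians.shape[1] < 2:
        raise ValueError("need at least two methods to rank")
    ranks = medians.rank(axis=1, method="average")
    n_methods = medians.shape[1]
    counts = pd.DataFrame(
        0.0, index=medians.columns, columns=[float(r) for r in range(1, n_methods + 1)]
    )
    for method in medians.columns:
        vc = ranks[method].value_counts()
        for rank_val, cnt in vc.items():
            if rank_val not in counts.columns:
                counts[rank_val] = 0.0
            counts.loc[method, rank_val] = cnt
    counts = counts[sorted(counts.columns)]
    mean_rank = ranks.mean(axis=0)
    mean_rank.name = "mean_rank"
    return counts, mean_rank


def paired_t_compare(
    records: pd.DataFrame, method_a: str, method_b: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-scenario paired comparison of mean MSE between two methods.

    Two-sided paired t-test on per-repetition MSE pairs.  The percent
    difference uses the larger mean as denominator,
    100*|mean_a - mean_b| / max(mean_a, mean_b), so "a better than b by
    d%" is symmetric and bounded by 100; magnitudes are binned as in
    the usual >20% / 10-20% / 0-10% reading.
    """
    sub = records[records["method"].isin([method_a, method_b])]
    wide = sub.pivot_table(index=["scenario", "rep"], columns="method", values="mse")
    if wide[[method_a, method_b]].isna().any().any():
        raise ValueError("methods must have matched repetitions per scenario")
    rows = []
    for scenario, grp in wide.groupby(level="scenario"):
        a = grp[method_a].to_numpy()
        b = grp[method_b].to_numpy()
        mean_a, mean_b = float(a.mean()), float(b.mean())
        denom = max(mean_a, mean_b)
        pct = 100.0 * abs(mean_a - mean_b) / denom if denom > 0 else 0.0
        d = a - b
        if np.allclose(d.std(ddof=1) if d.size > 1 else 0.0, 0.0):
            t_stat, p_val, significant = float("nan"), float("nan"), False
            degenerate = True
        else:
            res = sps.ttest_rel(a, b)
            t_stat, p_val = float(res.statistic), float(res.pvalue)
            significant = p_val < alpha
            degenerate = False
        if pct > 20:
            category = ">20%"
        elif pct >= 10:
            category = "10-20%"
        else:
            category = "0-10%"
        rows.append(
            {
                "scenario": scenario,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "pct_diff": pct,
                "better": method_a if mean_a < mean_b else method_b,
                "t": t_stat,
                "p": p_val,
                "significant": significant,
                "category": category,
                "degenerate": degenerate,
                "se_a": float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else float("nan"),
                "se_b": float(b.std(ddof=1) / np.sqrt(b.size)) if b.size > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
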