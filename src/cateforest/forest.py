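"""Bootstrap ensembles of CART-style trees with BOP extraction.

A forest here is a "weight-generating machine": prediction at a query
point x_new does not average tree outputs but collects the *bag of
observations for prediction* (BOP) — the multiset union, over trees, of
in-bag training rows that share x_new's terminal node.  Downstream code
fits the local model Y = mu + tau*G on that multiset.

Trees are grown without pruning or depth limits; growth stops when a
node cannot produce a valid split (minimum child size, or constant
covariates / constant G under the causal rules).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, TextIO, Union

import numpy as np

from .split_rules import SplitRule, best_split

__all__ = [
    "ForestConfig",
    "CausalTree",
    "CausalForest",
    "BOP",
    "build_tree",
    "build_forest",
    "get_bop",
    "oob_predict_mean",
    "forest_to_jsonl",
    "forest_from_jsonl",
]

_LEAF = -1


@dataclass(frozen=True)
class ForestConfig:
    """Hyperparameters of one forest.

    Defaults follow the benchmark setup: 100 trees, mtry 5, minimum
    node size 30 (counted in bootstrap rows, with multiplicity), 10
    random candidate thresholds per covariate, n-out-of-n bootstrap.
    """

    rule: SplitRule = SplitRule.HET
    n_trees: int = 100
    mtry: int = 5
    min_node: int = 30
    nsplit: Optional[int] = 10
    bootstrap: bool = True
    samptype: str = "swr"
    sample_fraction: float = 0.632
    het_weight: str = "product"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "rule", SplitRule(self.rule))
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_node < 1:
            raise ValueError("min_node must be >= 1")


@dataclass(frozen=True)
class BOP:
    """Multiset of training rows co-terminal with a query across trees."""

    indices: np.ndarray
    multiplicities: np.ndarray

    @property
    def size(self) -> int:
        return int(self.multiplicities.sum())


class CausalTree:
    """One recursive partition stored as flat node arrays.

    ``feature[i] == -1`` marks a terminal node.  Terminal nodes carry
    their in-bag members (training-row indices with bootstrap
    multiplicities) and cached raw sufficient sums
    (sum w, sum wG, sum wG^2, sum wY, sum wGY) of the build-time
    response/treatment, which let BOP regressions aggregate leaves in
    O(1) per tree.
    """

    def __init__(
        self,
        feature: np.ndarray,
        threshold: np.ndarray,
        left: np.ndarray,
        right: np.ndarray,
        leaf_rows: dict,
        leaf_stats: np.ndarray,
        inbag_counts: np.ndarray,
        rule: SplitRule,
    ) -> None:
        self.feature = np.asarray(feature, dtype=np.int64)
        self.threshold = np.asarray(threshold, dtype=float)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.leaf_rows = leaf_rows  # node_id -> (row indices, multiplicities)
        self.leaf_stats = np.asarray(leaf_stats, dtype=float)  # (n_nodes, 5)
        self.inbag_counts = np.asarray(inbag_counts, dtype=np.int64)
        self.rule = SplitRule(rule)

    @property
    def n_nodes(self) -> int:
        return self.feature.shape[0]

    @property
    def n_leaves(self) -> int:
        return int((self.feature == _LEAF).sum())

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Route rows of X to terminal-node ids (vectorized descent)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        node = np.zeros(X.shape[0], dtype=np.int64)
        active = self.feature[node] != _LEAF
        while active.any():
            idx = np.flatnonzero(active)
            cur = node[idx]
            go_left = X[idx, self.feature[cur]] <= self.threshold[cur]
            node[idx] = np.where(go_left, self.left[cur], self.right[cur])
            active[idx] = self.feature[node[idx]] != _LEAF
        return node


def build_tree(
    X: np.ndarray,
    Y: np.ndarray,
    G: np.ndarray,
    config: ForestConfig,
    rng: np.random.Generator,
    g_scale: Optional[float] = None,
) -> CausalTree:
    """Grow one tree on a bootstrap sample (or on the full data).

    The node stack is processed depth-first in a fixed order so the
    tree is a pure function of (data, config, rng state).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    n = Y.shape[0]
    if g_scale is None:
        g_scale = float(G.max() - G.min()) if n else 0.0

    if not config.bootstrap:
        rows = np.arange(n)
    elif config.samptype == "swr":
        rows = rng.integers(0, n, size=n)
    elif config.samptype == "swor":
        rows = rng.choice(n, size=max(2, int(round(config.sample_fraction * n))), replace=False)
    else:
        raise ValueError(f"unknown samptype {config.samptype!r}")
    inbag = np.bincount(rows, minlength=n)
    Xe, Ye, Ge = X[rows], Y[rows], G[rows]

    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    leaf_rows: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    stats: list[tuple[float, float, float, float, float]] = []

    def new_node() -> int:
        feature.append(_LEAF)
        threshold.append(np.nan)
        left.append(_LEAF)
        right.append(_LEAF)
        stats.append((0.0, 0.0, 0.0, 0.0, 0.0))
        return len(feature) - 1

    root = new_node()
    stack: list[tuple[int, np.ndarray]] = [(root, np.arange(rows.shape[0]))]
    while stack:
        node_id, pos = stack.pop()
        cand = None
        if pos.shape[0] >= 2 * config.min_node:
            cand = best_split(
                Xe[pos],
                Ye[pos],
                Ge[pos],
                config.rule,
                mtry=config.mtry,
                nsplit=config.nsplit,
                min_child=config.min_node,
                rng=rng,
                het_weight=config.het_weight,
                g_scale=g_scale,
            )
        if cand is None:
            ridx, cnt = np.unique(rows[pos], return_counts=True)
            leaf_rows[node_id] = (ridx, cnt)
            g = Ge[pos]
            y = Ye[pos]
            stats[node_id] = (
                float(pos.shape[0]),
                float(g.sum()),
                float((g * g).sum()),
                float(y.sum()),
                float((g * y).sum()),
            )
            continue
        go_left = Xe[pos, cand.var_index] <= cand.threshold
        lid, rid = new_node(), new_node()
        feature[node_id] = cand.var_index
        threshold[node_id] = cand.threshold
        left[node_id] = lid
        right[node_id] = rid
        # push right first so the left child is processed next (DFS order)
        stack.append((rid, pos[~go_left]))
        stack.append((lid, pos[go_left]))

    return CausalTree(
        np.array(feature),
        np.array(threshold),
        np.array(left),
        np.array(right),
        leaf_rows,
        np.array(stats),
        inbag,
        config.rule,
    )


class CausalForest:
    """Ensemble of :class:`CausalTree` sharing one training set."""

    def __init__(self, trees: list[CausalTree], config: ForestConfig, n_train: int, g_scale: float) -> None:
        self.trees = trees
        self.config = config
        self.n_train = n_train
        self.g_scale = g_scale

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def bop_suffstats(self, X: np.ndarray) -> np.ndarray:
        """Per-query BOP sufficient sums, aggregated leaf-wise.

        Returns an (n_queries, 5) array of
        (sum w, sum wG, sum wG^2, sum wY, sum wGY) over each query's
        BOP — exactly the sums a multiplicity-weighted OLS of Y on G
        over the materialized BOP would use.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.zeros((X.shape[0], 5))
        for tree in self.trees:
            out += tree.leaf_stats[tree.apply(X)]
        return out


def build_forest(
    X: np.ndarray,
    Y: np.ndarray,
    G: np.ndarray,
    config: ForestConfig,
) -> CausalForest:
    """Build ``config.n_trees`` independent bootstrap trees.

    Per-tree RNG substreams are spawned from ``config.seed``, so the
    forest is reproducible and trees are exchangeable.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    G = np.asarray(G, dtype=float)
    g_scale = float(G.max() - G.min()) if Y.size else 0.0
    streams = np.random.SeedSequence(config.seed).spawn(config.n_trees)
    trees = [
        build_tree(X, Y, G, config, np.random.default_rng(s), g_scale=g_scale)
        for s in streams
    ]
    return CausalForest(trees, config, Y.shape[0], g_scale)


def get_bop(forest: CausalForest, x_new: np.ndarray) -> BOP:
    """Materialize the BOP multiset for one query point.

    The multiplicity of training row i is the sum over trees of its
    in-bag count in that tree, restricted to trees where i shares the
    query's terminal node.
    """
    x_new = np.asarray(x_new, dtype=float).reshape(1, -1)
    counts = np.zeros(forest.n_train, dtype=np.int64)
    for tree in forest.trees:
        leaf = int(tree.apply(x_new)[0])
        ridx, cnt = tree.leaf_rows[leaf]
        counts[ridx] += cnt
    idx = np.flatnonzero(counts)
    return BOP(indices=idx, multiplicities=counts[idx])


def oob_predict_mean(
    forest: CausalForest,
    X_train: np.ndarray,
    target: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-bag ensemble prediction of each training row's leaf mean.

    For each row, leaf means (of the build-time response) are averaged
    over the trees in which the row is out-of-bag.  Rows that are
    in-bag in every tree fall back to the all-tree average and are
    flagged; with 100 bootstrap trees this is virtually impossible
    (0.632^100), but the contract is total.

    Returns ``(predictions, fallback_mask)``.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    n = X_train.shape[0]
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n)
    all_sum = np.zeros(n)
    for tree in forest.trees:
        leaves = tree.apply(X_train)
        sw = tree.leaf_stats[leaves, 0]
        mean = tree.leaf_stats[leaves, 3] / np.where(sw > 0, sw, 1.0)
        all_sum += mean
        oob = tree.inbag_counts == 0
        oob_sum[oob] += mean[oob]
        oob_cnt[oob] += 1
    fallback = oob_cnt == 0
    pred = np.empty(n)
    pred[~fallback] = oob_sum[~fallback] / oob_cnt[~fallback]
    pred[fallback] = all_sum[fallback] / forest.n_trees
    return pred, fallback


# ---------------------------------------------------------------------------
# serialization (JSON lines, one tree per record)

def forest_to_jsonl(forest: CausalForest, fh: Union[str, TextIO]) -> None:
    """Write a forest as JSON lines: a header record, then one tree each.

    The encoding is lossless: floats survive a JSON round trip exactly
    (shortest-repr encoding), and leaf membership is stored explicitly.
    """
    close = False
    if isinstance(fh, str):
        fh = open(fh, "w")
        close = True
    try:
        cfg = forest.config
        header = {
            "type": "causal_forest",
            "n_train": forest.n_train,
            "g_scale": forest.g_scale,
            "config": {
                "rule": cfg.rule.value,
                "n_trees": cfg.n_trees,
                "mtry": cfg.mtry,
                "min_node": cfg.min_node,
                "nsplit": cfg.nsplit,
                "bootstrap": cfg.bootstrap,
                "het_weight": cfg.het_weight,
                "seed": cfg.seed,
            },
        }
        fh.write(json.dumps(header) + "\n")
        for tree in forest.trees:
            rec = {
                "feature": tree.feature.tolist(),
                "threshold": [None if np.isnan(t) else t for t in tree.threshold],
                "left": tree.left.tolist(),
                "right": tree.right.tolist(),
                "inbag": tree.inbag_counts.tolist(),
                "leaves": {
                    str(k): [v[0].tolist(), v[1].tolist()]
                    for k, v in tree.leaf_rows.items()
                },
                "stats": tree.leaf_stats.tolist(),
            }
            fh.write(json.dumps(rec) + "\n")
    finally:
        if close:
            fh.close()


def forest_from_jsonl(fh: Union[str, TextIO]) -> CausalForest:
    """Read a forest written by :func:`forest_to_jsonl`."""
    close = False
    if isinstance(fh, str):
        fh = open(fh)
        close = True
    try:
        header = json.loads(fh.readline())
        if header.get("type") != "causal_forest":
            raise ValueError("not a causal-forest serialization")
        cfg = ForestConfig(**header["config"])
        trees = []
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            leaf_rows = {
                int(k): (np.asarray(v[0], dtype=np.int64), np.asarray(v[1], dtype=np.int64))
                for k, v in rec["leaves"].items()
            }
            trees.append(
                CausalTree(
                    np.asarray(rec["feature"]),
                    np.asarray([np.nan if t is None else t for t in rec["threshold"]]),
                    np.asarray(rec["left"]),
                    np.asarray(rec["right"]),
                    leaf_rows,
                    np.asarray(rec["stats"]),
                    np.asarray(rec["inbag"]),
                    cfg.rule,
                )
            )
        return CausalForest(trees, cfg, header["n_train"], header["g_scale"])
    finally:
        if close:
            fh.close()
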