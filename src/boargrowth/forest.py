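"""Random-forest regression pre-screen for climate variables.

Ranks candidate predictors of the growth rate by out-of-bag permutation
importance before the mixed-model stage, reproducing the screening step
that discards seasonal precipitation when it carries no signal.

The forest is a plain regression forest: each tree is grown on a
bootstrap sample (with replacement, size n) by recursive binary
splitting minimizing within-node response variance, examining ``mtry``
randomly chosen predictors per split.  Split points are midpoints of
sorted unique values; ties in variance reduction are broken by lowest
predictor index, then lowest threshold, so a seeded forest is fully
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 2000
    mtry: int = 4
    min_node: int = 5  # nodes with <= min_node rows are not split
    bootstrap: bool = True
    seed: int = 0

    def validate(self, n_predictors: int) -> None:
        if not 1 <= self.mtry <= n_predictors:
            raise ValueError(f"mtry={self.mtry} outside [1, {n_predictors}]")
        if self.n_trees < 1:
            raise ValueError("need at least one tree")


class _Tree:
    """Array-encoded binary regression tree (feature -1 marks a leaf)."""

    __slots__ = ("feature", "threshold", "left", "right", "value")

    def __init__(self):
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.value: list[float] = []

    def _new_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(0.0)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(0.0)
        return len(self.feature) - 1

    def finalize(self):
        self.feature = np.asarray(self.feature, np.int64)
        self.threshold = np.asarray(self.threshold, float)
        self.left = np.asarray(self.left, np.int64)
        self.right = np.asarray(self.right, np.int64)
        self.value = np.asarray(self.value, float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(len(X), np.int64)
        internal = self.feature[node] >= 0
        while internal.any():
            idx = np.flatnonzero(internal)
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.left[nd], self.right[nd])
            internal = self.feature[node] >= 0
        return self.value[node]


def _best_split(X, y, rows, features):
    """Best (feature, threshold, gain) over candidate features, or None."""
    n = len(rows)
    Xs = X[np.ix_(rows, features)]  # n x f, features in ascending order
    order = np.argsort(Xs, axis=0, kind="stable")
    xo = np.take_along_axis(Xs, order, axis=0)
    yo = y[rows][order]
    cy = np.cumsum(yo, axis=0)
    s_tot = cy[-1, 0]
    nl = np.arange(1, n, dtype=float)[:, None]
    sl = cy[:-1]
    with np.errstate(invalid="ignore"):
        gain = sl * sl / nl + (s_tot - sl) ** 2 / (n - nl) - (s_tot * s_tot) / n
    gain[xo[1:] == xo[:-1]] = -np.inf
    best = None  # (gain, feature, threshold, order, pos)
    for j in range(gain.shape[1]):  # ascending feature order fixes tie-breaks
        pos = int(np.argmax(gain[:, j]))  # first max = lowest threshold
        g = gain[pos, j]
        if g > 1e-12 and (best is None or g > best[0] + 1e-12):
            best = (float(g), int(features[j]),
                    float(0.5 * (xo[pos, j] + xo[pos + 1, j])), order[:, j], pos)
    return best


def _grow_tree(X, y, sample, cfg: ForestConfig, rng, impurity_acc):
    p = X.shape[1]
    tree = _Tree()
    root = tree._new_node()
    stack = [(root, np.asarray(sample, np.int64))]
    while stack:
        node, rows = stack.pop()
        ysub = y[rows]
        tree.value[node] = float(ysub.mean())
        if len(rows) <= cfg.min_node or np.ptp(ysub) == 0.0:
            continue
        features = np.sort(rng.choice(p, size=cfg.mtry, replace=False))
        found = _best_split(X, y, rows, features)
        if found is None:
            continue
        gain, f, thr, order, pos = found
        impurity_acc[f] += gain
        tree.feature[node] = f
        tree.threshold[node] = thr
        lrows = rows[order[: pos + 1]]
        rrows = rows[order[pos + 1:]]
        lid, rid = tree._new_node(), tree._new_node()
        tree.left[node], tree.right[node] = lid, rid
        stack.append((lid, lrows))
        stack.append((rid, rrows))
    tree.finalize()
    return tree


@dataclass
class Forest:
    trees: list[_Tree]
    oob: list[np.ndarray]  # out-of-bag row indices per tree
    impurity: np.ndarray  # summed variance reduction per predictor
    predictor_names: list[str]
    cfg: ForestConfig

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        return np.mean([t.predict(X) for t in self.trees], axis=0)

    def oob_mse(self, X, y) -> float:
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        total = np.zeros(len(y))
        count = np.zeros(len(y))
        for t, oob in zip(self.trees, self.oob):
            if len(oob):
                total[oob] += t.predict(X[oob])
                count[oob] += 1
        mask = count > 0
        return float(np.mean((y[mask] - total[mask] / count[mask]) ** 2))


def fit_forest(X, y, cfg: ForestConfig = ForestConfig(),
               predictor_names: list[str] | None = None) -> Forest:
    """Grow a seeded regression forest; records OOB rows per tree."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in predictors or response; drop them first")
    n, p = X.shape
    cfg.validate(p)
    if predictor_names is None:
        predictor_names = [f"x{j}" for j in range(p)]
    if np.ptp(y) == 0.0:
        warnings.warn("constant response: all trees are single leaves", stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    trees, oob = [], []
    impurity = np.zeros(p)
    for _ in range(cfg.n_trees):
        if cfg.bootstrap:
            sample = rng.integers(0, n, size=n)
            out = np.setdiff1d(np.arange(n), sample)
        else:
            sample = np.arange(n)
            out = np.empty(0, np.int64)
        trees.append(_grow_tree(X, y, sample, cfg, rng, impurity))
        oob.append(out)
    return Forest(trees, oob, impurity / cfg.n_trees, list(predictor_names), cfg)


def permutation_importance(forest: Forest, X, y, seed: int | None = None) -> pd.DataFrame:
    """OOB permutation importance per predictor (mean OOB MSE increase).

    For each tree, each predictor's OOB column is permuted and the MSE
    increase over the intact OOB MSE recorded; values are averaged over
    trees.  Impurity importance (mean variance reduction) is reported
    alongside, and ranks (1 = most important) use the permutation
    metric.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    rng = np.random.default_rng(forest.cfg.seed + 1 if seed is None else seed)
    imp = np.zeros(p)
    used = np.zeros(p)
    for tree, oob in zip(forest.trees, forest.oob):
        if len(oob) == 0:
            continue
        Xo = X[oob]
        base = float(np.mean((y[oob] - tree.predict(Xo)) ** 2))
        for f in range(p):
            perm = rng.permutation(len(oob))
            Xp = Xo.copy()
            Xp[:, f] = Xo[perm, f]
            imp[f] += float(np.mean((y[oob] - tree.predict(Xp)) ** 2)) - base
            used[f] += 1
    with np.errstate(invalid="ignore"):
        imp = np.where(used > 0, imp / np.maximum(used, 1), np.nan)
    report = pd.DataFrame(dict(
        predictor=forest.predictor_names,
        permutation_importance=imp,
        impurity_importance=forest.impurity,
    ))
    report["rank"] = report["permutation_importance"].rank(ascending=False, method="first")
    return report.sort_values("rank").reset_index(drop=True)


def screen_variables(
    report: pd.DataFrame,
    groups: dict[str, str] | None = None,
    keep_group: str = "temperature",
    drop_group: str = "precipitation",
    top_k: int | None = None,
    metric: str = "permutation_importance",
) -> list[str]:
    """Predictors passing the screening rule.

    Default rule: keep the ``keep_group`` predictors when every
    ``drop_group`` importance ranks below every retained importance
    (group labels supplied via ``groups``: predictor -> group).  With
    ``top_k`` set, simply keep the k most important predictors.
    """
    rep = report.dropna(subset=[metric])
    if top_k is not None:
        kept = rep.nsmallest(top_k, "rank")["predictor"].tolist()
        if not kept:
            raise ValueError("screening rule removed all predictors")
        return kept
    if groups is None:
        raise ValueError("group-based screening needs a predictor -> group mapping")
    keep = rep[[groups.get(pr) == keep_group for pr in rep["predictor"]]]
    drop = rep[[groups.get(pr) == drop_group for pr in rep["predictor"]]]
    if keep.empty:
        raise ValueError("screening rule removed all predictors")
    if not drop.empty and drop[metric].max() >= keep[metric].min():
        raise ValueError(
            f"cannot screen: some {drop_group} importance exceeds a {keep_group} importance")
    return keep["predictor"].tolist()
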