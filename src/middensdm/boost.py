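"""Stochastic gradient-boosted classification trees, written from scratch.

This is the modelling core: a TreeNet/MART-style additive ensemble of
depth-limited regression trees with a logistic link, trained on binomial
deviance with Newton leaf steps. The model's output is the relative index
of occurrence (RIO) in [0, 1] — a relative score, not a calibrated
probability.

Algorithm (per boosting iteration m):

1. residuals ``r_i = y_i - p_i`` with ``p_i = logistic(F_i)``;
2. draw a random subsample of rows (fraction without replacement, seeded);
3. grow a regression tree on ``(x_i, r_i)`` with sample weights by exact
   greedy search over every feature and every midpoint between sorted
   distinct values, maximizing the weighted squared-error reduction,
   subject to ``max_depth`` and a minimum unweighted leaf count;
4. replace each leaf's value by the Newton step
   ``gamma = sum(w r) / sum(w p (1 - p))`` over the leaf's subsample
   (0 when the denominator vanishes);
5. update ``F <- F + nu * gamma(x)`` for *all* rows.

``F_0`` is the logit of the weighted prevalence, so a 0-tree model scores
every row at the prevalence. Split ties break toward the lowest feature
index, then the lowest threshold, making fits bit-reproducible per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "BoostConfig",
    "RegressionTree",
    "BoostedModel",
    "fit_boosted_trees",
    "predict_rio",
    "variable_importance",
    "partial_dependence",
    "roc_auc",
    "binomial_deviance",
]

META_COLUMNS = ("id", "x", "y", "label", "weight")


@dataclass(frozen=True)
class BoostConfig:
    """Boosting hyperparameters.

    ``n_trees=400``, ``max_depth=10`` and ``min_leaf=2`` are the standard
    generic TreeNet defaults this pipeline adopts; shrinkage and subsample
    fraction are the usual stochastic-gradient-boosting choices (small
    learn rate with many trees, half the rows per tree) and are always
    logged because they are the main knobs a reader would vary.
    """

    n_trees: int = 400
    max_depth: int = 10
    min_leaf: int = 2
    shrinkage: float = 0.01
    subsample: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if not 0 < self.shrinkage <= 1:
            raise ValueError("shrinkage must be in (0, 1]")
        if not 0 < self.subsample <= 1:
            raise ValueError("subsample must be in (0, 1]")


class RegressionTree:
    """Binary regression tree as parallel node arrays.

    ``feature[i] == -1`` marks a leaf; internal nodes route
    ``x[feature] <= threshold`` to ``left``. ``improvement[i]`` stores the
    split's weighted squared-error reduction (0 at leaves), which is what
    variable importance accumulates.
    """

    def __init__(self):
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.value: list[float] = []
        self.improvement: list[float] = []

    def _new_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(np.nan)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(0.0)
        self.improvement.append(0.0)
        return len(self.feature) - 1

    def finalize(self) -> None:
        self._feature = np.asarray(self.feature, dtype=np.int64)
        self._threshold = np.asarray(self.threshold, dtype=np.float64)
        self._left = np.asarray(self.left, dtype=np.int64)
        self._right = np.asarray(self.right, dtype=np.int64)
        self._value = np.asarray(self.value, dtype=np.float64)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Leaf value per row, by vectorized traversal."""
        idx = np.zeros(X.shape[0], dtype=np.int64)
        while True:
            feat = self._feature[idx]
            active = np.nonzero(feat >= 0)[0]
            if active.size == 0:
                break
            node = idx[active]
            xval = X[active, self._feature[node]]
            goleft = xval <= self._threshold[node]
            idx[active] = np.where(goleft, self._left[node], self._right[node])
        return self._value[idx]

    def leaf_index(self, X: np.ndarray) -> np.ndarray:
        idx = np.zeros(X.shape[0], dtype=np.int64)
        while True:
            feat = self._feature[idx]
            active = np.nonzero(feat >= 0)[0]
            if active.size == 0:
                return idx
            node = idx[active]
            xval = X[active, self._feature[node]]
            goleft = xval <= self._threshold[node]
            idx[active] = np.where(goleft, self._left[node], self._right[node])

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left,
            "right": self.right,
            "value": self.value,
            "improvement": self.improvement,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        t = cls()
        t.feature = [int(v) for v in d["feature"]]
        t.threshold = [float(v) for v in d["threshold"]]
        t.left = [int(v) for v in d["left"]]
        t.right = [int(v) for v in d["right"]]
        t.value = [float(v) for v in d["value"]]
        t.improvement = [float(v) for v in d["improvement"]]
        t.finalize()
        return t


def _best_split(X: np.ndarray, r: np.ndarray, w: np.ndarray, min_leaf: int):
    """Exact greedy split search over all features and midpoints.

    Returns ``(feature, threshold, improvement)`` or ``None``. Improvement
    is the reduction in weighted SSE of the residuals:
    ``S_L^2/W_L + S_R^2/W_R - S^2/W`` with ``S = sum(w r)``, ``W = sum(w)``.
    """
    m, p = X.shape
    if m < 2 * min_leaf:
        return None
    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    ws = w[order]
    wrs = (w * r)[order]
    csw = np.cumsum(ws, axis=0)
    cswr = np.cumsum(wrs, axis=0)
    W = csw[-1]
    S = cswr[-1]
    # split at position i: left = rows [0, i), right = rows [i, m)
    i = np.arange(min_leaf, m - min_leaf + 1)
    if i.size == 0:
        return None
    WL = csw[i - 1]          # (k, p)
    SL = cswr[i - 1]
    WR = W[None, :] - WL
    SR = S[None, :] - SL
    distinct = Xs[i] > Xs[i - 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = SL ** 2 / WL + SR ** 2 / WR - (S ** 2 / W)[None, :]
    gain = np.where(distinct & (WL > 0) & (WR > 0), gain, -np.inf)
    best = None
    for f in range(p):  # ascending feature index: ties keep the lowest
        col = gain[:, f]
        k = int(np.argmax(col))  # first occurrence: lowest threshold on ties
        g = col[k]
        if not np.isfinite(g) or g <= 1e-12:
            continue
        if best is None or g > best[2] + 1e-15:
            pos = i[k]
            thr = 0.5 * (Xs[pos - 1, f] + Xs[pos, f])
            best = (f, float(thr), float(g))
    return best


def _grow_tree(X: np.ndarray, r: np.ndarray, w: np.ndarray, p_hat: np.ndarray,
               max_depth: int, min_leaf: int) -> RegressionTree:
    tree = RegressionTree()

    def leaf_value(rows: np.ndarray) -> float:
        num = float(np.sum(w[rows] * r[rows]))
        den = float(np.sum(w[rows] * p_hat[rows] * (1.0 - p_hat[rows])))
        return 0.0 if den < 1e-12 else num / den

    def build(rows: np.ndarray, depth: int) -> int:
        node = tree._new_node()
        split = None
        if depth < max_depth:
            split = _best_split(X[rows], r[rows], w[rows], min_leaf)
        if split is None:
            tree.value[node] = leaf_value(rows)
            return node
        f, thr, gain = split
        tree.feature[node] = f
        tree.threshold[node] = thr
        tree.improvement[node] = gain
        goleft = X[rows, f] <= thr
        tree.left[node] = build(rows[goleft], depth + 1)
        tree.right[node] = build(rows[~goleft], depth + 1)
        return node

    build(np.arange(X.shape[0]), 0)
    tree.finalize()
    return tree


@dataclass
class BoostedModel:
    """Fitted additive ensemble: ``RIO(x) = logistic(F0 + sum nu * tree(x))``."""

    f0: float
    trees: list[RegressionTree]
    feature_names: list[str]
    config: BoostConfig
    deviance_path: list[float] = field(default_factory=list)

    # -- prediction -------------------------------------------------------

    def _matrix(self, rows) -> np.ndarray:
        if isinstance(rows, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in rows.columns]
            if missing:
                raise ValueError(f"rows are missing feature '{missing[0]}'")
            X = rows[self.feature_names].to_numpy(dtype=np.float64)
        else:
            X = np.asarray(rows, dtype=np.float64)
            if X.ndim != 2 or X.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"expected (n, {len(self.feature_names)}) feature matrix"
                )
        if np.isnan(X).any():
            raise ValueError("NaN in predictor values")
        return X

    def raw_score(self, rows) -> np.ndarray:
        """Log-odds F(x) before the logistic link."""
        X = self._matrix(rows)
        F = np.full(X.shape[0], self.f0)
        nu = self.config.shrinkage
        for tree in self.trees:
            F += nu * tree.predict(X)
        return F

    def predict(self, rows) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.raw_score(rows)))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "f0": self.f0,
            "feature_names": self.feature_names,
            "config": asdict(self.config),
            "deviance_path": self.deviance_path,
            "trees": [t.to_dict() for t in self.trees],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "BoostedModel":
        return cls(
            f0=float(d["f0"]),
            trees=[RegressionTree.from_dict(t) for t in d["trees"]],
            feature_names=list(d["feature_names"]),
            config=BoostConfig(**d["config"]),
            deviance_path=[float(v) for v in d.get("deviance_path", [])],
        )

    @classmethod
    def from_json(cls, path) -> "BoostedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def binomial_deviance(y: np.ndarray, p: np.ndarray,
                      w: np.ndarray | None = None) -> float:
    """Weighted mean binomial deviance, -2 * mean(w * loglik) / mean(w)."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    w = np.ones_like(y) if w is None else np.asarray(w, dtype=float)
    ll = y * np.log(p) + (1 - y) * np.log(1 - p)
    return float(-2.0 * np.sum(w * ll) / np.sum(w))


def fit_boosted_trees(table: pd.DataFrame, config: BoostConfig = BoostConfig(),
                      feature_names: list[str] | None = None) -> BoostedModel:
    """Fit the boosted ensemble to a balanced sample table.

    ``table`` needs ``label`` (binary), optional ``weight`` (defaults to 1)
    and the predictor columns (every non-metadata column unless
    ``feature_names`` is given).
    """
    if feature_names is None:
        feature_names = [c for c in table.columns if c not in META_COLUMNS]
    if not feature_names:
        raise ValueError("no predictor columns found")
    y = table["label"].to_numpy(dtype=np.float64)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    w = (table["weight"].to_numpy(dtype=np.float64)
         if "weight" in table.columns else np.ones_like(y))
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    X = table[feature_names].to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        bad = [f for f in feature_names if table[f].isna().any()]
        raise ValueError(f"NaN in predictor column '{bad[0]}'")

    n = len(y)
    prev = float(np.sum(w * y) / np.sum(w))
    prev = min(max(prev, 1e-12), 1 - 1e-12)
    f0 = float(np.log(prev / (1 - prev)))
    F = np.full(n, f0)
    rng = np.random.default_rng(config.seed)
    trees: list[RegressionTree] = []
    nu = config.shrinkage
    m_sub = max(2 * config.min_leaf, int(round(config.subsample * n)))
    m_sub = min(m_sub, n)
    p = 1.0 / (1.0 + np.exp(-F))
    path = [binomial_deviance(y, p, w)]

    for _ in range(config.n_trees):
        r = y - p
        if config.subsample < 1.0:
            rows = np.sort(rng.choice(n, size=m_sub, replace=False))
        else:
            rows = np.arange(n)
        tree = _grow_tree(X[rows], r[rows], w[rows], p[rows],
                          config.max_depth, config.min_leaf)
        trees.append(tree)
        F += nu * tree.predict(X)
        p = 1.0 / (1.0 + np.exp(-F))
        path.append(binomial_deviance(y, p, w))

    return BoostedModel(f0=f0, trees=trees, feature_names=list(feature_names),
                        config=config, deviance_path=path)


def predict_rio(model: BoostedModel, rows) -> np.ndarray:
    """RIO in [0, 1] for each row: ``logistic(F0 + sum nu * tree(x))``."""
    return model.predict(rows)


def variable_importance(model: BoostedModel) -> pd.DataFrame:
    """Per-predictor importance: summed split improvements, max scaled to 100.

    Returns a two-column frame (predictor, score), descending; ties break
    alphabetically. A predictor never used in any split scores 0.00.
    """
    raw = {name: 0.0 for name in model.feature_names}
    for tree in model.trees:
        for f, imp in zip(tree.feature, tree.improvement):
            if f >= 0:
                raw[model.feature_names[f]] += imp
    top = max(raw.values()) if raw else 0.0
    df = pd.DataFrame(
        {"predictor": list(raw),
         "score": [100.0 * v / top if top > 0 else 0.0
                   for v in raw.values()]}
    )
    return (df.sort_values(["score", "predictor"], ascending=[False, True])
              .reset_index(drop=True))


def partial_dependence(model: BoostedModel, table: pd.DataFrame, feature: str,
                       grid: np.ndarray) -> pd.DataFrame:
    """Partial dependence on the centered log-odds scale.

    ``PD(v)`` is the mean raw score over the training rows with ``feature``
    forced to ``v``, centered by subtracting the grid-wide mean. Evaluated
    by brute force (no tree-traversal shortcut), so it is valid for any
    ensemble regardless of structure.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("partial dependence grid is empty")
    if feature not in model.feature_names:
        raise ValueError(f"model has no feature '{feature}'")
    X = table[model.feature_names].copy()
    pd_vals = np.empty(grid.size)
    for i, v in enumerate(grid):
        X[feature] = v
        pd_vals[i] = float(np.mean(model.raw_score(X)))
    pd_vals -= pd_vals.mean()
    return pd.DataFrame({"value": grid, "pd": pd_vals})


def pd_zero_crossing(curve: pd.DataFrame) -> float | None:
    """First sign change of the PD curve, by linear interpolation."""
    v = curve["value"].to_numpy()
    y = curve["pd"].to_numpy()
    for i in range(len(y) - 1):
        if y[i] == 0:
            return float(v[i])
        if y[i] * y[i + 1] < 0:
            return float(v[i] - y[i] * (v[i + 1] - v[i]) / (y[i + 1] - y[i]))
    return None


def roc_auc(labels: np.ndarray, scores: np.ndarray,
            weights: np.ndarray | None = None) -> float:
    """Weighted ROC AUC as the Mann-Whitney statistic
    ``P(score_1 > score_0) + 0.5 * P(tie)`` with weights multiplying pair
    contributions."""
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    w1 = np.where(y == 1, w, 0.0)
    w0 = np.where(y == 0, w, 0.0)
    W1, W0 = w1.sum(), w0.sum()
    if W1 <= 0 or W0 <= 0:
        raise ValueError("both classes must be present (with positive weight)")
    order = np.argsort(s, kind="stable")
    s, w1, w0 = s[order], w1[order], w0[order]
    # group ties
    new_group = np.empty(len(s), dtype=bool)
    new_group[0] = True
    new_group[1:] = s[1:] != s[:-1]
    gid = np.cumsum(new_group) - 1
    g1 = np.bincount(gid, weights=w1)
    g0 = np.bincount(gid, weights=w0)
    cum0_below = np.concatenate([[0.0], np.cumsum(g0)[:-1]])
    num = np.sum(g1 * (cum0_below + 0.5 * g0))
    return float(num / (W1 * W0))
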