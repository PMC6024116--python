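"""Boosted regression trees for presence/background response.

Stagewise gradient boosting of small regression trees under Bernoulli
deviance, the standard configuration for presence-only species
distribution models: the model starts at the logit of the observed
prevalence and at every stage fits a least-squares tree with ``tc``
internal splits to the current gradient (y - p) on a random bag of
``bf * n`` rows drawn without replacement, sets each terminal-node value
by a single Newton step, and adds the tree shrunk by the learning rate.

The three knobs are the classic BRT triple: learning rate (shrinkage),
tree complexity (splits per tree, controlling interaction order) and bag
fraction (stochasticity).  The number of trees actually used for
prediction is chosen by k-fold cross-validated predictive deviance.

Continuous features split on value thresholds; categorical features split
on category subsets, found by exhaustive search for up to 8 categories and
by the mean-gradient ordering otherwise.  Relative influence of a
predictor is the share of squared-error improvement over all splits on it,
normalized to percentages summing to 100.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .grid import EnvStack
from .evaluate import SuitabilityMap

__all__ = ["BRTConfig", "BRTModel", "PAPER_PRESET", "fit_brt", "select_n_trees",
           "relative_influence", "predict_map", "bernoulli_deviance"]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class BRTConfig:
    learning_rate: float = 0.01
    tree_complexity: int = 2
    bag_fraction: float = 0.75
    max_trees: int = 1000
    step: int = 50
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning rate must be in (0, 1]")
        if self.tree_complexity < 1:
            raise ValueError("tree complexity must be >= 1")
        if not 0 < self.bag_fraction <= 1:
            raise ValueError("bag fraction must be in (0, 1]")
        if not self.max_trees >= self.step >= 1:
            raise ValueError("need max_trees >= step >= 1")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 CV folds")


#: The study-scale preset: very small shrinkage, pairwise interactions,
#: stochastic bagging.  Desk-scale runs default to learning_rate=0.01.
PAPER_PRESET = BRTConfig(learning_rate=0.0001, tree_complexity=2, bag_fraction=0.75,
                         max_trees=20000, step=500)


# ---------------------------------------------------------------------------
# trees


@dataclass
class _Node:
    feature: int = -1              # -1 marks a leaf
    threshold: float = 0.0         # continuous split: x <= threshold goes left
    categories: tuple | None = None  # categorical split: x in categories goes left
    seen_categories: tuple | None = None  # all codes present at training time
    left: int = -1
    right: int = -1
    value: float = 0.0             # leaf value (Newton step)
    improvement: float = 0.0       # squared-error gain of this split
    n_left: int = 0
    n_right: int = 0


def _best_split(x: np.ndarray, r: np.ndarray, is_cat: bool):
    """Best least-squares split of gradient r on feature x.

    Returns (improvement, threshold, left_categories, seen_categories,
    left_mask) or None.  Improvement is sum_L^2/n_L + sum_R^2/n_R -
    sum^2/n, the decrease in node SSE achievable by the split.
    """
    n = x.size
    if n < 2:
        return None
    total = r.sum()
    base = total * total / n
    if is_cat:
        cats, inverse = np.unique(x, return_inverse=True)
        k = cats.size
        if k < 2:
            return None
        sums = np.bincount(inverse, weights=r, minlength=k)
        counts = np.bincount(inverse, minlength=k)
        if k <= 8:
            # exhaustive over proper subsets; fix category 0 on the left
            best = None
            for mask_bits in range(1, 1 << (k - 1)):
                bits = (mask_bits << 1) | 1
                sel = np.array([(bits >> i) & 1 for i in range(k)], dtype=bool)
                n_l = counts[sel].sum()
                if n_l == 0 or n_l == n:
                    continue
                s_l = sums[sel].sum()
                imp = s_l * s_l / n_l + (total - s_l) ** 2 / (n - n_l) - base
                if best is None or imp > best[0]:
                    best = (imp, sel.copy())
            if best is None:
                return None
            imp, sel = best
            left_cats = tuple(float(c) for c in cats[sel])
            seen = tuple(float(c) for c in cats)
            return imp, None, left_cats, seen, np.isin(x, cats[sel])
        # many categories: order by mean gradient and scan prefixes
        order = np.argsort(sums / np.maximum(counts, 1))
        cs = np.cumsum(sums[order])[:-1]
        cn = np.cumsum(counts[order])[:-1]
        ok = (cn > 0) & (cn < n)
        if not np.any(ok):
            return None
        imp = np.where(ok, cs**2 / np.maximum(cn, 1)
                       + (total - cs) ** 2 / np.maximum(n - cn, 1) - base, -np.inf)
        j = int(np.argmax(imp))
        left_cats = tuple(float(c) for c in cats[order[: j + 1]])
        seen = tuple(float(c) for c in cats)
        return float(imp[j]), None, left_cats, seen, np.isin(x, np.asarray(left_cats))
    order = np.argsort(x, kind="stable")
    xs = x[order]
    cs = np.cumsum(r[order])[:-1]
    cn = np.arange(1, n)
    valid = xs[:-1] < xs[1:]
    if not np.any(valid):
        return None
    imp = np.where(valid, cs**2 / cn + (total - cs) ** 2 / (n - cn) - base, -np.inf)
    j = int(np.argmax(imp))
    thr = 0.5 * (xs[j] + xs[j + 1])
    return float(imp[j]), float(thr), None, None, x <= thr


def _fit_tree(X: np.ndarray, r: np.ndarray, h: np.ndarray, tc: int,
              cat_cols: frozenset[int]) -> list[_Node]:
    """Best-first least-squares tree with at most tc internal splits.

    Leaf values are the single Newton step sum(r)/sum(h) for Bernoulli
    deviance.
    """
    n, p = X.shape
    nodes = [_Node()]
    rows_of = {0: np.arange(n)}

    def leaf_value(idx):
        denom = h[idx].sum()
        return float(r[idx].sum() / max(denom, _EPS))

    nodes[0].value = leaf_value(rows_of[0])
    # candidate best split per current leaf
    candidates: dict[int, tuple] = {}

    def compute_candidate(node_id):
        idx = rows_of[node_id]
        best = None
        for f in range(p):
            res = _best_split(X[idx, f], r[idx], f in cat_cols)
            if res is not None and (best is None or res[0] > best[0]):
                best = (res[0], f, res[1], res[2], res[3], res[4])
        if best is not None and best[0] > 0:
            candidates[node_id] = best

    compute_candidate(0)
    for _ in range(tc):
        if not candidates:
            break
        node_id = max(candidates, key=lambda k: (candidates[k][0], -k))
        imp, f, thr, cats, seen, left_mask = candidates.pop(node_id)
        idx = rows_of.pop(node_id)
        li, ri = idx[left_mask], idx[~left_mask]
        node = nodes[node_id]
        node.feature = f
        node.threshold = thr if thr is not None else 0.0
        node.categories = cats
        node.seen_categories = seen
        node.improvement = imp
        node.n_left, node.n_right = len(li), len(ri)
        node.left, node.right = len(nodes), len(nodes) + 1
        nodes.append(_Node(value=leaf_value(li)))
        nodes.append(_Node(value=leaf_value(ri)))
        rows_of[node.left], rows_of[node.right] = li, ri
        compute_candidate(node.left)
        compute_candidate(node.right)
    return nodes


def _tree_predict(nodes: list[_Node], X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    stack = [(0, np.arange(X.shape[0]))]
    while stack:
        node_id, idx = stack.pop()
        node = nodes[node_id]
        if node.feature < 0:
            out[idx] = node.value
            continue
        x = X[idx, node.feature]
        if node.categories is not None:
            go_left = np.isin(x, np.asarray(node.categories))
            if node.seen_categories is not None:
                unseen = ~np.isin(x, np.asarray(node.seen_categories))
                if np.any(unseen) and node.n_left >= node.n_right:
                    # unseen codes are routed to the more populous child
                    go_left = go_left | unseen
        else:
            go_left = x <= node.threshold
        stack.append((node.left, idx[go_left]))
        stack.append((node.right, idx[~go_left]))
    return out


@dataclass
class BRTModel:
    trees: list[list[_Node]]
    intercept: float
    config: BRTConfig
    feature_names: list[str]
    categorical: list[int]
    n_trees_opt: int = 0
    cv_deviance: list[tuple[int, float]] = field(default_factory=list)

    def decision(self, X: np.ndarray, n_trees: int | None = None) -> np.ndarray:
        n_trees = self.n_trees_opt if n_trees is None else n_trees
        F = np.full(X.shape[0], self.intercept)
        for tree in self.trees[:n_trees]:
            F += self.config.learning_rate * _tree_predict(tree, X)
        return F

    def predict(self, X: np.ndarray, n_trees: int | None = None) -> np.ndarray:
        """Presence probability per row (inverse-logit of the decision)."""
        return _sigmoid(self.decision(X, n_trees))

    def staged_decision(self, X: np.ndarray):
        """Yield (n_trees, decision) after every tree; used for CV curves."""
        F = np.full(X.shape[0], self.intercept)
        yield 0, F.copy()
        for i, tree in enumerate(self.trees, start=1):
            F += self.config.learning_rate * _tree_predict(tree, X)
            yield i, F.copy()

    # -- serialization (JSON, text-only) ------------------------------------

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "config": asdict(self.config),
            "feature_names": self.feature_names,
            "categorical": self.categorical,
            "n_trees_opt": self.n_trees_opt,
            "cv_deviance": [[int(k), float(d)] for k, d in self.cv_deviance],
            "trees": [[asdict(nd) for nd in tree] for tree in self.trees],
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict()))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "BRTModel":
        trees = []
        for tree in d["trees"]:
            trees.append([
                _Node(**{**nd,
                         "categories": tuple(nd["categories"])
                         if nd["categories"] is not None else None,
                         "seen_categories": tuple(nd["seen_categories"])
                         if nd.get("seen_categories") is not None else None})
                for nd in tree])
        return cls(trees=trees, intercept=d["intercept"], config=BRTConfig(**d["config"]),
                   feature_names=list(d["feature_names"]), categorical=list(d["categorical"]),
                   n_trees_opt=d["n_trees_opt"],
                   cv_deviance=[(int(k), float(v)) for k, v in d["cv_deviance"]])

    @classmethod
    def load(cls, path: str | Path) -> "BRTModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _sigmoid(F: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(F, -500, 500)))


def bernoulli_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Mean -2 log-likelihood of binary labels under probabilities p."""
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


# ---------------------------------------------------------------------------
# fitting


def fit_brt(X: np.ndarray, y: np.ndarray, config: BRTConfig = BRTConfig(),
            categorical: list[int] | None = None,
            feature_names: list[str] | None = None,
            n_trees: int | None = None) -> BRTModel:
    """Fit the boosted ensemble; ``n_trees`` overrides config.max_trees.

    The optimal tree count is left at the number fitted; use
    :func:`select_n_trees` (cross-validation) to choose it from data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) with one label per row")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be 0 (background) or 1 (presence)")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least one presence and one background row")
    n = X.shape[0]
    n_bag = max(2, int(round(config.bag_fraction * n)))
    if n_bag > n:
        n_bag = n
    cat_cols = frozenset(categorical or ())
    names = feature_names or [f"x{j}" for j in range(X.shape[1])]
    total = n_trees if n_trees is not None else config.max_trees

    p_bar = y.mean()
    intercept = float(np.log(p_bar / (1 - p_bar)))
    rng = np.random.default_rng(config.seed)
    F = np.full(n, intercept)
    trees: list[list[_Node]] = []
    for _ in range(total):
        p = _sigmoid(F)
        r = y - p
        h = np.maximum(p * (1 - p), _EPS)
        bag = rng.choice(n, size=n_bag, replace=False) if n_bag < n else np.arange(n)
        tree = _fit_tree(X[bag], r[bag], h[bag], config.tree_complexity, cat_cols)
        trees.append(tree)
        F += config.learning_rate * _tree_predict(tree, X)
    return BRTModel(trees=trees, intercept=intercept, config=config,
                    feature_names=list(names), categorical=sorted(cat_cols),
                    n_trees_opt=total)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for label in (0.0, 1.0):
        idx = np.flatnonzero(y == label)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % k].append(j)
    out = [np.sort(np.array(f, dtype=int)) for f in folds]
    for f in out:
        held = y[f]
        if len(np.unique(held)) < 2 and len(held) > 0:
            raise ValueError("stratified folding impossible: a fold has a single class")
    return out


def select_n_trees(X: np.ndarray, y: np.ndarray, config: BRTConfig = BRTConfig(),
                   categorical: list[int] | None = None) -> tuple[int, list[tuple[int, float]]]:
    """Optimal tree count by k-fold cross-validated predictive deviance.

    Held-out Bernoulli deviance is evaluated every ``config.step`` trees
    and averaged over folds; the first tree count attaining the minimum is
    returned together with the (n_trees, deviance) curve.  A minimum at
    max_trees logs a warning (the ensemble may still be improving).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(config.seed)
    folds = _stratified_folds(y, config.cv_folds, rng)
    checkpoints = list(range(config.step, config.max_trees + 1, config.step))
    dev_sum = np.zeros(len(checkpoints))
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        fold_cfg = BRTConfig(**{**asdict(config), "seed": config.seed + 1000 + i})
        model = fit_brt(X[train_idx], y[train_idx], fold_cfg, categorical)
        want = set(checkpoints)
        for k, Ftest in model.staged_decision(X[test_idx]):
            if k in want:
                dev_sum[checkpoints.index(k)] += bernoulli_deviance(
                    y[test_idx], _sigmoid(Ftest))
    mean_dev = dev_sum / len(folds)
    best = int(np.argmin(mean_dev))  # argmin returns the first minimum
    n_opt = checkpoints[best]
    if n_opt == config.max_trees:
        logger.warning("CV deviance still decreasing at max_trees=%d", config.max_trees)
    return n_opt, list(zip(checkpoints, mean_dev.tolist()))


def relative_influence(model: BRTModel, n_trees: int | None = None) -> dict[str, float]:
    """Per-predictor relative influence (%), summing to 100.

    The influence of a predictor is the total squared-error improvement of
    all splits made on it over the first ``n_trees`` trees.
    """
    n_trees = model.n_trees_opt if n_trees is None else n_trees
    totals = np.zeros(len(model.feature_names))
    for tree in model.trees[:n_trees]:
        for node in tree:
            if node.feature >= 0:
                totals[node.feature] += node.improvement
    s = totals.sum()
    if s <= 0:
        logger.warning("no split improvement recorded; reporting uniform influences")
        totals = np.ones_like(totals)
        s = totals.sum()
    pct = 100.0 * totals / s
    return dict(zip(model.feature_names, pct.tolist()))


def predict_map(model: BRTModel, stack: EnvStack, replicate: int | None = None
                ) -> SuitabilityMap:
    """Project the model onto a stack: per-cell presence probability.

    The stack must provide every predictor the model was trained on; its
    mask (geographic extent, depth limit, missing data) carries over to
    the output map.
    """
    missing = [n for n in model.feature_names if n not in stack]
    if missing:
        raise ValueError(f"stack {stack.period!r} lacks model predictors {missing}")
    X, flat_idx = stack.feature_matrix(model.feature_names)
    p = model.predict(X)
    values = np.full(stack.grid.shape, np.nan).ravel()
    values[flat_idx] = p
    values = values.reshape(stack.grid.shape)
    return SuitabilityMap(grid=stack.grid, values=values, mask=~stack.valid_mask(),
                          period=stack.period, replicate=replicate)
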