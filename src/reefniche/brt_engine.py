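"""Boosted regression trees for weighted presence/absence data.

A from-scratch stagewise gradient-boosting machine for the Bernoulli
deviance, in the style ecologists use for species distribution modelling:
small regression trees fit to the gradient residual ``y - p``, shrunk by a
learning rate, with stochastic bagging, balanced case weights so presences
and absences carry equal total weight, and tree-count selection by
cross-validated predictive deviance on inner folds of the training data.

The estimator follows the scikit-learn protocol (``fit`` /
``predict_proba`` / ``get_params``), so it composes with sklearn model
selection; the module-level functions are thin wrappers kept for pipeline
scripting.

Model internals are deliberately simple and auditable:

* intercept = logit of the weighted prevalence (zero under balanced weights);
* split search = exhaustive over midpoints of sorted unique values,
  maximizing the weighted squared-error reduction of the working response;
* terminal values = one Newton step, ``sum(w r) / sum(w p (1 - p))`` over the
  node's bagged cases;
* relative influence = per-predictor sum of split gain over all trees,
  normalized to 100 %;
* partial dependence = average model response with one predictor clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "FitConfig",
    "RegressionTree",
    "BoostedTreesClassifier",
    "balance_weights",
    "fit_tree",
    "fit_boosted",
    "bernoulli_deviance",
]

_EPS = 1e-12


class FitError(ValueError):
    pass


@dataclass
class FitConfig:
    """Hyper-parameters of the boosted model.

    Defaults follow common niche-model practice for ~1000-site surveys:
    a very small learning rate (0.0015) with trees grown in steps of 30
    from an initial 30, tree complexity of five splits (number of
    predictors minus two when seven predictors are in play), bag fraction
    0.8, and 5-fold inner cross-validation for tree-count selection.
    """

    tree_complexity: int = 5
    learning_rate: float = 0.0015
    bag_fraction: float = 0.8
    initial_trees: int = 30
    step_trees: int = 30
    max_trees: int = 3000
    cv_folds: int = 5
    min_obs_node: int = 5
    seed: int = 0
    bag_with_replacement: bool = False

    def validate(self) -> None:
        if not 0 < self.learning_rate <= 1:
            raise FitError("learning_rate must be in (0, 1]")
        if not 0 < self.bag_fraction <= 1:
            raise FitError("bag_fraction must be in (0, 1]")
        if self.initial_trees > self.max_trees:
            raise FitError("initial_trees must not exceed max_trees")
        if self.tree_complexity < 1:
            raise FitError("tree_complexity must be >= 1")


def balance_weights(y: np.ndarray) -> np.ndarray:
    """Case weights equalizing the total weight of presences and absences.

    The majority class gets weight 1; the minority class gets
    ``n_majority / n_minority``, so the class weight sums are equal.
    """
    y = np.asarray(y)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise FitError("both presences and absences are required")
    w = np.ones(len(y), dtype=float)
    if n1 <= n0:
        w[y == 1] = n0 / n1
    else:
        w[y == 0] = n1 / n0
    return w


def bernoulli_deviance(y, p, w=None) -> float:
    """Mean weighted Bernoulli deviance, -2 E[ y log p + (1-y) log(1-p) ]."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), _EPS, 1 - _EPS)
    w = np.ones_like(y) if w is None else np.asarray(w, dtype=float)
    ll = y * np.log(p) + (1 - y) * np.log(1 - p)
    return float(-2.0 * np.sum(w * ll) / np.sum(w))


# ---------------------------------------------------------------------------
# regression tree


class RegressionTree:
    """Binary regression tree stored as flat node arrays.

    ``feature[i] == -1`` marks a leaf with prediction ``value[i]``; internal
    nodes send rows left iff ``x[feature] < threshold``. ``gain[i]`` records
    the weighted squared-error reduction of the split at node ``i`` (used by
    relative influence).
    """

    def __init__(self) -> None:
        self.feature: list[int] = [-1]
        self.threshold: list[float] = [np.nan]
        self.left: list[int] = [-1]
        self.right: list[int] = [-1]
        self.value: list[float] = [0.0]
        self.gain: list[float] = [0.0]

    def add_leaf(self, value: float) -> int:
        self.feature.append(-1)
        self.threshold.append(np.nan)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(value)
        self.gain.append(0.0)
        return len(self.feature) - 1

    def split_node(self, node: int, feat: int, thr: float, gain: float,
                   left: int, right: int) -> None:
        self.feature[node] = feat
        self.threshold[node] = thr
        self.gain[node] = gain
        self.left[node] = left
        self.right[node] = right

    @property
    def n_splits(self) -> int:
        return sum(1 for f in self.feature if f >= 0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X))
        node_of = np.zeros(len(X), dtype=int)
        # iterate until every row sits in a leaf (tree depth is tiny)
        pending = np.arange(len(X))
        while len(pending):
            nodes = node_of[pending]
            feats = np.array(self.feature)[nodes]
            leaf = feats < 0
            out[pending[leaf]] = np.array(self.value)[nodes[leaf]]
            live = pending[~leaf]
            if not len(live):
                break
            nodes = node_of[live]
            feats = np.array(self.feature)[nodes]
            thr = np.array(self.threshold)[nodes]
            go_left = X[live, feats] < thr
            node_of[live] = np.where(
                go_left,
                np.array(self.left)[nodes],
                np.array(self.right)[nodes],
            )
            pending = live
        return out

    def splits(self) -> list[tuple[int, float, float]]:
        """(feature index, threshold, gain) for every internal node."""
        return [
            (f, t, g)
            for f, t, g in zip(self.feature, self.threshold, self.gain)
            if f >= 0
        ]

    def to_dict(self, feature_names: Sequence[str]) -> dict:
        return {
            "feature": [feature_names[f] if f >= 0 else None
                        for f in self.feature],
            "threshold": [None if np.isnan(t) else float(t)
                          for t in self.threshold],
            "left": self.left,
            "right": self.right,
            "value": [float(v) for v in self.value],
            "gain": [float(g) for g in self.gain],
        }


def _best_split(X, r, w, idx, min_obs):
    """Best (feature, threshold, gain) over candidate midpoint splits.

    gain = S_L^2/W_L + S_R^2/W_R - S^2/W with S = sum(w r), W = sum(w),
    i.e. the reduction in weighted squared error of the node mean model.
    Ties resolve to the first feature (input order) and lowest threshold.
    """
    best = (None, np.nan, 0.0)  # feature, threshold, gain
    S = float(np.sum(w[idx] * r[idx]))
    W = float(np.sum(w[idx]))
    if W <= 0 or len(idx) < 2 * min_obs:
        return best
    base = S * S / W
    for j in range(X.shape[1]):
        xj = X[idx, j]
        order = np.argsort(xj, kind="mergesort")
        xs = xj[order]
        ws = w[idx][order]
        rs = r[idx][order]
        cw = np.cumsum(ws * rs)
        cwt = np.cumsum(ws)
        # candidate boundaries: between adjacent distinct values
        distinct = xs[1:] != xs[:-1]
        pos = np.where(distinct)[0]  # split after sorted position pos
        if len(pos) == 0:
            continue
        nleft = pos + 1
        ok = (nleft >= min_obs) & (len(idx) - nleft >= min_obs)
        pos = pos[ok]
        if len(pos) == 0:
            continue
        SL = cw[pos]
        WL = cwt[pos]
        SR = S - SL
        WR = W - WL
        with np.errstate(divide="ignore", invalid="ignore"):
            gains = SL**2 / WL + SR**2 / WR - base
        gains = np.nan_to_num(gains, nan=0.0)
        k = int(np.argmax(gains))  # first max -> lowest threshold
        if gains[k] > best[2] + 1e-12:
            thr = 0.5 * (xs[pos[k]] + xs[pos[k] + 1])
            best = (j, float(thr), float(gains[k]))
    return best


def fit_tree(
    X: np.ndarray,
    r: np.ndarray,
    w: np.ndarray,
    h: np.ndarray,
    tree_complexity: int,
    min_obs_node: int,
    bag: np.ndarray,
) -> RegressionTree:
    """Greedy best-first regression tree on the bagged working response.

    At each of up to ``tree_complexity`` steps the leaf whose best split
    yields the largest weighted squared-error reduction is split. Terminal
    values are Newton steps ``sum(w r) / sum(w h)`` (h = p(1-p)) over the
    leaf's bagged cases; a degenerate denominator yields a zero increment.
    """
    tree = RegressionTree()
    members = {0: np.asarray(bag)}

    def newton(idx) -> float:
        num = float(np.sum(w[idx] * r[idx]))
        den = float(np.sum(w[idx] * h[idx]))
        return num / den if den > _EPS else 0.0

    tree.value[0] = newton(members[0])
    # candidate best split per leaf
    candidates = {0: _best_split(X, r, w, members[0], min_obs_node)}

    for _ in range(tree_complexity):
        # pick the leaf with the largest gain (stable: earliest leaf wins ties)
        leaf, cand = None, (None, np.nan, 0.0)
        for nid, c in candidates.items():
            if c[0] is not None and c[2] > cand[2] + 1e-12:
                leaf, cand = nid, c
        if leaf is None:
            break
        feat, thr, gain = cand
        idx = members.pop(leaf)
        go_left = X[idx, feat] < thr
        li = idx[go_left]
        ri = idx[~go_left]
        lid = tree.add_leaf(newton(li))
        rid = tree.add_leaf(newton(ri))
        tree.split_node(leaf, feat, thr, gain, lid, rid)
        del candidates[leaf]
        members[lid], members[rid] = li, ri
        candidates[lid] = _best_split(X, r, w, li, min_obs_node)
        candidates[rid] = _best_split(X, r, w, ri, min_obs_node)
    return tree


# ---------------------------------------------------------------------------
# boosted ensemble


class BoostedTreesClassifier(BaseEstimator, ClassifierMixin):
    """Stagewise boosted regression trees for binary presence/absence.

    Parameters mirror :class:`FitConfig`. With ``class_weight="balanced"``
    (the default) presences and absences receive equal total weight before
    fitting, so the intercept — the logit of the weighted prevalence — is
    zero and a 0.5 probability threshold is meaningful.

    Fitted attributes
    -----------------
    intercept_ : float
        Link-scale intercept.
    trees_ : list[RegressionTree]
        The selected boosting sequence.
    n_trees_ : int
        Number of trees selected by inner-fold CV deviance (or max_trees
        when ``cv_folds < 2``).
    relative_influence_ : pandas.Series
        Friedman importance per predictor, percentages summing to 100.
    train_deviance_ : numpy.ndarray
        Weighted training deviance after each boosting iteration.
    cv_deviance_ : numpy.ndarray or None
        Mean held-out deviance per tree count over the inner folds.
    """

    def __init__(
        self,
        tree_complexity: int = 5,
        learning_rate: float = 0.0015,
        bag_fraction: float = 0.8,
        initial_trees: int = 30,
        step_trees: int = 30,
        max_trees: int = 3000,
        cv_folds: int = 5,
        min_obs_node: int = 5,
        seed: int = 0,
        bag_with_replacement: bool = False,
        class_weight: str | None = "balanced",
    ) -> None:
        self.tree_complexity = tree_complexity
        self.learning_rate = learning_rate
        self.bag_fraction = bag_fraction
        self.initial_trees = initial_trees
        self.step_trees = step_trees
        self.max_trees = max_trees
        self.cv_folds = cv_folds
        self.min_obs_node = min_obs_node
        self.seed = seed
        self.bag_with_replacement = bag_with_replacement
        self.class_weight = class_weight

    # -- helpers -------------------------------------------------------
    def _config(self) -> FitConfig:
        cfg = FitConfig(
            tree_complexity=self.tree_complexity,
            learning_rate=self.learning_rate,
            bag_fraction=self.bag_fraction,
            initial_trees=self.initial_trees,
            step_trees=self.step_trees,
            max_trees=self.max_trees,
            cv_folds=self.cv_folds,
            min_obs_node=self.min_obs_node,
            seed=self.seed,
            bag_with_replacement=self.bag_with_replacement,
        )
        cfg.validate()
        return cfg

    @staticmethod
    def _as_matrix(X, feature_names=None):
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(X.columns)
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(X.shape[1])]
        return X, list(feature_names)

    def _boost_sequence(self, X, y, w, n_trees, rng, X_val=None, y_val=None,
                        w_val=None):
        """Run the stagewise loop; returns (trees, train trace, val trace)."""
        cfg = self._config()
        n = len(y)
        intercept = float(logit(np.clip(np.sum(w * y) / np.sum(w),
                                        _EPS, 1 - _EPS)))
        link = np.full(n, intercept)
        link_val = (np.full(len(y_val), intercept)
                    if X_val is not None else None)
        n_bag = max(2, int(np.ceil(cfg.bag_fraction * n)))
        trees: list[RegressionTree] = []
        train_trace = np.empty(n_trees)
        val_trace = np.empty(n_trees) if X_val is not None else None
        for m in range(n_trees):
            p = expit(link)
            r = y - p
            h = p * (1 - p)
            bag = rng.choice(n, size=min(n_bag, n),
                             replace=cfg.bag_with_replacement)
            if not cfg.bag_with_replacement:
                bag = np.sort(bag)
            tree = fit_tree(X, r, w, h, cfg.tree_complexity,
                            cfg.min_obs_node, bag)
            link = link + cfg.learning_rate * tree.predict(X)
            trees.append(tree)
            train_trace[m] = bernoulli_deviance(y, expit(link), w)
            if X_val is not None:
                link_val = link_val + cfg.learning_rate * tree.predict(X_val)
                val_trace[m] = bernoulli_deviance(y_val, expit(link_val),
                                                  w_val)
        return intercept, trees, train_trace, val_trace

    # -- sklearn API -----------------------------------------------------
    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        X, names = self._as_matrix(X, feature_names)
        y = np.asarray(y).astype(float)
        if X.ndim != 2 or len(X) != len(y):
            raise FitError("X must be 2-D and aligned with y")
        if np.isnan(X).any():
            raise FitError("predictors must be complete at fit time")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise FitError("y must be binary 0/1")
        if (y == 1).sum() < 2 or (y == 0).sum() < 2:
            raise FitError("need at least two sites of each class")
        cfg = self._config()
        self.classes_ = np.array([0, 1])
        self.feature_names_ = names

        w = (balance_weights(y) if self.class_weight == "balanced"
             else np.ones(len(y)))
        rng = np.random.default_rng(cfg.seed)

        self.converged_ = True
        if cfg.cv_folds >= 2:
            fold = np.repeat(np.arange(cfg.cv_folds),
                             int(np.ceil(len(y) / cfg.cv_folds)))[: len(y)]
            rng.shuffle(fold)
            traces = []
            for k in range(cfg.cv_folds):
                tr, va = fold != k, fold == k
                if y[tr].sum() < 2 or (1 - y[tr]).sum() < 2 or va.sum() == 0:
                    continue
                sub_rng = np.random.default_rng(rng.integers(2**31))
                _, _, _, val_trace = self._boost_sequence(
                    X[tr], y[tr], w[tr], cfg.max_trees, sub_rng,
                    X_val=X[va], y_val=y[va], w_val=w[va])
                traces.append(val_trace)
            if not traces:
                raise FitError("cross-validation folds degenerate")
            self.cv_deviance_ = np.mean(traces, axis=0)
            lo = min(cfg.initial_trees, cfg.max_trees) - 1
            n_best = lo + int(np.argmin(self.cv_deviance_[lo:])) + 1
            if n_best >= cfg.max_trees:
                self.converged_ = False  # still improving at the cap
            self.n_trees_ = n_best
        else:
            self.cv_deviance_ = None
            self.n_trees_ = cfg.max_trees

        final_rng = np.random.default_rng(rng.integers(2**31))
        intercept, trees, train_trace, _ = self._boost_sequence(
            X, y, w, self.n_trees_, final_rng)
        self.intercept_ = intercept
        self.trees_ = trees
        self.train_deviance_ = train_trace
        self.case_weights_ = w
        self._train_X = X
        self.relative_influence_ = self._relative_influence()
        return self

    def decision_function(self, X) -> np.ndarray:
        X = self._matrix_for_predict(X)
        link = np.full(len(X), self.intercept_)
        for tree in self.trees_:
            link += self.learning_rate * tree.predict(X)
        return link

    def _matrix_for_predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [n for n in self.feature_names_ if n not in X.columns]
            if missing:
                raise FitError(f"unknown predictors at predict: {missing}")
            X = X[self.feature_names_]
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names_):
            raise FitError("feature count mismatch")
        return X

    def predict_proba(self, X) -> np.ndarray:
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    # -- interpretation --------------------------------------------------
    def _relative_influence(self) -> pd.Series:
        gains = np.zeros(len(self.feature_names_))
        for tree in self.trees_:
            for feat, _thr, gain in tree.splits():
                gains[feat] += gain
        total = gains.sum()
        if total <= 0:
            pct = np.full_like(gains, 100.0 / len(gains))
        else:
            pct = 100.0 * gains / total
        return pd.Series(pct, index=self.feature_names_).sort_values(
            ascending=False)

    def partial_dependence(
        self,
        feature: str,
        grid: np.ndarray | None = None,
        X: np.ndarray | pd.DataFrame | None = None,
        output: str = "probability",
    ) -> pd.DataFrame:
        """Marginal response to one predictor.

        For each grid value the predictor is clamped for every row of the
        reference data (the training matrix by default), the link averaged,
        and the inverse link applied (``output="link"`` skips the inverse).
        """
        if feature not in self.feature_names_:
            raise FitError(f"unknown predictor {feature!r}")
        j = self.feature_names_.index(feature)
        ref = self._train_X if X is None else self._matrix_for_predict(X)
        if grid is None:
            vals = ref[:, j]
            grid = np.linspace(vals.min(), vals.max(), 50)
        grid = np.asarray(grid, dtype=float)
        if grid.size == 0:
            raise FitError("empty partial-dependence grid")
        responses = np.empty(len(grid))
        work = ref.copy()
        for i, v in enumerate(grid):
            work[:, j] = v
            link = np.full(len(work), self.intercept_)
            for tree in self.trees_:
                link += self.learning_rate * tree.predict(work)
            responses[i] = link.mean()
        if output == "probability":
            responses = expit(responses)
        elif output != "link":
            raise FitError("output must be 'probability' or 'link'")
        return pd.DataFrame({feature: grid, "response": responses})

    def to_dict(self) -> dict:
        """JSON-serializable model description."""
        return {
            "intercept": self.intercept_,
            "learning_rate": self.learning_rate,
            "feature_names": self.feature_names_,
            "n_trees": self.n_trees_,
            "trees": [t.to_dict(self.feature_names_) for t in self.trees_],
            "config": asdict(self._config()),
        }


# ---------------------------------------------------------------------------
# functional wrappers


def fit_boosted(
    sites: pd.DataFrame,
    species: str,
    predictors: Sequence[str],
    config: FitConfig | None = None,
) -> BoostedTreesClassifier:
    """Fit a boosted model for one species column of a site table."""
    config = config or FitConfig()
    est = BoostedTreesClassifier(**asdict(config))
    return est.fit(sites[list(predictors)], sites[species].to_numpy())


def predict(model: BoostedTreesClassifier, X) -> np.ndarray:
    """Occurrence probabilities for feature rows."""
    return model.predict_proba(X)[:, 1]


def relative_influence(model: BoostedTreesClassifier) -> pd.Series:
    return model.relative_influence_


def partial_dependence(model, feature, grid=None, X=None, output="probability"):
    return model.partial_dependence(feature, grid=grid, X=X, output=output)
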