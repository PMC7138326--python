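import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from reefniche.brt_engine import (
    BoostedTreesClassifier,
    FitError,
    balance_weights,
    bernoulli_deviance,
    fit_tree,
)
from reefniche.evaluation import auc, make_partition
from reefniche.synthetic_reefscape import two_driver_site_table


# --- case weights -----------------------------------------------------------

def test_balance_weights_equalizes_class_sums():
    y = np.array([1] * 100 + [0] * 900)
    w = balance_weights(y)
    assert w[y == 1][0] == pytest.approx(9.0)
    assert w[y == 0][0] == pytest.approx(1.0)
    assert w[y == 1].sum() == pytest.approx(w[y == 0].sum())


def test_balanced_weights_for_even_classes_are_uniform():
    y = np.array([0, 1] * 25)
    assert np.all(balance_weights(y) == 1.0)


def test_low_prevalence_survey_weights_balance():
    """A 7.78 % prevalence species at 985 sites still balances exactly."""
    n_pres = round(0.0778 * 985)
    y = np.array([1] * n_pres + [0] * (985 - n_pres))
    w = balance_weights(y)
    assert w[y == 1].sum() == pytest.approx(w[y == 0].sum())


def test_single_class_labels_rejected():
    with pytest.raises(FitError):
        balance_weights(np.ones(10))


# --- single tree ------------------------------------------------------------

def _exhaustive_stump(X, r, w):
    """Independent brute-force search over every (feature, midpoint)."""
    best = (None, None, -np.inf)
    S, W = np.sum(w * r), np.sum(w)
    base = S * S / W
    for j in range(X.shape[1]):
        for thr in np.unique(X[:, j]):
            left = X[:, j] < thr
            if left.sum() == 0 or (~left).sum() == 0:
                continue
            sl, wl = np.sum(w[left] * r[left]), np.sum(w[left])
            sr, wr = S - sl, W - wl
            gain = sl**2 / wl + sr**2 / wr - base
            if gain > best[2] + 1e-12:
                # candidate thresholds are midpoints in the implementation;
                # recover the midpoint below this unique value
                lower = X[:, j][X[:, j] < thr].max()
                best = (j, 0.5 * (lower + thr), gain)
    return best


def test_stump_equals_exhaustive_split_oracle():
    rng = np.random.default_rng(17)
    for trial in range(5):
        X = rng.normal(size=(40, 3))
        r = rng.normal(size=40)
        w = rng.uniform(0.5, 2.0, size=40)
        h = np.full(40, 0.25)
        tree = fit_tree(X, r, w, h, tree_complexity=1, min_obs_node=1,
                        bag=np.arange(40))
        feat, thr, gain = tree.splits()[0]
        ofeat, othr, ogain = _exhaustive_stump(X, r, w)
        assert feat == ofeat
        assert thr == pytest.approx(othr)
        assert gain == pytest.approx(ogain)


def test_stump_split_agrees_with_sklearn_regression_tree():
    from sklearn.tree import DecisionTreeRegressor

    rng = np.random.default_rng(3)
    X = rng.normal(size=(60, 4))
    r = rng.normal(size=60)
    w = rng.uniform(0.5, 2.0, size=60)
    tree = fit_tree(X, r, w, np.full(60, 0.25), 1, 1, np.arange(60))
    feat, thr, _ = tree.splits()[0]
    sk = DecisionTreeRegressor(max_depth=1).fit(X, r, sample_weight=w)
    assert feat == sk.tree_.feature[0]
    assert thr == pytest.approx(sk.tree_.threshold[0], abs=1e-8)


def test_perfect_binary_split_is_found():
    X = np.array([[0.0], [0.0], [1.0], [1.0]])
    r = np.array([-1.0, -1.0, 1.0, 1.0])
    tree = fit_tree(X, r, np.ones(4), np.full(4, 0.25), 1, 1, np.arange(4))
    feat, thr, _ = tree.splits()[0]
    assert feat == 0
    assert thr == pytest.approx(0.5)


def test_constant_response_yields_single_terminal():
    X = np.random.default_rng(0).normal(size=(20, 2))
    r = np.zeros(20)
    tree = fit_tree(X, r, np.ones(20), np.full(20, 0.25), 3, 1,
                    np.arange(20))
    assert tree.n_splits == 0
    assert tree.value[0] == 0.0


# --- boosted ensemble -------------------------------------------------------

@pytest.fixture(scope="module")
def two_driver():
    return two_driver_site_table(n_sites=600, seed=9)


def test_vanishing_learning_rate_reduces_to_intercept(two_driver):
    sites, _ = two_driver
    X = sites.drop(columns="species")
    est = BoostedTreesClassifier(learning_rate=1e-9, max_trees=5, cv_folds=0, initial_trees=1,
                                 tree_complexity=2, seed=0)
    est.fit(X, sites["species"])
    p = est.predict_proba(X)[:, 1]
    # balanced weighting re-centers the weighted prevalence at 1/2
    np.testing.assert_allclose(p, 0.5, atol=1e-6)


def test_training_deviance_nonincreasing_without_bagging(two_driver):
    sites, _ = two_driver
    est = BoostedTreesClassifier(learning_rate=0.05, bag_fraction=1.0,
                                 max_trees=80, cv_folds=0,
                                 tree_complexity=2, seed=1)
    est.fit(sites.drop(columns="species"), sites["species"])
    assert np.all(np.diff(est.train_deviance_) <= 1e-12)


def test_balanced_intercept_is_zero(two_driver):
    sites, _ = two_driver
    est = BoostedTreesClassifier(learning_rate=0.1, max_trees=10, cv_folds=0,
                                 initial_trees=1, seed=0)
    est.fit(sites.drop(columns="species"), sites["species"])
    assert abs(est.intercept_) < 0.01


def test_prediction_equals_manual_tree_traversal(two_driver):
    sites, _ = two_driver
    X = sites.drop(columns="species")
    est = BoostedTreesClassifier(learning_rate=0.1, max_trees=3, cv_folds=0, initial_trees=1,
                                 tree_complexity=2, seed=4)
    est.fit(X, sites["species"])

    def walk(tree, row):
        node = 0
        while tree.feature[node] >= 0:
            j = tree.feature[node]
            node = (tree.left[node] if row[j] < tree.threshold[node]
                    else tree.right[node])
        return tree.value[node]

    Xm = X.to_numpy()
    for i in (0, 7, 123):
        link = est.intercept_ + sum(
            est.learning_rate * walk(t, Xm[i]) for t in est.trees_)
        assert est.decision_function(Xm[[i]])[0] == pytest.approx(link)
        assert est.predict_proba(Xm[[i]])[0, 1] == pytest.approx(expit(link))


def test_adding_positive_increment_tree_raises_probabilities(two_driver):
    sites, _ = two_driver
    X = sites.drop(columns="species")
    est = BoostedTreesClassifier(learning_rate=0.1, max_trees=2, cv_folds=0,
                                 initial_trees=1, seed=0).fit(X, sites["species"])
    before = est.predict_proba(X)[:, 1]
    bump = type(est.trees_[0])()   # single-leaf tree, uniform +0.5
    bump.value[0] = 0.5
    est.trees_.append(bump)
    after = est.predict_proba(X)[:, 1]
    assert np.all(after > before)


def test_relative_influence_sums_to_100_and_ignores_column_order(two_driver):
    sites, _ = two_driver
    cols = [c for c in sites.columns if c != "species"]
    est = BoostedTreesClassifier(learning_rate=0.1, max_trees=40, cv_folds=0,
                                 tree_complexity=2, seed=2)
    est.fit(sites[cols], sites["species"])
    assert est.relative_influence_.sum() == pytest.approx(100.0, abs=0.01)
    est_rev = BoostedTreesClassifier(learning_rate=0.1, max_trees=40,
                                     cv_folds=0, tree_complexity=2, seed=2)
    est_rev.fit(sites[cols[::-1]], sites["species"])
    pd.testing.assert_series_equal(
        est.relative_influence_.sort_index(),
        est_rev.relative_influence_.sort_index(),
        rtol=1e-9,
    )


def test_single_usable_predictor_takes_all_influence():
    rng = np.random.default_rng(5)
    n = 300
    x = rng.normal(size=n)
    X = pd.DataFrame({"signal": x, "flat": np.zeros(n)})
    y = (rng.random(n) < expit(2.5 * x)).astype(int)
    est = BoostedTreesClassifier(learning_rate=0.1, max_trees=30, cv_folds=0,
                                 tree_complexity=1, seed=0).fit(X, y)
    assert est.relative_influence_["signal"] == pytest.approx(100.0)
    assert est.relative_influence_["flat"] == pytest.approx(0.0)


def test_partial_dependence_of_stump_is_two_level_step(two_driver):
    sites, _ = two_driver
    X = sites.drop(columns="species")
    est = BoostedTreesClassifier(learning_rate=0.1, max_trees=1, cv_folds=0, initial_trees=1,
                                 tree_complexity=1, bag_fraction=1.0,
                                 seed=0).fit(X, sites["species"])
    feat_idx, split, _ = est.trees_[0].splits()[0]
    feat = est.feature_names_[feat_idx]
    grid = np.array([split - 1.0, split - 1e-6, split + 1e-6, split + 1.0])
    curve = est.partial_dependence(feat, grid=grid, output="link")
    r = curve["response"].to_numpy()
    assert r[0] == pytest.approx(r[1])
    assert r[2] == pytest.approx(r[3])
    assert abs(r[2] - r[1]) > 0


def test_partial_dependence_recovers_unimodal_optimum(two_driver):
    sites, drivers = two_driver
    X = sites.drop(columns="species")
    est = BoostedTreesClassifier(learning_rate=0.05, max_trees=250,
                                 cv_folds=0, tree_complexity=3, seed=3)
    est.fit(X, sites["species"])
    grid = np.linspace(-2.0, 3.0, 26)   # steps of 0.2 around the 0.5 optimum
    curve = est.partial_dependence("pred_1", grid=grid)
    peak = curve.loc[curve["response"].idxmax(), "pred_1"]
    assert abs(peak - 0.5) <= 0.4


def test_two_driver_recovery_single_seed(two_driver):
    sites, drivers = two_driver
    X = sites.drop(columns="species")
    y = sites["species"].to_numpy()
    plan = make_partition(len(y), seed=31)
    tr, te = plan.train_mask(1), plan.test_mask(1)
    est = BoostedTreesClassifier(learning_rate=0.05, max_trees=250,
                                 cv_folds=0, tree_complexity=3, seed=7)
    est.fit(X[tr], y[tr])
    assert auc(y[te], est.predict_proba(X[te])[:, 1]) > 0.85
    assert set(est.relative_influence_.index[:2]) == set(drivers)


def test_cv_selection_picks_interior_tree_count(two_driver):
    sites, _ = two_driver
    est = BoostedTreesClassifier(learning_rate=0.2, max_trees=120,
                                 initial_trees=10, cv_folds=3,
                                 tree_complexity=2, seed=5)
    est.fit(sites.drop(columns="species"), sites["species"])
    assert 10 <= est.n_trees_ <= 120
    assert len(est.trees_) == est.n_trees_
    assert len(est.cv_deviance_) == 120


def test_fit_input_validation(two_driver):
    sites, _ = two_driver
    X = sites.drop(columns="species")
    est = BoostedTreesClassifier(max_trees=5, cv_folds=0, initial_trees=1)
    with pytest.raises(FitError):
        est.fit(X, np.ones(len(X)))          # single class
    bad = X.copy()
    bad.iloc[0, 0] = np.nan
    with pytest.raises(FitError):
        est.fit(bad, sites["species"])       # incomplete predictors
    est.fit(X, sites["species"])
    with pytest.raises(FitError):
        est.predict_proba(X.rename(columns={"pred_0": "mystery"}))


def test_deviance_of_perfect_predictions_is_zero():
    y = np.array([0, 1, 1, 0])
    assert bernoulli_deviance(y, y.astype(float)) == pytest.approx(0.0,
                                                                   abs=1e-9)
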