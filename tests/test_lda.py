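"""LDA fitting, metrics, permutation importance, and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from locostate.dataset import group_kfold
from locostate.errors import ConfigurationError, InsufficientDataError
from locostate.lda import (LocomotorLDA, cross_validated_lda,
                           evaluate_classifier, merge_classes,
                           metrics_from_predictions, permutation_importance)


def _two_gaussians(rng, n=500, sep=4.0, d=2):
    Xa = rng.standard_normal((n, d))
    Xb = rng.standard_normal((n, d))
    Xb[:, 0] += sep
    X = np.vstack([Xa, Xb])
    y = np.array(["a"] * n + ["b"] * n, dtype=object)
    return X, y


def test_merge_classes():
    labels = np.array(["gait", "akinesia", "stationary"], dtype=object)
    merged = merge_classes(labels, {"gait": "gait", "akinesia": "non-gait",
                                    "stationary": "non-gait"})
    assert list(merged) == ["gait", "non-gait", "non-gait"]
    same = merge_classes(labels, {l: l for l in labels})
    assert list(same) == list(labels)
    with pytest.raises(ConfigurationError):
        merge_classes(labels, {"gait": "gait"})


def test_separable_gaussians_accuracy_and_boundary():
    rng = np.random.default_rng(0)
    X, y = _two_gaussians(rng)
    Xt, yt = _two_gaussians(np.random.default_rng(1))
    res = LocomotorLDA(X, y).fit()
    acc = (res.predict(Xt) == yt).mean()
    assert acc >= 0.97
    # boundary normal within 5 degrees of the x-axis (the Bayes direction)
    w = res.estimator.coef_[0] if res.estimator.coef_.ndim > 1 else res.estimator.coef_
    angle = np.degrees(np.arccos(abs(w[0]) / np.linalg.norm(w)))
    assert angle <= 5.0


def test_direction_converges_to_mean_difference():
    rng = np.random.default_rng(2)
    X, y = _two_gaussians(rng, n=5000, d=3)
    res = LocomotorLDA(X, y).fit()
    w = res.directions[:, 0]
    target = np.array([1.0, 0, 0])
    cos = abs(w @ target) / np.linalg.norm(w)
    assert np.degrees(np.arccos(min(cos, 1.0))) <= 2.0


def test_rank_bound_three_classes():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((300, 10))
    y = np.array((["a", "b", "c"] * 100), dtype=object)
    res = LocomotorLDA(X, y).fit()
    assert res.directions.shape[1] <= 2


def test_duplicated_feature_column_handled_by_shrinkage():
    rng = np.random.default_rng(4)
    X, y = _two_gaussians(rng, n=100)
    X = np.hstack([X, X[:, :1]])  # exact duplicate -> singular covariance
    res = LocomotorLDA(X, y).fit()
    assert res.shrinkage_used is not None
    assert (res.predict(X) == y).mean() > 0.9


def test_too_few_classes_or_samples():
    with pytest.raises(InsufficientDataError):
        LocomotorLDA(np.zeros((10, 2)), np.array(["a"] * 10, dtype=object))
    with pytest.raises(InsufficientDataError):
        LocomotorLDA(np.zeros((3, 2)), np.array(["a", "a", "b"], dtype=object))


def test_metric_arithmetic():
    # TP=6, FP=2, FN=4, TN=8 for positive class "p"
    y_true = np.array(["p"] * 10 + ["n"] * 10, dtype=object)
    y_pred = np.array(["p"] * 6 + ["n"] * 4 + ["p"] * 2 + ["n"] * 8, dtype=object)
    m = metrics_from_predictions(y_true, y_pred, "p", ["n", "p"])
    assert m["precision"] == pytest.approx(0.75)
    assert m["recall"] == pytest.approx(0.6)
    assert m["f1"] == pytest.approx(2 * 0.75 * 0.6 / (0.75 + 0.6))
    np.testing.assert_allclose(m["confusion"].sum(axis=1), 1.0)
    # perfect predictions
    perfect = metrics_from_predictions(y_true, y_true, "p", ["n", "p"])
    assert perfect["f1"] == 1.0
    np.testing.assert_array_equal(perfect["confusion"], np.eye(2))
    # constant majority predictor is at chance balanced accuracy
    const = metrics_from_predictions(y_true, np.full(20, "n", dtype=object),
                                     "p", ["n", "p"])
    assert const["balanced_accuracy"] == pytest.approx(0.5)


def test_evaluate_positive_class_absent():
    rng = np.random.default_rng(5)
    X, y = _two_gaussians(rng, n=50)
    res = LocomotorLDA(X, y).fit()
    out = evaluate_classifier(res, X[:50], np.full(50, "a", dtype=object), "b")
    assert out["defined"] is False


def _informative_dataset(rng, n=400, n_noise=4):
    y = np.array(["a", "b"] * (n // 2), dtype=object)
    X = rng.standard_normal((n, n_noise + 1))
    X[:, 0] += np.where(y == "a", -1.5, 1.5)
    names = ["signal"] + [f"noise{j}" for j in range(n_noise)]
    return X, y, names


def test_importance_recovers_informative_feature():
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X, y, names = _informative_dataset(rng)
        Xt, yt, _ = _informative_dataset(np.random.default_rng(seed + 100))
        res = LocomotorLDA(X, y, names).fit()
        imp = permutation_importance(res, Xt, yt, n_repeats=10, seed=seed)
        hits += imp.idxmax() == "signal"
        assert np.abs(imp[[n for n in names if n != "signal"]]).max() < 0.02
    assert hits >= 9


def test_importance_deterministic():
    rng = np.random.default_rng(6)
    X, y, names = _informative_dataset(rng)
    res = LocomotorLDA(X, y, names).fit()
    i1 = permutation_importance(res, X, y, n_repeats=5, seed=42)
    i2 = permutation_importance(res, X, y, n_repeats=5, seed=42)
    pd.testing.assert_series_equal(i1, i2)


def test_permuting_all_columns_gives_chance():
    rng = np.random.default_rng(7)
    X, y, names = _informative_dataset(rng, n=2000)
    res = LocomotorLDA(X, y, names).fit()
    Xp = X.copy()
    for j in range(X.shape[1]):
        Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
    m = metrics_from_predictions(y, res.predict(Xp), "a", ["a", "b"])
    assert abs(m["balanced_accuracy"] - 0.5) <= 0.05


def _grid_oracle_rule(X, y, n_dirs=2000):
    """Exhaustive unit-direction grid + optimal threshold, both polarities.

    Returns ``(w, threshold, polarity)`` maximizing training balanced
    accuracy: predict positive when ``polarity * (X @ w) > threshold``.
    """
    rng = np.random.default_rng(123)
    d = X.shape[1]
    if d == 1:
        dirs = np.array([[1.0]])
    elif d == 2:
        ang = np.linspace(0, np.pi, n_dirs, endpoint=False)
        dirs = np.column_stack([np.cos(ang), np.sin(ang)])
    else:
        dirs = rng.standard_normal((n_dirs, d))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pos = y == y[0]
    n_pos, n_neg = pos.sum(), (~pos).sum()
    best = (0.0, dirs[0], 0.0, 1)
    for w in dirs:
        proj = X @ w
        order = np.argsort(proj)
        sp = pos[order]
        thresholds = (proj[order][:-1] + proj[order][1:]) / 2
        tp = n_pos - np.cumsum(sp)[:-1]  # positives above each threshold
        tn = np.cumsum(~sp)[:-1]
        bacc = 0.5 * (tp / n_pos + tn / n_neg)
        for b, thr, polarity in ((bacc, thresholds, 1),
                                 (1 - bacc, thresholds, -1)):
            k = int(np.argmax(b))
            if b[k] > best[0]:
                best = (float(b[k]), w, float(thr[k]), polarity)
    return best[1], best[2], best[3]


@pytest.mark.parametrize("seed,d,sep", [(0, 2, 2.0), (1, 3, 1.5), (2, 2, 3.0),
                                        (3, 3, 2.5)])
def test_lda_matches_grid_search_oracle(seed, d, sep):
    # both rules are selected on a small training instance and compared on
    # held-out data: LDA is not worse than the exhaustive projection search
    rng = np.random.default_rng(seed)
    n = 30
    def draw(r, m):
        X = np.vstack([r.standard_normal((m, d)),
                       r.standard_normal((m, d)) + sep / np.sqrt(d)])
        return X, np.array(["a"] * m + ["b"] * m, dtype=object)
    X, y = draw(rng, n)
    Xt, yt = draw(np.random.default_rng(seed + 500), 2000)
    res = LocomotorLDA(X, y).fit()
    m_lda = metrics_from_predictions(yt, res.predict(Xt), "a", ["a", "b"])
    w, thr, polarity = _grid_oracle_rule(X, y)
    proj = polarity * (Xt @ w)
    pred = np.where(proj > polarity * thr, y[0], y[-1])
    m_grid = metrics_from_predictions(yt, pred, "a", ["a", "b"])
    assert m_lda["balanced_accuracy"] >= m_grid["balanced_accuracy"] - 0.02


def test_cross_validated_lda_with_merge():
    rng = np.random.default_rng(8)
    n = 600
    y3 = np.array(["gait", "stationary", "akinesia"] * (n // 3), dtype=object)
    X = rng.standard_normal((n, 3))
    X[:, 0] += np.where(y3 == "gait", 3.0, 0.0)
    X[:, 1] += np.where(y3 == "akinesia", 3.0, 0.0)
    runs = np.repeat([f"r{i}" for i in range(6)], n // 6)
    plan = group_kfold(list(dict.fromkeys(runs)), 3, seed=0)
    metrics, confusion, imp = cross_validated_lda(
        X, y3, runs, plan, "gait", feature_names=["a", "b", "c"],
        n_repeats=3, eval_merge={"gait": "gait", "stationary": "non-gait",
                                 "akinesia": "non-gait"})
    assert confusion.labels == ["gait", "non-gait"]
    assert metrics["f1"].mean() > 0.9
    for m in confusion.matrices:
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-9)
    assert imp.rank("a") == 1 or imp.rank("b") == 1
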