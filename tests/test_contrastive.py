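"""Contrastive encoder: training behavior, embedding contracts, KNN decoding."""

import numpy as np
import pytest

from locostate.contrastive import (ContrastiveEmbedding, EmbeddingConfig,
                                   conv_plan, embedding_importance,
                                   knn_evaluate, shuffle_labels,
                                   single_feature_embedding, temperature_scan)
from locostate.errors import ConfigurationError, ShapeError


def _receptive_consumption(plan):
    """Input length consumed by a stack of valid convs ending at length 1."""
    L = 1
    for k, s in reversed(plan):
        L = (L - 1) * s + k
    return L


@pytest.mark.parametrize("rf", [1, 8, 20, 25, 40, 50, 100, 200, 256])
def test_conv_plan_consumes_receptive_field(rf):
    plan = conv_plan(rf)
    assert _receptive_consumption(plan) == rf
    assert all(k >= 1 and s >= 1 for k, s in plan)


def test_default_plan_has_six_layers():
    assert len(conv_plan(200)) == 6


def _toy_dataset(rng, n_per=600, n_noise=2, sep=2.5):
    """Three alternating state blocks with one informative feature."""
    states = ["a", "b", "c"]
    labels, cols = [], []
    for rep in range(6):
        for s in states:
            labels += [s] * (n_per // 6)
    labels = np.array(labels[: n_per * 3 // 3], dtype=object)
    n = len(labels)
    X = rng.standard_normal((n, 1 + n_noise))
    shift = {"a": -sep, "b": 0.0, "c": sep}
    X[:, 0] += np.array([shift[l] for l in labels])
    return X.astype(np.float32), labels


def _small_cfg(seed=0, iters=250):
    return EmbeddingConfig(receptive_field=20, batch_size=64,
                           max_iterations=iters, time_offset=40, seed=seed,
                           hidden_width=16)


def test_training_loss_decreases_and_unit_norm():
    rng = np.random.default_rng(0)
    X, y = _toy_dataset(rng)
    res = ContrastiveEmbedding(X, y, config=_small_cfg()).fit()
    assert res.final_loss < res.initial_loss
    coords, pos = res.embed(X)
    assert np.abs(np.linalg.norm(coords, axis=1) - 1).max() < 1e-5
    assert coords.shape[1] == 3
    assert "InfoNCE" in res.summary()


def test_embedding_deterministic_and_shape_checks():
    rng = np.random.default_rng(1)
    X, y = _toy_dataset(rng)
    res = ContrastiveEmbedding(X, y, config=_small_cfg()).fit()
    c1, p1 = res.embed(X)
    c2, p2 = res.embed(X)
    np.testing.assert_array_equal(c1, c2)
    np.testing.assert_array_equal(p1, p2)
    with pytest.raises(ShapeError):
        res.embed(X[:5])  # shorter than the receptive field
    with pytest.raises(ShapeError):
        res.embed(X[:, :2])  # wrong feature count


def test_feature_order_remap():
    rng = np.random.default_rng(2)
    X, y = _toy_dataset(rng)
    names = ["sig", "n0", "n1"]
    res = ContrastiveEmbedding(X, y, config=_small_cfg(),
                               feature_names=names).fit()
    c1, _ = res.embed(X)
    perm = [2, 0, 1]
    c2, _ = res.embed(X[:, perm], feature_names=[names[j] for j in perm])
    np.testing.assert_allclose(c1, c2, atol=1e-6)


def test_fit_requires_enough_labeled_windows():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((100, 3)).astype(np.float32)
    y = np.array(["a"] * 50 + ["b"] * 50, dtype=object)
    with pytest.raises(ConfigurationError):
        ContrastiveEmbedding(X, y, config=EmbeddingConfig(
            receptive_field=20, batch_size=512))


def test_windows_do_not_cross_runs():
    rng = np.random.default_rng(4)
    X, y = _toy_dataset(rng)
    runs = np.array(["r1"] * (len(X) // 2) + ["r2"] * (len(X) - len(X) // 2),
                    dtype=object)
    res = ContrastiveEmbedding(X, y, runs, config=_small_cfg()).fit()
    _c, pos = res.embed(X, runs)
    boundary = len(X) // 2
    # no embedded position whose window would straddle the run boundary
    assert not np.any((pos >= boundary) & (pos < boundary + 19))


def test_knn_basic_contracts():
    train = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
    labels = np.array(["a", "a", "b"], dtype=object)
    out = knn_evaluate(train, labels, train[:1], np.array(["a"], dtype=object),
                       k=1)
    assert out["predictions"][0] == "a"  # identical point -> its own label
    out3 = knn_evaluate(train, labels, np.array([[1, 0.01, 0]]),
                        np.array(["a"], dtype=object), k=3)
    assert out3["predictions"][0] == "a"  # 2-vs-1 majority
    with pytest.raises(ConfigurationError):
        knn_evaluate(np.empty((0, 3)), np.array([], dtype=object), train,
                     labels)
    with pytest.raises(ConfigurationError):
        knn_evaluate(train, labels, train, labels, k=10)


def test_knn_tie_broken_by_nearest():
    train = np.array([[1, 0], [0.9, 0.1], [0, 1], [0.1, 0.9]])
    labels = np.array(["a", "a", "b", "b"], dtype=object)
    query = np.array([[0.8, 0.2]])  # nearest is "a"; 4-NN vote ties 2-2
    out = knn_evaluate(train, labels, query, np.array(["a"], dtype=object), k=4)
    assert out["predictions"][0] == "a"


def test_knn_metrics_invariant_under_rotation():
    rng = np.random.default_rng(5)
    X, y = _toy_dataset(rng)
    res = ContrastiveEmbedding(X, y, config=_small_cfg()).fit()
    coords, pos = res.embed(X, hop=3)
    labels = y[pos]
    half = len(coords) // 2
    base = knn_evaluate(coords[:half], labels[:half], coords[half:], labels[half:])
    Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    rot = coords @ Q
    rotated = knn_evaluate(rot[:half], labels[:half], rot[half:], labels[half:])
    assert rotated["f1_macro"] == pytest.approx(base["f1_macro"], abs=1e-9)
    assert rotated["balanced_accuracy"] == pytest.approx(
        base["balanced_accuracy"], abs=1e-9)


def test_three_state_separation_and_shuffled_collapse():
    rng = np.random.default_rng(6)
    X, y = _toy_dataset(rng, sep=3.0)
    half = len(X) // 2
    cfg = _small_cfg(iters=400)
    res = ContrastiveEmbedding(X[:half], y[:half], config=cfg).fit()
    ctr, ptr = res.embed(X[:half], hop=2)
    cte, pte = res.embed(X[half:], hop=2)
    ev = knn_evaluate(ctr, y[:half][ptr], cte, y[half:][pte])
    assert ev["f1_macro"] >= 0.85
    # shuffled labels: decoding collapses to chance
    ysh = shuffle_labels(y[:half], seed=0)
    res_sh = ContrastiveEmbedding(X[:half], ysh, config=cfg).fit()
    c1, p1 = res_sh.embed(X[:half], hop=2)
    c2, p2 = res_sh.embed(X[half:], hop=2)
    ev_sh = knn_evaluate(c1, ysh[p1], c2, y[half:][p2])
    assert abs(ev_sh["balanced_accuracy"] - 1 / 3) <= 0.10


def _biomarker_panel(rng, n=3000, strong=3.0, weak=1.0):
    """Three-state data with a strong, a weak, and a constant feature."""
    labels = []
    while len(labels) < n:
        for s in ("a", "b", "c"):
            labels += [s] * 100
    y = np.array(labels[:n], dtype=object)
    shift = {"a": -1.0, "b": 0.0, "c": 1.0}
    base = np.array([shift[l] for l in y], dtype=np.float32)
    X = rng.standard_normal((n, 3)).astype(np.float32)
    X[:, 0] += strong * base
    X[:, 1] += weak * base
    X[:, 2] = 0.0  # constant column
    runs = np.repeat([f"r{i}" for i in range(6)], n // 6).astype(object)
    return X, y, runs, ["strong", "weak", "constant"]


def test_single_feature_embedding_orders_biomarkers():
    # a feature designed to be more state-informative wins the head-to-head
    # comparison in most seeds
    cfg = EmbeddingConfig(receptive_field=20, batch_size=64,
                          max_iterations=200, time_offset=40,
                          hidden_width=16)
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X, y, runs, names = _biomarker_panel(rng)
        _r1, m_strong = single_feature_embedding(
            X, y, runs, "strong", names, cfg.with_(seed=seed))
        _r2, m_weak = single_feature_embedding(
            X, y, runs, "weak", names, cfg.with_(seed=seed))
        wins += m_strong["f1_macro"].mean() >= m_weak["f1_macro"].mean()
    assert wins >= 8


def test_single_feature_embedding_constant_and_full_panel():
    rng = np.random.default_rng(3)
    X, y, runs, names = _biomarker_panel(rng)
    cfg = EmbeddingConfig(receptive_field=20, batch_size=64,
                          max_iterations=200, time_offset=40,
                          hidden_width=16, seed=3)
    _r, m_const = single_feature_embedding(X, y, runs, "constant", names, cfg)
    assert abs(m_const["balanced_accuracy"].mean() - 1 / 3) <= 0.15
    # the full panel does at least as well as the best single feature
    _r, m_strong = single_feature_embedding(X, y, runs, "strong", names, cfg)
    res = ContrastiveEmbedding(X[runs < "r3"], y[runs < "r3"],
                               runs[runs < "r3"], cfg,
                               feature_names=names).fit()
    ctr, ptr = res.embed(X[runs < "r3"], runs[runs < "r3"], hop=5)
    te = runs >= "r3"
    cte, pte = res.embed(X[te], runs[te], hop=5)
    full = knn_evaluate(ctr, y[runs < "r3"][ptr], cte, y[te][pte])
    assert full["f1_macro"] >= m_strong["f1_macro"].mean() - 0.05
    with pytest.raises(ConfigurationError):
        single_feature_embedding(X, y, runs, "missing", names, cfg)


def test_temperature_scan_utility():
    rng = np.random.default_rng(4)
    X, y, runs, _names = _biomarker_panel(rng, n=1800)
    cfg = EmbeddingConfig(receptive_field=10, batch_size=64,
                          max_iterations=60, time_offset=20, hidden_width=8)
    out = temperature_scan(X, y, runs, temperatures=(0.1, 1.0), config=cfg)
    assert list(out["temperature"]) == [0.1, 1.0]
    assert np.isfinite(out["final_loss"]).all()


def test_importance_singles_out_informative_feature():
    rng = np.random.default_rng(7)
    X, y = _toy_dataset(rng, n_per=1500, sep=3.0)
    half = len(X) // 2
    names = ["sig", "n0", "n1"]
    res = ContrastiveEmbedding(X[:half], y[:half], config=_small_cfg(iters=400),
                               feature_names=names).fit()
    ctr, ptr = res.embed(X[:half], hop=2)
    imp = embedding_importance(res, ctr, y[:half][ptr], X[half:], y[half:],
                               hop=1, seed=0)
    assert imp.idxmax() == "sig"
    assert np.abs(imp[["n0", "n1"]]).max() <= 0.03
    imp2 = embedding_importance(res, ctr, y[:half][ptr], X[half:], y[half:],
                                hop=1, seed=0)
    np.testing.assert_array_equal(imp.to_numpy(), imp2.to_numpy())
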