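"""Peri-onset curves, rankings, state statistics, FoG episode analyses."""

import numpy as np
import pandas as pd
import pytest

from locostate.analysis import (PermutationTestResult, bin_episodes,
                                bonferroni, episode_means,
                                episode_permutation_test, joint_ranking,
                                onset_modulation, pca_project,
                                peri_onset_curves,
                                select_channel_by_band_modulation,
                                state_feature_tests, top_correlated_features)
from locostate.core import FeatureMatrix, ImportanceTable
from locostate.errors import (ConfigurationError, InsufficientDataError,
                              ValidationError)

from conftest import make_events


def _fm(values, rate=200.0, labels=None, run="r1"):
    values = np.atleast_2d(values.T).T if values.ndim == 1 else values
    n = len(values)
    names = [f"f{j}" for j in range(values.shape[1])]
    return FeatureMatrix(values, names, np.arange(n) / rate, rate, labels,
                         run, "s1", "d1")


class TestPeriOnset:
    def test_unit_step_recovered_exactly(self):
        n = 2000
        step = np.zeros((n, 1))
        step[800:, 0] = 1.0  # onset at t = 4.0 s
        ev = make_events([("gait", 0, 4.0), ("akinesia", 4.0, 10.0)], 10.0)
        curves = peri_onset_curves([(_fm(step), ev)], "akinesia", (-2, 2))
        m, sd = curves.feature("f0")
        assert curves.n_events == 1
        np.testing.assert_array_equal(sd, 0.0)
        assert m[curves.time < 0].max() == 0.0
        assert m[curves.time >= 0].min() == 1.0
        assert onset_modulation(curves, "f0") == pytest.approx(1.0)

    def test_edge_onsets_excluded(self):
        n = 1000  # 5 s
        ev = make_events([("gait", 0, 4.5), ("akinesia", 4.5, 5.0)], 5.0)
        curves = peri_onset_curves([(_fm(np.zeros((n, 1))), ev)], "akinesia",
                                   (-2, 2))
        assert curves.empty and curves.n_excluded == 1

    def test_mean_of_identical_traces(self):
        n = 3000
        x = np.sin(np.arange(n) / 40.0)[:, None]
        ev = make_events([("gait", 0, 5), ("akinesia", 5, 10),
                          ("gait", 10, 15)], 15.0)
        curves = peri_onset_curves([(_fm(x), ev)], "akinesia", (-1, 1))
        assert curves.n_events == 1


class TestJointRanking:
    def _table(self, order):
        return ImportanceTable({f: [v] for f, v in order})

    def test_top_in_both_is_rank_one(self):
        lin = self._table([("a", 0.9), ("b", 0.5), ("c", 0.1)])
        emb = self._table([("a", 0.8), ("c", 0.4), ("b", 0.2)])
        jr = joint_ranking(lin, emb)
        assert jr.iloc[0]["feature"] == "a"
        assert jr.iloc[0]["combined_rank"] == 1

    def test_vocabulary_mismatch(self):
        lin = self._table([("a", 1.0)])
        emb = self._table([("b", 1.0)])
        with pytest.raises(ConfigurationError):
            joint_ranking(lin, emb)

    def test_mean_method(self):
        lin = self._table([("a", 0.9), ("b", 0.5)])
        emb = self._table([("b", 0.9), ("a", 0.5)])
        jr = joint_ranking(lin, emb, method="mean")
        assert set(jr["combined"]) == {1.5}


class TestStateFeatureTests:
    def _means(self, rng, shift=0.0, n_subj=6):
        rows = []
        for s in range(n_subj):
            base = rng.normal(0, 1, size=4)
            for state in ("gait", "stationary", "akinesia"):
                vals = base + rng.normal(0, 0.3, size=4)
                if state == "akinesia":
                    vals = vals + shift
                rows.append({"subject": f"s{s}", "state": state,
                             **{f"f{j}": vals[j] for j in range(4)}})
        return pd.DataFrame(rows)

    def test_twelve_tests_and_null(self):
        rng = np.random.default_rng(0)
        df = self._means(rng)
        # identical states per subject -> all adjusted p == 1
        for state in ("stationary", "akinesia"):
            for j in range(4):
                df.loc[df.state == state, f"f{j}"] = \
                    df.loc[df.state == "gait", f"f{j}"].to_numpy()
        out = state_feature_tests(df, [f"f{j}" for j in range(4)])
        assert len(out) == 12
        assert (out["p_holm"] > 0.999).all()

    def test_injected_shift_detected(self):
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            out = state_feature_tests(self._means(rng, shift=1.0),
                                      [f"f{j}" for j in range(4)])
            ak_gait = out[(out.state_a == "akinesia") & (out.state_b == "gait")
                          | (out.state_a == "gait") & (out.state_b == "akinesia")]
            hits += bool(ak_gait["significant"].any())
        assert hits / n_rep >= 0.8


class TestBinning:
    def test_floor_rule_and_majority_label(self):
        n = int(10.5 * 100)
        labels = np.array(["gait"] * n, dtype=object)
        # one bin spanning 0.6 s fog / 0.4 s gait
        labels[300:360] = "fog"
        fm = _fm(np.ones((n, 1)), rate=100.0, labels=labels)
        binned, skipped = bin_episodes(fm, 1.0)
        assert len(binned) == 10
        assert binned.iloc[3]["label"] == "fog"
        assert (binned["f0"] == 1.0).all()
        assert skipped == []

    def test_short_run_skipped(self):
        fm = _fm(np.ones((30, 1)), rate=100.0,
                 labels=np.array(["gait"] * 30, dtype=object))
        binned, skipped = bin_episodes(fm, 1.0)
        assert skipped == ["r1"] and len(binned) == 0


class TestPCA:
    def test_eigenratio_matches_closed_form(self):
        rng = np.random.default_rng(1)
        n = 20000
        z = rng.standard_normal((n, 2))
        rho = 0.8
        X = np.column_stack([z[:, 0], rho * z[:, 0] + np.sqrt(1 - rho ** 2) * z[:, 1]])
        df = pd.DataFrame(X, columns=["a", "b"])
        _s, _l, evr = pca_project(df, ["a", "b"])
        expected = np.array([1 + rho, 1 - rho]) / 2
        assert evr[0] == pytest.approx(expected[0], rel=0.01)
        assert evr.sum() == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_feature_splits_loadings(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(5000)
        noise = rng.standard_normal(5000)
        df = pd.DataFrame({"a": x, "b": x + 1e-9 * noise, "c": noise})
        _s, loadings, _e = pca_project(df, ["a", "b", "c"])
        assert loadings[0, 0] == pytest.approx(loadings[1, 0], rel=1e-3)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        _s1, l1, _ = pca_project(df, list("abc"))
        _s2, l2, _ = pca_project(df, list("abc"))
        np.testing.assert_array_equal(l1, l2)
        for c in range(l1.shape[1]):
            assert l1[np.argmax(np.abs(l1[:, c])), c] > 0


class TestCorrelatedFeatures:
    def test_indicator_feature_ranks_first(self):
        rng = np.random.default_rng(4)
        n = 1000
        lab = np.where(rng.random(n) < 0.5, "gait", "fog")
        df = pd.DataFrame({"ind": (lab == "gait").astype(float),
                           "noise": rng.standard_normal(n),
                           "label": lab})
        out = top_correlated_features(df, ["ind", "noise"], n=2)
        assert out.iloc[0]["feature"] == "ind"
        assert out.iloc[0]["r"] == pytest.approx(1.0)
        assert abs(out.set_index("feature").loc["noise", "r"]) < 0.1

    def test_single_class_errors_and_overlong_n_warns(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "label": ["gait", "gait"]})
        with pytest.raises(InsufficientDataError):
            top_correlated_features(df, ["x"])
        df2 = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0],
                            "label": ["gait", "fog", "gait", "fog"]})
        with pytest.warns(UserWarning):
            out = top_correlated_features(df2, ["x"], n=10)
        assert len(out) == 1


class TestChannelSelection:
    def _episodes(self, mods):
        rows = []
        rng = np.random.default_rng(0)
        for lab in ("gait", "fog"):
            for _ in range(6):
                row = {"label": lab}
                for ch, mod in mods.items():
                    base = rng.normal(0, 0.01)
                    row[f"beta {ch}"] = base + (mod if lab == "fog" else 0.0)
                rows.append(row)
        return pd.DataFrame(rows)

    def test_modulated_channel_selected(self):
        eps = self._episodes({"c1": 0.0, "c2": 2.0, "c3": 0.1})
        ch, info = select_channel_by_band_modulation(
            eps, {c: f"beta {c}" for c in ("c1", "c2", "c3")})
        assert ch == "c2" and not info["tie"]

    def test_tie_goes_to_first_and_single_channel(self):
        eps = self._episodes({"c1": 0.0, "c2": 0.0})
        eps["beta c2"] = eps["beta c1"]
        ch, info = select_channel_by_band_modulation(
            eps, {"c1": "beta c1", "c2": "beta c2"})
        assert ch == "c1" and info["tie"]
        ch2, _ = select_channel_by_band_modulation(eps, {"c1": "beta c1"})
        assert ch2 == "c1"


class TestPermutationTest:
    def _episodes(self, rng, effect=0.0, sessions=2, per=12):
        rows = []
        for s in range(sessions):
            for k in range(per):
                lab = "fog" if k % 2 else "gait"
                rows.append({"label": lab, "session": f"sess{s}",
                             "x": rng.normal(effect if lab == "fog" else 0.0, 1)})
        return pd.DataFrame(rows)

    def test_minimum_achievable_p(self):
        rng = np.random.default_rng(5)
        eps = self._episodes(rng, effect=50.0)
        r = episode_permutation_test(eps, "x", n_perm=999, seed=0)
        assert r.p_value == pytest.approx(1 / 1000)

    def test_constraint_blocks_session_confound(self):
        # feature depends on session only; label prevalence differs by
        # session, so an unconstrained test is fooled but the
        # session-constrained test is not
        rng = np.random.default_rng(6)
        rows = []
        for s, (n_gait, n_fog) in enumerate([(9, 3), (3, 9)]):
            for lab, n in (("gait", n_gait), ("fog", n_fog)):
                for _ in range(n):
                    rows.append({"label": lab, "session": f"sess{s}",
                                 "x": 5.0 * s + rng.normal(0, 0.1)})
        eps = pd.DataFrame(rows)
        constrained = episode_permutation_test(eps, "x", n_perm=2000, seed=1)
        unconstrained = episode_permutation_test(
            eps.assign(session="all"), "x", n_perm=2000, seed=1)
        assert unconstrained.p_value < 0.05
        assert constrained.p_value > 0.2

    def test_degenerate_strata(self):
        eps = pd.DataFrame({"label": ["gait", "gait", "fog", "fog"],
                            "session": ["a", "a", "b", "b"],
                            "x": [0.0, 1.0, 2.0, 3.0]})
        with pytest.raises(ValidationError):
            episode_permutation_test(eps, "x", n_perm=10, seed=0)

    def test_type_one_error_calibrated(self):
        # seeded null replicates: empirical rejection rate near alpha
        hits = 0
        n_rep = 400
        for seed in range(n_rep):
            rng = np.random.default_rng(10_000 + seed)
            eps = self._episodes(rng, effect=0.0)
            r = episode_permutation_test(eps, "x", n_perm=199, seed=seed)
            hits += r.p_value <= 0.05
        assert 0.03 <= hits / n_rep <= 0.07


def test_bonferroni_factor():
    np.testing.assert_allclose(bonferroni([0.01, 0.4], factor=4), [0.04, 1.0])


def test_episode_means_from_events():
    n = 600
    vals = np.zeros((n, 1))
    vals[200:400, 0] = 2.0
    fm = _fm(vals, rate=100.0)
    ev = make_events([("gait", 0, 2.0), ("fog", 2.0, 4.0)], 6.0,
                     vocabulary=("gait", "fog"))
    df = episode_means(fm, ev, ["f0"], run_id="r1")
    assert len(df) == 2
    assert df.set_index("label").loc["fog", "f0"] == pytest.approx(2.0)
    assert df.set_index("label").loc["gait", "f0"] == pytest.approx(0.0)
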