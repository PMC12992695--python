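"""Self-validation routines: closed-form checks and designed-effect recovery.

These functions recompute, from scratch, the quantities that the synthetic
cohorts are constructed to exhibit — spectral contrasts, classifier
separability, biomarker importance rankings, onset directionality,
statistical calibration — so that the whole toolchain can be exercised
end-to-end without external data. They are used by the acceptance test
suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import (episode_permutation_test, joint_ranking,
                       onset_modulation, peri_onset_curves,
                       per_subject_state_means)
from .contrastive import (ContrastiveEmbedding, EmbeddingConfig,
                          embedding_importance, knn_evaluate, shuffle_labels)
from .core import ImportanceTable
from .dataset import (assemble_dataset, group_kfold, state_time_fractions)
from .lda import LocomotorLDA, cross_validated_lda, permutation_importance
from .neural import hjorth_parameters, sinusoid_mobility
from .pipeline import _split_by_run, biomarker_features, build_run_matrices
from .synthetic import CohortSpec, generate_cohort


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------

def hjorth_sine_errors(f: float = 10.0, fs: float = 200.0,
                       seconds: float = 10.0) -> dict:
    """|error| of Hjorth complexity (vs 1) and mobility (vs closed form)."""
    t = np.arange(int(fs * seconds)) / fs
    h = hjorth_parameters(np.sin(2 * np.pi * f * t))
    return {"complexity_error": abs(h.complexity - 1.0),
            "mobility_error": abs(h.mobility - sinusoid_mobility(f, fs))}


# ---------------------------------------------------------------------------
# LDA checks
# ---------------------------------------------------------------------------

def two_gaussian_lda(seed: int = 0, n: int = 500, sep: float = 4.0) -> dict:
    """Held-out accuracy and boundary angle on the separable two-Gaussian task."""
    def draw(rng):
        X = np.vstack([rng.standard_normal((n, 2)),
                       rng.standard_normal((n, 2)) + [sep, 0.0]])
        return X, np.array(["a"] * n + ["b"] * n, dtype=object)
    X, y = draw(np.random.default_rng(seed))
    Xt, yt = draw(np.random.default_rng(seed + 1000))
    res = LocomotorLDA(X, y).fit()
    acc = float((res.predict(Xt) == yt).mean())
    w = np.ravel(res.estimator.coef_)[:2]
    angle = float(np.degrees(np.arccos(abs(w[0]) / np.linalg.norm(w))))
    return {"accuracy": acc, "boundary_angle_deg": angle}


def _informative_dataset(rng, n=400, n_noise=4):
    y = np.array(["a", "b"] * (n // 2), dtype=object)
    X = rng.standard_normal((n, n_noise + 1))
    X[:, 0] += np.where(y == "a", -1.5, 1.5)
    return X, y, ["signal"] + [f"noise{j}" for j in range(n_noise)]


def lda_importance_recovery(n_seeds: int = 10, seed0: int = 0) -> dict:
    """How often the sole informative feature ranks first; null magnitude."""
    hits, null_max = 0, 0.0
    for seed in range(seed0, seed0 + n_seeds):
        rng = np.random.default_rng(seed)
        X, y, names = _informative_dataset(rng)
        Xt, yt, _ = _informative_dataset(np.random.default_rng(seed + 100))
        res = LocomotorLDA(X, y, names).fit()
        imp = permutation_importance(res, Xt, yt, n_repeats=10, seed=seed)
        hits += imp.idxmax() == "signal"
        null_max = max(null_max, float(np.abs(imp[names[1:]]).max()))
    return {"rank1_rate": hits / n_seeds, "null_max_abs": null_max}


def embedding_importance_recovery(n_seeds: int = 10, seed0: int = 0) -> dict:
    """Embedding-importance analogue of :func:`lda_importance_recovery`."""
    cfg = EmbeddingConfig(receptive_field=20, batch_size=64,
                          max_iterations=400, time_offset=40, hidden_width=16)
    hits, null_max = 0, 0.0
    for seed in range(seed0, seed0 + n_seeds):
        rng = np.random.default_rng(seed)
        n = 3000
        blocks = []
        for rep in range(10):
            for s in ("a", "b", "c"):
                blocks += [s] * (n // 30)
        y = np.array(blocks, dtype=object)
        X = rng.standard_normal((len(y), 3)).astype(np.float32)
        shift = {"a": -3.0, "b": 0.0, "c": 3.0}
        X[:, 0] += np.array([shift[l] for l in y], dtype=np.float32)
        half = len(X) // 2
        names = ["signal", "noise0", "noise1"]
        res = ContrastiveEmbedding(X[:half], y[:half],
                                   config=cfg.with_(seed=seed),
                                   feature_names=names).fit()
        ctr, ptr = res.embed(X[:half], hop=2)
        imp = embedding_importance(res, ctr, y[:half][ptr], X[half:],
                                   y[half:], hop=1, seed=seed)
        hits += imp.idxmax() == "signal"
        null_max = max(null_max, float(np.abs(imp[["noise0", "noise1"]]).max()))
    return {"rank1_rate": hits / n_seeds, "null_max_abs": null_max}


# ---------------------------------------------------------------------------
# Embedding behavior on the three-state testbed
# ---------------------------------------------------------------------------

def _testbed_dataset(seed: int):
    spec = CohortSpec.embedding_testbed(seed=seed)
    records, _ = generate_cohort(spec)
    mats, kin, neu, _ev = build_run_matrices(records)
    return assemble_dataset(mats, blocks={"kinematic": kin, "neural": neu})


def embedding_separability(seed: int = 7, profile: str = "desk",
                           n_test_runs: int = 3) -> dict:
    """Desk-profile training on the three-state testbed + held-out KNN."""
    ds = _testbed_dataset(seed)
    runs = ds.unique_runs()
    tr = ds.run_mask(runs[:-n_test_runs])
    te = ds.run_mask(runs[-n_test_runs:])
    cfg = EmbeddingConfig.profile(profile, seed=seed)
    res = ContrastiveEmbedding(ds.X[tr], ds.labels[tr], ds.runs[tr], cfg,
                               feature_names=ds.names).fit()
    ctr, ptr = res.embed(ds.X[tr], ds.runs[tr], hop=10)
    cte, pte = res.embed(ds.X[te], ds.runs[te], hop=5)
    coords_norm = float(np.abs(np.linalg.norm(cte, axis=1) - 1).max())
    ev = knn_evaluate(ctr, ds.labels[tr][ptr], cte, ds.labels[te][pte])
    ak = ev["classes"].index("akinesia")
    return {"macro_f1": ev["f1_macro"],
            "balanced_accuracy": ev["balanced_accuracy"],
            "akinesia_tpr": float(ev["confusion"][ak, ak]),
            "loss_ratio": res.final_loss / res.initial_loss,
            "max_norm_deviation": coords_norm,
            "_dataset": ds, "_split": (tr, te), "_test_positions": pte}


def shuffled_label_control(seeds=(0, 1, 2, 3, 4), max_iterations: int = 500,
                           dataset=None, split=None, test_positions=None) -> dict:
    """Balanced accuracy of decoders trained on label-shuffled data."""
    ds = dataset if dataset is not None else _testbed_dataset(7)
    if split is None:
        runs = ds.unique_runs()
        tr = ds.run_mask(runs[:-3])
        te = ds.run_mask(runs[-3:])
    else:
        tr, te = split
    baccs = []
    for seed in seeds:
        ysh = shuffle_labels(ds.labels[tr], seed=seed)
        cfg = EmbeddingConfig.profile("desk", seed=seed,
                                      max_iterations=max_iterations)
        res = ContrastiveEmbedding(ds.X[tr], ysh, ds.runs[tr], cfg,
                                   feature_names=ds.names).fit()
        ctr, ptr = res.embed(ds.X[tr], ds.runs[tr], hop=10)
        cte, pte = res.embed(ds.X[te], ds.runs[te], hop=5)
        ev = knn_evaluate(ctr, ysh[ptr], cte, ds.labels[te][pte])
        baccs.append(ev["balanced_accuracy"])
    return {"mean_balanced_accuracy": float(np.mean(baccs)),
            "per_seed": baccs, "chance": 1.0 / 3.0}


# ---------------------------------------------------------------------------
# Statistical calibration
# ---------------------------------------------------------------------------

def permutation_type_one_error(n_replicates: int = 1000, n_perm: int = 199,
                               alpha: float = 0.05, seed: int = 0) -> dict:
    """Empirical rejection rate of the constrained test under the null."""
    hits = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed * 1_000_003 + rep)
        rows = []
        for s in range(2):
            for k in range(12):
                rows.append({"label": "fog" if k % 2 else "gait",
                             "session": f"sess{s}",
                             "x": rng.standard_normal()})
        eps = pd.DataFrame(rows)
        r = episode_permutation_test(eps, "x", n_perm=n_perm, seed=rep)
        hits += r.p_value <= alpha
    return {"type_one_error": hits / n_replicates, "alpha": alpha}


# ---------------------------------------------------------------------------
# Designed-effect recovery on synthetic cohorts
# ---------------------------------------------------------------------------

def occupancy_contrast(seed: int = 0) -> dict:
    """Cohort-mean akinesia occupancy per group (events only, fast)."""
    spec = CohortSpec(seed=seed)
    records, _ = generate_cohort(spec, signals=False)
    acc = {"sham": [], "lesioned": []}
    for r in records:
        acc[r.group].append(state_time_fractions(r.events)["akinesia"])
    return {g: float(np.mean(v)) for g, v in acc.items()}


def fold_structure(seed: int = 0) -> dict:
    """The 55-run lesioned cohort split into 11 grouped folds."""
    spec = CohortSpec(seed=seed)
    records, _ = generate_cohort(spec, signals=False)
    runs = [r.run_id for r in records if r.group == "lesioned"]
    plan = group_kfold(runs, 11, seed=seed)
    train_sizes = {len(tr) for tr, _te in plan.folds}
    test_sizes = {len(te) for _tr, te in plan.folds}
    return {"n_runs": len(runs), "k": plan.k,
            "train_sizes": sorted(train_sizes), "test_sizes": sorted(test_sizes)}


def onset_and_group_effects(seed: int = 0, n_subjects: int = 6,
                            runs_per_subject: int = 8,
                            run_duration: float = 15.0) -> dict:
    """Peri-onset deltas and group-level state means of the four biomarkers."""
    spec = CohortSpec.recovery_testbed(seed=seed, n_subjects=n_subjects,
                                       runs_per_subject=runs_per_subject,
                                       run_duration=run_duration)
    records, _ = generate_cohort(spec)
    mats, kin, neu, evmap = build_run_matrices(records)
    ds = assemble_dataset(mats, blocks={"kinematic": kin, "neural": neu})
    per_run = [(fm.select(ds.blocks["neural"]), evmap[fm.run_ids[0]])
               for fm in _split_by_run(ds)]
    curves = peri_onset_curves(per_run, "akinesia", (-3.0, 2.0))
    marks = biomarker_features(ds.blocks["neural"])
    deltas = {role: float(onset_modulation(curves, feat))
              for role, feat in marks.items()}
    sm = per_subject_state_means(ds, list(marks.values()))
    g = sm.groupby("state")[list(marks.values())].mean()
    return {"n_onsets": curves.n_events,
            "deltas": deltas,
            "complexity_akinesia_minus_gait": float(
                g.loc["akinesia", marks["complexity_left"]]
                - g.loc["gait", marks["complexity_left"]]),
            "gamma_akinesia_minus_gait": float(
                g.loc["akinesia", marks["gamma_right"]]
                - g.loc["gait", marks["gamma_right"]]),
            "mobility_akinesia_minus_gait": float(
                g.loc["akinesia", marks["mobility_right"]]
                - g.loc["gait", marks["mobility_right"]]),
            "hblg_akinesia_minus_gait": float(
                g.loc["akinesia", marks["hblg_left"]]
                - g.loc["gait", marks["hblg_left"]])}


def joint_ranking_recovery_trial(seed: int, n_folds: int = 3) -> dict:
    """One seeded trial: do the injected biomarkers reach the joint top 5?

    Runs the desk-scale neural branch on the recovery testbed: 3-class LDA
    importance plus embedding importance over grouped folds, combined into
    the joint ranking.
    """
    spec = CohortSpec.recovery_testbed(seed=seed)
    records, _ = generate_cohort(spec)
    mats, kin, neu, _ev = build_run_matrices(records)
    ds = assemble_dataset(mats, blocks={"kinematic": kin, "neural": neu})
    plan = group_kfold(ds.unique_runs(), n_folds, seed=seed)
    Xn = ds.block_values("neural")
    names = ds.blocks["neural"]
    _m, _c, imp_lin = cross_validated_lda(Xn, ds.labels, ds.runs, plan,
                                          "akinesia", feature_names=names,
                                          n_repeats=5, seed=seed)
    cfg = EmbeddingConfig(receptive_field=50, batch_size=64,
                          max_iterations=600, time_offset=50)
    fold_imp = []
    for fi, (trr, ter) in enumerate(plan.folds):
        tr = ds.run_mask(trr)
        te = ds.run_mask(ter)
        res = ContrastiveEmbedding(Xn[tr], ds.labels[tr], ds.runs[tr],
                                   cfg.with_(seed=seed + fi),
                                   feature_names=names).fit()
        ctr, ptr = res.embed(Xn[tr], ds.runs[tr], hop=20)
        fold_imp.append(embedding_importance(
            res, ctr, ds.labels[tr][ptr], Xn[te], ds.labels[te],
            ds.runs[te], hop=10, seed=seed + fi))
    imp_emb = ImportanceTable.from_fold_series(fold_imp)
    ranked = joint_ranking(imp_lin, imp_emb)
    top5 = set(ranked.head(5)["feature"])
    marks = biomarker_features(names)
    return {"hblg_in_top5": marks["hblg_left"] in top5,
            "complexity_in_top5": any("Hjorth complexity" in f for f in top5),
            "top5": sorted(top5)}


def joint_ranking_recovery(n_seeds: int = 10, seed0: int = 0) -> dict:
    hblg = comp = 0
    for seed in range(seed0, seed0 + n_seeds):
        out = joint_ranking_recovery_trial(seed)
        hblg += out["hblg_in_top5"]
        comp += out["complexity_in_top5"]
    return {"hblg_top5_rate": hblg / n_seeds,
            "complexity_top5_rate": comp / n_seeds}
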