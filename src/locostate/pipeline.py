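"""End-to-end workflows: rodent deep phenotyping and human FoG analysis.

Each pipeline is a sequence of stages over a config; any stage failure
marks the results bundle partial and records the failing stage instead of
aborting the whole batch. Every tunable is surfaced on the config and all
randomness flows from the single seed, so a results bundle is reproducible
from (config, seed) alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (bin_episodes, bonferroni, episode_means,
                       episode_permutation_test, joint_ranking,
                       onset_modulation, pca_project, peri_onset_curves,
                       per_subject_state_means, select_channel_by_band_modulation,
                       state_feature_tests, top_correlated_features)
from .contrastive import (ContrastiveEmbedding, EmbeddingConfig,
                          embedding_importance, knn_evaluate)
from .core import UNLABELED, ConfusionSummary, FeatureMatrix, ImportanceTable
from .dataset import (align_events_to_samples, assemble_dataset,
                      compare_group_fractions, group_kfold,
                      state_time_fractions)
from .errors import ConfigurationError
from .io import load_session, read_manifest
from .kinematics import SkeletonConfig, compute_kinematic_features, rodent_skeleton
from .lda import AKINESIA_MERGE, GAIT_MERGE, cross_validated_lda
from .neural import (extract_neural_features, human_bands, resample_recording,
                     rodent_bands)
from .synthetic import CohortSpec, HumanCohortSpec, generate_cohort, generate_human_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of the rodent workflow."""

    seed: int = 0
    profile: str = "desk"
    synthetic: bool = True
    manifest_path: str | None = None
    cohort: CohortSpec | None = None
    outdir: str | None = None
    folds: int = 11
    feature_rate: float = 200.0
    est_window: float = 1.0
    outlier_z: float = 4.0
    importance_repeats: int = 5
    # embedding branch (desk-scale defaults)
    embedding_overrides: dict = field(default_factory=dict)
    embedding_folds: int = 3  # folds actually trained in the embedding branch
    embed_hop: int = 20
    knn_k: int = 3
    peri_window: tuple = (-3.0, 2.0)
    stages: tuple = ("load", "features", "occupancy", "assemble", "lda",
                     "embedding", "ranking", "peri_onset", "state_tests")

    def __post_init__(self):
        if self.profile not in ("desk", "paper"):
            raise ConfigurationError(f"unknown profile {self.profile!r}")
        if not self.synthetic and self.manifest_path is None:
            raise ConfigurationError(
                "either synthetic=True or a manifest_path is required")

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "cohort" in doc and doc["cohort"] is not None:
            doc["cohort"] = CohortSpec(**doc["cohort"])
        return PipelineConfig(**doc)


@dataclass
class ResultsBundle:
    """Outputs of one pipeline execution; ``partial`` if a stage failed."""

    config: object
    stage_log: list = field(default_factory=list)
    partial: bool = False
    failed_stage: str | None = None
    tables: dict = field(default_factory=dict)
    objects: dict = field(default_factory=dict)

    def log_stage(self, name: str, seconds: float, status: str = "ok"):
        self.stage_log.append({"stage": name, "seconds": round(seconds, 3),
                               "status": status})

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            if isinstance(df, pd.DataFrame):
                df.to_csv(outdir / f"{name}.csv", index=False)
        log = {"version": __version__, "partial": self.partial,
               "failed_stage": self.failed_stage, "stages": self.stage_log,
               "config": _config_doc(self.config)}
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=1, default=str)


def _config_doc(cfg) -> dict:
    doc = dataclasses.asdict(cfg)
    return doc


def biomarker_features(names: list[str]) -> dict[str, str]:
    """The four consistently high-scoring neural features by convention:
    Hjorth complexity and HB-LG amplitude on the lesioned (left) hemisphere,
    Hjorth mobility and gamma amplitude on the healthy (right) hemisphere."""
    def first(pred):
        for n in names:
            if pred(n):
                return n
        raise ConfigurationError("expected biomarker feature not present")
    return {
        "complexity_left": first(lambda n: "Hjorth complexity" in n and "(L)" in n),
        "hblg_left": first(lambda n: "HB-LG amplitude" in n and "(L)" in n),
        "mobility_right": first(lambda n: "Hjorth mobility" in n and "(R)" in n),
        "gamma_right": first(lambda n: "gamma amplitude" in n and "(R)" in n),
    }


def _stage(bundle: ResultsBundle, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.time() - self.t0
            if exc is None:
                bundle.log_stage(name, dt)
                logger.info("stage %s done in %.1fs", name, dt)
                return False
            bundle.log_stage(name, dt, status=f"failed: {exc}")
            bundle.partial = True
            bundle.failed_stage = name
            logger.error("stage %s failed: %s", name, exc)
            return True  # swallow; bundle marked partial
    return _Ctx()


def build_run_matrices(sessions, skeleton: SkeletonConfig | None = None,
                       bands=None, feature_rate: float = 200.0,
                       est_window: float = 1.0, analysis_fs: float = 1000.0):
    """Per-run combined (kinematic | neural) labeled feature matrices.

    ``sessions`` yields objects with trajectories / recording / events /
    run_id / subject_id / day_id attributes (synthetic records or loaded
    sessions). Returns (matrices, kinematic names, neural names, events map).
    """
    skeleton = skeleton or rodent_skeleton()
    bands = bands or rodent_bands()
    mats, events_by_run = [], {}
    kin_names = neu_names = None
    for s in sessions:
        rec = s.recording
        if rec.fs > analysis_fs:
            rec = resample_recording(rec, analysis_fs)
        kin = compute_kinematic_features(s.trajectories, skeleton)
        neu = extract_neural_features(rec, bands, feature_rate, est_window,
                                      run_id=s.run_id, subject_id=s.subject_id,
                                      day_id=s.day_id)
        n = min(kin.n_samples, neu.n_samples)
        kin = FeatureMatrix(kin.values[:n], kin.names, kin.times[:n], kin.rate,
                            run_ids=s.run_id, subject_ids=s.subject_id,
                            day_ids=s.day_id)
        neu = FeatureMatrix(neu.values[:n], neu.names, neu.times[:n], neu.rate,
                            run_ids=s.run_id, subject_ids=s.subject_id,
                            day_ids=s.day_id)
        fm = kin.hstack(neu)
        fm.labels = align_events_to_samples(s.events, fm.times)
        mats.append(fm)
        events_by_run[s.run_id] = s.events
        kin_names, neu_names = kin.names, neu.names
    return mats, kin_names, neu_names, events_by_run


def _embedding_branch(dataset, block: str, plan, cfg: PipelineConfig,
                      positive_class: str, labels=None):
    """Cross-validated embedding: train per fold, KNN metrics + importance."""
    emb_cfg = EmbeddingConfig.profile(cfg.profile, seed=cfg.seed,
                                      **cfg.embedding_overrides)
    X = dataset.block_values(block)
    names = dataset.blocks[block]
    y = dataset.labels if labels is None else labels
    rows, matrices, fold_imp = [], [], []
    folds = plan.folds[:cfg.embedding_folds]
    for fold_id, (train_runs, test_runs) in enumerate(folds):
        tr = dataset.run_mask(train_runs)
        te = dataset.run_mask(test_runs)
        model = ContrastiveEmbedding(X[tr], y[tr], dataset.runs[tr],
                                     emb_cfg.with_(seed=cfg.seed + fold_id),
                                     feature_names=names)
        res = model.fit()
        ctr, ptr = res.embed(X[tr], dataset.runs[tr], hop=cfg.embed_hop)
        keep_tr = y[tr][ptr] != UNLABELED
        cte, pte = res.embed(X[te], dataset.runs[te], hop=max(1, cfg.embed_hop // 2))
        keep_te = y[te][pte] != UNLABELED
        ev = knn_evaluate(ctr[keep_tr], y[tr][ptr][keep_tr],
                          cte[keep_te], y[te][pte][keep_te],
                          k=cfg.knn_k, positive_class=positive_class)
        rows.append({"fold": fold_id, "f1_macro": ev["f1_macro"],
                     "f1": ev.get("f1"), "precision": ev.get("precision"),
                     "recall": ev.get("recall"),
                     "balanced_accuracy": ev["balanced_accuracy"],
                     "initial_loss": res.initial_loss,
                     "final_loss": res.final_loss})
        if not np.isnan(ev["confusion"]).any():
            matrices.append(ev["confusion"])
        fold_imp.append(embedding_importance(
            res, ctr[keep_tr], y[tr][ptr][keep_tr], X[te], y[te],
            dataset.runs[te], hop=cfg.embed_hop, seed=cfg.seed + fold_id,
            k=cfg.knn_k))
        classes = ev["classes"]
    metrics = pd.DataFrame(rows)
    confusion = ConfusionSummary(classes, matrices) if matrices else None
    importance = ImportanceTable.from_fold_series(fold_imp)
    return metrics, confusion, importance


def run_rodent_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Full rodent workflow on synthetic or manifest-listed sessions."""
    bundle = ResultsBundle(config)
    sessions = groups = None
    with _stage(bundle, "load"):
        if config.synthetic:
            spec = config.cohort or CohortSpec(seed=config.seed)
            records, _ = generate_cohort(spec)
            sessions = records
            groups = {r.subject_id: r.group for r in records}
        else:
            sessions = []
            groups = {}
            for manifest in read_manifest(config.manifest_path):
                result = load_session(manifest)
                if not result.ok:
                    logger.warning("skipping %s: %s", manifest.run_id,
                                   result.discard_reason)
                    continue
                result.run_id = manifest.run_id

                class _S:  # adapter with the attribute surface build_run_matrices needs
                    pass
                s = _S()
                s.trajectories, s.recording, s.events = (
                    result.trajectories, result.recording, result.events)
                s.run_id, s.subject_id, s.day_id = (
                    manifest.run_id, manifest.subject_id, manifest.day_id)
                sessions.append(s)
                groups[manifest.subject_id] = manifest.group or "lesioned"
    if sessions is None:
        return bundle

    with _stage(bundle, "occupancy"):
        rows = []
        for s in sessions:
            fr = state_time_fractions(s.events)
            fr.update({"subject": s.subject_id, "run": s.run_id,
                       "group": groups.get(s.subject_id, "")})
            rows.append(fr)
        occupancy = pd.DataFrame(rows)
        bundle.tables["occupancy"] = occupancy
        subject_means = occupancy.groupby(["subject", "group"], as_index=False)[
            ["gait", "stationary", "akinesia"]].mean()
        subject_means = subject_means.rename(columns={"group": "group"})
        if subject_means["group"].nunique() == 2:
            bundle.tables["occupancy_tests"] = compare_group_fractions(
                subject_means.drop(columns="subject"))

    # classification uses the lesioned cohort (the group expressing akinesia)
    lesioned = [s for s in sessions if groups.get(s.subject_id) == "lesioned"] \
        or list(sessions)

    mats = events_by_run = None
    with _stage(bundle, "features"):
        mats, kin_names, neu_names, events_by_run = build_run_matrices(
            lesioned, feature_rate=config.feature_rate,
            est_window=config.est_window)
    if mats is None:
        return bundle

    dataset = plan = None
    with _stage(bundle, "assemble"):
        dataset = assemble_dataset(mats, blocks={"kinematic": kin_names,
                                                 "neural": neu_names},
                                   outlier_z=config.outlier_z)
        plan = group_kfold(dataset.unique_runs(), config.folds, seed=config.seed)
        bundle.objects["dataset"] = dataset
        bundle.objects["plan"] = plan
    if dataset is None:
        return bundle

    labeled = dataset.labeled_mask()
    with _stage(bundle, "lda"):
        y3 = dataset.labels[labeled]
        m, c, imp = cross_validated_lda(
            dataset.block_values("kinematic")[labeled], y3,
            dataset.runs[labeled], plan, "gait",
            feature_names=dataset.blocks["kinematic"],
            n_repeats=config.importance_repeats, seed=config.seed,
            eval_merge=GAIT_MERGE)
        bundle.tables["lda_kinematic_metrics"] = m
        bundle.objects["lda_kinematic_confusion"] = c
        bundle.objects["lda_kinematic_importance"] = imp
        m, c, imp = cross_validated_lda(
            dataset.block_values("neural")[labeled], y3,
            dataset.runs[labeled], plan, "akinesia",
            feature_names=dataset.blocks["neural"],
            n_repeats=config.importance_repeats, seed=config.seed,
            eval_merge=AKINESIA_MERGE)
        bundle.tables["lda_neural_metrics"] = m
        bundle.objects["lda_neural_confusion"] = c
        bundle.objects["lda_neural_importance"] = imp

    with _stage(bundle, "embedding"):
        m, c, imp = _embedding_branch(dataset, "neural", plan, config, "akinesia")
        bundle.tables["embedding_neural_metrics"] = m
        bundle.objects["embedding_neural_confusion"] = c
        bundle.objects["embedding_neural_importance"] = imp

    with _stage(bundle, "ranking"):
        lin = bundle.objects.get("lda_neural_importance")
        emb = bundle.objects.get("embedding_neural_importance")
        if lin is not None and emb is not None:
            bundle.tables["joint_ranking"] = joint_ranking(lin, emb)

    with _stage(bundle, "peri_onset"):
        per_run = []
        for fm in _split_by_run(dataset):
            per_run.append((fm, events_by_run[fm.run_ids[0]]))
        curves = peri_onset_curves(per_run, "akinesia", config.peri_window)
        bundle.objects["peri_onset"] = curves
        marks = biomarker_features(dataset.blocks["neural"])
        bundle.tables["peri_onset_modulation"] = pd.DataFrame([
            {"feature": feat, "role": role,
             "delta": onset_modulation(curves, feat)}
            for role, feat in marks.items()])

    with _stage(bundle, "state_tests"):
        marks = biomarker_features(dataset.blocks["neural"])
        sm = per_subject_state_means(dataset, list(marks.values()))
        bundle.tables["state_feature_tests"] = state_feature_tests(
            sm, list(marks.values()))

    if config.outdir:
        bundle.write(config.outdir)
    return bundle


def _split_by_run(dataset):
    """Reconstruct per-run FeatureMatrix views from an assembled dataset."""
    out = []
    for run in dataset.unique_runs():
        m = dataset.runs == run
        out.append(FeatureMatrix(dataset.X[m], dataset.names, dataset.times[m],
                                 dataset.rate, dataset.labels[m],
                                 dataset.runs[m], dataset.subjects[m],
                                 dataset.days[m]))
    return out


# ---------------------------------------------------------------------------
# Human FoG pipeline
# ---------------------------------------------------------------------------

@dataclass
class HumanPipelineConfig:
    seed: int = 0
    cohort: HumanCohortSpec | None = None
    outdir: str | None = None
    feature_rate: float = 100.0
    analysis_fs: float = 200.0
    est_window: float = 1.0
    bin_s: float = 1.0
    top_n: int = 10
    n_perm: int = 2000
    outlier_z: float = 4.0


def run_human_pipeline(config: HumanPipelineConfig) -> ResultsBundle:
    """Walkway FoG workflow: binning, PCA, correlations, episode tests."""
    bundle = ResultsBundle(config)
    spec = config.cohort or HumanCohortSpec(seed=config.seed)
    sessions = None
    with _stage(bundle, "load"):
        sessions = generate_human_cohort(spec)
    if sessions is None:
        return bundle

    kin_mats, neu_mats, events_map, patient_of_run = None, [], {}, {}
    with _stage(bundle, "features"):
        kin_mats = []
        for patient, run_id, traj, rec, events in sessions:
            kin = compute_kinematic_features(traj, rodent_skeleton())
            kin = FeatureMatrix(kin.values, kin.names, kin.times, kin.rate,
                                run_ids=run_id, subject_ids=patient)
            kin.labels = align_events_to_samples(events, kin.times)
            kin_mats.append(kin)
            rec2 = resample_recording(rec, config.analysis_fs)
            neu = extract_neural_features(rec2, human_bands(),
                                          config.feature_rate,
                                          config.est_window, run_id=run_id,
                                          subject_id=patient)
            neu.labels = align_events_to_samples(events, neu.times)
            neu_mats.append(neu)
            events_map[run_id] = events
            patient_of_run[run_id] = patient
    if kin_mats is None:
        return bundle

    with _stage(bundle, "kinematic_analysis"):
        ds = assemble_dataset(kin_mats, outlier_z=config.outlier_z)
        fm = FeatureMatrix(ds.X, ds.names, ds.times, ds.rate, ds.labels,
                           ds.runs, ds.subjects, ds.days)
        binned, skipped = bin_episodes(fm, config.bin_s)
        bundle.tables["binned_kinematics"] = binned
        scores, loadings, evr = pca_project(binned, ds.names)
        bundle.tables["pca_scores"] = pd.DataFrame(
            {"pc1": scores[:, 0],
             "pc2": scores[:, 1] if scores.shape[1] > 1 else np.nan,
             "label": binned["label"]})
        bundle.objects["pca_loadings"] = loadings
        bundle.objects["pca_evr"] = evr
        bundle.tables["top_correlated"] = top_correlated_features(
            binned, ds.names, n=config.top_n)

    with _stage(bundle, "neural_analysis"):
        results = []
        for patient in dict.fromkeys(p for p, *_ in sessions):
            runs = [fm for fm in neu_mats if fm.subject_ids[0] == patient]
            eps = []
            for fm in runs:
                run = fm.run_ids[0]
                eps.append(episode_means(fm, events_map[run], fm.names,
                                         run_id=run, session_id=run))
            episodes = pd.concat(eps, ignore_index=True)
            names = runs[0].names
            beta_cols = {n.split("amplitude ")[1]: n for n in names
                         if "beta amplitude" in n}
            channel, info = select_channel_by_band_modulation(episodes, beta_cols)
            feats = {
                "Hjorth complexity": f"Hjorth complexity {channel}",
                "Hjorth mobility": f"Hjorth mobility {channel}",
                "beta amplitude": f"beta amplitude {channel}",
                "gamma amplitude": f"gamma amplitude {channel}",
            }
            pvals, stats_ = [], []
            for short, col in feats.items():
                r = episode_permutation_test(episodes, col, n_perm=config.n_perm,
                                             seed=config.seed)
                pvals.append(r.p_value)
                stats_.append(r.statistic)
            adj = bonferroni(pvals, factor=len(feats))
            for (short, col), p_raw, p_adj, t in zip(feats.items(), pvals, adj, stats_):
                results.append({"patient": patient, "channel": channel,
                                "feature": short, "statistic": t,
                                "p_raw": p_raw, "p_bonferroni": p_adj})
        bundle.tables["episode_tests"] = pd.DataFrame(results)

    if config.outdir:
        bundle.write(config.outdir)
    return bundle
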