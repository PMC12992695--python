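"""Peri-onset modulation, joint importance ranking, state statistics, and
the human freezing-of-gait branch (binning, PCA, correlated features,
channel selection, constrained permutation test)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .core import UNLABELED, FeatureMatrix, ImportanceTable
from .dataset import holm_adjust
from .errors import (ConfigurationError, InsufficientDataError,
                     ValidationError)
from .io import EventTable


# ---------------------------------------------------------------------------
# Peri-onset curves
# ---------------------------------------------------------------------------

@dataclass
class PeriEventCurves:
    """Event-triggered mean ± sd feature traces around state onsets."""

    time: np.ndarray  # s relative to onset
    feature_names: list[str]
    mean: np.ndarray  # (time, features)
    sd: np.ndarray
    n_events: int
    n_excluded: int
    empty: bool = False

    def feature(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        j = self.feature_names.index(name)
        return self.mean[:, j], self.sd[:, j]


def peri_onset_curves(runs: list[tuple[FeatureMatrix, EventTable]],
                      target_state: str,
                      window: tuple[float, float] = (-2.0, 2.0)
                      ) -> PeriEventCurves:
    """Average feature traces around every onset of ``target_state``.

    ``runs`` pairs each run's feature matrix with its event table. Onsets
    whose full window does not fit inside the run are excluded and counted.
    Traces are not re-baselined.
    """
    if not runs:
        raise InsufficientDataError("no runs supplied")
    rate = runs[0][0].rate
    pre = int(round(-window[0] * rate))
    post = int(round(window[1] * rate))
    taxis = np.arange(-pre, post + 1) / rate
    names = runs[0][0].names
    traces = []
    excluded = 0
    for fm, events in runs:
        if fm.names != names:
            raise ConfigurationError("feature vocabularies differ across runs")
        for t0, _t1 in events.occurrences(target_state):
            i0 = int(round(t0 * fm.rate))
            if i0 - pre < 0 or i0 + post >= fm.n_samples:
                excluded += 1
                continue
            traces.append(fm.values[i0 - pre:i0 + post + 1])
    if not traces:
        return PeriEventCurves(taxis, list(names), np.zeros((len(taxis), len(names))),
                               np.zeros((len(taxis), len(names))), 0, excluded,
                               empty=True)
    stack = np.stack(traces)
    return PeriEventCurves(taxis, list(names), stack.mean(axis=0),
                           stack.std(axis=0), len(traces), excluded)


def onset_modulation(curves: PeriEventCurves, feature: str,
                     before: tuple[float, float] = (-2.5, -1.5),
                     after: tuple[float, float] = (1.0, 2.0)) -> float:
    """Mean(after onset) - mean(before onset) of one peri-onset curve.

    The default windows leave one second of clearance on each side of the
    onset because causally estimated features (trailing 1-s windows) lag
    the underlying state by up to their estimation-window length.
    """
    m, _sd = curves.feature(feature)
    t = curves.time
    b = (t >= before[0]) & (t < before[1])
    a = (t > after[0]) & (t <= after[1])
    return float(m[a].mean() - m[b].mean())


# ---------------------------------------------------------------------------
# Joint importance ranking
# ---------------------------------------------------------------------------

def joint_ranking(imp_linear: ImportanceTable, imp_embedding: ImportanceTable,
                  method: str = "max") -> pd.DataFrame:
    """Combine linear and embedding importances into one ranked table.

    ``method='max'`` takes the worse (larger) of the two ranks — a feature
    must score high in both models to land on top; ``'mean'`` averages.
    """
    if set(imp_linear.features) != set(imp_embedding.features):
        raise ConfigurationError("importance tables cover different features")
    if method not in ("max", "mean"):
        raise ConfigurationError(f"unknown combination method {method!r}")
    rows = []
    for f in imp_linear.features:
        rl, re = imp_linear.rank(f), imp_embedding.rank(f)
        rows.append({"feature": f,
                     "importance_linear": imp_linear.mean(f),
                     "importance_embedding": imp_embedding.mean(f),
                     "rank_linear": rl, "rank_embedding": re,
                     "combined": max(rl, re) if method == "max" else (rl + re) / 2})
    out = pd.DataFrame(rows).sort_values(
        ["combined", "rank_linear"], kind="stable").reset_index(drop=True)
    out["combined_rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# Multi-comparison state statistics
# ---------------------------------------------------------------------------

def state_feature_tests(subject_means: pd.DataFrame, features: list[str],
                        states: list[str] | None = None,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Paired t-tests across subjects for each state pair x feature.

    ``subject_means`` is tidy: columns ``subject``, ``state`` and one column
    per feature, one row per (subject, state). With 3 states and 4 features
    this yields the 12 Holm-corrected comparisons. Subjects missing either
    state of a pair are dropped pairwise and recorded.
    """
    if states is None:
        states = sorted(subject_means["state"].unique())
    pairs = [(a, b) for i, a in enumerate(states) for b in states[i + 1:]]
    rows = []
    for a, b in pairs:
        for feat in features:
            pa = subject_means[subject_means["state"] == a].set_index("subject")[feat]
            pb = subject_means[subject_means["state"] == b].set_index("subject")[feat]
            common = pa.index.intersection(pb.index)
            dropped = len(set(pa.index) ^ set(pb.index))
            if len(common) < 2:
                raise InsufficientDataError(
                    f"fewer than 2 subjects with both {a!r} and {b!r}")
            va, vb = pa[common].to_numpy(), pb[common].to_numpy()
            if np.allclose(va, vb):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(va, vb)
            rows.append({"state_a": a, "state_b": b, "feature": feat,
                         "mean_a": va.mean(), "mean_b": vb.mean(),
                         "t": float(t), "p_raw": float(p),
                         "n_subjects": len(common), "n_dropped": dropped})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"])
    out["significant"] = out["p_holm"] < alpha
    return out


def per_subject_state_means(dataset, features: list[str]) -> pd.DataFrame:
    """Tidy (subject, state) means of selected features from a dataset."""
    cols = [dataset.names.index(f) for f in features]
    df = pd.DataFrame(dataset.X[:, cols], columns=features)
    df["subject"] = dataset.subjects
    df["state"] = dataset.labels
    df = df[df["state"] != UNLABELED]
    return df.groupby(["subject", "state"], as_index=False)[features].mean()


# ---------------------------------------------------------------------------
# Human FoG branch
# ---------------------------------------------------------------------------

def bin_episodes(fm: FeatureMatrix, bin_s: float = 1.0):
    """Per-bin feature means with majority-vote bin labels, per run.

    Trailing partial bins are dropped; runs shorter than one bin are skipped
    (returned in the skip list).
    """
    if fm.rate < 1.0 / bin_s:
        raise ConfigurationError("feature rate below one sample per bin")
    per_bin = int(round(bin_s * fm.rate))
    values, labels, bins_run = [], [], []
    skipped = []
    for run in dict.fromkeys(fm.run_ids.tolist()):
        mask = fm.run_ids == run
        v = fm.values[mask]
        lab = fm.labels[mask] if fm.labels is not None else None
        n_bins = len(v) // per_bin
        if n_bins == 0:
            skipped.append(run)
            continue
        for b in range(n_bins):
            sl = slice(b * per_bin, (b + 1) * per_bin)
            values.append(v[sl].mean(axis=0))
            bins_run.append(run)
            if lab is not None:
                u, c = np.unique(lab[sl].astype(str), return_counts=True)
                labels.append(u[np.argmax(c)])  # majority of the bin's samples
    binned = pd.DataFrame(values, columns=fm.names)
    binned["run_id"] = bins_run
    if labels:
        binned["label"] = labels
    return binned, skipped


def pca_project(binned: pd.DataFrame, feature_names: list[str],
                n_components: int = 2):
    """PCA on z-scored bins with a deterministic sign convention.

    Returns ``(scores, loadings, explained_variance_ratio)``; each
    component is flipped so its largest-magnitude loading is positive.
    """
    X = binned[feature_names].to_numpy(float)
    if X.shape[0] <= n_components:
        raise InsufficientDataError("need more bins than components")
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - X.mean(axis=0)) / sd
    rank = np.linalg.matrix_rank(Xz)
    k = min(n_components, rank)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Xz)
    loadings = pca.components_.T.copy()  # (features, components)
    for c in range(k):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    return scores, loadings, pca.explained_variance_ratio_


def top_correlated_features(binned: pd.DataFrame, feature_names: list[str],
                            label_col: str = "label",
                            positive_label: str = "gait",
                            n: int = 10) -> pd.DataFrame:
    """Top-n features by |point-biserial correlation| with the state indicator."""
    labels = binned[label_col].astype(str)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise InsufficientDataError("both labels must be present for correlation")
    ind = (labels == positive_label).astype(float).to_numpy()
    rows = []
    for f in feature_names:
        x = binned[f].to_numpy(float)
        if x.std() == 0:
            r = 0.0
        else:
            r = float(stats.pointbiserialr(ind, x).statistic)
        rows.append({"feature": f, "r": r})
    out = pd.DataFrame(rows).sort_values("r", key=np.abs, ascending=False,
                                         kind="stable").reset_index(drop=True)
    if n > len(out):
        import warnings
        warnings.warn(f"requested top {n} of only {len(out)} features")
    return out.head(min(n, len(out)))


def episode_means(binned_or_fm, events: EventTable, feature_names: list[str],
                  run_id: str = "", session_id: str = "") -> pd.DataFrame:
    """Per-episode mean of each feature (episodes = labeled event intervals)."""
    fm = binned_or_fm
    rows = []
    for k, (state, t0, t1) in enumerate(events.events):
        mask = (fm.times >= t0) & (fm.times < t1)
        if not mask.any():
            continue
        row = {"episode": f"{run_id}_e{k}", "label": state, "run_id": run_id,
               "session": session_id or run_id, "start": t0, "end": t1}
        for f in feature_names:
            row[f] = float(fm.column(f)[mask].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def select_channel_by_band_modulation(episodes: pd.DataFrame,
                                      channel_columns: dict[str, str],
                                      label_col: str = "label",
                                      fog_label: str = "fog",
                                      gait_label: str = "gait"):
    """Channel with the largest |mean(band|FoG) - mean(band|gait)|.

    ``channel_columns`` maps channel id -> episode-mean column of that
    channel's band feature. Ties go to the first channel in insertion
    order, flagged in the returned record.
    """
    labels = episodes[label_col].astype(str)
    if fog_label not in set(labels) or gait_label not in set(labels):
        raise InsufficientDataError("both episode labels must be present")
    mods = {}
    for ch, col in channel_columns.items():
        m_fog = episodes.loc[labels == fog_label, col].mean()
        m_gait = episodes.loc[labels == gait_label, col].mean()
        mods[ch] = abs(float(m_fog) - float(m_gait))
    best = max(mods, key=lambda c: mods[c])
    tie = sum(1 for v in mods.values() if np.isclose(v, mods[best])) > 1
    return best, {"modulation": mods, "tie": tie}


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    n_effective_strata: int


def episode_permutation_test(episodes: pd.DataFrame, feature: str,
                             n_perm: int = 10000, seed: int = 0,
                             label_col: str = "label",
                             constraint_col: str = "session",
                             labels: tuple[str, str] = ("gait", "fog")
                             ) -> PermutationTestResult:
    """Two-sided label-permutation test constrained within strata.

    The statistic is the difference of label-wise means of per-episode
    feature means; the null permutes episode labels only WITHIN each
    constraint stratum (session/trial), so label counts per stratum are
    preserved. p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm).
    """
    lab = episodes[label_col].astype(str).to_numpy()
    x = episodes[feature].to_numpy(float)
    strata = episodes[constraint_col].to_numpy()
    for l in labels:
        if (lab == l).sum() < 1:
            raise InsufficientDataError(f"no episodes with label {l!r}")
    if (lab == labels[0]).sum() + (lab == labels[1]).sum() < 4:
        raise InsufficientDataError("need at least 2 episodes per label overall")

    def stat(l):
        return x[l == labels[1]].mean() - x[l == labels[0]].mean()

    t_obs = stat(lab)
    rng = np.random.default_rng(seed)
    groups = [np.flatnonzero(strata == s) for s in dict.fromkeys(strata.tolist())]
    effective = [g for g in groups if len(set(lab[g])) > 1]
    if not effective:
        raise ValidationError("all strata have a single label: test undefined")
    count = 0
    perm = lab.copy()
    for _ in range(n_perm):
        for g in groups:
            perm[g] = lab[g][rng.permutation(len(g))]
        if abs(stat(perm)) >= abs(t_obs) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermutationTestResult(float(t_obs), float(p), n_perm, len(effective))


def bonferroni(pvalues, factor: int | None = None) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    m = factor if factor is not None else len(p)
    return np.minimum(1.0, p * m)


def mask_intervals(fm: FeatureMatrix, intervals: list[tuple[float, float]]
                   ) -> FeatureMatrix:
    """Drop samples inside artifact intervals (half-open, seconds)."""
    keep = np.ones(fm.n_samples, dtype=bool)
    for t0, t1 in intervals:
        keep &= ~((fm.times >= t0) & (fm.times < t1))
    return FeatureMatrix(fm.values[keep], fm.names, fm.times[keep], fm.rate,
                         None if fm.labels is None else fm.labels[keep],
                         fm.run_ids[keep], fm.subject_ids[keep], fm.day_ids[keep])
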