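"""Multimodal dataset assembly: labels, occupancy, cleaning, grouped CV.

The assembled dataset concatenates the kinematic and neural feature blocks
of every run, attaches a per-sample state label from the event tables, and
records the cleaning/normalization statistics (outlier-to-median on a robust
z scale, then Z-scoring) so that held-out partitions are always transformed
with statistics estimated on the training partition only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import UNLABELED, FeatureMatrix
from .errors import ConfigurationError, InsufficientDataError, ValidationError
from .io import EventTable


def align_events_to_samples(events: EventTable, times: np.ndarray) -> np.ndarray:
    """Label each sample time by its containing half-open [start, end) event."""
    times = np.asarray(times, dtype=float)
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValidationError("sample times must be strictly increasing")
    labels = np.full(times.shape, UNLABELED, dtype=object)
    for state, t0, t1 in events.events:
        labels[(times >= t0) & (times < t1)] = state
    return labels


def state_time_fractions(events: EventTable) -> dict[str, float]:
    """Fraction of trial time per state; the residual is 'unlabeled'."""
    total = events.trial_duration
    fractions = {s: 0.0 for s in events.vocabulary}
    for state, t0, t1 in events.events:
        fractions[state] += (t1 - t0) / total
    fractions[UNLABELED] = max(0.0, 1.0 - sum(fractions.values()))
    return fractions


def holm_adjust(pvalues) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment."""
    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


def compare_group_fractions(subject_fractions: pd.DataFrame,
                            group_col: str = "group",
                            groups: tuple[str, str] = ("sham", "lesioned"),
                            alpha: float = 0.05) -> pd.DataFrame:
    """Independent t-test per state between groups, Holm-adjusted.

    ``subject_fractions`` has one row per subject: the group column plus one
    column per state holding that subject's mean occupancy fraction.
    """
    states = [c for c in subject_fractions.columns
              if c not in (group_col, UNLABELED)]
    a = subject_fractions[subject_fractions[group_col] == groups[0]]
    b = subject_fractions[subject_fractions[group_col] == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need at least 2 subjects per group")
    rows = []
    for state in states:
        t, p = stats.ttest_ind(a[state], b[state])
        rows.append({"state": state, "t": float(t), "p_raw": float(p),
                     "mean_" + groups[0]: float(a[state].mean()),
                     "mean_" + groups[1]: float(b[state].mean())})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"])
    out["significant"] = out["p_holm"] < alpha
    return out


@dataclass
class NormalizationRecord:
    """Cleaning statistics estimated on the training partition."""

    names: list[str]
    median: np.ndarray
    mad: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    outlier_z: float
    outlier_count: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def apply(self, values: np.ndarray, names: list[str]) -> np.ndarray:
        """Transform a (possibly held-out) block with the stored statistics."""
        idx = [names.index(n) for n in self.names]
        x = values[:, idx].copy()
        scale = np.where(self.mad > 0, 1.4826 * self.mad, np.inf)
        rz = np.abs(x - self.median) / scale
        for j in range(x.shape[1]):
            x[rz[:, j] > self.outlier_z, j] = self.median[j]
        return (x - self.mean) / self.sd

    def to_json(self, path) -> None:
        doc = {"names": self.names, "median": self.median.tolist(),
               "mad": self.mad.tolist(), "mean": self.mean.tolist(),
               "sd": self.sd.tolist(), "outlier_z": self.outlier_z,
               "outlier_count": self.outlier_count.tolist(),
               "dropped": self.dropped}
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @staticmethod
    def from_json(path) -> "NormalizationRecord":
        with open(path) as fh:
            d = json.load(fh)
        return NormalizationRecord(d["names"], np.array(d["median"]),
                                   np.array(d["mad"]), np.array(d["mean"]),
                                   np.array(d["sd"]), d["outlier_z"],
                                   np.array(d["outlier_count"]), d["dropped"])


@dataclass
class MultimodalDataset:
    """Cleaned, concatenated feature matrix with labels and grouping keys."""

    X: np.ndarray
    names: list[str]
    labels: np.ndarray
    times: np.ndarray
    rate: float
    runs: np.ndarray
    subjects: np.ndarray
    days: np.ndarray
    blocks: dict[str, list[str]]
    normalization: NormalizationRecord

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def block_columns(self, block: str) -> np.ndarray:
        return np.array([self.names.index(n) for n in self.blocks[block]])

    def block_values(self, block: str) -> np.ndarray:
        return self.X[:, self.block_columns(block)]

    def labeled_mask(self) -> np.ndarray:
        return self.labels != UNLABELED

    def run_mask(self, runs) -> np.ndarray:
        return np.isin(self.runs, list(runs))

    def unique_runs(self) -> list:
        seen = dict.fromkeys(self.runs.tolist())
        return list(seen)


def assemble_dataset(run_matrices: list[FeatureMatrix],
                     blocks: dict[str, list[str]] | None = None,
                     outlier_z: float = 4.0,
                     normalization: NormalizationRecord | None = None
                     ) -> MultimodalDataset:
    """Concatenate runs, replace outliers with the feature median, Z-score.

    Outliers are detected on a robust (median/MAD) z scale at ``outlier_z``
    and set to the feature median before standardization. Features with zero
    variance after replacement are dropped and recorded. Passing a stored
    ``normalization`` record applies training statistics instead of
    re-estimating them (used for held-out partitions).
    """
    if not run_matrices:
        raise InsufficientDataError("no runs to assemble")
    fm = FeatureMatrix.concat(run_matrices)
    if fm.labels is None:
        raise ValidationError("run matrices must carry state labels")
    values, names = fm.values, list(fm.names)
    if normalization is None:
        median = np.median(values, axis=0)
        mad = np.median(np.abs(values - median), axis=0)
        scale = np.where(mad > 0, 1.4826 * mad, np.inf)
        rz = np.abs(values - median) / scale
        cleaned = values.copy()
        outlier_count = np.zeros(len(names), dtype=int)
        for j in range(len(names)):
            mask = rz[:, j] > outlier_z
            outlier_count[j] = mask.sum()
            cleaned[mask, j] = median[j]
        mean = cleaned.mean(axis=0)
        sd = cleaned.std(axis=0)
        # constant features: sd at float-noise level relative to magnitude
        zero = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
        dropped = [names[j] for j in range(len(names)) if zero[j]]
        keep = [j for j in range(len(names)) if not zero[j]]
        normalization = NormalizationRecord(
            [names[j] for j in keep], median[keep], mad[keep], mean[keep],
            sd[keep], outlier_z, outlier_count[keep], dropped)
        X = (cleaned[:, keep] - mean[keep]) / sd[keep]
    else:
        X = normalization.apply(values, names)
    kept_names = list(normalization.names)
    if np.isnan(X).any():
        raise ValidationError("NaN in assembled dataset; clean gaps upstream")
    if blocks is None:
        blocks = {"all": kept_names}
    else:
        blocks = {k: [n for n in v if n in kept_names] for k, v in blocks.items()}
    return MultimodalDataset(X, kept_names, fm.labels, fm.times, fm.rate,
                             fm.run_ids, fm.subject_ids, fm.day_ids,
                             blocks, normalization)


@dataclass
class SplitPlan:
    """Run-grouped k-fold plan: all samples of a run stay in one fold."""

    folds: list[tuple[list, list]]  # (train_runs, test_runs)
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed,
                       "folds": [{"train": list(tr), "test": list(te)}
                                 for tr, te in self.folds]}, fh)


def group_kfold(runs, k: int, seed: int = 0) -> SplitPlan:
    """Partition runs into k near-equal folds (grouping key = run)."""
    unique = list(dict.fromkeys(runs))
    if k > len(unique):
        raise ConfigurationError(f"k={k} exceeds the number of runs ({len(unique)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    shuffled = [unique[i] for i in order]
    folds = []
    test_sets = np.array_split(np.arange(len(shuffled)), k)
    for idx in test_sets:
        test = [shuffled[i] for i in idx]
        train = [r for r in shuffled if r not in test]
        folds.append((train, test))
    return SplitPlan(folds, seed)
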