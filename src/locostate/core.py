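"""Shared containers: feature matrices, importance tables, confusion summaries.

A :class:`FeatureMatrix` is the common currency of the toolchain: a
time-indexed block of named features at a fixed feature rate, optionally
carrying per-sample state labels and run/subject/day grouping keys so that
matrices from many runs can be concatenated without losing provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ShapeError, ValidationError

UNLABELED = "unlabeled"


def _as_key_array(value, n: int) -> np.ndarray:
    """Broadcast a scalar grouping key to a per-sample object array."""
    if value is None:
        value = ""
    if np.isscalar(value) or isinstance(value, str):
        return np.full(n, value, dtype=object)
    arr = np.asarray(value, dtype=object)
    if arr.shape != (n,):
        raise ShapeError(f"grouping key has shape {arr.shape}, expected ({n},)")
    return arr


@dataclass
class FeatureMatrix:
    """Named feature time series at a fixed rate with optional labels."""

    values: np.ndarray
    names: list[str]
    times: np.ndarray
    rate: float
    labels: np.ndarray | None = None
    run_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    day_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("values must be 2-D (samples x features)")
        n, f = self.values.shape
        self.names = [str(x) for x in self.names]
        if len(self.names) != f:
            raise ShapeError(f"{len(self.names)} names for {f} feature columns")
        if len(set(self.names)) != f:
            raise ValidationError("feature names must be unique")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (n,):
            raise ShapeError("times must match the number of samples")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (n,):
                raise ShapeError("labels must match the number of samples")
        self.run_ids = _as_key_array(self.run_ids, n)
        self.subject_ids = _as_key_array(self.subject_ids, n)
        self.day_ids = _as_key_array(self.day_ids, n)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def select(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.names.index(n) for n in names]
        return FeatureMatrix(
            self.values[:, idx], list(names), self.times, self.rate,
            None if self.labels is None else self.labels,
            self.run_ids, self.subject_ids, self.day_ids,
        )

    def hstack(self, other: "FeatureMatrix") -> "FeatureMatrix":
        """Join two feature blocks sampled on the same timeline."""
        if other.n_samples != self.n_samples:
            raise ShapeError("blocks have different sample counts")
        overlap = set(self.names) & set(other.names)
        if overlap:
            raise ValidationError(f"duplicate feature names across blocks: {sorted(overlap)}")
        return FeatureMatrix(
            np.hstack([self.values, other.values]),
            self.names + other.names,
            self.times, self.rate,
            self.labels if self.labels is not None else other.labels,
            self.run_ids, self.subject_ids, self.day_ids,
        )

    @staticmethod
    def concat(blocks: list["FeatureMatrix"]) -> "FeatureMatrix":
        """Concatenate runs along time; names must agree in order."""
        if not blocks:
            raise ValidationError("nothing to concatenate")
        names = blocks[0].names
        for b in blocks[1:]:
            if b.names != names:
                raise ValidationError("feature names differ across runs")
        labels = None
        if all(b.labels is not None for b in blocks):
            labels = np.concatenate([b.labels for b in blocks])
        return FeatureMatrix(
            np.vstack([b.values for b in blocks]),
            list(names),
            np.concatenate([b.times for b in blocks]),
            blocks[0].rate,
            labels,
            np.concatenate([b.run_ids for b in blocks]),
            np.concatenate([b.subject_ids for b in blocks]),
            np.concatenate([b.day_ids for b in blocks]),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "time", self.times)
        if self.labels is not None:
            df["label"] = self.labels
        df["run_id"] = self.run_ids
        df["subject_id"] = self.subject_ids
        df["day_id"] = self.day_ids
        return df

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# rate={self.rate}\n")
            self.to_frame().to_csv(fh, index=False)

    def to_hdf5(self, path) -> None:
        import h5py
        str_dt = h5py.string_dtype()
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.create_dataset("times", data=self.times)
            f.create_dataset("names", data=np.array(self.names, dtype=object),
                             dtype=str_dt)
            f.attrs["rate"] = self.rate
            for key in ("labels", "run_ids", "subject_ids", "day_ids"):
                arr = getattr(self, key)
                if arr is not None:
                    f.create_dataset(key, data=[str(s) for s in arr],
                                     dtype=str_dt)

    @staticmethod
    def from_hdf5(path) -> "FeatureMatrix":
        import h5py
        with h5py.File(path, "r") as f:
            def strs(key):
                if key not in f:
                    return None
                return np.array([s.decode() if isinstance(s, bytes) else s
                                 for s in f[key][()]], dtype=object)
            return FeatureMatrix(
                f["values"][()], list(strs("names")), f["times"][()],
                float(f.attrs["rate"]), strs("labels"), strs("run_ids"),
                strs("subject_ids"), strs("day_ids"))

    @staticmethod
    def from_csv(path) -> "FeatureMatrix":
        with open(path) as fh:
            header = fh.readline().strip()
            rate = float(header.split("rate=")[1]) if "rate=" in header else np.nan
            df = pd.read_csv(fh)
        meta = ["time", "label", "run_id", "subject_id", "day_id"]
        names = [c for c in df.columns if c not in meta]
        return FeatureMatrix(
            df[names].to_numpy(float), names, df["time"].to_numpy(float), rate,
            df["label"].to_numpy(object) if "label" in df else None,
            df["run_id"].to_numpy(object) if "run_id" in df else None,
            df["subject_id"].to_numpy(object) if "subject_id" in df else None,
            df["day_id"].to_numpy(object) if "day_id" in df else None,
        )


class ImportanceTable:
    """Per-feature importance values aggregated over cross-validation folds.

    ``rank`` is 1 for the most important feature (largest mean importance).
    """

    def __init__(self, per_fold: dict[str, list[float]]):
        if not per_fold:
            raise ValidationError("empty importance table")
        self.features = list(per_fold)
        self.per_fold = {k: [float(v) for v in vals] for k, vals in per_fold.items()}
        means = np.array([np.mean(self.per_fold[f]) for f in self.features])
        order = np.argsort(-means, kind="stable")
        ranks = np.empty(len(means), dtype=int)
        ranks[order] = np.arange(1, len(means) + 1)
        self.table = pd.DataFrame(
            {"feature": self.features, "importance": means, "rank": ranks}
        ).set_index("feature")

    def mean(self, feature: str) -> float:
        return float(self.table.loc[feature, "importance"])

    def rank(self, feature: str) -> int:
        return int(self.table.loc[feature, "rank"])

    def top(self, n: int) -> list[str]:
        return list(self.table.sort_values("rank").index[:n])

    @staticmethod
    def from_fold_series(fold_values: list[pd.Series]) -> "ImportanceTable":
        feats = list(fold_values[0].index)
        return ImportanceTable({f: [float(s[f]) for s in fold_values] for f in feats})


class ConfusionSummary:
    """Row-normalized confusion matrices per fold with mean and sd."""

    def __init__(self, labels: list[str], matrices: list[np.ndarray]):
        self.labels = list(labels)
        self.matrices = [np.asarray(m, dtype=float) for m in matrices]
        for m in self.matrices:
            if m.shape != (len(labels), len(labels)):
                raise ShapeError("confusion matrix shape mismatch")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ValidationError("confusion rows must sum to 1")
        stack = np.stack(self.matrices)
        self.mean = stack.mean(axis=0)
        self.sd = stack.std(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean, index=self.labels, columns=self.labels)
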