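"""Reading/writing trajectories, neural recordings, event tables, manifests.

Formats
-------
Marker trajectories
    Either C3D (through the optional ``ezc3d`` reader) or the package's CSV
    dialect: a ``# key=value`` metadata line (``frame_rate`` mandatory), a
    header row of ``marker.axis`` columns and one row per frame. Missing
    samples are empty cells, kept as NaN sentinels — never silently dropped.
Neural recordings
    A data file (CSV with one column per channel, or flat binary float32,
    samples x channels row-major) plus a YAML sidecar with the sampling rate
    and the per-channel hemisphere assignment.
Event tables
    CSV rows ``state,start,end`` in seconds, with an optional
    ``# trial_duration=..`` metadata line. Intervals are half-open
    ``[start, end)`` everywhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, StructureError, ValidationError

logger = logging.getLogger(__name__)

RODENT_STATES = ("gait", "stationary", "akinesia")
HUMAN_STATES = ("gait", "fog")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MarkerTrajectories:
    """Time-indexed 3-D marker positions (mm) for one run.

    ``positions`` has shape (frames, markers, 3); gaps are NaN.
    """

    marker_names: list[str]
    positions: np.ndarray
    frame_rate: float
    run_id: str = ""
    subject_id: str = ""
    day_id: str = ""

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise StructureError("positions must have shape (frames, markers, 3)")
        if self.positions.shape[1] != len(self.marker_names):
            raise StructureError("marker_names does not match positions")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def marker(self, name: str) -> np.ndarray:
        return self.positions[:, self.marker_names.index(name), :]

    def missing_mask(self) -> np.ndarray:
        """(frames, markers) boolean mask of gap samples."""
        return np.isnan(self.positions).any(axis=2)


@dataclass
class NeuralRecording:
    """Multichannel field-potential signal (µV) for one run."""

    channel_names: list[str]
    signal: np.ndarray  # (channels, samples)
    fs: float
    hemispheres: list[str]
    run_id: str = ""

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.shape[0] != len(self.channel_names):
            raise StructureError("channel_names does not match signal rows")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if len(self.hemispheres) != len(self.channel_names):
            raise ValidationError("hemisphere must be defined for every channel")
        for h in self.hemispheres:
            if h not in ("left", "right"):
                raise ValidationError(f"unknown hemisphere {h!r}")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.signal[self.channel_names.index(name)]


@dataclass
class EventTable:
    """Labeled, non-overlapping state intervals of one run (half-open)."""

    events: list[tuple[str, float, float]]
    trial_duration: float
    vocabulary: tuple[str, ...] = RODENT_STATES

    def __post_init__(self):
        if self.trial_duration <= 0:
            raise ValidationError("trial_duration must be positive")
        evs = []
        for label, t0, t1 in self.events:
            t0, t1 = float(t0), float(t1)
            if label not in self.vocabulary:
                raise ValidationError(f"unknown state label {label!r}")
            if not t0 < t1:
                raise ValidationError(f"event ({label}, {t0}, {t1}) has t_start >= t_end")
            if t0 < -1e-9 or t1 > self.trial_duration + 1e-9:
                raise ValidationError(f"event ({label}, {t0}, {t1}) outside [0, trial_duration]")
            evs.append((label, t0, t1))
        evs.sort(key=lambda e: e[1])
        for (l0, a0, b0), (l1, a1, b1) in zip(evs, evs[1:]):
            if a1 < b0 - 1e-9:
                raise ValidationError(
                    f"overlapping events ({l0}, {a0}, {b0}) and ({l1}, {a1}, {b1})")
        self.events = evs

    def __len__(self) -> int:
        return len(self.events)

    def states(self) -> list[str]:
        return sorted({e[0] for e in self.events})

    def occurrences(self, state: str) -> list[tuple[float, float]]:
        return [(t0, t1) for s, t0, t1 in self.events if s == state]


@dataclass
class SessionManifest:
    """Paths and identifiers of one recorded session."""

    trajectory_path: str
    neural_path: str
    neural_sidecar_path: str
    events_path: str
    run_id: str
    subject_id: str
    day_id: str = "day0"
    group: str = ""
    expected_frames: int | None = None

    def __post_init__(self):
        for name in ("run_id", "subject_id"):
            if not getattr(self, name):
                raise ValidationError(f"{name} must be non-empty")

    def validate_paths(self) -> None:
        for p in (self.trajectory_path, self.neural_path,
                  self.neural_sidecar_path, self.events_path):
            if not Path(p).exists():
                raise ValidationError(f"referenced file does not exist: {p}")


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

def _parse_meta_line(line: str) -> dict:
    if not line.startswith("#"):
        return {}
    out = {}
    for tok in line.lstrip("#").split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def read_marker_trajectories(path, dialect: str = "csv") -> MarkerTrajectories:
    """Read 3-D marker trajectories from a C3D or CSV dialect file."""
    if dialect == "c3d":
        return _read_c3d(path)
    if dialect != "csv":
        raise FormatError(f"unknown trajectory dialect {dialect!r}")
    path = Path(path)
    try:
        with open(path) as fh:
            meta = _parse_meta_line(fh.readline())
            df = pd.read_csv(fh)
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot read trajectory CSV {path}: {exc}") from exc
    if "frame_rate" not in meta:
        raise FormatError(f"{path}: missing '# frame_rate=..' metadata line")
    markers: list[str] = []
    for col in df.columns:
        if "." not in col:
            raise StructureError(f"{path}: column {col!r} is not 'marker.axis'")
        m, axis = col.rsplit(".", 1)
        if axis not in ("x", "y", "z"):
            raise StructureError(f"{path}: unknown axis {axis!r} in column {col!r}")
        if m not in markers:
            markers.append(m)
    expected = [f"{m}.{a}" for m in markers for a in "xyz"]
    if list(df.columns) != expected:
        raise StructureError(f"{path}: columns must come in x,y,z triples per marker")
    pos = df.to_numpy(float).reshape(len(df), len(markers), 3)
    return MarkerTrajectories(
        markers, pos, float(meta["frame_rate"]),
        run_id=meta.get("run_id", ""), subject_id=meta.get("subject_id", ""),
        day_id=meta.get("day_id", ""),
    )


def write_marker_trajectories(traj: MarkerTrajectories, path) -> None:
    cols = [f"{m}.{a}" for m in traj.marker_names for a in "xyz"]
    df = pd.DataFrame(traj.positions.reshape(traj.n_frames, -1), columns=cols)
    with open(path, "w") as fh:
        fh.write(f"# frame_rate={traj.frame_rate} run_id={traj.run_id} "
                 f"subject_id={traj.subject_id} day_id={traj.day_id}\n")
        df.to_csv(fh, index=False)


def _read_c3d(path) -> MarkerTrajectories:
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise FormatError(
            "C3D support requires the optional 'ezc3d' package "
            "(pip install locostate[c3d]); the CSV dialect needs no extras"
        ) from exc
    c3d = ezc3d.c3d(str(path))  # pragma: no cover
    labels = [l.strip() for l in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    pts = np.asarray(c3d["data"]["points"])[:3]  # (3, markers, frames)
    return MarkerTrajectories(labels, np.transpose(pts, (2, 1, 0)), rate)


# ---------------------------------------------------------------------------
# Neural I/O
# ---------------------------------------------------------------------------

def read_neural_recording(data_path, sidecar_path) -> NeuralRecording:
    """Read a multichannel recording (CSV or flat float32) + YAML sidecar."""
    try:
        with open(sidecar_path) as fh:
            meta = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        raise FormatError(f"cannot read neural sidecar {sidecar_path}: {exc}") from exc
    for key in ("fs", "channels"):
        if key not in meta:
            raise FormatError(f"{sidecar_path}: sidecar missing {key!r}")
    names = [c["name"] for c in meta["channels"]]
    hemis = [c["hemisphere"] for c in meta["channels"]]
    fmt = meta.get("format", "csv")
    if fmt == "csv":
        df = pd.read_csv(data_path)
        missing = [n for n in names if n not in df.columns]
        if missing:
            raise StructureError(f"{data_path}: missing channel columns {missing}")
        sig = df[names].to_numpy(float).T
    elif fmt == "float32":
        raw = np.fromfile(data_path, dtype=np.float32)
        if raw.size % len(names):
            raise StructureError(f"{data_path}: size not divisible by channel count")
        sig = raw.reshape(-1, len(names)).T.astype(float)
    else:
        raise FormatError(f"unknown neural data format {fmt!r}")
    return NeuralRecording(names, sig, float(meta["fs"]), hemis,
                           run_id=str(meta.get("run_id", "")))


def write_neural_recording(rec: NeuralRecording, data_path, sidecar_path,
                           fmt: str = "csv") -> None:
    meta = {
        "fs": float(rec.fs),
        "run_id": rec.run_id,
        "format": fmt,
        "channels": [{"name": n, "hemisphere": h}
                     for n, h in zip(rec.channel_names, rec.hemispheres)],
    }
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(meta, fh)
    if fmt == "csv":
        pd.DataFrame(rec.signal.T, columns=rec.channel_names).to_csv(data_path, index=False)
    elif fmt == "float32":
        rec.signal.T.astype(np.float32).tofile(data_path)
    else:
        raise FormatError(f"unknown neural data format {fmt!r}")


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def read_event_table(path, vocabulary: tuple[str, ...] = RODENT_STATES,
                     trial_duration: float | None = None) -> EventTable:
    """Read a CSV of ``state,start,end`` rows (seconds) and validate it."""
    try:
        with open(path) as fh:
            meta = {}
            first = fh.readline()
            if first.startswith("#"):
                meta = _parse_meta_line(first)
            else:
                fh.seek(0)
            df = pd.read_csv(fh)
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot read event table {path}: {exc}") from exc
    for col in ("state", "start", "end"):
        if col not in df.columns:
            raise StructureError(f"{path}: missing column {col!r}")
    if trial_duration is None:
        if "trial_duration" in meta:
            trial_duration = float(meta["trial_duration"])
        else:
            trial_duration = float(df["end"].max()) if len(df) else 0.0
    events = list(zip(df["state"].astype(str), df["start"].astype(float),
                      df["end"].astype(float)))
    return EventTable(events, trial_duration, vocabulary)


def write_event_table(table: EventTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# trial_duration={table.trial_duration}\n")
        pd.DataFrame(table.events, columns=["state", "start", "end"]).to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Manifests and session loading
# ---------------------------------------------------------------------------

def read_manifest(path) -> list[SessionManifest]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    sessions = doc["sessions"] if isinstance(doc, dict) else doc
    return [SessionManifest(**s) for s in sessions]


def write_manifest(manifests: list[SessionManifest], path) -> None:
    doc = {"sessions": [vars(m).copy() for m in manifests]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class LoadResult:
    """Outcome of loading one session; ``ok=False`` carries a discard record."""

    manifest: SessionManifest
    ok: bool
    trajectories: MarkerTrajectories | None = None
    recording: NeuralRecording | None = None
    events: EventTable | None = None
    trimmed_frames: int = 0
    discard_reason: str = ""


def load_session(manifest: SessionManifest, mismatch_tolerance: int = 5,
                 vocabulary: tuple[str, ...] = RODENT_STATES) -> LoadResult:
    """Load one session, enforcing kinematic/neural length consistency.

    A kinematic file longer than the neural-implied frame count by at most
    ``mismatch_tolerance`` frames is trimmed from its start (extra frames are
    occasionally recorded before the neural stream begins). Longer mismatches
    reject the session with a discard record so that batch processing can
    continue; a kinematic file more than one frame short is likewise rejected
    because missing frames cannot be reconstructed.
    """
    manifest.validate_paths()
    traj = read_marker_trajectories(manifest.trajectory_path)
    rec = read_neural_recording(manifest.neural_path, manifest.neural_sidecar_path)
    events = read_event_table(manifest.events_path, vocabulary=vocabulary)
    expected = manifest.expected_frames
    if expected is None:
        expected = int(round(rec.duration * traj.frame_rate))
    mismatch = traj.n_frames - expected
    trimmed = 0
    if mismatch > mismatch_tolerance:
        reason = (f"kinematic/neural length mismatch of {mismatch} frames "
                  f"exceeds tolerance {mismatch_tolerance}")
        logger.warning("discarding session %s: %s", manifest.run_id, reason)
        return LoadResult(manifest, False, discard_reason=reason)
    if mismatch < -1:
        reason = f"kinematic file {-mismatch} frames shorter than neural recording"
        logger.warning("discarding session %s: %s", manifest.run_id, reason)
        return LoadResult(manifest, False, discard_reason=reason)
    if mismatch > 0:
        traj = MarkerTrajectories(
            traj.marker_names, traj.positions[mismatch:], traj.frame_rate,
            run_id=traj.run_id, subject_id=traj.subject_id, day_id=traj.day_id)
        trimmed = mismatch
        logger.info("trimmed %d leading frames from %s", mismatch, manifest.run_id)
    return LoadResult(manifest, True, traj, rec, events, trimmed_frames=trimmed)
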