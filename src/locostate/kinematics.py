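"""Sliding-window kinematic features from marker trajectories.

Features are computed one output sample per input frame (window of two
frames, hop of one frame), so the feature rate equals the capture frame
rate — 200 Hz for the rodent setup, 100 Hz for the human setup. Derivatives
use forward first differences with the leading sample(s) back-filled so the
feature matrix keeps the frame count of the trajectory.

Categories (per marker / per configured angle triple):

* speed ``|dP| * frame_rate`` in mm/s, acceleration ``|d2P| * frame_rate^2``
  in mm/s^2, tangential acceleration ``d(speed) * frame_rate`` in mm/s^2
* joint angle at the middle marker of a triple (degrees), its velocity and
  acceleration (deg/s, deg/s^2)
* height: z of the reference marker (mm), and forward movement: per-frame
  displacement of the reference marker along the travel axis, sign-normalized
  so that travel in either runway direction yields positive forward values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import FeatureMatrix
from .errors import (AmbiguousDirectionError, ConfigurationError,
                     DegenerateGeometryError, InsufficientDataError,
                     ValidationError)
from .io import MarkerTrajectories


@dataclass
class SkeletonConfig:
    """Declarative description of which kinematic features to compute."""

    markers: list[str] | None = None  # None = all markers in the file
    angles: list[tuple[str, str, str]] = field(default_factory=list)
    reference_marker: str = "toe"
    include_speed: bool = True
    include_acceleration: bool = True
    include_tangential_acceleration: bool = True
    include_angles: bool = True
    include_height: bool = True
    include_forward_movement: bool = True
    gap_max_frames: int = 10
    min_valid_fraction: float = 0.7

    def __post_init__(self):
        self.angles = [tuple(t) for t in self.angles]
        for triple in self.angles:
            if len(triple) != 3:
                raise ConfigurationError(f"angle triple {triple} must have 3 markers")

    def validate(self, marker_names: list[str]) -> None:
        wanted = self.markers if self.markers is not None else marker_names
        missing = [m for m in wanted if m not in marker_names]
        if missing:
            raise ConfigurationError(f"skeleton references unknown markers {missing}")
        for triple in self.angles:
            for m in triple:
                if m not in marker_names:
                    raise ConfigurationError(f"angle triple {triple} references unknown marker {m!r}")
        if self.reference_marker not in marker_names:
            raise ConfigurationError(f"reference marker {self.reference_marker!r} not in trajectory")

    def feature_names(self, marker_names: list[str]) -> list[str]:
        """Deterministic feature list for a given marker set."""
        markers = [m for m in (self.markers or marker_names) if m in marker_names]
        names: list[str] = []
        if self.include_speed:
            names += [f"speed {m}" for m in markers]
        if self.include_acceleration:
            names += [f"acceleration {m}" for m in markers]
        if self.include_tangential_acceleration:
            names += [f"tangential acceleration {m}" for m in markers]
        if self.include_angles:
            for a, b, c in self.angles:
                names += [f"angle {a}-{b}-{c}", f"angle velocity {a}-{b}-{c}",
                          f"angle acceleration {a}-{b}-{c}"]
        if self.include_height:
            names.append(f"height {self.reference_marker}")
        if self.include_forward_movement:
            names.append(f"forward movement {self.reference_marker}")
        return names

    def to_yaml(self, path) -> None:
        doc = vars(self).copy()
        doc["angles"] = [list(t) for t in self.angles]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @staticmethod
    def from_yaml(path) -> "SkeletonConfig":
        with open(path) as fh:
            return SkeletonConfig(**yaml.safe_load(fh))


def rodent_skeleton() -> SkeletonConfig:
    """Hindlimb skeleton fixture mirroring the runway marker set."""
    return SkeletonConfig(
        markers=["shoulder", "crest", "hip", "knee", "ankle", "toe"],
        angles=[("crest", "hip", "knee"), ("hip", "knee", "ankle"),
                ("knee", "ankle", "toe")],
        reference_marker="toe",
    )


def joint_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Angle at ``b`` (degrees, in [0, 180]) between limbs b->a and b->c."""
    a, b, c = (np.atleast_2d(np.asarray(x, dtype=float)) for x in (a, b, c))
    if not (a.shape == b.shape == c.shape):
        raise ValidationError("marker series must have equal shapes")
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    bad = np.flatnonzero((nu == 0) | (nv == 0))
    if bad.size:
        raise DegenerateGeometryError(
            f"zero-length limb vector at frame {int(bad[0])}")
    cosang = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def derive_travel_direction(traj: MarkerTrajectories, reference_marker: str,
                            min_displacement: float = 10.0) -> int:
    """Sign (+1/-1) of the net x displacement of the reference marker."""
    x = traj.marker(reference_marker)[:, 0]
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise AmbiguousDirectionError("too few valid frames to infer direction")
    net = x[-1] - x[0]
    if abs(net) < min_displacement:
        raise AmbiguousDirectionError(
            f"net displacement {net:.3g} mm below minimum {min_displacement} mm")
    return 1 if net > 0 else -1


def interpolate_gaps(traj: MarkerTrajectories, gap_max_frames: int = 10,
                     min_valid_fraction: float = 0.7):
    """Fill short gaps linearly; reject markers with long gaps or sparse data.

    Returns ``(cleaned trajectory, rejected marker list)``. Mirrors the
    at-least-70%-of-points rule applied per marker.
    """
    pos = traj.positions.copy()
    n = traj.n_frames
    keep, rejected = [], []
    for j, name in enumerate(traj.marker_names):
        miss = np.isnan(pos[:, j, :]).any(axis=1)
        if not miss.any():
            keep.append(j)
            continue
        if (1 - miss.mean()) < min_valid_fraction:
            rejected.append(name)
            continue
        # longest internal gap
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, miss.view(np.int8), 0])))[::2]
        if miss[0] or miss[-1] or (runs.size and runs.max() > gap_max_frames):
            rejected.append(name)
            continue
        valid = ~miss
        idx = np.arange(n)
        for ax in range(3):
            pos[miss, j, ax] = np.interp(idx[miss], idx[valid], pos[valid, j, ax])
        keep.append(j)
    cleaned = MarkerTrajectories(
        [traj.marker_names[j] for j in keep], pos[:, keep, :], traj.frame_rate,
        run_id=traj.run_id, subject_id=traj.subject_id, day_id=traj.day_id)
    return cleaned, rejected


def _backfilled_diff(x: np.ndarray, order: int = 1) -> np.ndarray:
    """Forward difference along axis 0, back-filled to keep the length."""
    d = np.diff(x, n=order, axis=0)
    pad = np.repeat(d[:1], order, axis=0)
    return np.concatenate([pad, d], axis=0)


def compute_kinematic_features(traj: MarkerTrajectories,
                               skeleton: SkeletonConfig,
                               direction: int | None = None) -> FeatureMatrix:
    """Sliding-window kinematic feature matrix at the frame rate.

    ``direction`` (+1/-1) normalizes the forward-movement sign; when None it
    is derived from the reference marker's net displacement, falling back to
    +1 if the run has no net displacement (e.g. no gait at all).
    """
    if traj.n_frames < 3:
        raise InsufficientDataError("need at least 3 frames for second differences")
    traj, rejected = interpolate_gaps(traj, skeleton.gap_max_frames,
                                      skeleton.min_valid_fraction)
    skeleton.validate(traj.marker_names)
    fr = traj.frame_rate
    markers = [m for m in (skeleton.markers or traj.marker_names)
               if m in traj.marker_names]
    cols: list[np.ndarray] = []
    names: list[str] = []

    speeds = {}
    for m in markers:
        p = traj.marker(m)
        speeds[m] = np.linalg.norm(_backfilled_diff(p), axis=1) * fr
    if skeleton.include_speed:
        for m in markers:
            cols.append(speeds[m])
            names.append(f"speed {m}")
    if skeleton.include_acceleration:
        for m in markers:
            p = traj.marker(m)
            cols.append(np.linalg.norm(_backfilled_diff(p, 2), axis=1) * fr ** 2)
            names.append(f"acceleration {m}")
    if skeleton.include_tangential_acceleration:
        for m in markers:
            cols.append(_backfilled_diff(speeds[m]) * fr)
            names.append(f"tangential acceleration {m}")
    if skeleton.include_angles:
        for a, b, c in skeleton.angles:
            ang = joint_angle(traj.marker(a), traj.marker(b), traj.marker(c))
            cols += [ang, _backfilled_diff(ang) * fr,
                     _backfilled_diff(ang, 2) * fr ** 2]
            names += [f"angle {a}-{b}-{c}", f"angle velocity {a}-{b}-{c}",
                      f"angle acceleration {a}-{b}-{c}"]
    ref = traj.marker(skeleton.reference_marker)
    if skeleton.include_height:
        cols.append(ref[:, 2])
        names.append(f"height {skeleton.reference_marker}")
    if skeleton.include_forward_movement:
        if direction is None:
            try:
                direction = derive_travel_direction(traj, skeleton.reference_marker)
            except AmbiguousDirectionError:
                direction = 1
        cols.append(_backfilled_diff(ref[:, 0]) * direction)
        names.append(f"forward movement {skeleton.reference_marker}")

    fm = FeatureMatrix(np.column_stack(cols), names, traj.times, fr,
                       run_ids=traj.run_id, subject_ids=traj.subject_id,
                       day_ids=traj.day_id)
    fm.rejected_markers = rejected  # type: ignore[attr-defined]
    return fm
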