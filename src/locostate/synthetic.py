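"""Seeded synthetic multimodal sessions with known ground-truth structure.

The generator emulates the statistical structure the analyses assume, not
biophysics: semi-Markov locomotor state sequences; gait as sinusoidal limb
oscillation riding on forward drift versus near-zero akinetic motion; and
neural channels built from 1/f background plus state-gated band-limited
oscillators. Akinesia gates a strong 20-42 Hz (HB-LG) component together
with a steep low-frequency component — spreading the spectrum, which raises
Hjorth complexity and lowers mobility — while gait gates a 60-90 Hz gamma
component that raises mobility. Transitions are smoothed over ~100 ms.

Group structure mirrors a unilateral-lesion cohort: lesioned subjects dwell
far longer in akinesia than shams, and the lesioned (left) hemisphere
carries the stronger HB-LG effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .io import (HUMAN_STATES, RODENT_STATES, EventTable, MarkerTrajectories,
                 NeuralRecording, SessionManifest, write_event_table,
                 write_manifest, write_marker_trajectories,
                 write_neural_recording)

# resting pose of the hindlimb marker chain, mm (x = runway axis, z = up)
_BASE_POSE = {
    "shoulder": (0.0, 0.0, 90.0),
    "crest": (-40.0, 0.0, 80.0),
    "hip": (-60.0, 0.0, 70.0),
    "knee": (-70.0, 10.0, 40.0),
    "ankle": (-75.0, 10.0, 20.0),
    "toe": (-80.0, 15.0, 0.0),
}


@dataclass
class StateNeuralProfile:
    """Per-state spectral recipe: amplitudes are envelope sd in µV.

    ``low_amp`` is a 2-8 Hz component (lowers Hjorth mobility, and raises
    complexity when mixed with a narrowband); ``white_amp`` is broadband
    noise used to keep total power comparable across states so that signal
    variance itself carries little state information.
    """

    hblg_amp: float = 0.0
    gamma_amp: float = 0.0
    low_amp: float = 0.0
    white_amp: float = 0.0
    extra_bands: tuple = ()  # ((f_lo, f_hi, amp), ...) shape-matching bands


@dataclass
class CohortSpec:
    """Study-condition parameters of the synthetic rodent cohort."""

    n_sham: int = 8
    n_lesioned: int = 6
    runs_per_sham: int = 5
    lesioned_total_runs: int = 55  # distributed round-robin over subjects
    run_duration: float = 12.0
    frame_rate: float = 200.0
    neural_fs: float = 1000.0
    runs_per_day: int = 3
    seed: int = 0
    # semi-Markov mean dwells (s) per group and state
    dwell_means: dict = field(default_factory=lambda: {
        "sham": {"gait": 4.0, "stationary": 2.0, "akinesia": 0.8},
        "lesioned": {"gait": 2.0, "stationary": 2.0, "akinesia": 4.0},
    })
    min_dwell: float = 0.5
    # kinematic profile
    gait_speed: float = 300.0       # mm/s forward drift during gait
    gait_amplitude: float = 15.0    # mm limb oscillation
    stride_freq: float = 4.0        # Hz
    stationary_jitter: float = 2.0  # mm sd
    akinesia_jitter: float = 0.1    # mm sd
    # neural profile
    background_sd: float = 5.0      # µV pink background
    background_exponent: float = 1.0
    # per-hemisphere, per-state recipes: the lesioned (left) hemisphere
    # carries the HB-LG/complexity signature of akinesia, the healthy
    # (right) hemisphere the gamma/mobility signature of movement
    # The lesioned (left) hemisphere is the only place where akinesia and
    # stationary movement differ — and they differ exactly in the HB-LG
    # band; the stationary recipe mimics akinesia's Hjorth signature with
    # shape-matching off-band components. The healthy (right) hemisphere
    # carries the gamma/mobility signature of gait and is blind to the
    # akinesia/stationary distinction.
    neural_profiles: dict = field(default_factory=lambda: {
        "left": {
            "akinesia": StateNeuralProfile(hblg_amp=7.3, low_amp=2.0),
            "stationary": StateNeuralProfile(low_amp=2.0,
                                             extra_bands=((8, 16, 6.0),
                                                          (45, 70, 4.0))),
            "gait": StateNeuralProfile(white_amp=7.5),
        },
        "right": {
            "akinesia": StateNeuralProfile(low_amp=5.0, white_amp=2.8,
                                           extra_bands=((8, 16, 5.0),)),
            "stationary": StateNeuralProfile(low_amp=5.0, white_amp=2.8,
                                             extra_bands=((8, 16, 5.0),)),
            "gait": StateNeuralProfile(gamma_amp=7.0, white_amp=3.0),
        },
    })
    low_band: tuple = (2.0, 8.0)
    transition_smoothing: float = 0.1  # s

    @staticmethod
    def embedding_testbed(seed: int = 0, n_subjects: int = 3,
                          runs_per_subject: int = 3,
                          run_duration: float = 30.0) -> "CohortSpec":
        """Three-state separability testbed: balanced, long dwells.

        With a 1-s causal receptive field, windows inside the first second
        of a state are intrinsically ambiguous; long balanced dwells keep
        that fraction small so decoding quality reflects the embedding, not
        label ambiguity at transitions.
        """
        return CohortSpec(
            n_sham=0, n_lesioned=n_subjects, runs_per_sham=0,
            lesioned_total_runs=n_subjects * runs_per_subject,
            run_duration=run_duration, seed=seed,
            dwell_means={
                "sham": {"gait": 5.0, "stationary": 5.0, "akinesia": 1.0},
                "lesioned": {"gait": 6.0, "stationary": 6.0, "akinesia": 6.0},
            })

    @staticmethod
    def recovery_testbed(seed: int = 0, n_subjects: int = 3,
                         runs_per_subject: int = 3,
                         run_duration: float = 15.0) -> "CohortSpec":
        """Biomarker-recovery testbed: lesioned-only cohort, moderate dwells.

        Used for checking that the injected neural biomarkers dominate the
        model-importance rankings; dwells are long enough that
        transition-window ambiguity contributes little ranking noise.
        """
        return CohortSpec(
            n_sham=0, n_lesioned=n_subjects, runs_per_sham=0,
            lesioned_total_runs=n_subjects * runs_per_subject,
            run_duration=run_duration, seed=seed,
            dwell_means={
                "sham": {"gait": 4.0, "stationary": 2.0, "akinesia": 0.8},
                "lesioned": {"gait": 4.0, "stationary": 4.0, "akinesia": 5.0},
            })

    def subject_ids(self) -> list[tuple[str, str]]:
        """(subject_id, group) in generation order."""
        return ([(f"sham{i + 1:02d}", "sham") for i in range(self.n_sham)]
                + [(f"les{i + 1:02d}", "lesioned") for i in range(self.n_lesioned)])

    def runs_for(self, group: str, subject_index: int) -> int:
        if group == "sham":
            return self.runs_per_sham
        base, extra = divmod(self.lesioned_total_runs, self.n_lesioned)
        return base + (1 if subject_index < extra else 0)


def _truncated_exp(rng: np.random.Generator, mean: float, lo: float, hi: float) -> float:
    return float(np.clip(rng.exponential(mean), lo, hi))


def generate_state_sequence(dwell_means: dict[str, float], duration: float,
                            rng: np.random.Generator, min_dwell: float = 0.5,
                            vocabulary=RODENT_STATES) -> EventTable:
    """Alternating-state semi-Markov sequence covering the whole run."""
    states = list(dwell_means)
    if duration <= min_dwell:
        raise ValueError("duration must exceed the minimum dwell")
    events = []
    t = 0.0
    # first state drawn proportional to mean dwell (occupancy-weighted)
    weights = np.array([dwell_means[s] for s in states])
    current = states[rng.choice(len(states), p=weights / weights.sum())]
    while t < duration - 1e-9:
        dwell = _truncated_exp(rng, dwell_means[current], min_dwell, duration)
        end = min(t + dwell, duration)
        if duration - end < min_dwell:  # absorb a too-short tail
            end = duration
        events.append((current, t, end))
        t = end
        others = [s for s in states if s != current]
        w = np.array([dwell_means[s] for s in others])
        current = others[rng.choice(len(others), p=w / w.sum())]
    return EventTable(events, duration, vocabulary)


def _state_envelope(events: EventTable, state: str, n: int, fs: float,
                    smoothing: float) -> np.ndarray:
    t = np.arange(n) / fs
    gate = np.zeros(n)
    for t0, t1 in events.occurrences(state):
        gate[(t >= t0) & (t < t1)] = 1.0
    if smoothing > 0:
        gate = gaussian_filter1d(gate, smoothing * fs / 2.0)
    return gate


def _pink_noise(n: int, fs: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_noise(n: int, fs: float, lo: float, hi: float,
                rng: np.random.Generator) -> np.ndarray:
    sos = sps.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _smooth_jitter(n: int, fs: float, sd: float, cutoff: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Low-passed Gaussian jitter with the requested sd."""
    x = gaussian_filter1d(rng.standard_normal(n), fs / (2.0 * np.pi * cutoff))
    s = x.std()
    return x / s * sd if s > 0 else x


def generate_kinematics(spec: CohortSpec, events: EventTable,
                        rng: np.random.Generator, run_id: str = "",
                        subject_id: str = "", day_id: str = "",
                        frame_rate: float | None = None) -> MarkerTrajectories:
    fr = frame_rate or spec.frame_rate
    n = int(round(events.trial_duration * fr))
    gait = _state_envelope(events, "gait", n, fr, spec.transition_smoothing)
    stat_states = [s for s in events.vocabulary if s not in ("gait",)]
    markers = list(_BASE_POSE)
    pos = np.zeros((n, len(markers), 3))
    t = np.arange(n) / fr
    drift = np.cumsum(gait) / fr * spec.gait_speed  # forward progress in mm
    # state-dependent jitter amplitude per sample
    jitter_amp = np.zeros(n)
    for s in stat_states:
        amp = spec.akinesia_jitter if s in ("akinesia", "fog") else spec.stationary_jitter
        jitter_amp += amp * _state_envelope(events, s, n, fr, spec.transition_smoothing)
    for j, name in enumerate(markers):
        base = np.array(_BASE_POSE[name])
        phase = rng.uniform(0, 2 * np.pi)
        # limb oscillation only during gait, stronger distally
        distal = 0.3 + 0.7 * j / (len(markers) - 1)
        osc_x = spec.gait_amplitude * distal * np.sin(2 * np.pi * spec.stride_freq * t + phase)
        osc_z = 0.4 * spec.gait_amplitude * distal * np.sin(
            4 * np.pi * spec.stride_freq * t + phase)
        jit = np.column_stack([
            _smooth_jitter(n, fr, 1.0, 5.0, rng) for _ in range(3)]) * jitter_amp[:, None]
        pos[:, j, 0] = base[0] + drift + gait * osc_x + jit[:, 0]
        pos[:, j, 1] = base[1] + jit[:, 1]
        pos[:, j, 2] = base[2] + gait * np.abs(osc_z) + jit[:, 2]
    return MarkerTrajectories(markers, pos, fr, run_id=run_id,
                              subject_id=subject_id, day_id=day_id)


def generate_neural(spec: CohortSpec, events: EventTable,
                    rng: np.random.Generator, run_id: str = "",
                    channels=(("M1", "left"), ("M1", "right")),
                    fs: float | None = None) -> NeuralRecording:
    fs = fs or spec.neural_fs
    n = int(round(events.trial_duration * fs))
    envs = {s: _state_envelope(events, s, n, fs, spec.transition_smoothing)
            for s in events.vocabulary}
    sig = np.zeros((len(channels), n))
    names, hemis = [], []
    for ci, (name, hemi) in enumerate(channels):
        x = spec.background_sd * _pink_noise(n, fs, spec.background_exponent, rng)
        hblg_env = np.zeros(n)
        gamma_env = np.zeros(n)
        low_env = np.zeros(n)
        white_env = np.zeros(n)
        extra_envs: dict[tuple, np.ndarray] = {}
        for s, prof in spec.neural_profiles[hemi].items():
            if s not in envs:
                continue
            hblg_env += prof.hblg_amp * envs[s]
            gamma_env += prof.gamma_amp * envs[s]
            low_env += prof.low_amp * envs[s]
            white_env += prof.white_amp * envs[s]
            for lo, hi, amp in prof.extra_bands:
                key = (float(lo), float(hi))
                extra_envs[key] = extra_envs.get(key, 0.0) + amp * envs[s]
        x = x + hblg_env * _band_noise(n, fs, 20.0, 42.0, rng)
        x = x + gamma_env * _band_noise(n, fs, 60.0, 90.0, rng)
        x = x + low_env * _band_noise(n, fs, *spec.low_band, rng)
        x = x + white_env * rng.standard_normal(n)
        for (lo, hi), env in extra_envs.items():
            x = x + env * _band_noise(n, fs, lo, hi, rng)
        sig[ci] = x
        names.append(f"{name}{ci}" if len(channels) > 2 else name)
        hemis.append(hemi)
    # distinct default channel names for the two-channel rodent montage
    if len(channels) == 2 and names[0] == names[1]:
        names = [f"{names[0]}L", f"{names[1]}R"]
    return NeuralRecording(names, sig, fs, hemis, run_id=run_id)


def generate_session(spec: CohortSpec, group: str = "lesioned",
                     run_id: str = "run0", subject_id: str = "subj0",
                     day_id: str = "day0", seed: int | None = None,
                     rng: np.random.Generator | None = None):
    """One synchronized (trajectories, recording, events) triple."""
    if rng is None:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
    events = generate_state_sequence(spec.dwell_means[group],
                                     spec.run_duration, rng, spec.min_dwell)
    traj = generate_kinematics(spec, events, rng, run_id, subject_id, day_id)
    rec = generate_neural(spec, events, rng, run_id)
    return traj, rec, events


@dataclass
class SessionRecord:
    subject_id: str
    group: str
    run_id: str
    day_id: str
    trajectories: MarkerTrajectories
    recording: NeuralRecording
    events: EventTable


def generate_cohort(spec: CohortSpec, outdir=None, signals: bool = True):
    """Reproducible cohort; optionally written as CSV files + YAML manifest.

    With ``signals=False`` only the event tables are generated (state
    occupancy analyses do not need the signal content). Returns
    ``(records, manifests)``; manifests are None unless ``outdir`` is given.
    """
    root = np.random.SeedSequence(spec.seed)
    records: list[SessionRecord] = []
    manifests: list[SessionManifest] | None = [] if outdir is not None else None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    subjects = spec.subject_ids()
    total_runs = spec.n_sham * spec.runs_per_sham + spec.lesioned_total_runs
    seq_iter = iter(root.spawn(total_runs))
    les_index = 0
    for sid, group in subjects:
        n_runs = spec.runs_for(group, les_index if group == "lesioned" else 0)
        if group == "lesioned":
            les_index += 1
        for r in range(n_runs):
            rng = np.random.default_rng(next(seq_iter))
            run_id = f"{sid}_r{r + 1:02d}"
            day_id = f"day{r // spec.runs_per_day + 1}"
            events = generate_state_sequence(spec.dwell_means[group],
                                             spec.run_duration, rng, spec.min_dwell)
            if signals:
                traj = generate_kinematics(spec, events, rng, run_id, sid, day_id)
                rec = generate_neural(spec, events, rng, run_id)
            else:
                traj = rec = None
            records.append(SessionRecord(sid, group, run_id, day_id, traj, rec, events))
            if outdir is not None and signals:
                tpath = outdir / f"{run_id}_traj.csv"
                npath = outdir / f"{run_id}_neural.csv"
                spath = outdir / f"{run_id}_neural.yaml"
                epath = outdir / f"{run_id}_events.csv"
                write_marker_trajectories(traj, tpath)
                write_neural_recording(rec, npath, spath)
                write_event_table(events, epath)
                manifests.append(SessionManifest(
                    str(tpath), str(npath), str(spath), str(epath),
                    run_id=run_id, subject_id=sid, day_id=day_id, group=group))
    if outdir is not None and manifests:
        write_manifest(manifests, Path(outdir) / "manifest.yaml")
    return records, manifests


# ---------------------------------------------------------------------------
# Human freezing-of-gait variant
# ---------------------------------------------------------------------------

@dataclass
class HumanCohortSpec:
    """Walkway sessions for FoG analysis: gait/fog states, STN-like channels."""

    n_patients: int = 2
    runs_per_patient: int = 4
    run_duration: float = 25.0
    frame_rate: float = 100.0
    lfp_fs: float = 250.0
    seed: int = 0
    dwell_means: dict = field(default_factory=lambda: {"gait": 6.0, "fog": 4.0})
    min_dwell: float = 1.0
    # per-patient effect scale (patient 1 of the study showed no modulation)
    effect_scale: list = field(default_factory=lambda: [1.0, 1.0])
    # fog gates: beta (13-20) up, broadband slow up (complexity up / mobility
    # down), gamma up — and one channel per hemisphere carries the strongest
    # beta modulation
    beta_amp: float = 6.0
    gamma_amp: float = 2.0
    slow_amp: float = 8.0   # 2-8 Hz mass: drives complexity up, mobility down
    slow_band: tuple = (2.0, 8.0)
    channel_beta_scale: list = field(
        default_factory=lambda: [1.0, 0.4, 0.4])  # per contact pair, both sides
    background_sd: float = 5.0
    gait_speed: float = 900.0
    gait_amplitude: float = 40.0
    stride_freq: float = 1.8
    fog_jitter: float = 1.0


def generate_human_session(spec: HumanCohortSpec, patient_index: int = 1,
                           run_id: str = "walk1", seed: int | None = None,
                           rng: np.random.Generator | None = None,
                           direction: int = 1):
    """(trajectories, recording, events) for one walkway bout.

    ``direction`` is +1/-1: patients walk the 10 m walkway back and forth,
    so alternate bouts progress in the -x direction.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
    events = generate_state_sequence(spec.dwell_means, spec.run_duration, rng,
                                     spec.min_dwell, vocabulary=HUMAN_STATES)
    kin_spec = CohortSpec(run_duration=spec.run_duration,
                          frame_rate=spec.frame_rate,
                          gait_speed=spec.gait_speed * direction,
                          gait_amplitude=spec.gait_amplitude,
                          stride_freq=spec.stride_freq,
                          akinesia_jitter=spec.fog_jitter)
    traj = generate_kinematics(kin_spec, events, rng, run_id,
                               subject_id=f"patient{patient_index + 1}",
                               frame_rate=spec.frame_rate)
    fs = spec.lfp_fs
    n = int(round(spec.run_duration * fs))
    fog = _state_envelope(events, "fog", n, fs, 0.1)
    scale = spec.effect_scale[patient_index]
    sig, names, hemis = [], [], []
    for hemi, tag in (("left", "L"), ("right", "R")):
        for pi, pair in enumerate(("02", "13", "03")):
            x = spec.background_sd * _pink_noise(n, fs, 1.0, rng)
            cscale = spec.channel_beta_scale[pi]
            x = x + scale * cscale * spec.beta_amp * fog * _band_noise(n, fs, 13, 20, rng)
            x = x + scale * spec.gamma_amp * fog * _band_noise(n, fs, 60, 90, rng)
            x = x + scale * spec.slow_amp * fog * _band_noise(n, fs, *spec.slow_band, rng)
            sig.append(x)
            names.append(f"STN{tag}{pair}")
            hemis.append(hemi)
    rec = NeuralRecording(names, np.array(sig), fs, hemis, run_id=run_id)
    return traj, rec, events


def generate_human_cohort(spec: HumanCohortSpec):
    """List of (patient_id, run_id, trajectories, recording, events)."""
    root = np.random.SeedSequence(spec.seed)
    seqs = iter(root.spawn(spec.n_patients * spec.runs_per_patient))
    out = []
    for p in range(spec.n_patients):
        for r in range(spec.runs_per_patient):
            rng = np.random.default_rng(next(seqs))
            run_id = f"patient{p + 1}_walk{r + 1}"
            traj, rec, events = generate_human_session(
                spec, p, run_id, rng=rng, direction=1 if r % 2 == 0 else -1)
            out.append((f"patient{p + 1}", run_id, traj, rec, events))
    return out
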