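"""Per-window neural features and state-specific spectral summaries.

The feature panel per channel is: the three Hjorth parameters (activity =
variance, mobility = sqrt(var(dx)/var(x)) — the mean frequency content in
per-sample radians — and complexity = mobility(dx)/mobility(x), the
deviation from a pure sine wave, which is exactly 1 for a sinusoid), the
log band amplitude of each configured band (Hann periodogram), and
optionally burst rate/duration for bands where transient events matter.

Features are computed on a trailing (causal) estimation window ending at
each output sample, at a configurable feature rate (200 Hz rodent,
100 Hz human), so they align sample-for-sample with kinematic features.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .core import FeatureMatrix
from .errors import (ConfigurationError, DegenerateSignalError,
                     InsufficientDataError)
from .io import EventTable, NeuralRecording

HBLG_BAND = (20.0, 42.0)  # high-beta / low-gamma, the pathological band


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not 0 < self.f_lo < self.f_hi:
            raise ConfigurationError(f"invalid band {self.name}: [{self.f_lo}, {self.f_hi}]")

    def validate(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ConfigurationError(
                f"band {self.name} upper edge {self.f_hi} Hz >= Nyquist {fs / 2} Hz")


def rodent_bands() -> list[BandDefinition]:
    return [BandDefinition("HB-LG", *HBLG_BAND), BandDefinition("gamma", 60.0, 90.0)]


def human_bands() -> list[BandDefinition]:
    return [BandDefinition("beta", 13.0, 20.0), BandDefinition("gamma", 60.0, 90.0)]


@dataclass(frozen=True)
class HjorthTriple:
    activity: float
    mobility: float
    complexity: float


def hjorth_parameters(window: np.ndarray) -> HjorthTriple:
    """Hjorth activity / mobility / complexity of one signal segment."""
    x = np.asarray(window, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("Hjorth parameters need at least 3 samples")
    if not np.all(np.isfinite(x)):
        raise DegenerateSignalError("non-finite values in signal segment")
    v0 = np.var(x)
    d1 = np.diff(x)
    v1 = np.var(d1)
    if v0 == 0 or v1 == 0:
        raise DegenerateSignalError("zero variance: Hjorth ratios undefined")
    v2 = np.var(np.diff(d1))
    mob = np.sqrt(v1 / v0)
    return HjorthTriple(float(v0), float(mob), float(np.sqrt(v2 / v1) / mob))


def sinusoid_mobility(f: float, fs: float) -> float:
    """Closed-form first-difference mobility of a sampled sinusoid."""
    return 2.0 * np.sin(np.pi * f / fs)


def _hann_periodogram(frames: np.ndarray, fs: float):
    """Hann-windowed periodogram density for a (n_windows, W) frame block."""
    w = np.hanning(frames.shape[-1])
    scale = 1.0 / (fs * (w ** 2).sum())
    spec = np.fft.rfft(frames * w, axis=-1)
    psd = (spec.real ** 2 + spec.imag ** 2) * scale
    psd[..., 1:] *= 2.0
    if frames.shape[-1] % 2 == 0:
        psd[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(frames.shape[-1], 1.0 / fs)
    return freqs, psd


def band_amplitude(window: np.ndarray, band: BandDefinition, fs: float,
                   eps: float = 1e-20) -> float:
    """Log mean Hann-periodogram power within the band."""
    band.validate(fs)
    x = np.asarray(window, dtype=float)
    if x.size < 2 * fs / band.f_lo:
        raise InsufficientDataError(
            f"window of {x.size} samples is shorter than 2 cycles of {band.f_lo} Hz")
    freqs, psd = _hann_periodogram(x[None, :], fs)
    sel = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    return float(np.log(max(psd[0, sel].mean(), eps)))


def band_envelope(x: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Amplitude envelope of the band-passed signal (4th-order Butterworth + Hilbert)."""
    band.validate(fs)
    sos = sps.butter(4, [band.f_lo, band.f_hi], btype="band", fs=fs, output="sos")
    return np.abs(sps.hilbert(sps.sosfiltfilt(sos, np.asarray(x, dtype=float))))


def _burst_segments(envelope: np.ndarray, threshold: float):
    """(onset index, length) of contiguous supra-threshold excursions."""
    above = envelope > threshold
    edges = np.diff(np.r_[0, above.view(np.int8), 0])
    onsets = np.flatnonzero(edges == 1)
    offsets = np.flatnonzero(edges == -1)
    return onsets, offsets - onsets


def burst_metrics(window: np.ndarray, band: BandDefinition, fs: float,
                  threshold_pct: float = 75.0,
                  threshold: float | None = None) -> tuple[float, float]:
    """(burst rate in bursts/s, mean burst duration in s) for one segment.

    ``threshold`` overrides the percentile when run-level calibration
    statistics are available; otherwise the percentile is taken over this
    segment's own envelope.
    """
    if not 0 < threshold_pct < 100:
        raise ConfigurationError("threshold_pct must be in (0, 100)")
    env = band_envelope(window, band, fs)
    if threshold is None:
        threshold = float(np.percentile(env, threshold_pct))
    onsets, lengths = _burst_segments(env, threshold)
    rate = len(onsets) / (len(env) / fs)
    duration = float(lengths.mean() / fs) if len(onsets) else 0.0
    return float(rate), duration


def resample_recording(rec: NeuralRecording, target_fs: float) -> NeuralRecording:
    """Anti-aliased resampling (polyphase) to the analysis rate.

    Raw acquisition rates (e.g. 24,414.1 Hz) carry no information for bands
    below 100 Hz; analysis runs at 1,000 Hz by default.
    """
    if target_fs >= rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    out = sps.resample_poly(rec.signal, frac.numerator, frac.denominator, axis=1)
    return NeuralRecording(rec.channel_names, out, rec.fs * frac.numerator / frac.denominator,
                           rec.hemispheres, run_id=rec.run_id)


def _hemi_suffix(hemisphere: str) -> str:
    return "(L)" if hemisphere == "left" else "(R)"


def extract_neural_features(rec: NeuralRecording,
                            bands: list[BandDefinition] | None = None,
                            feature_rate: float = 200.0,
                            est_window: float = 1.0,
                            burst_bands: list[BandDefinition] | None = None,
                            burst_threshold_pct: float = 75.0,
                            run_id: str | None = None,
                            subject_id: str = "",
                            day_id: str = "") -> FeatureMatrix:
    """Causal per-window neural features at the feature rate.

    For output sample ``i`` the estimation window is the trailing
    ``est_window`` seconds of signal ending at that sample; output samples
    whose full window precedes the recording start are back-filled with the
    first valid value so the matrix aligns with the kinematic timeline.
    """
    if bands is None:
        bands = rodent_bands()
    fs = rec.fs
    if feature_rate > fs:
        raise ConfigurationError("feature_rate cannot exceed the sampling rate")
    hop = fs / feature_rate
    if abs(hop - round(hop)) > 1e-9:
        raise ConfigurationError(
            f"fs {fs} must be an integer multiple of feature_rate {feature_rate}; "
            "resample the recording first")
    hop = int(round(hop))
    W = int(round(est_window * fs))
    if W < 3:
        raise InsufficientDataError("est_window too short (need >= 3 samples)")
    if rec.n_samples < W:
        raise InsufficientDataError(
            f"recording of {rec.n_samples} samples shorter than est_window {W}")
    for b in bands:
        b.validate(fs)
    n_out = rec.n_samples // hop
    first_valid = int(np.ceil(W / hop)) - 1
    ends = (np.arange(first_valid, n_out) + 1) * hop  # exclusive window ends
    starts = ends - W

    all_cols: list[np.ndarray] = []
    names: list[str] = []
    for ci, (ch, hemi) in enumerate(zip(rec.channel_names, rec.hemispheres)):
        x = rec.signal[ci].astype(np.float64)
        view = sliding_window_view(x, W)
        suffix = f"{ch} {_hemi_suffix(hemi)}"
        cols = {f"Hjorth activity {suffix}": np.empty(len(starts)),
                f"Hjorth mobility {suffix}": np.empty(len(starts)),
                f"Hjorth complexity {suffix}": np.empty(len(starts))}
        for b in bands:
            cols[f"{b.name} amplitude {suffix}"] = np.empty(len(starts))
        chunk = 4096
        freqs = np.fft.rfftfreq(W, 1.0 / fs)
        band_sel = {b.name: (freqs >= b.f_lo) & (freqs <= b.f_hi) for b in bands}
        for s0 in range(0, len(starts), chunk):
            sl = slice(s0, min(s0 + chunk, len(starts)))
            frames = view[starts[sl]]
            v0 = frames.var(axis=1)
            d1 = np.diff(frames, axis=1)
            v1 = d1.var(axis=1)
            v2 = np.diff(d1, axis=1).var(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                mob = np.sqrt(v1 / v0)
                comp = np.sqrt(v2 / np.maximum(v1, 1e-300)) / np.maximum(mob, 1e-300)
            cols[f"Hjorth activity {suffix}"][sl] = v0
            cols[f"Hjorth mobility {suffix}"][sl] = np.nan_to_num(mob)
            cols[f"Hjorth complexity {suffix}"][sl] = np.nan_to_num(comp)
            _, psd = _hann_periodogram(frames, fs)
            for b in bands:
                p = psd[:, band_sel[b.name]].mean(axis=1)
                cols[f"{b.name} amplitude {suffix}"][sl] = np.log(np.maximum(p, 1e-20))
        if burst_bands:
            for b in burst_bands:
                env = band_envelope(x, b, fs)
                thr = float(np.percentile(env, burst_threshold_pct))
                if not 0 < burst_threshold_pct < 100:
                    raise ConfigurationError("threshold_pct must be in (0, 100)")
                onsets, lengths = _burst_segments(env, thr)
                rate_col = np.empty(len(starts))
                dur_col = np.empty(len(starts))
                for k, (s, e) in enumerate(zip(starts, ends)):
                    lo = np.searchsorted(onsets, s)
                    hi = np.searchsorted(onsets, e)
                    rate_col[k] = (hi - lo) / (W / fs)
                    dur_col[k] = lengths[lo:hi].mean() / fs if hi > lo else 0.0
                cols[f"{b.name} burst rate {suffix}"] = rate_col
                cols[f"{b.name} burst duration {suffix}"] = dur_col
        for name, col in cols.items():
            full = np.empty(n_out)
            full[first_valid:] = col
            full[:first_valid] = col[0]  # back-fill before the first full window
            all_cols.append(full)
            names.append(name)

    times = np.arange(n_out) / feature_rate
    return FeatureMatrix(np.column_stack(all_cols), names, times, feature_rate,
                         run_ids=run_id if run_id is not None else rec.run_id,
                         subject_ids=subject_id, day_ids=day_id)


@dataclass
class PSDSummary:
    """State-averaged Welch PSD over a fixed frequency range."""

    freqs: np.ndarray
    mean_power: dict[str, np.ndarray]
    occurrence_counts: dict[str, int]
    excluded_counts: dict[str, int]
    band_means: dict[str, float]
    empty: bool = False


def welch_psd(x: np.ndarray, fs: float, segment_s: float = 0.5):
    """Welch density with Hann segments and 50% overlap."""
    nper = min(int(round(segment_s * fs)), len(x))
    return sps.welch(x, fs, window="hann", nperseg=nper, noverlap=nper // 2)


def state_psd(rec: NeuralRecording, events: EventTable, channel: str | None = None,
              occurrence_window: float = 1.5,
              f_range: tuple[float, float] = (5.0, 100.0),
              band: tuple[float, float] = HBLG_BAND,
              segment_s: float = 0.5) -> PSDSummary:
    """Welch PSD on the first ``occurrence_window`` s of each state occurrence.

    Occurrences shorter than the window are excluded and counted. The band
    mean (default 20-42 Hz) is reported per state over the averaged PSD.
    """
    x = rec.signal[0] if channel is None else rec.channel(channel)
    fs = rec.fs
    w = int(round(occurrence_window * fs))
    per_state: dict[str, list[np.ndarray]] = {}
    excluded: dict[str, int] = {}
    freqs_full = None
    for state in events.states():
        per_state[state] = []
        excluded[state] = 0
        for t0, t1 in events.occurrences(state):
            if t1 - t0 < occurrence_window - 1e-9:
                excluded[state] += 1
                continue
            i0 = int(round(t0 * fs))
            seg = x[i0:i0 + w]
            if len(seg) < w:
                excluded[state] += 1
                continue
            freqs_full, pxx = welch_psd(seg, fs, segment_s)
            per_state[state].append(pxx)
    if freqs_full is None:
        return PSDSummary(np.array([]), {}, {s: 0 for s in per_state},
                          excluded, {}, empty=True)
    sel = (freqs_full >= f_range[0]) & (freqs_full <= f_range[1])
    bsel = (freqs_full >= band[0]) & (freqs_full <= band[1])
    mean_power, counts, band_means = {}, {}, {}
    for state, traces in per_state.items():
        counts[state] = len(traces)
        if traces:
            avg = np.mean(traces, axis=0)
            mean_power[state] = avg[sel]
            band_means[state] = float(avg[bsel].mean())
    return PSDSummary(freqs_full[sel], mean_power, counts, excluded, band_means,
                      empty=not mean_power)
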