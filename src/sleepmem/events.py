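"""Spindle and slow-oscillation detection, coupling, and densities.

Spindles: the sigma-band amplitude is extracted with a single-scale
complex Morlet continuous wavelet transform centered mid-band; the squared
magnitude is smoothed with a 100-ms moving average and compared against a
threshold of ``threshold_factor`` (default 4) times that trace's mean over
artifact-free S2+S3 samples of the same channel (the moving-average-of-
squared-coefficients form of the classic wavelet detector). Each
contiguous supra-threshold excursion inside the duration bounds is one
spindle; reported peak amplitudes are the square root of the trace peak,
i.e. uV-equivalent envelope units.

Slow oscillations: on the zero-phase band-pass filtered signal, every
consecutive (down, up, down) zero-crossing triple is screened against five
criteria: crossing pattern, down-state duration 0.3-1.0 s, total length
< 10 s, down-state amplitude >= 80 uV, up-state amplitude < 140 uV.

Coupling: a spindle is coupled to an SO when its peak falls within
+/- 1.25 s of the SO down-state (trough) time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .io import EEGRecording, Hypnogram

__all__ = [
    "DetectorConfig",
    "SpindleEvent",
    "SlowOscillationEvent",
    "CoupledEvent",
    "detect_spindles",
    "detect_slow_oscillations",
    "couple_so_spindles",
    "event_density",
    "density_table",
    "match_events",
    "sigma_envelope",
]

NREM_STAGES = ("S2", "S3")


@dataclass
class DetectorConfig:
    """Numeric criteria for both detectors and the coupling window."""

    spindle_band_low_hz: float = 9.0
    spindle_band_high_hz: float = 15.0
    ma_window_s: float = 0.100
    threshold_factor: float = 4.0
    spindle_min_dur_s: float = 0.3
    spindle_max_dur_s: float = 3.0
    so_filter_low_hz: float = 0.1
    so_filter_high_hz: float = 4.0
    so_down_dur_min_s: float = 0.3
    so_down_dur_max_s: float = 1.0
    so_max_len_s: float = 10.0
    so_down_amp_min_uv: float = 80.0
    so_up_amp_max_uv: float = 140.0
    coupling_window_s: float = 1.25

    def __post_init__(self) -> None:
        for name in ("ma_window_s", "spindle_min_dur_s", "spindle_max_dur_s",
                     "so_down_dur_min_s", "so_down_dur_max_s", "so_max_len_s",
                     "threshold_factor", "coupling_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SpindleEvent:
    channel: str
    start_s: float
    end_s: float
    peak_s: float
    peak_amplitude: float  # smoothed sigma-envelope units (uV-equivalent)
    stage: str


@dataclass
class SlowOscillationEvent:
    channel: str
    zc_down1_s: float
    zc_up_s: float
    zc_down2_s: float
    trough_s: float
    trough_amp_uv: float   # negative
    peak_amp_uv: float     # positive
    stage: str


@dataclass
class CoupledEvent:
    so: SlowOscillationEvent
    spindle: SpindleEvent

    @property
    def offset_s(self) -> float:
        return self.spindle.peak_s - self.so.trough_s

    @property
    def channel(self) -> str:
        return self.so.channel

    @property
    def stage(self) -> str:
        return self.so.stage


@lru_cache(maxsize=16)
def _morlet_gain(fs: float, center_hz: float) -> float:
    """|CWT| response to a unit-amplitude tone at the center frequency."""
    t = np.arange(0, 4.0, 1.0 / fs)
    tone = np.sin(2 * np.pi * center_hz * t)
    coef, _ = pywt.cwt(tone, [fs / center_hz], "cmor1.0-1.0",
                       sampling_period=1.0 / fs)
    return float(np.abs(coef[0][len(t) // 2]))


def sigma_envelope(x: np.ndarray, fs: float, cfg: DetectorConfig) -> np.ndarray:
    """Smoothed sigma-band wavelet amplitude of one channel.

    A complex Morlet ('cmor1.0-1.0') at the scale whose center frequency is
    the middle of the spindle band; its half-amplitude points fall near the
    band edges. The magnitude is normalized so a pure tone of amplitude A
    at the center frequency yields a trace value of A, then smoothed with
    the moving-average window.
    """
    center = 0.5 * (cfg.spindle_band_low_hz + cfg.spindle_band_high_hz)
    coef, _ = pywt.cwt(np.asarray(x, dtype=float), [fs / center],
                       "cmor1.0-1.0", sampling_period=1.0 / fs, method="fft")
    amp = np.abs(coef[0]) / _morlet_gain(fs, center)
    win = max(int(round(cfg.ma_window_s * fs)), 1)
    return uniform_filter1d(amp, size=win, mode="nearest")


def spindle_detection_trace(x: np.ndarray, fs: float,
                            cfg: DetectorConfig) -> np.ndarray:
    """Moving average of the squared sigma-band wavelet magnitude.

    This is the quantity thresholded by the detector; its units are uV^2.
    """
    center = 0.5 * (cfg.spindle_band_low_hz + cfg.spindle_band_high_hz)
    coef, _ = pywt.cwt(np.asarray(x, dtype=float), [fs / center],
                       "cmor1.0-1.0", sampling_period=1.0 / fs, method="fft")
    power = (np.abs(coef[0]) / _morlet_gain(fs, center)) ** 2
    win = max(int(round(cfg.ma_window_s * fs)), 1)
    return uniform_filter1d(power, size=win, mode="nearest")


def _eligible_samples(hyp: Hypnogram, mask: np.ndarray, n_samples: int,
                      fs: float) -> np.ndarray:
    """Boolean per-sample array: artifact-free S2/S3."""
    ok = np.zeros(n_samples, dtype=bool)
    spe = int(round(hyp.epoch_len_s * fs))
    for i, st in enumerate(hyp.stages):
        if st in NREM_STAGES and mask[i]:
            ok[i * spe: min((i + 1) * spe, n_samples)] = True
    return ok


def _epoch_ok(hyp: Hypnogram, mask: np.ndarray, t_s: float) -> str | None:
    """Stage label if the epoch containing t is artifact-free NREM."""
    i = hyp.epoch_of(t_s)
    if 0 <= i < hyp.n_epochs and mask[i] and hyp.stages[i] in NREM_STAGES:
        return hyp.stages[i]
    return None


def detect_spindles(rec: EEGRecording, hyp: Hypnogram, mask: np.ndarray,
                    cfg: DetectorConfig | None = None,
                    channels: list[str] | None = None) -> list[SpindleEvent]:
    """Wavelet-threshold spindle detection on central channels.

    The threshold is ``threshold_factor`` times the mean of the smoothed
    sigma envelope over artifact-free S2+S3 samples, computed per channel
    per recording. Events are contiguous supra-threshold excursions with
    duration inside the configured bounds whose peak lies in an
    artifact-free S2/S3 epoch.
    """
    cfg = cfg or DetectorConfig()
    if channels is None:
        channels = rec.channels_with_role("central")
        if not channels:
            raise ValueError("no central channels found; pass channels=")
    fs = rec.sampling_rate_hz
    eligible = _eligible_samples(hyp, mask, rec.n_samples, fs)
    events: list[SpindleEvent] = []
    if not eligible.any():
        warnings.warn("no artifact-free NREM samples; no spindles detectable",
                      stacklevel=2)
        return events
    for ch in channels:
        trace = spindle_detection_trace(rec.get(ch), fs, cfg)
        baseline = trace[eligible].mean()
        thr = cfg.threshold_factor * baseline
        above = trace > thr
        if not above.any():
            continue
        padded = np.concatenate([[False], above, [False]])
        d = np.diff(padded.astype(np.int8))
        run_starts = np.flatnonzero(d == 1)
        run_ends = np.flatnonzero(d == -1)  # exclusive
        for i0, i1 in zip(run_starts, run_ends):
            dur = (i1 - i0) / fs
            if not cfg.spindle_min_dur_s <= dur <= cfg.spindle_max_dur_s:
                continue
            pk = i0 + int(np.argmax(trace[i0:i1]))
            stage = _epoch_ok(hyp, mask, pk / fs)
            if stage is None:
                continue
            events.append(SpindleEvent(
                channel=ch, start_s=i0 / fs, end_s=(i1 - 1) / fs,
                peak_s=pk / fs, peak_amplitude=float(np.sqrt(trace[pk])),
                stage=stage))
    return events


def _zero_crossings(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Sub-sample down (+ -> -) and up (- -> +) crossing times.

    A sample exactly at zero counts as non-positive, so crossings are
    where the strict sign of ``x > 0`` changes; times are linearly
    interpolated between the bracketing samples.
    """
    pos = x > 0
    flips = np.flatnonzero(pos[:-1] != pos[1:])
    if len(flips) == 0:
        return np.array([]), np.array([])
    frac = x[flips] / (x[flips] - x[flips + 1])
    frac = np.where(np.isfinite(frac), frac, 0.0)
    times = (flips + frac) / fs
    down = times[pos[flips]]
    up = times[~pos[flips]]
    return down, up


def detect_slow_oscillations(rec: EEGRecording, hyp: Hypnogram,
                             mask: np.ndarray,
                             cfg: DetectorConfig | None = None,
                             channels: list[str] | None = None,
                             ) -> list[SlowOscillationEvent]:
    """Zero-crossing slow-oscillation detection per channel.

    Scans consecutive (down, up, down) zero-crossing triples of the
    band-pass filtered signal and applies the duration and amplitude
    criteria literally; the trough is the filtered-signal minimum between
    the first down and the up crossing, the up-state peak the maximum
    between the up and second down crossing.
    """
    cfg = cfg or DetectorConfig()
    if channels is None:
        channels = rec.channels_with_role("frontal", "central")
        if not channels:
            raise ValueError("no frontal/central channels found; pass channels=")
    fs = rec.sampling_rate_hz
    sos = sps.butter(3, [cfg.so_filter_low_hz, cfg.so_filter_high_hz],
                     btype="bandpass", fs=fs, output="sos")
    events: list[SlowOscillationEvent] = []
    for ch in channels:
        xf = sps.sosfiltfilt(sos, rec.get(ch))
        down, up = _zero_crossings(xf, fs)
        for i, d1 in enumerate(down):
            nxt_up = up[np.searchsorted(up, d1)] \
                if np.searchsorted(up, d1) < len(up) else None
            if nxt_up is None:
                continue
            j = np.searchsorted(down, nxt_up)
            if j >= len(down):
                continue
            d2 = down[j]
            if not cfg.so_down_dur_min_s <= nxt_up - d1 <= cfg.so_down_dur_max_s:
                continue
            if not d2 - d1 < cfg.so_max_len_s:
                continue
            i0, i1 = int(np.ceil(d1 * fs)), int(np.floor(nxt_up * fs)) + 1
            seg_down = xf[i0:i1]
            if seg_down.size == 0:
                continue
            trough_rel = int(np.argmin(seg_down))
            trough_amp = float(seg_down[trough_rel])
            if not -trough_amp >= cfg.so_down_amp_min_uv:
                continue
            j0, j1 = int(np.ceil(nxt_up * fs)), int(np.floor(d2 * fs)) + 1
            seg_up = xf[j0:j1]
            peak_amp = float(seg_up.max()) if seg_up.size else 0.0
            if not peak_amp < cfg.so_up_amp_max_uv:
                continue
            t_trough = (i0 + trough_rel) / fs
            stage = _epoch_ok(hyp, mask, t_trough)
            if stage is None:
                continue
            events.append(SlowOscillationEvent(
                channel=ch, zc_down1_s=float(d1), zc_up_s=float(nxt_up),
                zc_down2_s=float(d2), trough_s=t_trough,
                trough_amp_uv=trough_amp, peak_amp_uv=peak_amp, stage=stage))
    return events


def couple_so_spindles(sos: list[SlowOscillationEvent],
                       spindles: list[SpindleEvent],
                       cfg: DetectorConfig | None = None,
                       ) -> list[CoupledEvent]:
    """Pair each SO with every same-channel spindle inside the window.

    Pairing is per SO: a spindle may appear in several pairs if its peak
    falls within the window of more than one SO.
    """
    cfg = cfg or DetectorConfig()
    out: list[CoupledEvent] = []
    for so in sos:
        for sp in spindles:
            if sp.channel != so.channel:
                continue
            if abs(sp.peak_s - so.trough_s) <= cfg.coupling_window_s:
                out.append(CoupledEvent(so=so, spindle=sp))
    return out


def event_density(events, hyp: Hypnogram, stage: str,
                  channel: str | None = None) -> float:
    """Stage-matched events per minute of that stage.

    Returns NaN (with a warning) when the hypnogram contains no minutes of
    the stage.
    """
    mins = hyp.stage_minutes(stage)
    if mins == 0:
        warnings.warn(f"zero minutes of stage {stage}; density undefined",
                      stacklevel=2)
        return float("nan")
    n = sum(1 for e in events
            if e.stage == stage and (channel is None or e.channel == channel))
    return n / mins


def density_table(spindles, sos, coupled, hyp: Hypnogram,
                  subject=None, condition=None) -> pd.DataFrame:
    """Per (channel, stage) densities of spindles, SOs and coupled events."""
    rows = []
    channels = sorted({e.channel for e in spindles}
                      | {e.channel for e in sos})
    for ch in channels:
        for stage in NREM_STAGES:
            if hyp.stage_minutes(stage) == 0:
                continue
            rows.append({
                "subject": subject, "condition": condition,
                "channel": ch, "stage": stage,
                "spindle_density_per_min": event_density(
                    spindles, hyp, stage, channel=ch),
                "so_density_per_min": event_density(
                    sos, hyp, stage, channel=ch),
                "coupling_density_per_min": event_density(
                    coupled, hyp, stage, channel=ch),
            })
    return pd.DataFrame(rows)


def match_events(detected_times, truth_times, tol_s: float = 0.5,
                 ) -> tuple[float, float, list[tuple[int, int]]]:
    """Greedy one-to-one matching of detected to ground-truth anchors.

    Returns (recall, precision, matched index pairs). Pairs are formed in
    order of increasing time difference; each event matches at most once.
    """
    det = np.asarray(list(detected_times), dtype=float)
    tru = np.asarray(list(truth_times), dtype=float)
    if len(tru) == 0 and len(det) == 0:
        return 1.0, 1.0, []
    cand = [(abs(d - t), i, j) for i, d in enumerate(det)
            for j, t in enumerate(tru) if abs(d - t) <= tol_s]
    cand.sort()
    used_d, used_t, pairs = set(), set(), []
    for _, i, j in cand:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        pairs.append((i, j))
    recall = len(pairs) / len(tru) if len(tru) else 1.0
    precision = len(pairs) / len(det) if len(det) else (1.0 if not len(tru) else 0.0)
    return recall, precision, pairs
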