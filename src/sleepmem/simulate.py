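"""Synthetic staged EEG and recognition-memory cohorts.

The EEG generator produces 1/f background noise with stage-gated injected
sleep spindles (Gaussian-windowed sigma-band bursts) and slow oscillations
(one-cycle asymmetric slow waves), together with a ground-truth event list
so detector recall/precision can be measured exactly.

The behavioral generator draws recognition confidence ratings from an
equal-variance Gaussian signal-detection model with known per-cell d' and a
fixed decision criterion, over the study's trial structure: per condition,
an encoding list of 20 negative and 28 neutral pictures (8 neutral buffers
for primacy/recency), and two recognition tests of 10 old + 10 novel
pictures per valence each.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import EEGRecording, Hypnogram, canonical_stage

__all__ = [
    "EEGSimConfig",
    "GroundTruth",
    "GTSpindle",
    "GTSlowOscillation",
    "BehaviorSimConfig",
    "BehaviorDataset",
    "generate_eeg",
    "generate_behavior",
    "so_waveform",
    "spindle_waveform",
    "DEFAULT_TRUE_DPRIME",
]

CONDITIONS = ("placebo", "zolpidem")
TESTS = (1, 2)
VALENCES = ("negative", "neutral")

#: Default per-cell true discriminability (condition, test, valence) -> d'.
#: Values sit in the d' ~ 1.8-2.4 range typical of picture recognition at
#: these delays, with mild forgetting from test 1 to test 2.
DEFAULT_TRUE_DPRIME: dict[tuple[str, int, str], float] = {
    ("placebo", 1, "negative"): 2.43,
    ("placebo", 1, "neutral"): 2.07,
    ("placebo", 2, "negative"): 1.84,
    ("placebo", 2, "neutral"): 2.30,
    ("zolpidem", 1, "negative"): 2.30,
    ("zolpidem", 1, "neutral"): 2.36,
    ("zolpidem", 2, "negative"): 2.18,
    ("zolpidem", 2, "neutral"): 1.98,
}


# ---------------------------------------------------------------------------
# EEG simulation
# ---------------------------------------------------------------------------

@dataclass
class EEGSimConfig:
    """Parameters of the staged-EEG generator.

    ``stage_sequence`` is a list of ``(stage, minutes)`` blocks; total
    duration is their sum. Event densities apply per eligible NREM stage
    (S2 and S3). All amplitudes are uV; the SO amplitudes are the values
    the *detection-filtered* waveform attains, so the generator can place
    events exactly on or off the detector's amplitude criteria.
    """

    stage_sequence: list[tuple[str, float]] = field(default_factory=lambda: [
        ("Wake", 2.0), ("S1", 2.0), ("S2", 10.0), ("S3", 8.0),
        ("S2", 4.0), ("REM", 4.0),
    ])
    sampling_rate_hz: float = 256.0
    channels: list[str] = field(default_factory=lambda: [
        "F3", "F4", "C3", "C4", "A1", "A2",
    ])
    noise_exponent: float = 1.0
    noise_rms_uv: float = 20.0
    spindle_density_per_min: float = 2.0
    spindle_freq_hz: float = 13.0
    spindle_amp_uv: float = 25.0
    spindle_dur_s: float = 1.0
    so_density_per_min: float = 3.0
    so_down_amp_uv: float = 120.0
    so_up_amp_uv: float = 60.0
    coupled_fraction: float = 0.5
    coupling_offset_s: float = 0.3
    so_down_dur_s: float = 0.5
    so_up_dur_s: float = 2.0
    so_filter_band: tuple[float, float] = (0.1, 4.0)
    mastoid_noise_fraction: float = 0.3
    epoch_len_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.stage_sequence = [(canonical_stage(s), float(m))
                               for s, m in self.stage_sequence]
        if self.duration_s <= 0:
            raise ValueError("stage_sequence has zero total duration")
        for name in ("spindle_density_per_min", "so_density_per_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.coupled_fraction <= 1.0:
            raise ValueError("coupled_fraction must lie in [0, 1]")
        if not 9.0 <= self.spindle_freq_hz <= 15.0:
            raise ValueError("spindle_freq_hz must lie in the sigma band [9, 15]")
        if abs(self.coupling_offset_s) > 1.25:
            raise ValueError("coupling_offset_s must lie in [-1.25, 1.25]")
        for s, m in self.stage_sequence:
            if (m * 60.0) % self.epoch_len_s != 0:
                raise ValueError("stage block minutes must be whole epochs")

    @property
    def duration_s(self) -> float:
        return 60.0 * sum(m for _, m in self.stage_sequence)


@dataclass
class GTSpindle:
    channel: str
    start_s: float
    end_s: float
    peak_s: float
    stage: str


@dataclass
class GTSlowOscillation:
    channel: str
    trough_s: float
    down_amp_uv: float
    up_amp_uv: float
    stage: str


@dataclass
class GroundTruth:
    """Injected-event bookkeeping for detector validation."""

    spindles: list[GTSpindle] = field(default_factory=list)
    slow_oscillations: list[GTSlowOscillation] = field(default_factory=list)
    coupled_pairs: list[tuple[int, int]] = field(default_factory=list)

    def to_json(self, path) -> None:
        obj = {
            "spindles": [vars(s) for s in self.spindles],
            "slow_oscillations": [vars(s) for s in self.slow_oscillations],
            "coupled_pairs": [list(p) for p in self.coupled_pairs],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            spindles=[GTSpindle(**s) for s in obj["spindles"]],
            slow_oscillations=[GTSlowOscillation(**s)
                               for s in obj["slow_oscillations"]],
            coupled_pairs=[tuple(p) for p in obj["coupled_pairs"]],
        )


def spindle_waveform(fs: float, freq_hz: float, amp_uv: float,
                     dur_s: float) -> np.ndarray:
    """Gaussian-windowed sinusoid; support is +/- dur/2 around the peak."""
    half = dur_s / 2.0
    t = np.arange(-half, half + 1.0 / fs / 2, 1.0 / fs)
    sigma = dur_s / 4.0  # FWHM ~ 0.6 * dur: sigma power spans most of dur
    return amp_uv * np.exp(-t ** 2 / (2 * sigma ** 2)) * np.sin(2 * np.pi * freq_hz * t)


_SO_LEAD_S = 0.5       # positive lead-in bump, pins the first down crossing
_SO_LEAD_FRAC = 0.3    # lead amplitude as a fraction of the down amplitude
_SO_TAIL_S = 4.0       # shallow balancing tail


def _so_raw(fs: float, down_amp: float, up_amp: float,
            d_down: float, d_up: float) -> np.ndarray:
    """Lead bump + down half-sine + up half-sine + zero-mean tail.

    The small positive lead-in keeps the filtered signal positive just
    before the down lobe so the initial down zero-crossing falls at the
    lobe onset (zero-phase filtering otherwise pre-rings it away); the
    shallow tail absorbs the area imbalance so the waveform is zero-mean
    and passes the SO detection band-pass with little shape distortion.
    Neither satisfies the SO criteria on its own.
    """
    n_lead = int(round(_SO_LEAD_S * fs))
    n_down = int(round(d_down * fs))
    n_up = int(round(d_up * fs))
    n_tail = int(round(_SO_TAIL_S * fs))
    lead = _SO_LEAD_FRAC * down_amp * np.sin(
        np.pi * np.arange(n_lead) / n_lead)
    down = -down_amp * np.sin(np.pi * np.arange(n_down) / n_down)
    up = up_amp * np.sin(np.pi * np.arange(n_up) / n_up)
    area = lead.sum() + down.sum() + up.sum()
    tail_shape = np.sin(np.pi * np.arange(n_tail) / n_tail)
    tail = -area / tail_shape.sum() * tail_shape
    return np.concatenate([lead, down, up, tail])


def _filtered_extrema(w: np.ndarray, fs: float, band: tuple[float, float],
                      n_down: int, n_up: int) -> tuple[float, float, int]:
    """(trough depth, peak height, trough index) of the filtered waveform."""
    pad = int(round(30.0 * fs))
    n_lead = int(round(_SO_LEAD_S * fs))
    sos = sps.butter(3, band, btype="bandpass", fs=fs, output="sos")
    x = np.zeros(2 * pad + len(w))
    x[pad: pad + len(w)] = w
    f = sps.sosfiltfilt(sos, x)
    a = pad + n_lead
    i_tr = a + int(np.argmin(f[a: a + n_down]))
    i_pk = a + n_down + int(np.argmax(f[a + n_down: a + n_down + n_up]))
    return -float(f[i_tr]), float(f[i_pk]), i_tr - pad


@lru_cache(maxsize=64)
def _so_calibration(fs: float, down_amp: float, up_amp: float,
                    d_down: float, d_up: float,
                    band: tuple[float, float]) -> tuple[float, float, int]:
    """Raw lobe amplitudes whose *filtered* trough/peak hit the targets."""
    n_down = int(round(d_down * fs))
    n_up = int(round(d_up * fs))
    a_d, a_u = down_amp, up_amp
    trough_idx = n_down // 2
    for _ in range(40):
        w = _so_raw(fs, a_d, a_u, d_down, d_up)
        tr, pk, trough_idx = _filtered_extrema(w, fs, band, n_down, n_up)
        if tr <= 0 or pk <= 0:
            a_d *= 1.5
            a_u *= 1.5
            continue
        err = max(abs(tr - down_amp), abs(pk - up_amp))
        if err < 1e-9 * max(down_amp, up_amp):
            break
        a_d *= down_amp / tr
        a_u *= up_amp / pk
    return a_d, a_u, trough_idx


def so_waveform(fs: float, down_amp_uv: float, up_amp_uv: float,
                d_down_s: float = 0.5, d_up_s: float = 2.0,
                filter_band: tuple[float, float] = (0.1, 4.0),
                ) -> tuple[np.ndarray, int]:
    """One-cycle slow wave calibrated against the SO detection filter.

    The raw lobe amplitudes are iterated until, after zero-phase band-pass
    filtering with ``filter_band``, the waveform's down-state trough depth
    equals ``down_amp_uv`` and its up-state peak equals ``up_amp_uv`` (to
    ~1e-9 relative). Returns ``(waveform, trough_index)`` where
    ``trough_index`` is the sample offset of the filtered trough.
    """
    a_d, a_u, trough_idx = _so_calibration(
        fs, float(down_amp_uv), float(up_amp_uv),
        float(d_down_s), float(d_up_s), tuple(filter_band))
    w = _so_raw(fs, a_d, a_u, d_down_s, d_up_s)
    return w, trough_idx


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                      exponent: float, rms_uv: float,
                      f_floor: float = 0.1) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent amplitude spectrum (flat < f_floor)."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = np.maximum(freqs[nz], f_floor) ** (-exponent / 2.0)
    shaping[0] = 0.0
    spec = (rng.standard_normal(len(freqs))
            + 1j * rng.standard_normal(len(freqs))) * shaping
    x = np.fft.irfft(spec, n=n)
    x *= rms_uv / np.sqrt(np.mean(x ** 2))
    return x


def _stage_intervals(cfg: EEGSimConfig, stage: str) -> list[tuple[float, float]]:
    out, t = [], 0.0
    for s, m in cfg.stage_sequence:
        dur = m * 60.0
        if s == stage:
            out.append((t, t + dur))
        t += dur
    return out


def _place_anchors(rng: np.random.Generator, intervals, n: int,
                   margin_s: float, min_sep_s: float,
                   fixed: list[float] | None = None) -> list[float]:
    """Uniform anchor times within intervals, >= min_sep apart.

    ``fixed`` anchors (already accepted, e.g. coupled events) are honored
    for separation but not re-emitted.
    """
    usable = [(a + margin_s, b - margin_s) for a, b in intervals
              if b - a > 2 * margin_s]
    if not usable or n <= 0:
        return []
    spans = np.array([b - a for a, b in usable])
    total = spans.sum()
    placed: list[float] = []
    occupied = list(fixed or [])
    attempts = 0
    while len(placed) < n and attempts < 20000:
        attempts += 1
        u = rng.uniform(0, total)
        k = int(np.searchsorted(np.cumsum(spans), u, side="right"))
        k = min(k, len(usable) - 1)
        t = usable[k][0] + (u - (np.cumsum(spans)[k] - spans[k]))
        if all(abs(t - o) >= min_sep_s for o in occupied):
            placed.append(t)
            occupied.append(t)
    if len(placed) < n:
        warnings.warn(
            f"placed only {len(placed)}/{n} events before giving up "
            "(stage too crowded for the requested density)", stacklevel=2)
    return placed


def _add_waveform(sig: np.ndarray, fs: float, start_s: float,
                  w: np.ndarray) -> None:
    i0 = int(round(start_s * fs))
    i1 = min(i0 + len(w), sig.shape[-1])
    if i0 < 0 or i1 <= i0:
        return
    sig[..., i0:i1] += w[: i1 - i0]


def generate_eeg(config: EEGSimConfig,
                 ) -> tuple[EEGRecording, Hypnogram, GroundTruth]:
    """Simulate a staged recording with ground-truth embedded events.

    Spindles are injected simultaneously on both central channels and slow
    oscillations on frontal + central channels (events are bilaterally
    synchronous); the ground truth lists one entry per channel per event.
    A configurable fraction of spindles is placed at a fixed offset from an
    SO trough to create coupled pairs.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate_hz
    n = int(round(config.duration_s * fs))

    stages = []
    for s, m in config.stage_sequence:
        stages.extend([s] * int(round(m * 60.0 / config.epoch_len_s)))
    hyp = Hypnogram(stages=stages, epoch_len_s=config.epoch_len_s)

    labels = list(config.channels)
    rec = EEGRecording(
        signal=np.zeros((len(labels), n)),
        sampling_rate_hz=fs,
        channel_labels=labels,
    )
    for i, lab in enumerate(labels):
        rms = config.noise_rms_uv
        if rec.channel_roles[lab] == "mastoid":
            rms *= config.mastoid_noise_fraction
        rec.signal[i] = _one_over_f_noise(rng, n, fs, config.noise_exponent, rms)

    central = rec.channels_with_role("central")
    so_channels = rec.channels_with_role("frontal", "central")
    truth = GroundTruth()

    # --- slow oscillations -------------------------------------------------
    so_len = config.so_down_dur_s + config.so_up_dur_s
    so_anchors: dict[str, list[float]] = {}
    if config.so_density_per_min > 0 and so_channels:
        w, trough_idx = so_waveform(
            fs, config.so_down_amp_uv, config.so_up_amp_uv,
            config.so_down_dur_s, config.so_up_dur_s, config.so_filter_band)
        trough_off = trough_idx / fs
        for stage in ("S2", "S3"):
            mins = hyp.stage_minutes(stage)
            n_ev = int(round(config.so_density_per_min * mins))
            anchors = _place_anchors(
                rng, _stage_intervals(config, stage), n_ev,
                margin_s=so_len + 0.5, min_sep_s=max(2.0, so_len + 2.0))
            so_anchors.setdefault(stage, []).extend(sorted(anchors))
        for stage, anchors in so_anchors.items():
            for t_trough in anchors:
                start = t_trough - trough_off
                for ch in so_channels:
                    _add_waveform(rec.signal[rec.index(ch)], fs, start, w)
                    truth.slow_oscillations.append(GTSlowOscillation(
                        channel=ch, trough_s=t_trough,
                        down_amp_uv=config.so_down_amp_uv,
                        up_amp_uv=config.so_up_amp_uv, stage=stage))

    # --- spindles ----------------------------------------------------------
    if config.spindle_density_per_min > 0 and central:
        w_sp = spindle_waveform(fs, config.spindle_freq_hz,
                                config.spindle_amp_uv, config.spindle_dur_s)
        half = config.spindle_dur_s / 2.0
        for stage in ("S2", "S3"):
            mins = hyp.stage_minutes(stage)
            n_ev = int(round(config.spindle_density_per_min * mins))
            if n_ev == 0:
                continue
            intervals = _stage_intervals(config, stage)
            # coupled spindles ride on this stage's SOs at a fixed offset
            peaks: list[float] = []
            pair_so_idx: list[int] = []
            stage_sos = [(i, s) for i, s in enumerate(truth.slow_oscillations)
                         if s.stage == stage]
            # one ground-truth row per channel; unique events = every
            # len(so_channels)-th row
            unique_sos = stage_sos[:: max(len(so_channels), 1)]
            n_coupled = min(int(round(config.coupled_fraction * len(unique_sos))),
                            n_ev)
            for i_so, so in unique_sos[:n_coupled]:
                t_peak = so.trough_s + config.coupling_offset_s
                ok = any(a + half <= t_peak <= b - half for a, b in intervals)
                if ok and all(abs(t_peak - p) >= 2.0 for p in peaks):
                    peaks.append(t_peak)
                    pair_so_idx.append(i_so)
            free = _place_anchors(rng, intervals, n_ev - len(peaks),
                                  margin_s=half + 0.1, min_sep_s=2.0,
                                  fixed=peaks)
            order = np.argsort(peaks + free)
            all_peaks = np.array(peaks + free)[order]
            coupled_flag = np.array([True] * len(peaks) + [False] * len(free))[order]
            so_for_peak = {p: i for p, i in zip(peaks, pair_so_idx)}
            for t_peak, is_coupled in zip(all_peaks, coupled_flag):
                for ch in central:
                    _add_waveform(rec.signal[rec.index(ch)], fs,
                                  t_peak - half, w_sp)
                    sp_idx = len(truth.spindles)
                    truth.spindles.append(GTSpindle(
                        channel=ch, start_s=t_peak - half,
                        end_s=t_peak + half, peak_s=t_peak, stage=stage))
                    if is_coupled:
                        # pair with the same-channel SO row when it exists
                        base = so_for_peak[t_peak]
                        so_row = next(
                            (j for j in range(base, len(truth.slow_oscillations))
                             if truth.slow_oscillations[j].trough_s
                             == truth.slow_oscillations[base].trough_s
                             and truth.slow_oscillations[j].channel == ch),
                            base)
                        truth.coupled_pairs.append((so_row, sp_idx))

    return rec, hyp, truth


# ---------------------------------------------------------------------------
# Behavior simulation
# ---------------------------------------------------------------------------

@dataclass
class BehaviorSimConfig:
    """Parameters of the recognition-memory cohort generator.

    ``true_dprime`` maps (condition, test, valence) to the generating d'
    of the equal-variance Gaussian signal-detection model; ``criterion``
    is the shared decision criterion (latent evidence above it yields a
    "present" response). Confidence uses 5 fixed cut-points spaced
    ``confidence_noise`` apart, symmetric around the criterion.
    """

    n_subjects: int = 25
    true_dprime: dict[tuple[str, int, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_DPRIME))
    criterion: float = 1.1
    n_old_per_valence: int = 10
    n_new_per_valence: int = 10
    confidence_noise: float = 0.5
    weight_mean_kg: float = 75.0
    weight_sd_kg: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_old_per_valence < 1 or self.n_new_per_valence < 1:
            raise ValueError("picture counts per valence must be >= 1")
        for key in DEFAULT_TRUE_DPRIME:
            if key not in self.true_dprime:
                raise ValueError(f"true_dprime missing cell {key}")
            if not math.isfinite(self.true_dprime[key]):
                raise ValueError(f"true_dprime[{key}] must be finite")
        if self.confidence_noise <= 0:
            raise ValueError("confidence_noise must be positive")


@dataclass
class BehaviorDataset:
    """Simulated cohort: recognition trials, encoding lists, covariates."""

    trials: pd.DataFrame
    encoding: pd.DataFrame
    subjects: pd.DataFrame

    def write(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(outdir / "trials.csv", index=False)
        self.encoding.to_csv(outdir / "encoding.csv", index=False)
        self.subjects.to_csv(outdir / "subjects.csv", index=False)


def _confidence_from_latent(x: np.ndarray, criterion: float,
                            spacing: float) -> np.ndarray:
    """Map latent familiarity to a 1-6 confidence rating.

    Cut-points sit at criterion + spacing * {2, 1, 0, -1, -2}; the middle
    cut-point is the decision criterion itself, so collapsing 1-3 vs 4-6
    reproduces the present / not-present decision exactly.
    """
    cuts = criterion + spacing * np.array([2.0, 1.0, 0.0, -1.0, -2.0])
    conf = 1 + (x[:, None] < cuts[None, :]).sum(axis=1)
    return conf.astype(int)


def generate_behavior(config: BehaviorSimConfig) -> BehaviorDataset:
    """Simulate the two-condition cross-over recognition cohort.

    Returns trials (one row per subject x condition x test x picture),
    encoding lists (with buffer flags), and per-subject weight covariates.
    """
    rng = np.random.default_rng(config.seed)
    n_old = config.n_old_per_valence
    n_new = config.n_new_per_valence

    subjects = pd.DataFrame({
        "subject": np.arange(config.n_subjects),
        "weight_kg": rng.normal(config.weight_mean_kg, config.weight_sd_kg,
                                config.n_subjects).round(1),
    })

    # Encoding lists: 20 negative + 28 neutral per condition; the extra
    # 8 neutral pictures occupy the first and last 4 serial positions.
    enc_rows = []
    for subj in range(config.n_subjects):
        for cond in CONDITIONS:
            middle = ([("negative", False)] * 2 * n_old
                      + [("neutral", False)] * 2 * n_old)
            order = rng.permutation(len(middle))
            seq = ([("neutral", True)] * 4
                   + [middle[k] for k in order]
                   + [("neutral", True)] * 4)
            for pos, (val, buf) in enumerate(seq, start=1):
                enc_rows.append((subj, cond, pos, val, buf))
    encoding = pd.DataFrame(
        enc_rows, columns=["subject", "condition", "position", "valence",
                           "is_buffer"])

    # Recognition trials from the signal-detection model.
    rows = {k: [] for k in ("subject", "condition", "test", "valence",
                            "status", "picture_id", "latent")}
    for subj in range(config.n_subjects):
        for cond in CONDITIONS:
            for test in TESTS:
                for val in VALENCES:
                    d = config.true_dprime[(cond, test, val)]
                    lat_old = rng.normal(d, 1.0, n_old)
                    lat_new = rng.normal(0.0, 1.0, n_new)
                    for k, (status, lat) in enumerate(
                            (("old", lat_old), ("new", lat_new))):
                        m = len(lat)
                        rows["subject"].extend([subj] * m)
                        rows["condition"].extend([cond] * m)
                        rows["test"].extend([test] * m)
                        rows["valence"].extend([val] * m)
                        rows["status"].extend([status] * m)
                        rows["picture_id"].extend(
                            f"{cond[:3]}_{val[:3]}_{status}_t{test}_{j}"
                            for j in range(m))
                        rows["latent"].extend(lat)
    trials = pd.DataFrame(rows)
    trials["confidence"] = _confidence_from_latent(
        trials.pop("latent").to_numpy(), config.criterion,
        config.confidence_noise)
    return BehaviorDataset(trials=trials, encoding=encoding, subjects=subjects)
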