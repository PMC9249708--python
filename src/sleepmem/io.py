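"""Polysomnography I/O and preprocessing.

EEG recordings are kept as plain channels x samples arrays in microvolts.
EDF reading goes through :mod:`mne`; writing uses a small self-contained
16-bit EDF writer so that simulated recordings round-trip through the same
on-disk format a sleep lab would use.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "EEGRecording",
    "Hypnogram",
    "SleepArchitecture",
    "EDFFormatError",
    "MissingChannelError",
    "STAGES",
    "SLEEP_STAGES",
    "SCALP_ROLES",
    "infer_channel_role",
    "read_edf",
    "write_edf",
    "read_hypnogram_csv",
    "write_hypnogram_csv",
    "rereference_contralateral_mastoid",
    "bandpass_filter",
    "mark_artifact_epochs",
    "sleep_architecture",
]

#: Canonical stage labels (Rechtschaffen & Kales, 30-s epochs).
STAGES = ("Wake", "S1", "S2", "S3", "REM", "Unscored")
SLEEP_STAGES = ("S1", "S2", "S3", "REM")
SCALP_ROLES = frozenset({"frontal", "central", "parietal", "occipital"})

_STAGE_ALIASES = {
    "W": "Wake", "WAKE": "Wake", "0": "Wake",
    "N1": "S1", "S1": "S1", "1": "S1",
    "N2": "S2", "S2": "S2", "2": "S2",
    "N3": "S3", "S3": "S3", "SWS": "S3", "3": "S3", "4": "S3",
    "R": "REM", "REM": "REM", "5": "REM",
    "U": "Unscored", "UNSCORED": "Unscored", "?": "Unscored", "-1": "Unscored",
}
_STAGE_CODES = {"Wake": "W", "S1": "N1", "S2": "N2", "S3": "N3",
                "REM": "R", "Unscored": "U"}


class EDFFormatError(ValueError):
    """Raised for malformed or truncated EDF files."""


class MissingChannelError(ValueError):
    """Raised when a required channel (e.g. a mastoid) is absent."""


def canonical_stage(label: str) -> str:
    key = str(label).strip().upper()
    if key in _STAGE_ALIASES:
        return _STAGE_ALIASES[key]
    raise ValueError(f"unknown sleep stage label: {label!r}")


def infer_channel_role(label: str) -> str:
    """Guess a channel's role from its 10-20 label."""
    u = label.strip().upper()
    if u in ("A1", "A2", "M1", "M2"):
        return "mastoid"
    if "EOG" in u or u in ("LOC", "ROC", "E1", "E2"):
        return "EOG"
    if "EMG" in u or "CHIN" in u:
        return "EMG"
    if "ECG" in u or "EKG" in u:
        return "ECG"
    if u and u[0] == "F":
        return "frontal"
    if u and u[0] == "C":
        return "central"
    if u and u[0] == "P":
        return "parietal"
    if u and u[0] == "O":
        return "occipital"
    return "other"


@dataclass
class EEGRecording:
    """Multi-channel EEG in microvolts.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal in uV.
    sampling_rate_hz : float
        Sampling rate, Hz.
    channel_labels : list of str
        One label per row of ``signal``.
    channel_roles : dict, optional
        label -> role; missing roles are inferred from the label.
    """

    signal: np.ndarray
    sampling_rate_hz: float
    channel_labels: list[str]
    channel_roles: dict[str, str] = field(default_factory=dict)
    start_time: str | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("channel_labels length != number of signal rows")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        roles = dict(self.channel_roles)
        for lab in self.channel_labels:
            roles.setdefault(lab, infer_channel_role(lab))
        self.channel_roles = roles

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise MissingChannelError(f"channel {label!r} not in recording") from None

    def get(self, label: str) -> np.ndarray:
        return self.signal[self.index(label)]

    def channels_with_role(self, *roles: str) -> list[str]:
        return [c for c in self.channel_labels if self.channel_roles.get(c) in roles]

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            signal=self.signal.copy(),
            sampling_rate_hz=self.sampling_rate_hz,
            channel_labels=list(self.channel_labels),
            channel_roles=dict(self.channel_roles),
            start_time=self.start_time,
        )


@dataclass
class Hypnogram:
    """Per-epoch sleep-stage labels aligned to a recording.

    Epochs are 0-based and half-open: epoch ``i`` covers
    ``[i * epoch_len_s, (i + 1) * epoch_len_s)`` seconds.
    """

    stages: list[str]
    epoch_len_s: float = 30.0
    lights_out_epoch: int = 0
    lights_on_epoch: int | None = None

    def __post_init__(self) -> None:
        self.stages = [canonical_stage(s) for s in self.stages]
        if self.lights_on_epoch is None:
            self.lights_on_epoch = len(self.stages)
        if not 0 <= self.lights_out_epoch <= self.lights_on_epoch <= len(self.stages):
            raise ValueError("require 0 <= lights_out <= lights_on <= n_epochs")
        if self.epoch_len_s <= 0:
            raise ValueError("epoch_len_s must be positive")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    def epoch_of(self, t_s: float) -> int:
        return int(t_s // self.epoch_len_s)

    def stage_at(self, t_s: float) -> str:
        i = self.epoch_of(t_s)
        if not 0 <= i < self.n_epochs:
            return "Unscored"
        return self.stages[i]

    def stage_minutes(self, stage: str) -> float:
        stage = canonical_stage(stage)
        return self.stages.count(stage) * self.epoch_len_s / 60.0

    def sample_stages(self, n_samples: int, rate_hz: float) -> np.ndarray:
        """Per-sample stage labels (object array)."""
        out = np.full(n_samples, "Unscored", dtype=object)
        spe = int(round(self.epoch_len_s * rate_hz))
        for i, st in enumerate(self.stages):
            out[i * spe: min((i + 1) * spe, n_samples)] = st
        return out


@dataclass
class SleepArchitecture:
    """Summary sleep-architecture metrics over the lights-out window."""

    tst_min: float
    stage_minutes: dict[str, float]
    sl_min: float          # NaN when no sleep epoch occurs
    waso_min: float
    se_pct: float
    time_in_bed_min: float


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

def _pad(value, n: int) -> bytes:
    b = str(value).encode("ascii")[:n]
    return b + b" " * (n - len(b))


def write_edf(path, rec: EEGRecording) -> None:
    """Write a recording as a 16-bit EDF file (1-s data records).

    The sampling rate must be a whole number of samples per second and the
    duration a whole number of seconds; simulated recordings satisfy both.
    Quantization error is bounded by the per-channel physical range divided
    by 2**16 - 2.
    """
    fs = rec.sampling_rate_hz
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    if rec.n_samples % spr != 0:
        raise ValueError("EDF writer requires whole seconds of data")
    ndr = rec.n_samples // spr
    nch = rec.n_channels

    # Symmetric physical range, rounded outward so no sample clips.
    pabs = np.maximum(np.abs(rec.signal).max(axis=1), 1.0) * 1.001
    pmax_s = ["%.6g" % v for v in pabs]
    pmax = np.array([float(s) for s in pmax_s])
    pmin = -pmax
    dmin, dmax = -32767, 32767

    hdr = b""
    hdr += _pad("0", 8)
    hdr += _pad("X X X X", 80)
    hdr += _pad("Startdate 01-JAN-2000 X X X", 80)
    hdr += _pad("01.01.00", 8)
    hdr += _pad(rec.start_time or "00.00.00", 8)
    hdr += _pad(256 * (nch + 1), 8)
    hdr += _pad("", 44)
    hdr += _pad(ndr, 8)
    hdr += _pad("1", 8)
    hdr += _pad(nch, 4)
    for values, width in (
        (rec.channel_labels, 16),
        ([""] * nch, 80),
        (["uV"] * nch, 8),
        (["-" + s for s in pmax_s], 8),
        (pmax_s, 8),
        ([dmin] * nch, 8),
        ([dmax] * nch, 8),
        ([""] * nch, 80),
        ([spr] * nch, 8),
    ):
        for v in values:
            hdr += _pad(v, width)
    hdr += b" " * (32 * nch)

    gain = (dmax - dmin) / (pmax - pmin)
    dig = np.round((rec.signal - pmin[:, None]) * gain[:, None] + dmin)
    dig = np.clip(dig, dmin, dmax).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(ndr):
            fh.write(np.ascontiguousarray(dig[:, r * spr:(r + 1) * spr]).tobytes())


def _check_edf_size(path: Path) -> None:
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise EDFFormatError(f"{path}: header truncated")
        try:
            hdr_bytes = int(hdr[184:192])
            ndr = int(hdr[236:244])
            nch = int(hdr[252:256])
        except ValueError as exc:
            raise EDFFormatError(f"{path}: malformed EDF header") from exc
        sig_hdr = fh.read(nch * 256)
        if len(sig_hdr) < nch * 256:
            raise EDFFormatError(f"{path}: signal headers truncated")
        try:
            spr = [int(sig_hdr[nch * 216 + 8 * i: nch * 216 + 8 * (i + 1)])
                   for i in range(nch)]
        except ValueError as exc:
            raise EDFFormatError(f"{path}: malformed signal header") from exc
    expected = hdr_bytes + ndr * sum(spr) * 2
    actual = Path(path).stat().st_size
    if ndr >= 0 and actual < expected:
        raise EDFFormatError(
            f"{path}: file truncated ({actual} bytes, header promises {expected})"
        )


def read_edf(path, channel_roles: dict[str, str] | None = None) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (uV).

    Raises :class:`EDFFormatError` for malformed or truncated files rather
    than returning a partial recording.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_edf_size(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on bad files
        raise EDFFormatError(f"{path}: not a readable EDF file ({exc})") from exc
    sig_uv = raw.get_data() * 1e6
    return EEGRecording(
        signal=sig_uv,
        sampling_rate_hz=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        channel_roles=channel_roles or {},
    )


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------

def write_hypnogram_csv(path, hyp: Hypnogram) -> None:
    df = pd.DataFrame({
        "epoch_index": np.arange(hyp.n_epochs),
        "stage": [_STAGE_CODES[s] for s in hyp.stages],
    })
    df.to_csv(path, index=False)


def read_hypnogram_csv(path, epoch_len_s: float = 30.0,
                       lights_out_epoch: int = 0,
                       lights_on_epoch: int | None = None) -> Hypnogram:
    df = pd.read_csv(path)
    df = df.sort_values("epoch_index")
    return Hypnogram(
        stages=[canonical_stage(s) for s in df["stage"]],
        epoch_len_s=epoch_len_s,
        lights_out_epoch=lights_out_epoch,
        lights_on_epoch=lights_on_epoch,
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _hemisphere(label: str) -> str:
    u = label.strip().upper()
    if u.endswith("Z"):
        return "midline"
    digits = "".join(ch for ch in u if ch.isdigit())
    if not digits:
        return "midline"
    return "left" if int(digits[-1]) % 2 == 1 else "right"


def rereference_contralateral_mastoid(
    rec: EEGRecording, left_mastoid: str = "A1", right_mastoid: str = "A2"
) -> EEGRecording:
    """Re-reference scalp channels to the contralateral mastoid.

    Left-hemisphere channels (odd 10-20 index) are referenced to the right
    mastoid, right-hemisphere channels to the left mastoid, and midline
    channels to the mean of both. Mastoids and non-scalp channels are
    returned unmodified.
    """
    for m in (left_mastoid, right_mastoid):
        if m not in rec.channel_labels:
            raise MissingChannelError(f"mastoid channel {m!r} missing")
    a1 = rec.get(left_mastoid)
    a2 = rec.get(right_mastoid)
    out = rec.copy()
    for i, lab in enumerate(rec.channel_labels):
        if rec.channel_roles.get(lab) not in SCALP_ROLES:
            continue
        hemi = _hemisphere(lab)
        if hemi == "left":
            out.signal[i] = rec.signal[i] - a2
        elif hemi == "right":
            out.signal[i] = rec.signal[i] - a1
        else:
            out.signal[i] = rec.signal[i] - 0.5 * (a1 + a2)
    return out


def bandpass_filter(rec: EEGRecording, low_hz: float = 0.3,
                    high_hz: float = 35.0, order: int = 5) -> EEGRecording:
    """Zero-phase Butterworth band-pass of scalp EEG and EOG channels.

    With the default order-5 design applied forward and backward, stopband
    attenuation exceeds 20 dB at 0.05 Hz and at 45 Hz for the 0.3-35 Hz
    band; passband ripple is zero (Butterworth is maximally flat).
    """
    nyq = rec.sampling_rate_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"require 0 < low ({low_hz}) < high ({high_hz}) < Nyquist ({nyq})"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=rec.sampling_rate_hz, output="sos")
    out = rec.copy()
    for i, lab in enumerate(rec.channel_labels):
        role = rec.channel_roles.get(lab)
        if role in SCALP_ROLES or role == "EOG":
            out.signal[i] = sps.sosfiltfilt(sos, rec.signal[i])
    return out


def mark_artifact_epochs(rec: EEGRecording, hyp: Hypnogram,
                         threshold_uv: float = 200.0,
                         highpass_hz: float = 0.5) -> np.ndarray:
    """Boolean per-epoch mask; ``True`` means artifact-free.

    An epoch is artifactual iff any scalp-EEG sample of its 0.5-Hz
    high-pass filtered version exceeds the +/- threshold. The whole 30-s
    epoch is rejected, never individual samples.
    """
    scalp = [rec.index(c) for c in rec.channels_with_role(*SCALP_ROLES)]
    mask = np.ones(hyp.n_epochs, dtype=bool)
    if not scalp:
        return mask
    sos = sps.butter(3, highpass_hz, btype="highpass",
                     fs=rec.sampling_rate_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.signal[scalp], axis=1)
    spe = int(round(hyp.epoch_len_s * rec.sampling_rate_hz))
    for i in range(hyp.n_epochs):
        seg = filtered[:, i * spe: (i + 1) * spe]
        if seg.size and np.abs(seg).max() > threshold_uv:
            mask[i] = False
    return mask


def sleep_architecture(hyp: Hypnogram) -> SleepArchitecture:
    """Architecture metrics from a hypnogram over the lights-out window.

    Sleep onset (for WASO) is the first epoch of any non-Wake sleep stage.
    SL is minutes from lights out to that epoch (NaN if the subject never
    sleeps); SE = 100 * TST / time in bed.
    """
    window = hyp.stages[hyp.lights_out_epoch: hyp.lights_on_epoch]
    epoch_min = hyp.epoch_len_s / 60.0
    tib_min = len(window) * epoch_min
    minutes = {st: window.count(st) * epoch_min for st in STAGES}
    tst = sum(minutes[s] for s in SLEEP_STAGES)
    onset = next((i for i, s in enumerate(window) if s in SLEEP_STAGES), None)
    if onset is None:
        sl = math.nan
        waso = 0.0
    else:
        sl = onset * epoch_min
        waso = window[onset:].count("Wake") * epoch_min
    se = 100.0 * tst / tib_min if tib_min > 0 else 0.0
    return SleepArchitecture(
        tst_min=tst,
        stage_minutes=minutes,
        sl_min=sl,
        waso_min=waso,
        se_pct=se,
        time_in_bed_min=tib_min,
    )


def architecture_row(arch: SleepArchitecture) -> dict[str, float]:
    """Flatten a SleepArchitecture into one summary-table row."""
    row = {
        "TST_min": arch.tst_min,
        "S1_min": arch.stage_minutes["S1"],
        "S2_min": arch.stage_minutes["S2"],
        "S3_min": arch.stage_minutes["S3"],
        "REM_min": arch.stage_minutes["REM"],
        "SL_min": arch.sl_min,
        "WASO_min": arch.waso_min,
        "SE_pct": arch.se_pct,
    }
    return row
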