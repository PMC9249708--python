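"""Welch power spectra and per-stage band power.

Per 30-s artifact-free epoch, the PSD is estimated with 4-s Hann windows
at 50% overlap (14 segments per epoch) and averaged across the epochs of a
stage before band integration. Band power integrates the linearly
interpolated PSD between the band edges (trapezoidal rule with fractional
end bins), which makes band powers exactly additive over contiguous
sub-intervals: the five analysis bands plus their complement within
0.3-35 Hz always sum to the broadband total.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import EEGRecording, Hypnogram

__all__ = [
    "DEFAULT_BANDS",
    "TOTAL_BAND",
    "COMPLEMENT_NAME",
    "welch_psd",
    "band_power",
    "complement_intervals",
    "stage_band_power",
]

#: Analysis bands (Hz, half-open [low, high)).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "SWA": (0.3, 1.0),
    "delta": (1.0, 4.0),
    "theta": (4.0, 7.0),
    "slow_sigma": (9.0, 11.0),
    "fast_sigma": (12.0, 15.0),
}

#: Broadband denominator for relative power.
TOTAL_BAND: tuple[float, float] = (0.3, 35.0)
COMPLEMENT_NAME = "other"


def welch_psd(epoch_signal: np.ndarray, rate_hz: float,
              segment_s: float = 4.0, overlap: float = 0.5,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD of one epoch in uV^2/Hz over [0, Nyquist]."""
    x = np.asarray(epoch_signal, dtype=float)
    nperseg = int(round(segment_s * rate_hz))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"epoch ({x.shape[-1]} samples) shorter than one "
            f"{segment_s}-s segment ({nperseg} samples)")
    freqs, psd = sps.welch(x, fs=rate_hz, window="hann", nperseg=nperseg,
                           noverlap=int(nperseg * overlap), detrend=False)
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray,
               low_hz: float, high_hz: float) -> float:
    """Integrate the PSD between two frequencies (uV^2).

    The PSD is treated as piecewise linear over the frequency grid;
    fractional end bins are handled by interpolation, so integrals over a
    partition of an interval sum exactly to the integral over the whole.
    """
    if not low_hz < high_hz:
        raise ValueError("require low_hz < high_hz")
    lo = max(low_hz, freqs[0])
    hi = min(high_hz, freqs[-1])
    if hi <= lo:
        return 0.0
    inner = freqs[(freqs > lo) & (freqs < hi)]
    grid = np.concatenate([[lo], inner, [hi]])
    vals = np.interp(grid, freqs, psd)
    return float(np.trapezoid(vals, grid))


def complement_intervals(bands: dict[str, tuple[float, float]],
                         total: tuple[float, float] = TOTAL_BAND,
                         ) -> list[tuple[float, float]]:
    """Sub-intervals of the broadband range not covered by any band."""
    edges = sorted(bands.values())
    out = []
    cursor = total[0]
    for lo, hi in edges:
        if lo > cursor:
            out.append((cursor, min(lo, total[1])))
        cursor = max(cursor, hi)
    if cursor < total[1]:
        out.append((cursor, total[1]))
    return out


def stage_band_power(rec: EEGRecording, hyp: Hypnogram, mask: np.ndarray,
                     bands: dict[str, tuple[float, float]] | None = None,
                     stages: tuple[str, ...] = ("S2", "S3"),
                     channels: list[str] | None = None,
                     subject=None, condition=None,
                     total_band: tuple[float, float] = TOTAL_BAND,
                     ) -> pd.DataFrame:
    """Per-stage absolute and relative band power table.

    PSDs are averaged across the artifact-free epochs of each stage, then
    integrated per band. Relative power is the band's percentage of
    broadband (0.3-35 Hz) power. Channel-average rows "F" (mean of F3/F4)
    and "C" (mean of C3/C4) are appended when both members exist. Stages
    with no artifact-free epochs yield NaN rows flagged by ``n_epochs=0``.
    """
    bands = dict(bands or DEFAULT_BANDS)
    if channels is None:
        channels = rec.channels_with_role("frontal", "central", "parietal",
                                          "occipital")
    fs = rec.sampling_rate_hz
    spe = int(round(hyp.epoch_len_s * fs))
    comp = complement_intervals(bands, total_band)

    rows = []
    for stage in stages:
        epochs = [i for i, st in enumerate(hyp.stages)
                  if st == stage and mask[i] and (i + 1) * spe <= rec.n_samples]
        psd_by_channel: dict[str, np.ndarray] = {}
        freqs = None
        for ch in channels:
            x = rec.get(ch)
            if epochs:
                psds = []
                for i in epochs:
                    freqs, p = welch_psd(x[i * spe: (i + 1) * spe], fs)
                    psds.append(p)
                psd_by_channel[ch] = np.mean(psds, axis=0)
        # synthesize channel-average PSDs (mean PSD == mean band power)
        averages = {"F": ("F3", "F4"), "C": ("C3", "C4")}
        for avg, members in averages.items():
            if all(m in psd_by_channel for m in members):
                psd_by_channel[avg] = np.mean(
                    [psd_by_channel[m] for m in members], axis=0)
        emit = list(channels) + [a for a in averages if a in psd_by_channel]
        for ch in emit:
            if not epochs or ch not in psd_by_channel:
                for name in list(bands) + [COMPLEMENT_NAME]:
                    rows.append(dict(subject=subject, condition=condition,
                                     stage=stage, channel=ch, band=name,
                                     abs_uv2=np.nan, rel_pct=np.nan,
                                     n_epochs=0))
                continue
            psd = psd_by_channel[ch]
            total = band_power(freqs, psd, *total_band)
            powers = {name: band_power(freqs, psd, lo, hi)
                      for name, (lo, hi) in bands.items()}
            powers[COMPLEMENT_NAME] = sum(
                band_power(freqs, psd, lo, hi) for lo, hi in comp)
            for name, p in powers.items():
                rel = 100.0 * p / total if total > 0 else np.nan
                rows.append(dict(subject=subject, condition=condition,
                                 stage=stage, channel=ch, band=name,
                                 abs_uv2=p, rel_pct=rel,
                                 n_epochs=len(epochs)))
    return pd.DataFrame(rows)
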