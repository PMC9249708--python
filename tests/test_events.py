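"""Detector correctness: bursts, criteria boundaries, oracle equivalence."""

import numpy as np
import pytest
from scipy import signal as sps

from sleepmem import (DetectorConfig, EEGRecording, Hypnogram,
                      SlowOscillationEvent, SpindleEvent, couple_so_spindles,
                      detect_slow_oscillations, detect_spindles, event_density,
                      generate_eeg, match_events)
from sleepmem.simulate import EEGSimConfig, so_waveform, spindle_waveform

FS = 128.0


def _recording(x, fs=FS, label="C3"):
    return EEGRecording(signal=np.atleast_2d(np.asarray(x, dtype=float)),
                        sampling_rate_hz=fs, channel_labels=[label])


def _nrem(n_epochs):
    hyp = Hypnogram(stages=["S2"] * n_epochs)
    return hyp, np.ones(n_epochs, dtype=bool)


def brute_force_sos(x, fs, cfg):
    """Literal reference implementation of the five SO criteria.

    Enumerates every consecutive (down, up, down) zero-crossing triple of
    the band-pass filtered signal with an explicit loop, independent of
    the detector's vectorized path.
    """
    sos = sps.butter(3, [cfg.so_filter_low_hz, cfg.so_filter_high_hz],
                     btype="bandpass", fs=fs, output="sos")
    xf = sps.sosfiltfilt(sos, np.asarray(x, dtype=float))
    crossings = []
    for i in range(len(xf) - 1):
        a, b = xf[i], xf[i + 1]
        if (a > 0) != (b > 0):
            t = (i + a / (a - b)) / fs
            crossings.append((t, "down" if a > 0 else "up"))
    found = []
    for k in range(len(crossings) - 2):
        (t1, k1), (t2, k2), (t3, k3) = crossings[k: k + 3]
        if (k1, k2, k3) != ("down", "up", "down"):
            continue
        if not cfg.so_down_dur_min_s <= t2 - t1 <= cfg.so_down_dur_max_s:
            continue
        if not t3 - t1 < cfg.so_max_len_s:
            continue
        seg = xf[int(np.ceil(t1 * fs)): int(np.floor(t2 * fs)) + 1]
        if seg.size == 0 or -seg.min() < cfg.so_down_amp_min_uv:
            continue
        seg_up = xf[int(np.ceil(t2 * fs)): int(np.floor(t3 * fs)) + 1]
        peak = seg_up.max() if seg_up.size else 0.0
        if not peak < cfg.so_up_amp_max_uv:
            continue
        found.append((round(t1, 6), round(t2, 6), round(t3, 6)))
    return found


class TestSpindleDetector:
    def test_flat_signal_no_events(self, detector_cfg):
        hyp, mask = _nrem(4)
        rec = _recording(np.zeros(int(4 * 30 * FS)))
        assert detect_spindles(rec, hyp, mask, detector_cfg,
                               channels=["C3"]) == []

    def test_single_burst_single_event(self, detector_cfg, rng):
        # 1/f-ish background + one 13-Hz burst well above the sigma floor
        n = int(10 * 60 * FS)
        x = rng.normal(0, 5.0, n)
        w = spindle_waveform(FS, 13.0, 30.0, 1.0)
        i0 = n // 2
        x[i0: i0 + len(w)] += w
        hyp, mask = _nrem(20)
        events = detect_spindles(_recording(x), hyp, mask, detector_cfg,
                                 channels=["C3"])
        assert len(events) == 1
        ev = events[0]
        burst_mid = (i0 + len(w) / 2) / FS
        assert abs(ev.peak_s - burst_mid) < 0.5
        assert ev.start_s < ev.peak_s < ev.end_s
        assert detector_cfg.spindle_min_dur_s <= ev.end_s - ev.start_s

    def test_high_snr_recall_and_precision(self, s2_recording):
        _, rec, hyp, mask, truth = s2_recording
        events = detect_spindles(rec, hyp, mask)
        for ch in ("C3", "C4"):
            det = [e.peak_s for e in events if e.channel == ch]
            tru = [s.peak_s for s in truth.spindles if s.channel == ch]
            recall, precision, _ = match_events(det, tru, tol_s=0.5)
            assert recall >= 0.8
            assert precision >= 0.8

    def test_threshold_monotonicity(self, s2_recording):
        _, rec, hyp, mask, _ = s2_recording
        counts = []
        for factor in (2.0, 3.0, 4.0, 5.0, 6.0):
            cfg = DetectorConfig(threshold_factor=factor)
            counts.append(len(detect_spindles(rec, hyp, mask, cfg)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_events_confined_to_nrem(self, detector_cfg):
        cfg = EEGSimConfig(seed=6)
        rec, hyp, truth = generate_eeg(cfg)
        mask = np.ones(hyp.n_epochs, bool)
        for ev in detect_spindles(rec, hyp, mask, detector_cfg):
            assert ev.stage in ("S2", "S3")
            assert hyp.stage_at(ev.peak_s) == ev.stage


class TestSODetector:
    def _inject(self, target_down, up=60.0, d_down=0.5, n_min=2):
        w, _ = so_waveform(FS, target_down, up, d_down_s=d_down)
        x = np.zeros(int(n_min * 60 * FS))
        i0 = len(x) // 2
        x[i0: i0 + len(w)] += w
        return _recording(x)

    def test_flat_signal_no_events(self, detector_cfg):
        hyp, mask = _nrem(4)
        rec = _recording(np.zeros(int(4 * 30 * FS)))
        assert detect_slow_oscillations(rec, hyp, mask, detector_cfg,
                                        channels=["C3"]) == []

    def test_subthreshold_trough_rejected(self, detector_cfg):
        hyp, mask = _nrem(4)
        rec = self._inject(70.0)
        assert detect_slow_oscillations(rec, hyp, mask, detector_cfg,
                                        channels=["C3"]) == []

    def test_amplitude_boundary(self, detector_cfg):
        # the generator calibrates the *filtered* trough to ~1e-9 relative,
        # so the 80-uV criterion can be probed directly at the boundary
        hyp, mask = _nrem(4)
        at_80 = detect_slow_oscillations(self._inject(80.0), hyp, mask,
                                         detector_cfg, channels=["C3"])
        below = detect_slow_oscillations(self._inject(79.9), hyp, mask,
                                         detector_cfg, channels=["C3"])
        assert len(at_80) == 1
        assert at_80[0].trough_amp_uv == pytest.approx(-80.0, abs=1e-6)
        assert below == []

    def test_up_state_boundary(self, detector_cfg):
        hyp, mask = _nrem(4)
        ok = detect_slow_oscillations(self._inject(120.0, up=139.0), hyp,
                                      mask, detector_cfg, channels=["C3"])
        too_high = detect_slow_oscillations(self._inject(120.0, up=141.0),
                                            hyp, mask, detector_cfg,
                                            channels=["C3"])
        assert len(ok) == 1
        assert too_high == []

    @pytest.mark.parametrize("d_down,expect", [
        (0.12, False),  # filtered down state < 0.3 s
        (0.3, True),
        (0.95, True),
        (1.2, False),   # filtered down state > 1.0 s
    ])
    def test_down_duration_boundary(self, detector_cfg, d_down, expect):
        hyp, mask = _nrem(4)
        evs = detect_slow_oscillations(self._inject(120.0, d_down=d_down),
                                       hyp, mask, detector_cfg,
                                       channels=["C3"])
        assert bool(evs) == expect
        if evs:
            dur = evs[0].zc_up_s - evs[0].zc_down1_s
            assert 0.3 <= dur <= 1.0

    def test_oracle_equivalence_on_random_signals(self, detector_cfg, rng):
        """Detector output == literal-criteria brute force, 100 signals."""
        n = int(2 * 60 * FS)
        t = np.arange(n) / FS
        hyp, mask = _nrem(4)
        checked_events = 0
        for _ in range(100):
            x = np.zeros(n)
            for _ in range(rng.integers(3, 8)):
                f = rng.uniform(0.15, 2.5)
                x += rng.uniform(20, 90) * np.sin(
                    2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            x += rng.normal(0, 15, n)
            rec = _recording(x)
            det = detect_slow_oscillations(rec, hyp, mask, detector_cfg,
                                           channels=["C3"])
            got = [(round(e.zc_down1_s, 6), round(e.zc_up_s, 6),
                    round(e.zc_down2_s, 6)) for e in det]
            expected = brute_force_sos(x, FS, detector_cfg)
            assert got == expected
            checked_events += len(expected)
        assert checked_events > 50  # the comparison must be non-vacuous

    def test_invariants_on_detected_events(self, s2_recording):
        _, rec, hyp, mask, _ = s2_recording
        for ev in detect_slow_oscillations(rec, hyp, mask):
            assert ev.zc_down1_s < ev.zc_up_s < ev.zc_down2_s
            assert 0.3 <= ev.zc_up_s - ev.zc_down1_s <= 1.0
            assert ev.zc_down2_s - ev.zc_down1_s < 10.0
            assert ev.trough_amp_uv <= -80.0
            assert ev.peak_amp_uv < 140.0


def _so_at(t, channel="C3"):
    return SlowOscillationEvent(channel=channel, zc_down1_s=t - 0.5,
                                zc_up_s=t + 0.3, zc_down2_s=t + 1.5,
                                trough_s=t, trough_amp_uv=-100.0,
                                peak_amp_uv=50.0, stage="S2")


def _spindle_at(t, channel="C3"):
    return SpindleEvent(channel=channel, start_s=t - 0.4, end_s=t + 0.4,
                        peak_s=t, peak_amplitude=20.0, stage="S2")


class TestCoupling:
    @pytest.mark.parametrize("offset,expect", [
        (-1.5, False), (-1.25, True), (0.0, True), (1.25, True), (1.5, False),
    ])
    def test_window_boundaries(self, detector_cfg, offset, expect):
        pairs = couple_so_spindles([_so_at(100.0)],
                                   [_spindle_at(100.0 + offset)],
                                   detector_cfg)
        assert bool(pairs) == expect
        if pairs:
            assert pairs[0].offset_s == pytest.approx(offset)

    def test_empty_so_list(self, detector_cfg):
        assert couple_so_spindles([], [_spindle_at(10.0)], detector_cfg) == []

    def test_channel_must_match(self, detector_cfg):
        pairs = couple_so_spindles([_so_at(100.0, "C3")],
                                   [_spindle_at(100.0, "C4")], detector_cfg)
        assert pairs == []

    def test_time_reversal_symmetry(self, detector_cfg, rng):
        T = 600.0
        sos = [_so_at(t) for t in rng.uniform(10, T - 10, 15)]
        sps_ = [_spindle_at(t) for t in rng.uniform(10, T - 10, 25)]
        fwd = couple_so_spindles(sos, sps_, detector_cfg)
        rev_sos = [_so_at(T - s.trough_s) for s in sos]
        rev_sps = [_spindle_at(T - s.peak_s) for s in sps_]
        rev = couple_so_spindles(rev_sos, rev_sps, detector_cfg)
        assert len(rev) == len(fwd)
        fwd_offsets = sorted(round(p.offset_s, 9) for p in fwd)
        rev_offsets = sorted(round(-p.offset_s, 9) for p in rev)
        assert fwd_offsets == rev_offsets


class TestDensity:
    def test_simple_arithmetic(self):
        hyp = Hypnogram(stages=["S2"] * 80)  # 40 min
        events = [_spindle_at(10.0 + 20 * k) for k in range(20)]
        assert event_density(events, hyp, "S2") == pytest.approx(0.5)

    def test_no_events_zero(self):
        hyp = Hypnogram(stages=["S2"] * 10)
        assert event_density([], hyp, "S2") == 0.0

    def test_zero_stage_minutes_flagged(self):
        hyp = Hypnogram(stages=["S2"] * 10)
        with pytest.warns(UserWarning, match="density undefined"):
            assert np.isnan(event_density([], hyp, "S3"))

    def test_ground_truth_density_matches_config(self):
        cfg = EEGSimConfig(stage_sequence=[("S2", 30.0)],
                           channels=["C3", "A1", "A2"],
                           spindle_density_per_min=2.0, seed=4)
        _, hyp, truth = generate_eeg(cfg)
        dens = event_density(truth.spindles, hyp, "S2")
        assert dens == pytest.approx(2.0, rel=0.10)
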