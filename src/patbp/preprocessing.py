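"""Baseline removal, R-peak detection, recording gating, ensemble averaging.

The baseline estimator is a cascade of two median filters (250 ms then
600 ms); subtracting the estimate removes slow wander while leaving beat
morphology above ~0.5 Hz essentially intact.  R-peaks come from a
Pan-Tompkins style detector (5-15 Hz band-pass, derivative, squaring, 150 ms
moving integration, adaptive signal/noise thresholds with search-back and a
200 ms refractory period).  Recording-level gating enforces a minimum
duration, a 40-200 BPM mean heart rate and an automated saturation screen
(a programmatic substitute for manual visual inspection).  Ensemble averaging
aligns the waveforms of ten consecutive cardiac cycles at their R-peaks,
truncates to the window's shortest RR interval and averages point-wise,
sliding one cycle at a time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, find_peaks, medfilt, sosfiltfilt

from patbp.io import WaveformRecord


@dataclass
class EnsembledCycle:
    """One ensemble-averaged cardiac cycle, time-referenced to the first
    R-peak of its 10-beat window (that window's leading beat)."""

    window_start_beat: int
    r_time: float
    abp_cycle: np.ndarray
    ppg_cycle: np.ndarray

    @property
    def cycle_len(self) -> int:
        return len(self.abp_cycle)

    def __post_init__(self) -> None:
        if len(self.abp_cycle) != len(self.ppg_cycle):
            raise ValueError("abp and ppg cycles must have equal length")
        if self.cycle_len < 2:
            raise ValueError("cycle_len must be >= 2")


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def remove_baseline(signal: np.ndarray, fs: float,
                    win1_ms: float = 250.0, win2_ms: float = 600.0,
                    cutoff_hz: float = 0.5) -> np.ndarray:
    """Subtract a cascaded-median-filter baseline estimate from *signal*.

    The two medians (250 then 600 ms) track the slow wander through the
    pulses; a zero-phase low-pass at *cutoff_hz* then strips the residual
    beat-frequency ripple from the estimate so that morphology above
    ~0.5 Hz is left untouched by the subtraction.
    """
    x = np.asarray(signal, float)
    if len(x) < 2 * fs:
        raise ValueError("signal shorter than 2 s; cannot estimate baseline")
    k1 = _odd(max(3, int(round(win1_ms / 1000.0 * fs))))
    k2 = _odd(max(3, int(round(win2_ms / 1000.0 * fs))))
    baseline = medfilt(medfilt(x, k1), k2)
    if cutoff_hz > 0:
        sos = butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
        baseline = sosfiltfilt(sos, baseline)
    return x - baseline


def detect_r_peaks(ecg: np.ndarray, fs: float,
                   refractory_ms: float = 200.0) -> np.ndarray:
    """Pan-Tompkins R-peak times (seconds), strictly increasing.

    A flat (or too short) signal yields an empty array rather than an error.
    """
    x = np.asarray(ecg, float)
    if len(x) < 2 * fs or np.ptp(x) == 0:
        return np.array([])
    sos = butter(2, [5.0, 15.0], btype="band", fs=fs, output="sos")
    filt = sosfiltfilt(sos, x)
    deriv = np.gradient(filt) * fs
    sq = deriv * deriv
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    refr = max(1, int(round(refractory_ms / 1000.0 * fs)))
    cand, _ = find_peaks(integ, distance=refr)
    if len(cand) == 0:
        return np.array([])

    # adaptive signal/noise levels initialised from the first two seconds
    head = integ[: max(win, int(2 * fs))]
    spki = 0.5 * float(np.max(head))
    npki = 0.5 * float(np.mean(head))
    thr = npki + 0.25 * (spki - npki)
    accepted: list[int] = []
    for p in cand:
        if integ[p] > thr:
            accepted.append(p)
            spki = 0.125 * integ[p] + 0.875 * spki
        else:
            npki = 0.125 * integ[p] + 0.875 * npki
        thr = npki + 0.25 * (spki - npki)

    # search-back: re-examine long gaps with the lower threshold
    if len(accepted) >= 3:
        rr_med = float(np.median(np.diff(accepted)))
        out: list[int] = [accepted[0]]
        for p in accepted[1:]:
            gap = p - out[-1]
            if gap > 1.66 * rr_med:
                inside = cand[(cand > out[-1] + refr) & (cand < p - refr)]
                if len(inside):
                    best = inside[np.argmax(integ[inside])]
                    if integ[best] > 0.25 * thr:
                        out.append(int(best))
            out.append(int(p))
        accepted = out

    # localise the R wave on the band-passed ECG (T waves are suppressed
    # there) around each integrated peak, which lags R by up to the
    # integration window
    r_idx = []
    for p in accepted:
        lo = max(0, p - win)
        hi = min(len(x), p + 3)
        r_idx.append(lo + int(np.argmax(filt[lo:hi])))
    r_idx = np.array(sorted(set(r_idx)), dtype=int)
    if len(r_idx) > 1:  # enforce refractory on the localised peaks
        keep = [0]
        for i in range(1, len(r_idx)):
            if r_idx[i] - r_idx[keep[-1]] >= refr:
                keep.append(i)
            elif x[r_idx[i]] > x[r_idx[keep[-1]]]:
                keep[-1] = i
        r_idx = r_idx[keep]
    return r_idx / fs


def detect_saturation(signal: np.ndarray, fs: float,
                      min_flat_s: float = 0.5) -> list[tuple[float, float]]:
    """Flag intervals where the signal is saturated or dropped out.

    An interval is flagged when the first difference is exactly zero for
    longer than *min_flat_s*, or the signal sits at its global extreme for
    longer than *min_flat_s*.  Returns merged (start_s, end_s) intervals.
    """
    x = np.asarray(signal, float)
    if len(x) < 2:
        return []
    min_len = int(np.ceil(min_flat_s * fs))
    flat = np.diff(x) == 0.0
    extreme = (x == np.max(x)) | (x == np.min(x))

    def runs(mask: np.ndarray, min_run: int) -> list[tuple[int, int]]:
        out = []
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
        for lo, hi in zip(edges[::2], edges[1::2]):
            if hi - lo > min_run:
                out.append((int(lo), int(hi)))
        return out

    spans = [(lo, hi + 1) for lo, hi in runs(flat, min_len)]
    spans += runs(extreme, min_len)
    spans.sort()
    merged: list[list[int]] = []
    for lo, hi in spans:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo / fs, hi / fs) for lo, hi in merged]


@dataclass
class GateResult:
    accept: bool
    reason: str | None = None  # 'duration' | 'heart_rate' | 'saturation'
    mean_hr_bpm: float | None = None
    saturated_intervals: dict | None = None


def gate_recording(record: WaveformRecord, r_times: np.ndarray,
                   min_duration_min: float = 30.0,
                   hr_lo: float = 40.0, hr_hi: float = 200.0,
                   saturation_min_flat_s: float = 0.5,
                   saturation_max_fraction: float = 0.1) -> GateResult:
    """Recording-level acceptance: duration, saturation screen, mean HR.

    The mean heart rate is computed after excluding beats inside flagged
    saturation intervals, since saturated stretches carry no valid beats.
    """
    if record.duration_s < min_duration_min * 60.0:
        return GateResult(False, "duration")
    sat = {ch: detect_saturation(record.channel(ch), record.fs,
                                 saturation_min_flat_s)
           for ch in ("ecg", "ppg", "abp")}
    worst = max((sum(hi - lo for lo, hi in ivs) for ivs in sat.values()), default=0.0)
    if worst > saturation_max_fraction * record.duration_s:
        return GateResult(False, "saturation", saturated_intervals=sat)
    r = np.asarray(r_times, float)
    flagged = [iv for ivs in sat.values() for iv in ivs]
    if flagged and len(r):
        keep = np.ones(len(r), bool)
        for lo, hi in flagged:
            keep &= ~((r >= record.t0 + lo) & (r <= record.t0 + hi))
        r = r[keep]
    if len(r) < 2:
        return GateResult(False, "heart_rate", mean_hr_bpm=None,
                          saturated_intervals=sat)
    mean_hr = 60.0 / float(np.mean(np.diff(r)))
    if not hr_lo <= mean_hr <= hr_hi:
        return GateResult(False, "heart_rate", mean_hr_bpm=mean_hr,
                          saturated_intervals=sat)
    return GateResult(True, None, mean_hr_bpm=mean_hr, saturated_intervals=sat)


def ensemble_average(signal: np.ndarray, r_times: np.ndarray, fs: float,
                     n_beats: int = 10) -> list[tuple[int, float, np.ndarray]]:
    """Moving-window ensemble average of R-peak-aligned cycles.

    Returns one ``(window_start_beat, r_time, averaged_cycle)`` per window
    position; exactly ``max(0, len(r_times) - n_beats)`` windows.  Cycles in a
    window are truncated to the window's shortest RR interval before
    averaging, preserving sample-accurate timing relative to the R-peak.
    """
    x = np.asarray(signal, float)
    r = np.asarray(r_times, float)
    if len(r) < n_beats + 1:
        return []
    r_idx = np.round(r * fs).astype(int)
    rr = np.diff(r_idx)
    if np.any(rr <= 0):
        raise ValueError("r_times must be strictly increasing")
    min_rr = np.lib.stride_tricks.sliding_window_view(rr, n_beats).min(axis=1)
    out = []
    for w in range(len(r) - n_beats):
        length = int(min_rr[w])
        if r_idx[w + n_beats - 1] + length > len(x):
            length = len(x) - r_idx[w + n_beats - 1]
        if length < 2:
            continue
        segs = np.empty((n_beats, length))
        for j in range(n_beats):
            start = r_idx[w + j]
            segs[j] = x[start: start + length]
        out.append((w, r[w], segs.mean(axis=0)))
    return out


def ensemble_cycles(record: WaveformRecord, r_times: np.ndarray,
                    n_beats: int = 10) -> list[EnsembledCycle]:
    """Ensemble-average the ABP and PPG channels into per-window cycles."""
    abp = ensemble_average(record.abp, r_times, record.fs, n_beats)
    ppg = ensemble_average(record.ppg, r_times, record.fs, n_beats)
    out = []
    for (w, r, a), (_, _, p) in zip(abp, ppg):
        length = min(len(a), len(p))
        out.append(EnsembledCycle(window_start_beat=w, r_time=r,
                                  abp_cycle=a[:length], ppg_cycle=p[:length]))
    return out
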