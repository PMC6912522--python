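"""Per-beat BP values, temporal features, plausibility gating and smoothing.

SBP and DBP are the ABP values at the systolic peak and the foot; MBP is the
arithmetic mean of one averaged cycle; PP = SBP - DBP.  The nine temporal
features are the delays (ms) from the R-peak to the ABP foot (PAT_ABP) and to
each of the four PPG landmarks (PAT_PPG_1..4), plus the same four PPG
landmarks referenced to the ABP foot (PTT1..4 = PAT_PPG_k - PAT_ABP).

Each beat must pass six plausibility conditions; the first failure is
recorded.  Conditions 4 and 6 compare against the nearest earlier *valid*
beat at least 5 s back and pass vacuously when none exists:

1. 50 < SBP < 250 mmHg
2. 30 < DBP < 160 mmHg
3. PP > 10 mmHg
4. |dSBP| < 30 and |dDBP| < 30 mmHg over the previous 5 s
5. 70 < PAT_ABP < 250 ms
6. every PAT/PTT feature changes by < 300 ms over the previous 5 s

Surviving features and BP values are smoothed with a centered 20 s moving
average over valid beats, and subjects with fewer than 100 valid beats are
excluded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from patbp.fiducials import FiducialSet, gate_fiducials
from patbp.io import FEATURE_NAMES, BeatFeatures
from patbp.preprocessing import EnsembledCycle


@dataclass
class ConditionConfig:
    sbp_lo: float = 50.0
    sbp_hi: float = 250.0
    dbp_lo: float = 30.0
    dbp_hi: float = 160.0
    pp_min: float = 10.0
    bp_jump_mmhg: float = 30.0
    pat_abp_lo: float = 70.0
    pat_abp_hi: float = 250.0
    feature_jump_ms: float = 300.0
    lookback_s: float = 5.0


@dataclass
class SubjectSeries:
    """Smoothed, gated per-subject feature / BP time series (valid beats)."""

    subject_id: str
    t: np.ndarray  # beat times, s
    sbp: np.ndarray
    dbp: np.ndarray
    mbp: np.ndarray
    pp: np.ndarray
    pat_abp: np.ndarray
    pat_ppg: np.ndarray  # (n, 4) ms
    ptt: np.ndarray  # (n, 4) ms

    @property
    def n_valid(self) -> int:
        return len(self.t)

    def feature(self, name: str) -> np.ndarray:
        """One of the nine canonical features by name (see FEATURE_NAMES)."""
        if name == "pat_abp":
            return self.pat_abp
        kind, _, idx = name.rpartition("_")
        k = int(idx) - 1
        if kind == "pat_ppg":
            return self.pat_ppg[:, k]
        if kind == "ptt":
            return self.ptt[:, k]
        raise KeyError(f"unknown feature {name!r}")

    def bp(self, name: str) -> np.ndarray:
        if name not in ("sbp", "dbp", "mbp", "pp"):
            raise KeyError(f"unknown BP target {name!r}")
        return getattr(self, name)


@dataclass
class ExclusionRecord:
    subject_id: str
    reason: str
    n_valid: int
    reject_counts: Counter = field(default_factory=Counter)


def extract_bp(abp_cycle: np.ndarray, fiducials: FiducialSet,
               fs: float) -> tuple[float, float, float, float]:
    """(SBP, DBP, MBP, PP) of one averaged ABP cycle in mmHg."""
    if fiducials.abp_peak is None or fiducials.abp_valley is None:
        raise ValueError("ABP fiducials absent; beat is invalid")
    ip = int(round(fiducials.abp_peak * fs))
    iv = int(round(fiducials.abp_valley * fs))
    sbp = float(abp_cycle[ip])
    dbp = float(abp_cycle[iv])
    mbp = float(np.mean(abp_cycle))
    return sbp, dbp, mbp, sbp - dbp


def extract_temporal(r_time: float, fiducials: FiducialSet
                     ) -> tuple[float, tuple, tuple]:
    """(PAT_ABP, PAT_PPG_1..4, PTT1..4) in ms for one beat.

    Fiducial times are relative to the R-peak, so PAT is the fiducial time
    itself and PTT_k = PAT_PPG_k - PAT_ABP by construction.
    """
    if not fiducials.complete():
        raise ValueError("fiducials incomplete; beat is invalid")
    pat_abp = fiducials.abp_valley * 1000.0
    ppg_points = (fiducials.ppg_valley, fiducials.ppg_peak,
                  fiducials.ppg_maxderiv, fiducials.ppg_it)
    pat_ppg = tuple(p * 1000.0 for p in ppg_points)
    ptt = tuple(p - pat_abp for p in pat_ppg)
    return pat_abp, pat_ppg, ptt


def beat_from_cycle(cycle: EnsembledCycle, fiducials: FiducialSet, fs: float,
                    ranges: dict | None = None) -> BeatFeatures:
    """Assemble one BeatFeatures row; invalid rows carry the gate reason."""
    ok, reason = gate_fiducials(fiducials, ranges)
    beat = BeatFeatures(beat_index=cycle.window_start_beat, r_time=cycle.r_time)
    f = fiducials.as_dict()
    for name in f:
        if f[name] is not None:
            setattr(beat, name, float(f[name]))
    if not ok:
        beat.valid = False
        beat.reject_reason = reason
        return beat
    sbp, dbp, mbp, pp = extract_bp(cycle.abp_cycle, fiducials, fs)
    pat_abp, pat_ppg, ptt = extract_temporal(cycle.r_time, fiducials)
    beat.sbp, beat.dbp, beat.mbp, beat.pp = sbp, dbp, mbp, pp
    beat.pat_abp = pat_abp
    beat.pat_ppg = pat_ppg
    beat.ptt = ptt
    beat.valid = True
    return beat


def _features_of(beat: BeatFeatures) -> np.ndarray:
    return np.array([beat.pat_abp, *beat.pat_ppg, *beat.ptt])


def apply_conditions(beats: list[BeatFeatures],
                     config: ConditionConfig | None = None) -> list[BeatFeatures]:
    """Annotate time-ordered beats with the six plausibility conditions.

    Beats already invalid (missing/out-of-range fiducials) stay invalid and
    do not serve as comparison references.  Validity is decided sequentially,
    so a rejected beat never becomes the 5 s-lookback reference.
    """
    cfg = config or ConditionConfig()
    valid_hist: list[BeatFeatures] = []
    for beat in beats:
        if not beat.valid:
            continue
        reason = ""
        if not cfg.sbp_lo < beat.sbp < cfg.sbp_hi:
            reason = "cond1"
        elif not cfg.dbp_lo < beat.dbp < cfg.dbp_hi:
            reason = "cond2"
        elif not beat.pp > cfg.pp_min:
            reason = "cond3"
        else:
            ref = None
            for prev in reversed(valid_hist):
                if prev.r_time <= beat.r_time - cfg.lookback_s:
                    ref = prev
                    break
            if ref is not None and (
                    abs(beat.sbp - ref.sbp) >= cfg.bp_jump_mmhg
                    or abs(beat.dbp - ref.dbp) >= cfg.bp_jump_mmhg):
                reason = "cond4"
            elif not cfg.pat_abp_lo < beat.pat_abp < cfg.pat_abp_hi:
                reason = "cond5"
            elif ref is not None and np.any(
                    np.abs(_features_of(beat) - _features_of(ref))
                    >= cfg.feature_jump_ms):
                reason = "cond6"
        if reason:
            beat.valid = False
            beat.reject_reason = reason
        else:
            beat.valid = True
            beat.reject_reason = ""
            valid_hist.append(beat)
    return beats


def _moving_average(t: np.ndarray, values: np.ndarray, half_window_s: float,
                    centered: bool = True) -> np.ndarray:
    """Mean of *values* over beats within the time window around each beat."""
    if centered:
        lo = np.searchsorted(t, t - half_window_s, side="left")
        hi = np.searchsorted(t, t + half_window_s, side="right")
    else:  # trailing window
        lo = np.searchsorted(t, t - 2 * half_window_s, side="left")
        hi = np.arange(1, len(t) + 1)
    csum = np.concatenate(([0.0], np.cumsum(values, axis=0)))
    return (csum[hi] - csum[lo]) / (hi - lo)


def smooth_series(series: SubjectSeries, window_s: float = 20.0,
                  centered: bool = True) -> SubjectSeries:
    """Smooth every feature and BP array with a moving average over valid
    beats (window *window_s* wide, centered by default).  Length unchanged."""
    half = window_s / 2.0

    def sm(v: np.ndarray) -> np.ndarray:
        if v.ndim == 1:
            return _moving_average(series.t, v, half, centered)
        return np.column_stack([
            _moving_average(series.t, v[:, k], half, centered)
            for k in range(v.shape[1])
        ])

    return SubjectSeries(
        subject_id=series.subject_id,
        t=series.t.copy(),
        sbp=sm(series.sbp), dbp=sm(series.dbp),
        mbp=sm(series.mbp), pp=sm(series.pp),
        pat_abp=sm(series.pat_abp),
        pat_ppg=sm(series.pat_ppg), ptt=sm(series.ptt),
    )


def build_subject_series(subject_id: str, beats: list[BeatFeatures],
                         min_valid: int = 100, window_s: float = 20.0,
                         smooth: bool = True
                         ) -> SubjectSeries | ExclusionRecord:
    """Collect valid beats into a (smoothed) SubjectSeries, or exclude the
    subject with per-reason counts when fewer than *min_valid* remain."""
    valid = [b for b in beats if b.valid]
    if len(valid) < min_valid:
        counts = Counter(b.reject_reason for b in beats if not b.valid)
        return ExclusionRecord(subject_id=subject_id, reason="n_beats",
                               n_valid=len(valid), reject_counts=counts)
    series = SubjectSeries(
        subject_id=subject_id,
        t=np.array([b.r_time for b in valid]),
        sbp=np.array([b.sbp for b in valid]),
        dbp=np.array([b.dbp for b in valid]),
        mbp=np.array([b.mbp for b in valid]),
        pp=np.array([b.pp for b in valid]),
        pat_abp=np.array([b.pat_abp for b in valid]),
        pat_ppg=np.array([b.pat_ppg for b in valid]),
        ptt=np.array([b.ptt for b in valid]),
    )
    if smooth:
        series = smooth_series(series, window_s=window_s)
    return series
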