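"""Synthetic ECG/PPG/ABP cohorts with analytic, per-beat ground truth.

The generator emulates the statistical structure the extraction pipeline
assumes: a beat train whose R-peaks follow a heart-rate trajectory; an ABP
pulse train whose per-cycle maximum/minimum equal the systolic/diastolic
trajectories exactly; and a PPG pulse train whose intersecting-tangent onset
lands at R-peak + PAT, where PAT is linearly coupled to systolic pressure
with additive white noise plus a slow Ornstein-Uhlenbeck drift (the drift
stands in for the pre-ejection-period and vasomotor variability that limits
the PAT-BP correlation in real recordings).  The peripheral ABP-foot-to-PPG
transit time is generated independently of BP, so pulse transit time is
decoupled from pressure unless configured otherwise.  A constant device
delay can be added to the PPG channel to emulate a fixed acquisition offset
between monitors.

All ground-truth fiducial times are continuous (not snapped to the sample
grid) and exact for the rendered waveforms, because the pulse templates'
landmark phases are known analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from patbp import _templates as tpl
from patbp.io import WaveformRecord

Trajectory = Callable[[np.ndarray], np.ndarray] | float

ARTIFACT_KINDS = ("saturation", "dropout")


@dataclass(frozen=True)
class Artifact:
    """A measurement artifact on one channel: saturation clamp or dropout."""

    channel: str
    start_s: float
    end_s: float
    kind: str = "saturation"

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.end_s <= self.start_s:
            raise ValueError("artifact end must be after start")


@dataclass
class SimConfig:
    """Study conditions for one simulated subject.

    Trajectories may be constants or callables of time (vectorized, seconds).
    PAT coupling: PAT_ABP(t) = pep_ms + intercept + slope * SBP(t) + drift +
    noise, with slope in ms/mmHg (non-positive).  The PPG onset adds an
    independently drifting peripheral transit time plus the constant device
    delay.
    """

    duration_s: float = 1200.0
    fs: float = 100.0
    hr_trajectory: Trajectory = 75.0
    sbp_trajectory: Trajectory = 120.0
    dbp_trajectory: Trajectory = 60.0
    pat_coupling_slope: float = -1.0  # ms per mmHg
    pat_coupling_intercept: float = 206.0  # ms
    pat_noise_sd: float = 8.0  # ms, white per beat
    pat_drift_sd: float = 20.0  # ms, slow OU drift
    pat_drift_tau_s: float = 180.0
    pep_ms: float = 60.0
    peripheral_delay_ms: float = 150.0  # ABP foot -> PPG onset transit
    ptt_noise_sd: float = 5.0
    ptt_drift_sd: float = 10.0
    ptt_drift_tau_s: float = 180.0
    device_delay_ms: float = 0.0  # constant PPG channel delay
    baseline_wander_amp: float = 0.1
    baseline_wander_freq_hz: float = 0.25
    noise_sd: float = 0.02  # ECG/PPG additive white noise (signal units)
    abp_noise_sd: float = 0.5  # mmHg
    artifact_spec: tuple[Artifact, ...] = ()
    subject_id: str = "sim"
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.pat_coupling_slope > 0:
            raise ValueError("pat_coupling_slope must be <= 0")
        t = np.arange(0.0, self.duration_s, 1.0)
        hr = _eval_traj(self.hr_trajectory, t)
        if np.any(hr <= 20.0) or np.any(hr >= 250.0):
            raise ValueError("heart rate trajectory outside (20, 250) BPM")
        sbp = _eval_traj(self.sbp_trajectory, t)
        dbp = _eval_traj(self.dbp_trajectory, t)
        if np.any(sbp <= dbp):
            raise ValueError("sbp_trajectory must exceed dbp_trajectory everywhere")


@dataclass
class GroundTruth:
    """Exact per-beat quantities behind a rendered record.

    ``true_pat_*`` exclude the device delay (they are the physiological
    delays); the rendered PPG channel is additionally shifted by
    ``device_delay_ms``.  ``true_ptt[:, k] = true_pat_ppg[:, k] -
    true_pat_abp`` holds exactly by construction.
    """

    r_times: np.ndarray  # s
    true_sbp: np.ndarray  # mmHg
    true_dbp: np.ndarray
    true_mbp: np.ndarray
    true_pp: np.ndarray
    true_pat_abp: np.ndarray  # ms
    true_pat_ppg: np.ndarray  # (n, 4) ms; columns: valley, peak, maxderiv, IT
    true_ptt: np.ndarray  # (n, 4) ms
    device_delay_ms: float = 0.0

    @property
    def n_beats(self) -> int:
        return len(self.r_times)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "r_time": self.r_times,
            "true_sbp": self.true_sbp,
            "true_dbp": self.true_dbp,
            "true_mbp": self.true_mbp,
            "true_pp": self.true_pp,
            "true_pat_abp": self.true_pat_abp,
        }
        for k in range(4):
            data[f"true_pat_ppg_{k + 1}"] = self.true_pat_ppg[:, k]
        for k in range(4):
            data[f"true_ptt_{k + 1}"] = self.true_ptt[:, k]
        return pd.DataFrame(data)


@dataclass
class CohortSubject:
    subject_id: str
    record: WaveformRecord
    truth: GroundTruth
    metadata: dict
    config: SimConfig


def _eval_traj(traj: Trajectory, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, float)
    if callable(traj):
        return np.broadcast_to(np.asarray(traj(t), float), t.shape).astype(float)
    return np.full_like(t, float(traj))


def _ou_path(rng: np.random.Generator, times: np.ndarray, tau: float,
             sd: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck samples at (possibly uneven) *times*."""
    n = len(times)
    x = np.zeros(n)
    if sd <= 0 or n == 0:
        return x
    x[0] = sd * rng.standard_normal()
    for i in range(1, n):
        a = math.exp(-(times[i] - times[i - 1]) / tau)
        x[i] = a * x[i - 1] + sd * math.sqrt(max(0.0, 1 - a * a)) * rng.standard_normal()
    return x


def _beat_times(config: SimConfig) -> np.ndarray:
    """Integrate the heart-rate trajectory into R-peak times."""
    r = []
    t = 1.0  # lead-in so the first pulse is fully rendered
    stop = config.duration_s - 2.0
    while t <= stop:
        r.append(t)
        hr = float(_eval_traj(config.hr_trajectory, np.array([t]))[0])
        if not 20.0 < hr < 250.0:
            raise ValueError(f"heart rate {hr:.1f} BPM outside (20, 250) at t={t:.1f}")
        t += 60.0 / hr
    if len(r) < 12:
        raise ValueError("record too short: fewer than 12 beats")
    return np.asarray(r)


def generate_beat_truth(config: SimConfig,
                        rng: np.random.Generator | None = None) -> GroundTruth:
    """Per-beat ground truth (no waveform rendering).

    This is the generative model itself: useful for feature-level studies
    (e.g. slope-recovery simulations) where rendering and re-extracting
    waveforms would only add quantization noise.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    r = _beat_times(config)
    n = len(r)
    sbp = _eval_traj(config.sbp_trajectory, r)
    dbp = _eval_traj(config.dbp_trajectory, r)

    pat_drift = _ou_path(rng, r, config.pat_drift_tau_s, config.pat_drift_sd)
    pat_noise = config.pat_noise_sd * rng.standard_normal(n)
    pat_abp = (config.pep_ms + config.pat_coupling_intercept
               + config.pat_coupling_slope * sbp + pat_drift + pat_noise)

    ptt_drift = _ou_path(rng, r, config.ptt_drift_tau_s, config.ptt_drift_sd)
    ptt_noise = config.ptt_noise_sd * rng.standard_normal(n)
    ptt4 = config.peripheral_delay_ms + ptt_drift + ptt_noise

    pat4 = pat_abp + ptt4

    # landmark geometry of the rendered PPG train (IT-anchored warping)
    ppg_lm = tpl.CycleTemplate(tpl.PPG_COMPONENTS).landmarks
    tau = r + pat4 / 1000.0  # IT anchor times (physiological, no device delay)
    d_tau = np.diff(tau)
    t_cur = np.append(d_tau, d_tau[-1])  # warp of the segment starting at tau_i
    t_prev = np.insert(d_tau, 0, d_tau[0])  # warp of the segment ending at tau_i

    pat_ppg = np.empty((n, 4))
    pat_ppg[:, 3] = pat4
    pat_ppg[:, 0] = pat4 - ppg_lm.v_it * t_prev * 1000.0  # diastolic valley
    pat_ppg[:, 1] = pat4 + (ppg_lm.v_peak - ppg_lm.v_it) * t_cur * 1000.0
    pat_ppg[:, 2] = pat4 + (ppg_lm.v_md - ppg_lm.v_it) * t_cur * 1000.0

    ptt = pat_ppg - pat_abp[:, None]

    abp_lm = tpl.CycleTemplate(tpl.ABP_COMPONENTS).landmarks
    mbp = dbp + abp_lm.mean_norm * (sbp - dbp)

    return GroundTruth(
        r_times=r,
        true_sbp=sbp,
        true_dbp=dbp,
        true_mbp=mbp,
        true_pp=sbp - dbp,
        true_pat_abp=pat_abp,
        true_pat_ppg=pat_ppg,
        true_ptt=ptt,
        device_delay_ms=config.device_delay_ms,
    )


def generate_record(config: SimConfig) -> tuple[WaveformRecord, GroundTruth]:
    """Render a full three-channel record plus its exact ground truth.

    Identical config (including seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = generate_beat_truth(config, rng)
    n_samples = int(round(config.duration_s * config.fs))
    t = np.arange(n_samples) / config.fs

    ecg = tpl.render_ecg(t, truth.r_times)

    abp_template = tpl.CycleTemplate(tpl.ABP_COMPONENTS)
    foot_times = truth.r_times + truth.true_pat_abp / 1000.0
    abp = tpl.render_pulse_train(t, foot_times, abp_template, 0.0,
                                 truth.true_dbp, truth.true_sbp)

    ppg_template = tpl.CycleTemplate(tpl.PPG_COMPONENTS)
    it_times = (truth.r_times
                + (truth.true_pat_ppg[:, 3] + config.device_delay_ms) / 1000.0)
    zeros = np.zeros(truth.n_beats)
    ones = np.ones(truth.n_beats)
    ppg = tpl.render_pulse_train(t, it_times, ppg_template,
                                 ppg_template.landmarks.v_it, zeros, ones)

    # measurement imperfections: baseline wander (ECG/PPG) and white noise
    if config.baseline_wander_amp > 0:
        f = config.baseline_wander_freq_hz
        ph = rng.uniform(0, 2 * np.pi, size=4)
        wander_e = config.baseline_wander_amp * (
            np.sin(2 * np.pi * f * t + ph[0]) + 0.5 * np.sin(2 * np.pi * f / 3 * t + ph[1]))
        wander_p = config.baseline_wander_amp * (
            np.sin(2 * np.pi * f * t + ph[2]) + 0.5 * np.sin(2 * np.pi * f / 3 * t + ph[3]))
        ecg = ecg + wander_e
        ppg = ppg + wander_p
    if config.noise_sd > 0:
        ecg = ecg + config.noise_sd * rng.standard_normal(n_samples)
        ppg = ppg + config.noise_sd * rng.standard_normal(n_samples)
    if config.abp_noise_sd > 0:
        abp = abp + config.abp_noise_sd * rng.standard_normal(n_samples)

    record = WaveformRecord(subject_id=config.subject_id, fs=config.fs,
                            ecg=ecg, ppg=ppg, abp=abp)
    if config.artifact_spec:
        record = inject_artifacts(record, config.artifact_spec)
    return record, truth


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def inject_artifacts(record: WaveformRecord,
                     artifact_spec: Sequence[Artifact]) -> WaveformRecord:
    """Return a copy of *record* with saturation/dropout intervals applied.

    Saturation clamps the channel at its rail (the channel's global maximum);
    dropout holds the value at the interval start.  Overlapping intervals of
    the same kind are merged.  Untouched samples are bit-identical.
    """
    out = record.copy()
    for art in artifact_spec:
        if art.start_s < record.t0 or art.end_s > record.t0 + record.duration_s:
            raise ValueError(
                f"artifact [{art.start_s}, {art.end_s}] s outside record duration")
    for channel in set(a.channel for a in artifact_spec):
        sig = out.channel(channel)
        for kind in ARTIFACT_KINDS:
            spans = [
                (int(round((a.start_s - record.t0) * record.fs)),
                 int(round((a.end_s - record.t0) * record.fs)))
                for a in artifact_spec
                if a.channel == channel and a.kind == kind
            ]
            if kind == "saturation":
                rail = float(np.max(sig))
            for lo, hi in _merge_intervals(spans):
                lo = max(lo, 0)
                hi = min(hi, len(sig))
                if kind == "saturation":
                    sig[lo:hi] = rail
                else:
                    sig[lo:hi] = sig[lo]
    return out


# ---------------------------------------------------------------------------
# cohort generation


def _clip(x: float, lo: float, hi: float) -> float:
    return float(min(max(x, lo), hi))


def default_config_sampler(rng: np.random.Generator, index: int,
                           duration_s: float = 1200.0,
                           fs: float = 100.0) -> tuple[SimConfig, dict]:
    """Draw one subject's study conditions.

    Demographic marginals follow a surgical-cohort profile (age 58 +/- 15,
    53% male, BMI 23 +/- 4, 34% hypertensive, 11% diabetic).  Blood pressure
    follows a slow sinusoid (10 min period) plus a bounded random walk, with
    amplitudes spread so per-subject SBP ranges span a few tens of mmHg;
    diastolic pressure co-moves with systolic at a reduced gain.
    """
    age = _clip(rng.normal(58.0, 15.0), 5.0, 92.0)
    male = bool(rng.random() < 0.53)
    bmi = _clip(rng.normal(23.0, 4.0), 14.0, 45.0)
    hypertension = bool(rng.random() < 0.34)
    diabetes = bool(rng.random() < 0.11)

    hr0 = _clip(rng.normal(75.0, 8.0), 58.0, 100.0)
    hr_phase = rng.uniform(0, 2 * np.pi)
    sbp0 = _clip(rng.normal(116.0, 15.0), 90.0, 165.0)
    dbp0 = _clip(0.54 * sbp0 + rng.normal(0.0, 4.0), 45.0, sbp0 - 30.0)

    amp = rng.uniform(8.0, 22.0)
    phase = rng.uniform(0, 2 * np.pi)
    grid = np.arange(0.0, duration_s + 4.0, 2.0)
    walk = _ou_path(rng, grid, 200.0, 6.0)
    dwalk = _ou_path(rng, grid, 200.0, 2.0)
    sbp_dev = amp * np.sin(2 * np.pi * grid / 600.0 + phase) + walk
    dbp_dev = 0.55 * sbp_dev + dwalk

    def sbp_fn(t, _g=grid, _d=sbp_dev, _b=sbp0):
        return _b + np.interp(t, _g, _d)

    def dbp_fn(t, _g=grid, _d=dbp_dev, _b=dbp0):
        return _b + np.interp(t, _g, _d)

    def hr_fn(t, _b=hr0, _p=hr_phase):
        return _b + 3.0 * np.sin(2 * np.pi * np.asarray(t) / 300.0 + _p)

    config = SimConfig(
        duration_s=duration_s,
        fs=fs,
        hr_trajectory=hr_fn,
        sbp_trajectory=sbp_fn,
        dbp_trajectory=dbp_fn,
        subject_id=f"subj{index:04d}",
        seed=int(rng.integers(2**31)),
    )
    metadata = {
        "age": round(age),
        "gender": "male" if male else "female",
        "bmi": round(bmi, 1),
        "hypertension": hypertension,
        "diabetes": diabetes,
    }
    return config, metadata


def generate_cohort(n_subjects: int,
                    config_sampler: Callable[..., tuple[SimConfig, dict]] | None = None,
                    seed: int = 0) -> list[CohortSubject]:
    """Generate *n_subjects* independent records with per-subject substreams.

    Subject k's output depends only on (seed, k), so cohorts are reproducible
    and subjects are identical across differently sized cohorts.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    sampler = config_sampler if config_sampler is not None else default_config_sampler
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    cohort = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        config, metadata = sampler(rng, k)
        record, truth = generate_record(config)
        record.metadata = dict(metadata)
        cohort.append(CohortSubject(subject_id=config.subject_id, record=record,
                                    truth=truth, metadata=metadata, config=config))
    return cohort


def with_device_delay(config: SimConfig, delay_ms: float) -> SimConfig:
    """Copy of *config* with only the constant PPG device delay changed."""
    return replace(config, device_delay_ms=delay_ms)
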