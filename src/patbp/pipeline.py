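"""End-to-end orchestration: record -> beats -> series -> model -> report.

``process_record`` runs one record through baseline removal, R-peak
detection, recording-level gating, artifact masking, ensemble averaging,
fiducial detection, plausibility conditions, smoothing and the >= 100-beat
subject gate.  ``run_extract`` maps it over a cohort and tallies exclusions;
``run_study`` performs the correlation analysis, fits the calibrated linear
model per BP target and grades it against the device standards.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from patbp import fiducials as fid
from patbp import preprocessing as pre
from patbp.evaluation import EvaluationReport, evaluate_model
from patbp.features import (
    ConditionConfig,
    ExclusionRecord,
    SubjectSeries,
    apply_conditions,
    beat_from_cycle,
    build_subject_series,
)
from patbp.io import BeatFeatures, WaveformRecord
from patbp.modeling import (
    CalibratedLinearModel,
    correlation_table,
    fit_calibrated_model,
    pairs_from_series,
    per_subject_slope,
    pearson,
    UndefinedCorrelationError,
)


@dataclass
class PipelineConfig:
    # baseline removal (ECG and PPG only; ABP stays in absolute mmHg)
    baseline_win1_ms: float = 250.0
    baseline_win2_ms: float = 600.0
    # R-peak detection
    pt_refractory_ms: float = 200.0
    # recording gate
    gate_min_duration_min: float = 30.0
    gate_hr_lo: float = 40.0
    gate_hr_hi: float = 200.0
    saturation_min_flat_s: float = 0.5
    saturation_max_fraction: float = 0.1
    # ensemble averaging
    ensemble_n_beats: int = 10
    # fiducial gating ranges, ms relative to R-peak
    fiducial_ranges: dict = field(default_factory=dict)
    # plausibility conditions
    conditions: ConditionConfig = field(default_factory=ConditionConfig)
    # smoothing and subject gate
    smooth_window_s: float = 20.0
    smooth_centered: bool = True
    min_valid_beats: int = 100


@dataclass
class ExtractionResult:
    subject_id: str
    accepted: bool
    reason: str | None  # None | duration | heart_rate | saturation | n_beats
    beats: list[BeatFeatures]
    series: SubjectSeries | None
    reject_counts: Counter


def extract_beats(record: WaveformRecord, r_times: np.ndarray,
                  config: PipelineConfig | None = None,
                  flagged: list[tuple[float, float]] | None = None
                  ) -> list[BeatFeatures]:
    """Ensemble-average and extract one BeatFeatures row per window.

    Windows overlapping a flagged (saturated/dropout) interval on any channel
    are marked invalid with reason ``artifact``.
    """
    cfg = config or PipelineConfig()
    cycles = pre.ensemble_cycles(record, r_times, cfg.ensemble_n_beats)
    r = np.asarray(r_times, float)
    beats = []
    for cyc in cycles:
        w = cyc.window_start_beat
        win_lo = r[w]
        win_hi = r[w + cfg.ensemble_n_beats] if w + cfg.ensemble_n_beats < len(r) \
            else r[-1] + cyc.cycle_len / record.fs
        if flagged and any(lo < win_hi and hi > win_lo for lo, hi in flagged):
            beats.append(BeatFeatures(beat_index=w, r_time=cyc.r_time,
                                      valid=False, reject_reason="artifact"))
            continue
        fset = fid.merge_fiducials(
            fid.detect_abp_fiducials(cyc, record.fs),
            fid.detect_ppg_fiducials(cyc, record.fs),
        )
        beats.append(beat_from_cycle(cyc, fset, record.fs,
                                     cfg.fiducial_ranges or None))
    return beats


def process_record(record: WaveformRecord,
                   config: PipelineConfig | None = None) -> ExtractionResult:
    """Full single-record extraction; see the module docstring for stages."""
    cfg = config or PipelineConfig()
    ecg = pre.remove_baseline(record.ecg, record.fs,
                              cfg.baseline_win1_ms, cfg.baseline_win2_ms)
    ppg = pre.remove_baseline(record.ppg, record.fs,
                              cfg.baseline_win1_ms, cfg.baseline_win2_ms)
    clean = WaveformRecord(subject_id=record.subject_id, fs=record.fs,
                           ecg=ecg, ppg=ppg, abp=record.abp, t0=record.t0,
                           metadata=record.metadata)
    r_times = pre.detect_r_peaks(ecg, record.fs, cfg.pt_refractory_ms)
    gate = pre.gate_recording(record, r_times,
                              cfg.gate_min_duration_min,
                              cfg.gate_hr_lo, cfg.gate_hr_hi,
                              cfg.saturation_min_flat_s,
                              cfg.saturation_max_fraction)
    if not gate.accept:
        return ExtractionResult(record.subject_id, False, gate.reason,
                                [], None, Counter())
    flagged = [iv for ivs in (gate.saturated_intervals or {}).values()
               for iv in ivs]
    beats = extract_beats(clean, r_times, cfg, flagged)
    beats = apply_conditions(beats, cfg.conditions)
    built = build_subject_series(record.subject_id, beats,
                                 min_valid=cfg.min_valid_beats,
                                 window_s=cfg.smooth_window_s,
                                 smooth=True)
    counts = Counter(b.reject_reason for b in beats if not b.valid)
    if isinstance(built, ExclusionRecord):
        return ExtractionResult(record.subject_id, False, "n_beats",
                                beats, None, counts)
    return ExtractionResult(record.subject_id, True, None, beats, built, counts)


def run_extract(records: list[WaveformRecord],
                config: PipelineConfig | None = None
                ) -> tuple[list[SubjectSeries], pd.DataFrame]:
    """Extract a cohort; returns included series plus an exclusion summary
    (one row per record with the stage that rejected it, if any)."""
    series, rows = [], []
    for record in records:
        result = process_record(record, config)
        rows.append({
            "subject_id": record.subject_id,
            "accepted": result.accepted,
            "reason": result.reason or "",
            "n_valid": result.series.n_valid if result.series else
                       sum(b.valid for b in result.beats),
            "n_beats_total": len(result.beats),
        })
        if result.series is not None:
            series.append(result.series)
    return series, pd.DataFrame(rows)


@dataclass
class StudyResult:
    corr_mean: pd.DataFrame  # 4 BP x 9 features, mean across subjects
    corr_sd: pd.DataFrame
    models: dict  # target -> CalibratedLinearModel
    reports: dict  # target -> EvaluationReport
    subject_table: pd.DataFrame  # per-subject slopes/correlations/Delta-BP
    n_subjects: int


def run_study(cohort: list[SubjectSeries],
              metadata: dict[str, dict] | None = None,
              targets: tuple[str, ...] = ("sbp", "dbp"),
              feature: str = "pat_ppg_4") -> StudyResult:
    """Correlation analysis + calibrated linear model + standards grading."""
    if len(cohort) < 2:
        raise ValueError("need at least 2 included subjects")
    _, corr_mean, corr_sd, _ = correlation_table(cohort)
    models: dict[str, CalibratedLinearModel] = {}
    reports: dict[str, EvaluationReport] = {}
    for target in targets:
        pairs = pairs_from_series(cohort, target=target, feature=feature)
        model = fit_calibrated_model(pairs, target=target)
        models[target] = model
        reports[target] = evaluate_model(model, cohort, target, feature)

    rows = []
    for s in cohort:
        row: dict = {"subject_id": s.subject_id, "n_valid": s.n_valid}
        for target in ("sbp", "dbp"):
            bp = s.bp(target)
            row[f"delta_{target}"] = float(bp.max() - bp.min())
            row[f"mean_{target}"] = float(bp.mean())
            try:
                row[f"corr_{target}"] = pearson(s.feature(feature), bp)
            except UndefinedCorrelationError:
                row[f"corr_{target}"] = np.nan
            try:
                row[f"slope_{target}"] = per_subject_slope(s, target, feature)
            except UndefinedCorrelationError:
                row[f"slope_{target}"] = np.nan
        if metadata and s.subject_id in metadata:
            row.update(metadata[s.subject_id])
        rows.append(row)
    return StudyResult(corr_mean=corr_mean, corr_sd=corr_sd, models=models,
                       reports=reports, subject_table=pd.DataFrame(rows),
                       n_subjects=len(cohort))
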