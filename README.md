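# patbp — pulse arrival time as a blood-pressure indicator

`patbp` is an analysis pipeline for the central question of cuffless blood
pressure monitoring: **how well do the timing features between ECG, PPG and
arterial pressure waveforms track beat-by-beat blood pressure?** It is
aimed at biosignal researchers who want a tested, reproducible
re-implementation of the classic extraction → correlation → calibrated
linear model → device-standards evaluation chain, exercised on synthetic
waveform cohorts with exact ground truth.

## What it computes

From time-synchronized ECG (lead II), finger PPG and radial ABP at 100 Hz,
per cardiac cycle:

- reference BP: SBP, DBP (ABP peak/foot values), MBP (cycle mean),
  PP = SBP − DBP;
- nine temporal features: PAT_ABP (R-peak → ABP foot), PAT_PPG_1–4 (R-peak →
  PPG valley / peak / max-derivative / intersecting-tangent point), and
  PTT1–4 (ABP foot → the same PPG landmarks), with
  PTT_k = PAT_PPG_k − PAT_ABP by construction.

The intersecting-tangent (IT) onset is the intersection of the tangent at
the PPG's maximum upslope with the horizontal tangent through its diastolic
minimum, `t_IT = t_md − (y(t_md) − y_min)/y′(t_md)`, kept at sub-sample
resolution.

Extraction follows the standard recipe: nonlinear (median-cascade) baseline
removal, Pan–Tompkins R-peak detection, 10-beat moving ensemble averaging,
fiducial gating, six plausibility conditions (BP ranges, pulse-pressure
floor, PAT_ABP range, and 5-s jump limits on BP and on every feature), 20-s
smoothing, and a ≥100-valid-beat subject gate.

Modelling and evaluation: per-subject Pearson correlations (summarised
mean ± SD across subjects); a pooled linear model `BP = α₁·PAT_PPG_4 + α₀`
calibrated by subtracting each subject's mean BP and mean PAT before
fitting α₁ and adding the mean BP back as α₀; ME/SDE/MAD, cumulative error
percentages within 5/10/15 mmHg, and AAMI / BHS / IEEE-1708 grading.

Because per-subject mean calibration removes each subject's offset exactly,
the model's mean error is zero up to floating-point rounding — by design,
not by accuracy; SDE and MAD carry the real information.

## Worked example

```python
from patbp.studies import make_study_cohort, study_pipeline_config
from patbp.pipeline import run_extract, run_study
from patbp.evaluation import report_text

cohort = make_study_cohort(4, seed=7, duration_s=600.0)
series, exclusions = run_extract([c.record for c in cohort],
                                 study_pipeline_config())
study = run_study(series, {c.subject_id: c.metadata for c in cohort})
print(study.corr_mean.round(2).loc[["sbp", "dbp"],
                                   ["pat_abp", "pat_ppg_4", "ptt_4"]])
print(report_text(study.reports))
```

prints

```
     pat_abp  pat_ppg_4  ptt_4
sbp    -0.54      -0.49   0.20
dbp    -0.55      -0.55   0.15

Performance measure                 SBP         DBP
Correlation to reference           0.49        0.55
ME (mmHg)                     -6.15e-15    5.69e-16
SDE (mmHg)                         9.01        5.30
Cum. error <5 mmHg (%)             45.8        64.7
Cum. error <10 mmHg (%)            68.2        94.3
Cum. error <15 mmHg (%)            90.4       100.0
MAD (mmHg)                         7.28        4.28
AAMI                               fail        pass
BHS grade                             C           A
IEEE-1708 grade                       D           A
```

Reading it: the pulse-arrival-time features correlate clearly negatively
with BP (arterial stiffening at higher pressure shortens the transit),
while the peripheral PPG-based transit time — decoupled from BP in this
cohort — hovers near zero. The calibrated model's ME is numerically zero by
construction; diastolic pressure, with its smaller dynamic range, grades
well against the monitor standards while systolic does not. That asymmetry
is a property of pooled error-based grading, not of the predictor.

## Repository layout

- `src/patbp/` — the library: `simulate` (synthetic ECG/PPG/ABP cohorts
  with analytic ground truth), `io` (text record/table formats),
  `preprocessing`, `fiducials`, `features`, `modeling`, `evaluation`,
  `pipeline` (orchestration), `studies` (pre-registered synthetic study
  designs).
- `analysis/01–06` — numbered drivers: simulate cohort → extract features →
  correlation table → fit BP model → standards grading → risk-factor
  regression and ΔBP stratification. Waveforms land in `scratch/`
  (regenerable), summary tables in `results/`.
- `docs/methods.md` — the full methods note: generator model, numerical
  choices, study designs and limitations.

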