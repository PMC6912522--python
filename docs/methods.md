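# Methods

## Scope and model

`patbp` re-implements, end to end, a beat-by-beat analysis of the coupling
between pulse arrival time (PAT) and arterial blood pressure (BP):

1. **Extraction.** From time-synchronized ECG (lead II), finger PPG and
   radial ABP sampled at 100 Hz, each cardiac cycle yields four reference BP
   values (SBP, DBP, MBP, PP) and nine temporal features: PAT_ABP (R-peak to
   ABP foot), PAT_PPG_1–4 (R-peak to the PPG valley / peak / maximum
   derivative / intersecting-tangent point) and PTT1–4 (the same four PPG
   landmarks referenced to the ABP foot, so PTT_k = PAT_PPG_k − PAT_ABP by
   construction).
2. **Modelling.** Per subject, Pearson correlations between each BP value
   and each feature; pooled across subjects, a calibrated linear model
   `BP = α₁·PAT_PPG_4 + α₀` in which each subject's mean BP and mean PAT are
   removed before fitting the single pooled slope α₁, and the subject mean BP
   is restored as α₀ at prediction time.
3. **Evaluation.** ME / SDE / MAD of the predictions (mean error; sample SD
   of the error with n−1 denominator; mean absolute difference), cumulative
   error percentages within 5/10/15 mmHg, and grading against AAMI
   (|ME| ≤ 5 and SDE ≤ 8 mmHg), BHS (A ≥ 60/85/95, B ≥ 50/75/90,
   C ≥ 40/65/85, else D) and IEEE-1708 (MAD ≤ 5/6/7 mmHg → A/B/C, else D).
   Standards thresholds are configurable constants, since the standards
   documents themselves are not distributed with this package.

Because the original recordings come from a clinical data bank that this
package deliberately does not download, every analysis runs on synthetic
cohorts with known ground truth; the paper-scale numbers are therefore
reproduced *structurally* (identities, calibration properties, grading
logic, qualitative contrasts), not numerically.

## Synthetic waveform generator

Each subject is generated from a `SimConfig`:

- **Beat train.** R-peak times integrate a heart-rate trajectory (default
  ≈75 BPM with a slow ±3 BPM sinusoid; valid range 20–250 BPM). ECG is one
  Gaussian QRS complex per beat (σ = 12 ms) plus low-amplitude P/T waves.
- **BP trajectories.** SBP(t) and DBP(t) are slow sinusoids (10-min period,
  per-subject amplitude 8–22 mmHg for SBP) plus bounded Ornstein–Uhlenbeck
  walks (τ = 200 s); DBP co-moves with SBP at gain 0.55. Cohort means are
  drawn near 116/63 mmHg so per-subject ΔSBP spans a few tens of mmHg.
- **PAT coupling.** PAT_ABP = PEP + intercept + slope·SBP + drift + noise,
  with slope −1 ms/mmHg (configurable, non-positive), PEP fixed at 60 ms
  (the cohort's true PEP distribution is unknown; this is a stand-in, not an
  estimate), white noise SD 8 ms and a slow OU drift (SD 20 ms, τ = 180 s).
  The drift stands in for PEP and vasomotor variability and is what keeps
  per-subject correlations moderate rather than ≈1 after smoothing.
- **Peripheral transit.** The ABP-foot→PPG-onset delay is 150 ms plus its
  own independent OU drift (SD 10 ms) and white noise (SD 5 ms): PTT is
  decoupled from BP by default, which is exactly the contrast the
  correlation analysis is designed to detect.
- **Pulse shapes.** ABP and PPG pulses are periodic two-Gaussian templates
  on the unit cycle (systolic hump + dicrotic bump), warped linearly onto
  each cycle. Template landmark phases — foot, peak, maximum upslope and the
  intersecting-tangent (IT) point t_md − (y(t_md) − y_min)/y′(t_md) — are
  located once on the analytic function to ~1e-10 and reused, so the
  generator knows the exact continuous-time location of every fiducial it
  renders. The ABP train is anchored at the foot and scaled so each cycle's
  max/min equal the true SBP/DBP exactly; the PPG train is anchored at the
  IT point, which makes the rendered IT time exact by construction (the
  tangent construction is invariant under linear time-warping and amplitude
  scaling).
- **Imperfections.** Baseline wander (0.25 Hz + sub-harmonic sinusoids) on
  ECG and PPG only, additive white noise on all channels (0.5 mmHg on ABP),
  and optional saturation/dropout artifacts that clamp a channel at its rail
  or hold it constant.
- **Device delay.** A constant instrumentation delay can be added to the PPG
  channel. Ground-truth PAT/PTT are physiological (delay-free); extracted
  PAT_PPG values shift by exactly the delay and extracted PTT by the same
  constant, which cancels from every correlation, slope and error statistic.
  This mirrors a fixed acquisition offset between monitor channels.

All randomness flows from a single `numpy` SeedSequence; cohort subjects use
spawned substreams, so subject *k* is identical across runs and across
cohort sizes.

What the generator does **not** emulate: respiration modulation, cardiac
output changes, arrhythmia, waveform-shape dependence on BP, or any
nonlinear PAT–BP relationship. Passing tests therefore demonstrate that the
pipeline is correct and faithful to its stated rules — not that a linear
PAT model is adequate on real patients.

## Extraction pipeline: numerical choices

- **Baseline removal** (ECG and PPG only; ABP stays in absolute mmHg):
  cascaded median filters (250 ms then 600 ms) estimate the baseline; a
  zero-phase 2nd-order Butterworth low-pass at 0.5 Hz then strips the
  residual beat-frequency ripple from that estimate before subtraction.
  Without the low-pass stage the ripple measurably distorts the PPG upstroke
  (IT point biased ~14 ms); with it, noiseless extraction is exact to within
  one sample. DC level is not preserved (it is meaningless for ECG/PPG in
  arbitrary units).
- **R-peak detection**: Pan-Tompkins style — 5–15 Hz band-pass (zero-phase),
  derivative, squaring, 150 ms moving integration, adaptive signal/noise
  thresholds with search-back on long gaps, 200 ms refractory period; the R
  wave is localised on the band-passed signal (T waves are suppressed
  there).
- **Ensemble averaging**: the ABP and PPG stretches between 10 consecutive
  R-peaks are aligned at their R-peaks, truncated to the window's shortest
  RR interval (no time-warping, preserving sample-accurate timing) and
  averaged point-wise; the window slides one cycle at a time, so
  `len(r_times) − 10` cycles result, each attributed to its leading beat.
- **Fiducials**: the foot/valley is the within-range minimum constrained to
  precede the systolic peak and to be a genuine local minimum (monotone
  segments yield an absent fiducial with a reason); the PPG maximum
  derivative uses central differences on the averaged cycle (no extra
  smoothing — the ensemble already raised SNR); the IT time is kept as a
  real number, not snapped to the 10 ms grid, because grid quantization
  would otherwise dominate the error budget at 100 Hz. Default gating
  ranges: ABP valley 50–400 ms after the R-peak; all PPG points 50–1200 ms
  (wide, to accommodate a constant device delay). The original study's
  ranges were data-derived and unpublished; these defaults are replacements,
  not reconstructions.
- **Plausibility conditions** (strict inequalities, first failure recorded):
  50 < SBP < 250; 30 < DBP < 160; PP > 10; |ΔSBP| and |ΔDBP| < 30 mmHg
  against the nearest *valid* beat ≥ 5 s earlier (vacuously true when none
  exists); 70 < PAT_ABP < 250 ms; every feature's change < 300 ms over the
  same lookback. The BP-jump rule is applied to SBP and DBP each; rejected
  beats never serve as lookback references and are excluded from smoothing
  windows entirely.
- **Smoothing and gating**: centered ±10 s moving average over valid beats
  (trailing window available); subjects with < 100 valid beats are excluded
  with per-reason counts. Recording-level gating requires ≥ 30 min duration,
  mean HR 40–200 BPM (computed after excluding beats inside flagged
  saturation intervals) and an automated saturation screen — intervals where
  the derivative is exactly zero or the signal sits at its global extreme
  for > 0.5 s; a recording fails if > 10% of any channel is flagged. The
  screen is a programmatic substitute for the original manual visual
  inspection.

## Model and evaluation choices

- The pooled slope is fitted through the origin of the mean-centered pairs
  (α₁ = Σx̃ỹ/Σx̃²). Centering makes any fitted intercept ≈ 0; constraining it
  to 0 makes the per-subject mean error *exactly* zero — the mechanism
  behind a reported pooled ME < 0.001 mmHg in this design.
- Cohort correlation summaries are unweighted means ± SD across subjects,
  never pooled beats. Correlations are computed on the smoothed series,
  consistent with the processing order of the extraction stage.
- Headline ME/SDE/MAD pool all beat pairs; per-recording metrics and
  per-subject estimate–reference correlations (mean ± SD) are emitted
  alongside, since pooled grading can mask per-subject failures.
- Confounder regression: OLS of a per-subject response (PAT–BP slope or
  correlation) on age, gender (male = 1), BMI, hypertension and diabetes
  (0/1), unstandardized, with SEs, two-sided t p-values and VIFs computed on
  the design with intercept; singular designs raise an error naming the
  dependent columns.

## Study designs (problem sizes)

- **Calibration study** (`run_calibration_study`, also the acceptance
  script): 20 subjects × 20 min (≥ 1000 valid beats each after gating),
  default generator, full pipeline; reports pooled and per-subject ME, SDE,
  MAD per target. Runs in well under a minute on one CPU.
- **Slope recovery** (`run_recovery_study`): 20 replicates × 50 subjects ×
  1000 beats of generator ground truth (no waveform rendering — that layer
  only adds sample quantization and is validated separately), design slope
  −0.4 mmHg/ms, white PAT noise 3 ms SD, no drift. Regressing BP on a
  noisy PAT is an errors-in-variables problem: the OLS slope is attenuated
  by R² = b²Var(SBP)/(b²Var(SBP) + σ²), so the recovery experiment fixes the
  noise where attenuation (~2%) stays inside the 5% recovery budget; at the
  generator's default noise the attenuation itself, not estimator error,
  would dominate. Median relative recovery error observed ≈ 2%.
- **Correlation contrast** (`run_contrast_study`): 8 subjects × 12 min,
  default generator (PAT coupled, PTT decoupled); mean |ρ(SBP, PAT_PPG_4)|
  must exceed mean |ρ(SBP, PTT4)|.
- **Analysis chain** (`analysis/01–06`): 12 subjects × 20 min, seed 42;
  waveforms and beat tables under `scratch/`, summary tables under
  `results/`.

The desk-scale studies set the recording-duration gate to 5 min
(`study_pipeline_config`), because the 30-min rule is a data-bank screening
criterion, not a property of the extraction; all other gates stay at their
defaults.

## Known limitations

- Extracted PAT for a beat is the ensemble average over its 10-beat window,
  so beat-level PAT noise appears low-pass filtered and the attribution to
  the leading beat introduces a small lag; with the default slow
  trajectories this bias is ≪ 1 sample on average.
- At 100 Hz, grid-quantized fiducials (foot, peak, maximum derivative)
  carry up to 5 ms error each; only the IT point is sub-sample.
- The simulator's linear, stationary PAT–BP coupling makes the calibrated
  model well-specified by construction; real-data misspecification
  (nonlinearity, PEP dynamics, posture, drugs) is out of scope.
- `pearson` raises on zero-variance input rather than returning NaN;
  cohort summaries count and exclude undefined entries.
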