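"""Error metrics and BP-monitor standards grading (AAMI, BHS, IEEE-1708).

Error metrics over estimate/reference pairs (p_i, y_i):

    ME  = mean(p_i - y_i)
    SDE = sample standard deviation of (p_i - y_i), n-1 denominator
    MAD = mean |p_i - y_i|

Grading encodes the published standards: AAMI requires |ME| <= 5 mmHg and
SDE <= 8 mmHg; BHS grades on the cumulative percentage of absolute errors
within 5/10/15 mmHg (A >= 60/85/95, B >= 50/75/90, C >= 40/65/85, else D);
IEEE-1708 bands the MAD (A <= 5, B <= 6, C <= 7, else D).  All thresholds
are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from patbp.features import SubjectSeries
from patbp.modeling import CalibratedLinearModel, predict

#: BHS cumulative-percentage thresholds per grade, (<=5, <=10, <=15) mmHg
BHS_THRESHOLDS = {"A": (60.0, 85.0, 95.0),
                  "B": (50.0, 75.0, 90.0),
                  "C": (40.0, 65.0, 85.0)}
#: IEEE-1708 MAD bands, mmHg
IEEE_BANDS = {"A": 5.0, "B": 6.0, "C": 7.0}
AAMI_ME_LIMIT = 5.0
AAMI_SDE_LIMIT = 8.0


def error_metrics(pred: np.ndarray, ref: np.ndarray
                  ) -> tuple[float, float, float]:
    """(ME, SDE, MAD) in mmHg for estimate/reference pairs."""
    pred = np.asarray(pred, float)
    ref = np.asarray(ref, float)
    if len(pred) != len(ref):
        raise ValueError("pred and ref must have equal length")
    if len(pred) < 2:
        raise ValueError("need at least 2 pairs (SDE undefined otherwise)")
    err = pred - ref
    me = float(np.mean(err))
    sde = float(np.std(err, ddof=1))
    mad = float(np.mean(np.abs(err)))
    return me, sde, mad


def cumulative_pct(errors: np.ndarray,
                   thresholds=(5.0, 10.0, 15.0)) -> tuple[float, ...]:
    """Percent of absolute errors within each threshold (non-decreasing)."""
    errors = np.asarray(errors, float)
    if len(errors) == 0:
        raise ValueError("empty error array")
    a = np.abs(errors)
    return tuple(float(100.0 * np.mean(a <= thr)) for thr in thresholds)


def grade_bhs(pct5: float, pct10: float, pct15: float,
              thresholds: dict | None = None) -> str:
    """Best BHS grade whose all three cumulative thresholds are met."""
    thresholds = thresholds or BHS_THRESHOLDS
    for grade in ("A", "B", "C"):
        t5, t10, t15 = thresholds[grade]
        if pct5 >= t5 and pct10 >= t10 and pct15 >= t15:
            return grade
    return "D"


def check_aami(me: float, sde: float, me_limit: float = AAMI_ME_LIMIT,
               sde_limit: float = AAMI_SDE_LIMIT) -> bool:
    """AAMI pass criterion: |ME| <= 5 mmHg and SDE <= 8 mmHg."""
    return abs(me) <= me_limit and sde <= sde_limit


def grade_ieee(mad: float, bands: dict | None = None) -> str:
    """IEEE-1708 grade from the mean absolute difference."""
    if mad < 0:
        raise ValueError("MAD cannot be negative")
    bands = bands or IEEE_BANDS
    for grade in ("A", "B", "C"):
        if mad <= bands[grade]:
            return grade
    return "D"


@dataclass
class EvaluationReport:
    """Pooled evaluation of one BP target, plus per-recording views."""

    target: str
    me: float
    sde: float
    mad: float
    cum_pct: tuple  # within 5 / 10 / 15 mmHg, percent
    corr_mean: float  # mean per-subject corr(estimate, reference)
    corr_sd: float
    aami_pass: bool
    bhs_grade: str
    ieee_grade: str
    n_pairs: int
    n_subjects: int
    per_subject: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "me": self.me, "sde": self.sde, "mad": self.mad,
            "cum_pct": list(self.cum_pct),
            "corr_mean": self.corr_mean, "corr_sd": self.corr_sd,
            "aami_pass": self.aami_pass,
            "bhs_grade": self.bhs_grade, "ieee_grade": self.ieee_grade,
            "n_pairs": self.n_pairs, "n_subjects": self.n_subjects,
        }


def evaluate_model(model: CalibratedLinearModel, cohort: list[SubjectSeries],
                   target: str | None = None,
                   feature: str = "pat_ppg_4") -> EvaluationReport:
    """Evaluate calibrated predictions pooled over all beat pairs.

    The headline ME/SDE/MAD/cumulative percentages pool every pair; the
    per-recording metrics and the per-subject estimate-reference correlations
    (summarised as mean +/- SD) are kept alongside.
    """
    target = target or model.target
    errors, rows = [], []
    n_pairs = 0
    for s in cohort:
        p = predict(model, s.subject_id, s.feature(feature))
        y = s.bp(target)
        err = p - y
        errors.append(err)
        n_pairs += len(err)
        me_s, sde_s, mad_s = error_metrics(p, y)
        sy = np.std(y)
        sp = np.std(p)
        corr = float(np.corrcoef(p, y)[0, 1]) if sy > 0 and sp > 0 else np.nan
        rows.append({"subject_id": s.subject_id, "n": len(err), "me": me_s,
                     "sde": sde_s, "mad": mad_s, "corr": corr})
    if not rows:
        raise ValueError("empty cohort")
    err_all = np.concatenate(errors)
    me = float(np.mean(err_all))
    sde = float(np.std(err_all, ddof=1))
    mad = float(np.mean(np.abs(err_all)))
    pct = cumulative_pct(err_all)
    per_subject = pd.DataFrame(rows)
    corr_vals = per_subject["corr"].dropna()
    return EvaluationReport(
        target=target, me=me, sde=sde, mad=mad, cum_pct=pct,
        corr_mean=float(corr_vals.mean()) if len(corr_vals) else float("nan"),
        corr_sd=float(corr_vals.std(ddof=1)) if len(corr_vals) > 1 else float("nan"),
        aami_pass=check_aami(me, sde),
        bhs_grade=grade_bhs(*pct),
        ieee_grade=grade_ieee(mad),
        n_pairs=n_pairs, n_subjects=len(rows),
        per_subject=per_subject,
    )


def stratify_by_delta_bp(corr: np.ndarray, delta_bp: np.ndarray,
                         bin_width: float = 20.0) -> pd.DataFrame:
    """Mean/SD of per-subject correlations binned by the subject's BP range.

    ``delta_bp`` is max - min of the smoothed BP series per subject.  Bins of
    *bin_width* mmHg start at 0; empty bins are absent from the output, and
    undefined (NaN) correlations are excluded.
    """
    corr = np.asarray(corr, float)
    delta_bp = np.asarray(delta_bp, float)
    if len(corr) != len(delta_bp):
        raise ValueError("corr and delta_bp must have equal length")
    keep = ~np.isnan(corr)
    corr, delta_bp = corr[keep], delta_bp[keep]
    if len(corr) == 0:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "n", "mean", "sd"])
    idx = np.floor(delta_bp / bin_width).astype(int)
    rows = []
    for b in sorted(set(idx)):
        vals = corr[idx == b]
        rows.append({
            "bin_lo": b * bin_width, "bin_hi": (b + 1) * bin_width,
            "n": len(vals), "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
        })
    return pd.DataFrame(rows)


def report_text(reports: dict[str, EvaluationReport]) -> str:
    """Human-readable performance table, one column per BP target."""
    targets = list(reports)
    lines = ["Performance measure        " + "".join(f"{t.upper():>12}" for t in targets)]

    def row(label, fmt, getter):
        vals = "".join(f"{fmt.format(getter(reports[t])):>12}" for t in targets)
        lines.append(f"{label:<27}{vals}")

    row("Correlation to reference", "{:.2f}", lambda r: r.corr_mean)
    row("ME (mmHg)", "{:.3g}", lambda r: r.me)
    row("SDE (mmHg)", "{:.2f}", lambda r: r.sde)
    row("Cum. error <5 mmHg (%)", "{:.1f}", lambda r: r.cum_pct[0])
    row("Cum. error <10 mmHg (%)", "{:.1f}", lambda r: r.cum_pct[1])
    row("Cum. error <15 mmHg (%)", "{:.1f}", lambda r: r.cum_pct[2])
    row("MAD (mmHg)", "{:.2f}", lambda r: r.mad)
    row("AAMI", "{}", lambda r: "pass" if r.aami_pass else "fail")
    row("BHS grade", "{}", lambda r: r.bhs_grade)
    row("IEEE-1708 grade", "{}", lambda r: r.ieee_grade)
    return "\n".join(lines)


def write_report(report: EvaluationReport, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True) + "\n")
    return path
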