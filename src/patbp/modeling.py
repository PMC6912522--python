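"""Correlation analysis, the mean-calibrated linear BP model, confounders.

Per subject, Pearson correlations are computed between the four reference BP
values (SBP, DBP, MBP, PP) and the nine temporal features; the cohort summary
is the unweighted mean +/- SD of the per-subject coefficients.

The pooled linear model BP = alpha1 * PAT + alpha0 is calibrated per subject
by mean-subtraction: each subject's mean BP and mean PAT are removed before
pooling, a single slope alpha1 is fitted through the origin of the pooled
centered pairs, and the subject's mean BP is added back at prediction time
(alpha0_s).  Centering makes the per-subject mean prediction error exactly
zero and makes the fit invariant to any per-subject constant offset in BP or
PAT.

The confounder analysis regresses a per-subject response (PAT-BP slope or
correlation) on age, gender, BMI, hypertension and diabetes with ordinary
least squares, reporting beta, SE, two-sided t p-values and variance
inflation factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from patbp.features import SubjectSeries
from patbp.io import BP_NAMES, FEATURE_NAMES


class UndefinedCorrelationError(ValueError):
    """Correlation is undefined: one of the arguments has zero variance."""


class CollinearityError(ValueError):
    """The regression design matrix is singular; names offending columns."""


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation, rho = E[(X-muX)(Y-muY)]/(sX sY)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError("zero variance in one argument")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(np.mean(xd * xd))
    sy = np.sqrt(np.mean(yd * yd))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("zero variance in one argument")
    rho = float(np.mean(xd * yd) / (sx * sy))
    return float(np.clip(rho, -1.0, 1.0))


@dataclass
class CorrelationResult:
    subject_id: str
    rho: pd.DataFrame  # 4 BP rows x 9 feature columns, NaN where undefined
    n_beats: int


def correlation_matrix(series: SubjectSeries) -> CorrelationResult:
    """Per-subject 4x9 matrix of BP-feature Pearson coefficients."""
    mat = np.full((len(BP_NAMES), len(FEATURE_NAMES)), np.nan)
    for i, bp_name in enumerate(BP_NAMES):
        bp = series.bp(bp_name)
        for j, feat_name in enumerate(FEATURE_NAMES):
            try:
                mat[i, j] = pearson(series.feature(feat_name), bp)
            except UndefinedCorrelationError:
                pass
    rho = pd.DataFrame(mat, index=list(BP_NAMES), columns=list(FEATURE_NAMES))
    return CorrelationResult(subject_id=series.subject_id, rho=rho,
                             n_beats=series.n_valid)


def correlation_table(cohort: list[SubjectSeries]
                      ) -> tuple[list[CorrelationResult], pd.DataFrame,
                                 pd.DataFrame, int]:
    """Per-subject correlation matrices plus the cohort mean and SD tables.

    The summary is taken across subjects (not pooled beats); undefined
    entries are excluded, and their count is returned.
    """
    if not cohort:
        raise ValueError("empty cohort")
    results = [correlation_matrix(s) for s in cohort]
    stack = np.stack([r.rho.to_numpy() for r in results])
    n_undefined = int(np.isnan(stack).sum())
    with warnings.catch_warnings():
        # all-NaN or single-entry slices legitimately yield NaN summaries
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_arr = np.nanmean(stack, axis=0)
        if stack.shape[0] > 1:
            sd_arr = np.nanstd(stack, axis=0, ddof=1)
        else:
            sd_arr = np.full(stack.shape[1:], np.nan)
    mean = pd.DataFrame(mean_arr, index=list(BP_NAMES),
                        columns=list(FEATURE_NAMES))
    sd = pd.DataFrame(sd_arr, index=list(BP_NAMES), columns=list(FEATURE_NAMES))
    return results, mean, sd, n_undefined


@dataclass
class CalibratedLinearModel:
    """BP = alpha1 * (PAT - mean_pat_s) + mean_bp_s for subject s."""

    target: str  # 'sbp' or 'dbp' (any BP name accepted)
    alpha1: float  # mmHg per ms, pooled slope
    per_subject: dict  # subject_id -> (mean_pat_ms, mean_bp_mmhg)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "alpha1": self.alpha1,
            "per_subject": {
                k: {"mean_pat": v[0], "mean_bp": v[1]}
                for k, v in self.per_subject.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibratedLinearModel":
        return cls(
            target=d["target"], alpha1=float(d["alpha1"]),
            per_subject={k: (float(v["mean_pat"]), float(v["mean_bp"]))
                         for k, v in d["per_subject"].items()},
        )


def fit_calibrated_model(pairs: pd.DataFrame,
                         target: str = "sbp") -> CalibratedLinearModel:
    """Fit the pooled mean-calibrated slope.

    *pairs* needs columns ``subject_id``, ``pat`` (ms) and ``bp`` (mmHg).
    Each subject's means are removed, and the slope is the least-squares
    solution through the origin of the pooled centered pairs:
    alpha1 = sum(x~ y~) / sum(x~^2).
    """
    required = {"subject_id", "pat", "bp"}
    if not required.issubset(pairs.columns):
        raise ValueError(f"pairs must have columns {sorted(required)}")
    groups = pairs.groupby("subject_id", sort=True)
    if groups.ngroups < 1:
        raise ValueError("no subjects")
    if (groups.size() < 2).any():
        raise ValueError("every subject needs at least 2 beats")
    centered = pairs.copy()
    means = groups[["pat", "bp"]].transform("mean")
    centered["pat"] -= means["pat"]
    centered["bp"] -= means["bp"]
    sxx = float(np.sum(centered["pat"] ** 2))
    if sxx == 0.0:
        raise ValueError("zero pooled PAT variance; slope undefined")
    alpha1 = float(np.sum(centered["pat"] * centered["bp"]) / sxx)
    per_subject = {
        str(sid): (float(g["pat"].mean()), float(g["bp"].mean()))
        for sid, g in groups
    }
    return CalibratedLinearModel(target=target, alpha1=alpha1,
                                 per_subject=per_subject)


def predict(model: CalibratedLinearModel, subject_id: str,
            pat: np.ndarray) -> np.ndarray:
    """Per-subject calibrated BP estimates for a PAT series (ms)."""
    if subject_id not in model.per_subject:
        raise KeyError(f"no calibration for subject {subject_id!r}")
    mean_pat, mean_bp = model.per_subject[subject_id]
    return model.alpha1 * (np.asarray(pat, float) - mean_pat) + mean_bp


def pairs_from_series(cohort: list[SubjectSeries], target: str = "sbp",
                      feature: str = "pat_ppg_4") -> pd.DataFrame:
    """Tidy (subject_id, pat, bp) table pooled over a cohort of series."""
    frames = [
        pd.DataFrame({
            "subject_id": s.subject_id,
            "pat": s.feature(feature),
            "bp": s.bp(target),
        })
        for s in cohort
    ]
    return pd.concat(frames, ignore_index=True)


DEFAULT_COVARIATES = ("age", "gender", "bmi", "hypertension", "diabetes")


@dataclass
class ConfounderRegressionResult:
    response: str
    table: pd.DataFrame  # index: covariates; columns beta, se, p_value, vif
    n_subjects: int
    r_squared: float


def _encode_covariates(data: pd.DataFrame, covariates) -> pd.DataFrame:
    X = pd.DataFrame(index=data.index)
    for cov in covariates:
        col = data[cov]
        if col.dtype == object:
            col = (col == "male").astype(float)  # gender: male=1, female=0
        X[cov] = col.astype(float)
    return X


def confounder_regression(data: pd.DataFrame, response: str,
                          covariates=DEFAULT_COVARIATES
                          ) -> ConfounderRegressionResult:
    """Multivariate OLS of a per-subject response on risk factors.

    Binary factors are encoded 0/1 (male = 1); continuous covariates stay on
    their natural units so betas are per-unit effects.  VIFs are computed on
    the design with intercept.
    """
    missing = [c for c in (*covariates, response) if c not in data.columns]
    if missing:
        raise ValueError(f"columns absent: {missing}")
    n = len(data)
    if n <= len(covariates) + 2:
        raise ValueError("need n_subjects > covariate count + 2")
    X = _encode_covariates(data, covariates)
    exog = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        bad = [c for c in X.columns if X[c].nunique() <= 1]
        if not bad:  # find linearly dependent columns by leave-one-out rank
            bad = [c for c in X.columns
                   if np.linalg.matrix_rank(
                       exog.drop(columns=[c]).to_numpy()) == rank]
        raise CollinearityError(f"design is singular; offending columns: {bad}")
    fit = sm.OLS(data[response].astype(float), exog).fit()
    vif = {c: variance_inflation_factor(exog.to_numpy(), i)
           for i, c in enumerate(exog.columns) if c != "const"}
    table = pd.DataFrame({
        "beta": fit.params.drop("const"),
        "se": fit.bse.drop("const"),
        "p_value": fit.pvalues.drop("const"),
        "vif": pd.Series(vif),
    })
    return ConfounderRegressionResult(response=response, table=table,
                                      n_subjects=n,
                                      r_squared=float(fit.rsquared))


def per_subject_slope(series: SubjectSeries, target: str = "sbp",
                      feature: str = "pat_ppg_4") -> float:
    """OLS slope (mmHg/ms) of the subject's BP on the feature."""
    x = series.feature(feature)
    y = series.bp(target)
    xd = x - x.mean()
    sxx = float(np.sum(xd * xd))
    if sxx == 0.0:
        raise UndefinedCorrelationError("zero feature variance")
    return float(np.sum(xd * (y - y.mean())) / sxx)
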