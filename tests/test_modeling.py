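"""Correlation, calibrated linear model, confounder regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from patbp.features import SubjectSeries
from patbp.modeling import (
    CollinearityError,
    UndefinedCorrelationError,
    confounder_regression,
    correlation_table,
    fit_calibrated_model,
    pairs_from_series,
    pearson,
    per_subject_slope,
    predict,
)

finite = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


def _xy_arrays():
    return st.integers(3, 60).flatmap(
        lambda n: st.tuples(
            hnp.arrays(np.float64, n, elements=finite),
            hnp.arrays(np.float64, n, elements=finite),
        )
    )


class TestPearson:
    def test_identity_and_negative_affine(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -2.0 * x + 3.0) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6, abs=1e-12)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert pearson(x, y) == pytest.approx(pearson(y, x), abs=1e-14)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(max_examples=100, derandomize=True)
    @given(_xy_arrays())
    def test_matches_numpy_corrcoef(self, xy):
        x, y = xy
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            with pytest.raises(UndefinedCorrelationError):
                pearson(x, y)
            return
        expected = np.corrcoef(x, y)[0, 1]
        if not np.isfinite(expected):
            return  # numerically degenerate (catastrophic cancellation)
        assert pearson(x, y) == pytest.approx(expected, abs=1e-8)

    @settings(max_examples=50, derandomize=True)
    @given(_xy_arrays(), st.floats(0.1, 10), st.floats(-5, 5))
    def test_affine_invariance(self, xy, a, b):
        x, y = xy
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        r0 = pearson(x, y)
        assert pearson(a * x + b, y) == pytest.approx(r0, abs=1e-6)
        assert pearson(-a * x + b, y) == pytest.approx(-r0, abs=1e-6)


def _make_series(sid, pat, sbp):
    pat = np.asarray(pat, float)
    sbp = np.asarray(sbp, float)
    n = len(pat)
    pat_ppg = np.tile(pat[:, None], 4)
    ptt = np.tile(np.full(n, 150.0)[:, None], 4)
    return SubjectSeries(sid, np.arange(n) * 0.8, sbp, sbp * 0.5, sbp * 0.7,
                         sbp * 0.5, pat - 150.0, pat_ppg, ptt)


class TestCorrelationTable:
    def test_noiseless_linear_cohort_all_minus_one(self):
        cohort = []
        for k in range(4):
            sbp = 120 + 10 * np.sin(np.linspace(0, 6, 200) + k)
            cohort.append(_make_series(f"s{k}", 300 - 2 * sbp, sbp))
        _, mean, sd, _ = correlation_table(cohort)
        assert mean.loc["sbp", "pat_ppg_4"] == pytest.approx(-1.0, abs=1e-9)
        assert sd.loc["sbp", "pat_ppg_4"] == pytest.approx(0.0, abs=1e-9)

    def test_null_cohort_mean_near_zero(self):
        rng = np.random.default_rng(5)
        cohort = [_make_series(f"s{k}", rng.normal(300, 10, 200),
                               rng.normal(120, 10, 200)) for k in range(40)]
        _, mean, _, _ = correlation_table(cohort)
        # independent draws: per-subject rho ~ N(0, 1/sqrt(200)); the mean of
        # 40 of them stays within 4 sigma of zero
        assert abs(mean.loc["sbp", "pat_ppg_4"]) < 4 / np.sqrt(200 * 40)

    def test_undefined_entries_counted(self):
        cohort = [_make_series("a", np.full(150, 300.0),
                               120 + np.sin(np.arange(150.0)))]
        results, mean, _, n_undef = correlation_table(cohort)
        assert np.isnan(results[0].rho.loc["sbp", "pat_ppg_4"])
        assert n_undef > 0

    def test_matrix_shape_and_bounds(self):
        rng = np.random.default_rng(6)
        s = _make_series("a", rng.normal(300, 5, 150), rng.normal(120, 8, 150))
        results, mean, sd, _ = correlation_table([s, s])
        assert results[0].rho.shape == (4, 9)
        vals = results[0].rho.to_numpy()
        ok = np.isnan(vals) | ((vals >= -1) & (vals <= 1))
        assert ok.all()


class TestCalibratedModel:
    def test_single_subject_exact_fit(self):
        pat = np.linspace(250, 350, 50)
        df = pd.DataFrame({"subject_id": "a", "pat": pat,
                           "bp": -0.5 * pat + 100})
        model = fit_calibrated_model(df)
        assert model.alpha1 == pytest.approx(-0.5, abs=1e-12)

    def test_offsets_removed_by_centering(self):
        pat = np.linspace(250, 350, 40)
        frames = [
            pd.DataFrame({"subject_id": "a", "pat": pat, "bp": -0.5 * pat + 100}),
            pd.DataFrame({"subject_id": "b", "pat": pat + 55,
                          "bp": -0.5 * (pat + 55) + 140}),
        ]
        model = fit_calibrated_model(pd.concat(frames, ignore_index=True))
        assert model.alpha1 == pytest.approx(-0.5, abs=1e-12)

    def test_invariant_to_per_subject_offsets(self):
        rng = np.random.default_rng(7)
        rows = []
        for k in range(5):
            pat = rng.normal(300, 20, 100)
            bp = -0.4 * pat + rng.normal(0, 3, 100)
            rows.append(pd.DataFrame({"subject_id": f"s{k}", "pat": pat,
                                      "bp": bp}))
        df = pd.concat(rows, ignore_index=True)
        a0 = fit_calibrated_model(df).alpha1
        shifted = df.copy()
        offsets = {f"s{k}": 50.0 * k for k in range(5)}
        shifted["bp"] += shifted["subject_id"].map(offsets)
        shifted["pat"] += shifted["subject_id"].map(offsets)
        assert fit_calibrated_model(shifted).alpha1 == pytest.approx(a0, abs=1e-12)

    def test_zero_pat_variance_rejected(self):
        df = pd.DataFrame({"subject_id": "a", "pat": np.full(10, 300.0),
                           "bp": np.arange(10.0)})
        with pytest.raises(ValueError):
            fit_calibrated_model(df)

    def test_predict_centering_properties(self):
        rng = np.random.default_rng(8)
        cohort = [
            _make_series(f"s{k}", rng.normal(300, 15, 200),
                         rng.normal(120 + 5 * k, 10, 200))
            for k in range(3)
        ]
        pairs = pairs_from_series(cohort)
        model = fit_calibrated_model(pairs)
        for s in cohort:
            est = predict(model, s.subject_id, s.feature("pat_ppg_4"))
            # mean estimate equals the subject's mean reference BP exactly
            assert np.mean(est) == pytest.approx(np.mean(s.sbp), abs=1e-9)
            mean_pat = model.per_subject[s.subject_id][0]
            at_mean = predict(model, s.subject_id, np.array([mean_pat]))[0]
            assert at_mean == pytest.approx(np.mean(s.sbp), abs=1e-9)

    def test_estimate_correlation_flips_sign_of_pat_correlation(self):
        rng = np.random.default_rng(9)
        sbp = 120 + 10 * np.sin(np.linspace(0, 12, 300))
        pat = 300 - 2 * sbp + rng.normal(0, 5, 300)
        cohort = [_make_series("a", pat, sbp), _make_series("b", pat, sbp)]
        model = fit_calibrated_model(pairs_from_series(cohort))
        assert model.alpha1 < 0
        est = predict(model, "a", pat)
        assert np.corrcoef(est, sbp)[0, 1] == pytest.approx(
            -np.corrcoef(pat, sbp)[0, 1], abs=1e-12)

    def test_unknown_subject_rejected(self):
        df = pd.DataFrame({"subject_id": ["a"] * 5 + ["b"] * 5,
                           "pat": np.arange(10.0), "bp": np.arange(10.0)})
        model = fit_calibrated_model(df)
        with pytest.raises(KeyError):
            predict(model, "zz", np.array([1.0]))

    def test_serialization_round_trip(self):
        from patbp.modeling import CalibratedLinearModel
        df = pd.DataFrame({"subject_id": ["a"] * 5 + ["b"] * 5,
                           "pat": np.arange(10.0),
                           "bp": 2.0 * np.arange(10.0)})
        model = fit_calibrated_model(df)
        back = CalibratedLinearModel.from_dict(model.to_dict())
        assert back.alpha1 == model.alpha1
        assert back.per_subject == model.per_subject


def _cohort_frame(rng, n=300, age_beta=0.0, noise=0.1):
    age = np.clip(rng.normal(58, 15, n), 5, 92)
    gender = np.where(rng.random(n) < 0.53, "male", "female")
    bmi = np.clip(rng.normal(23, 4, n), 14, 45)
    ht = (rng.random(n) < 0.34).astype(int)
    dm = (rng.random(n) < 0.11).astype(int)
    resp = age_beta * age + noise * rng.standard_normal(n)
    return pd.DataFrame({"age": age, "gender": gender, "bmi": bmi,
                         "hypertension": ht, "diabetes": dm,
                         "slope": resp})


class TestConfounderRegression:
    def test_null_covariates_give_null_betas(self):
        rng = np.random.default_rng(10)
        res = confounder_regression(_cohort_frame(rng), "slope")
        assert set(res.table.index) == {"age", "gender", "bmi",
                                        "hypertension", "diabetes"}
        # no effect planted: every |beta| should sit within ~3 SE of zero
        assert (res.table["beta"].abs() < 3.5 * res.table["se"]).all()
        assert (res.table["vif"] >= 1.0).all()

    def test_planted_age_effect_recovered(self):
        rng = np.random.default_rng(11)
        df = _cohort_frame(rng, n=500, age_beta=-0.004, noise=0.05)
        res = confounder_regression(df, "slope")
        beta = res.table.loc["age", "beta"]
        se = res.table.loc["age", "se"]
        assert abs(beta - (-0.004)) < 2 * se
        assert res.table.loc["age", "p_value"] < 0.01

    def test_orthogonal_standardized_covariates_have_unit_vif(self):
        rng = np.random.default_rng(12)
        n = 64
        base = rng.normal(size=(n, 3))
        q, _ = np.linalg.qr(base - base.mean(axis=0))
        df = pd.DataFrame(q, columns=["age", "bmi", "gender"])
        df["slope"] = rng.normal(size=n)
        res = confounder_regression(df, "slope", covariates=("age", "bmi",
                                                             "gender"))
        assert np.allclose(res.table["vif"], 1.0, atol=1e-8)

    def test_singular_design_names_columns(self):
        rng = np.random.default_rng(13)
        df = _cohort_frame(rng)
        df["bmi"] = 2.0 * df["age"]  # exact collinearity
        with pytest.raises(CollinearityError, match="age|bmi"):
            confounder_regression(df, "slope")

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValueError):
            confounder_regression(_cohort_frame(rng, n=6), "slope")


class TestPerSubjectSlope:
    def test_exact_linear_series(self):
        sbp = 120 + 10 * np.sin(np.linspace(0, 6, 100))
        s = _make_series("a", 300 - 2.5 * sbp, sbp)
        assert per_subject_slope(s) == pytest.approx(-0.4, abs=1e-12)
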