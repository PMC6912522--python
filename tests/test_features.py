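"""BP/feature extraction, the six plausibility conditions, smoothing."""

import numpy as np
import pytest

from conftest import valid_beats
from patbp.features import (
    ConditionConfig,
    ExclusionRecord,
    SubjectSeries,
    apply_conditions,
    build_subject_series,
    extract_bp,
    extract_temporal,
    smooth_series,
)
from patbp.fiducials import FiducialSet
from patbp.io import BeatFeatures

FS = 100.0


class TestExtractBp:
    def test_sinusoidal_cycle(self):
        t = np.arange(80) / FS
        cycle = 90.0 - 30.0 * np.cos(2 * np.pi * (t - 0.15) / 0.8)
        fset = FiducialSet(abp_valley=0.15, abp_peak=0.55)
        sbp, dbp, mbp, pp = extract_bp(cycle, fset, FS)
        assert sbp == pytest.approx(120.0)
        assert dbp == pytest.approx(60.0)
        assert pp == pytest.approx(60.0)
        assert mbp == pytest.approx(90.0)  # full-period sinusoid mean

    def test_constant_cycle(self):
        cycle = np.full(80, 80.0)
        fset = FiducialSet(abp_valley=0.15, abp_peak=0.55)
        sbp, dbp, mbp, pp = extract_bp(cycle, fset, FS)
        assert (sbp, dbp, mbp, pp) == (80.0, 80.0, 80.0, 0.0)

    def test_absent_fiducials_raise(self):
        with pytest.raises(ValueError):
            extract_bp(np.zeros(80), FiducialSet(), FS)

    def test_simulator_oracle(self, clean_extraction):
        result, truth = clean_extraction
        beats = valid_beats(result)
        idx = [b.beat_index for b in beats]
        for attr, true in (("sbp", truth.true_sbp), ("dbp", truth.true_dbp),
                           ("mbp", truth.true_mbp)):
            err = np.array([getattr(b, attr) for b in beats]) - true[idx]
            assert np.max(np.abs(err)) < 0.5  # mmHg, template tolerance


class TestExtractTemporal:
    def test_arithmetic(self):
        fset = FiducialSet(abp_peak=0.4, abp_valley=0.15, ppg_valley=0.22,
                           ppg_peak=0.45, ppg_maxderiv=0.35, ppg_it=0.30)
        pat_abp, pat_ppg, ptt = extract_temporal(0.0, fset)
        assert pat_abp == pytest.approx(150.0)
        assert pat_ppg == pytest.approx((220.0, 450.0, 350.0, 300.0))
        assert ptt == pytest.approx((70.0, 300.0, 200.0, 150.0))

    def test_ptt_identity_on_extracted_beats(self, noisy_extraction):
        result, _ = noisy_extraction
        for b in valid_beats(result):
            for k in range(4):
                assert b.ptt[k] == pytest.approx(b.pat_ppg[k] - b.pat_abp,
                                                 abs=1e-9)

    def test_incomplete_fiducials_raise(self):
        with pytest.raises(ValueError):
            extract_temporal(0.0, FiducialSet(abp_valley=0.15))


def make_beat(i, t, sbp=120.0, dbp=60.0, pat_abp=150.0, feat=200.0, **kw):
    features = dict(
        sbp=sbp, dbp=dbp, mbp=(sbp + 2 * dbp) / 3, pp=sbp - dbp,
        pat_abp=pat_abp,
        pat_ppg=(feat, feat + 150, feat + 100, feat + 50),
        ptt=(feat - pat_abp, feat + 150 - pat_abp,
             feat + 100 - pat_abp, feat + 50 - pat_abp),
        valid=True,
    )
    features.update(kw)
    return BeatFeatures(beat_index=i, r_time=t, **features)


class TestApplyConditions:
    """Hand-built tables exercising each condition on both boundary sides."""

    @pytest.mark.parametrize("mod,expected_reason", [
        (dict(sbp=260.0), "cond1"),
        (dict(sbp=250.0), "cond1"),
        (dict(sbp=50.0, pp=-10.0), "cond1"),
        (dict(sbp=249.0, pp=189.0), ""),        # inside the bound but jumps
        (dict(dbp=160.0, pp=-40.0), "cond2"),
        (dict(dbp=30.0, pp=90.0), "cond2"),
        (dict(dbp=110.0, pp=10.0), "cond3"),    # PP exactly 10 fails
        (dict(dbp=109.0, pp=11.0), ""),
        (dict(pat_abp=60.0), "cond5"),
        (dict(pat_abp=70.0), "cond5"),
        (dict(pat_abp=250.0), "cond5"),
        (dict(pat_abp=71.0), ""),
    ])
    def test_value_bounds(self, mod, expected_reason):
        # one probe beat in a stable stretch; jump rules may fire after the
        # bound rules pass, so expectations list the FIRST failing condition
        beats = [make_beat(i, float(i)) for i in range(10)]
        probe = make_beat(6, 6.0, **mod)
        beats[6] = probe
        out = apply_conditions(beats)
        if expected_reason:
            assert not probe.valid and probe.reject_reason == expected_reason
        elif abs(probe.sbp - 120.0) >= 30.0 or abs(probe.dbp - 60.0) >= 30.0:
            assert probe.reject_reason == "cond4"
        else:
            assert probe.valid

    @pytest.mark.parametrize("dsbp,ddbp,ok", [
        (35.0, 0.0, False), (30.0, 0.0, False), (29.9, 0.0, True),
        (0.0, 30.0, False), (0.0, 29.9, True), (-35.0, 0.0, False),
    ])
    def test_bp_jump_rule(self, dsbp, ddbp, ok):
        beats = [make_beat(i, float(i)) for i in range(10)]
        probe = make_beat(6, 6.0, sbp=120.0 + dsbp, dbp=60.0 + ddbp,
                          pp=60.0 + dsbp - ddbp)
        beats[6] = probe
        apply_conditions(beats)
        assert probe.valid is ok
        if not ok:
            assert probe.reject_reason == "cond4"

    @pytest.mark.parametrize("dfeat,ok", [(350.0, False), (300.0, False),
                                          (299.0, True)])
    def test_feature_jump_rule(self, dfeat, ok):
        beats = [make_beat(i, float(i)) for i in range(10)]
        probe = make_beat(6, 6.0, feat=200.0 + dfeat)
        beats[6] = probe
        apply_conditions(beats)
        assert probe.valid is ok
        if not ok:
            assert probe.reject_reason == "cond6"

    def test_jump_rules_vacuous_at_record_start(self):
        beats = [make_beat(0, 0.0, sbp=120.0), make_beat(1, 1.0, sbp=149.0,
                                                         pp=89.0)]
        out = apply_conditions(beats)
        assert all(b.valid for b in out)  # no reference >= 5 s earlier

    def test_jump_beat_invalid_neighbors_valid(self):
        beats = [make_beat(i, float(i)) for i in range(12)]
        beats[7] = make_beat(7, 7.0, sbp=155.0, pp=95.0)
        out = apply_conditions(beats)
        assert not out[7].valid and out[7].reject_reason == "cond4"
        assert all(out[i].valid for i in range(12) if i != 7)

    def test_invalid_beats_do_not_serve_as_reference(self):
        # beat at t=6 jumps; beat at t=11 matches the jump but must be
        # compared against the earlier valid stretch, not the rejected beat
        beats = [make_beat(i, float(i)) for i in range(12)]
        beats[6] = make_beat(6, 6.0, sbp=155.0, pp=95.0)
        beats[11] = make_beat(11, 11.0, sbp=152.0, pp=92.0)
        out = apply_conditions(beats)
        assert not out[6].valid
        assert not out[11].valid and out[11].reject_reason == "cond4"

    def test_validity_monotone_in_thresholds(self, noisy_extraction):
        result, _ = noisy_extraction
        import copy
        base = copy.deepcopy(result.beats)
        wide = copy.deepcopy(result.beats)
        n_base = sum(b.valid for b in apply_conditions(base))
        cfg = ConditionConfig(sbp_hi=500.0, bp_jump_mmhg=60.0,
                              feature_jump_ms=600.0, pat_abp_hi=500.0)
        n_wide = sum(b.valid for b in apply_conditions(wide, cfg))
        assert n_wide >= n_base


def _series(t, values):
    n = len(t)
    arr = np.asarray(values, float)
    return SubjectSeries("s", np.asarray(t, float), arr, arr * 0.5,
                         arr * 0.7, arr * 0.5, arr, np.tile(arr[:, None], 4),
                         np.tile(arr[:, None], 4))


class TestSmoothSeries:
    def test_constant_series_unchanged(self):
        s = _series(np.arange(50.0), np.full(50, 7.0))
        out = smooth_series(s)
        assert np.allclose(out.sbp, 7.0)

    def test_single_beat_unchanged(self):
        s = _series([3.0], [100.0])
        out = smooth_series(s)
        assert out.sbp[0] == 100.0

    def test_matches_brute_force_window_average(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 120, 300))
        v = rng.normal(100, 10, 300)
        out = smooth_series(_series(t, v), window_s=20.0)
        brute = np.array([np.mean(v[(t >= ti - 10.0) & (t <= ti + 10.0)])
                          for ti in t])
        assert np.allclose(out.sbp, brute, atol=1e-10)

    def test_commutes_with_constant_shift(self):
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0, 60, 100))
        v = rng.normal(0, 5, 100)
        a = smooth_series(_series(t, v)).sbp
        b = smooth_series(_series(t, v + 13.5)).sbp
        assert np.allclose(b, a + 13.5, atol=1e-10)

    def test_preserves_mean_within_edge_effects(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 600, 0.8)
        v = rng.normal(100, 8, len(t))
        out = smooth_series(_series(t, v)).sbp
        assert abs(np.mean(out) - np.mean(v)) < 0.01 * abs(np.mean(v))


class TestBuildSubjectSeries:
    @staticmethod
    def _beats(n_valid, n_invalid=5):
        beats = [make_beat(i, i * 0.8) for i in range(n_valid)]
        for j in range(n_invalid):
            b = BeatFeatures(beat_index=n_valid + j, r_time=(n_valid + j) * 0.8,
                             valid=False, reject_reason="cond1")
            beats.append(b)
        return beats

    def test_99_valid_beats_excluded(self):
        out = build_subject_series("s", self._beats(99))
        assert isinstance(out, ExclusionRecord)
        assert out.reason == "n_beats"
        assert out.n_valid == 99
        assert out.reject_counts["cond1"] == 5

    def test_100_valid_beats_included(self):
        out = build_subject_series("s", self._beats(100))
        assert isinstance(out, SubjectSeries)
        assert out.n_valid == 100

    def test_noiseless_linear_coupling_gives_rho_minus_one(self, clean_extraction):
        # inverse PAT-BP relationship: with exact linear coupling and no
        # noise the smoothed series correlate at exactly -1 (up to sample
        # quantization of the extracted PAT)
        from conftest import noiseless_config
        from patbp.pipeline import process_record, PipelineConfig
        from patbp.simulate import generate_record
        from patbp.modeling import pearson

        cfg = noiseless_config(
            duration_s=300.0,
            sbp_trajectory=lambda t: 120.0 + 15.0 * np.sin(2 * np.pi * np.asarray(t) / 150.0),
            seed=2,
        )
        record, _ = generate_record(cfg)
        res = process_record(record, PipelineConfig(gate_min_duration_min=2.0))
        rho = pearson(res.series.feature("pat_ppg_4"), res.series.sbp)
        assert rho < -0.99
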