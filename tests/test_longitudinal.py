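"""OLS slopes, progression criteria, baseline deltas, slope-vs-MD relation."""

import datetime as dt

import numpy as np
import pytest

import vfdecomp as vd
from vfdecomp.longitudinal import aa_decomposer, fcm_decomposer
from tests.test_vf_core import make_test


def make_series(t_days, tdv_rows, md=None, vfi=None, pid="P1", eye="R"):
    """Series with explicit visit offsets (days) and per-visit TDV rows."""
    visits = []
    for i, (d, tdv) in enumerate(zip(t_days, tdv_rows)):
        kw = {}
        if md is not None:
            kw["md_db"] = float(md[i])
        if vfi is not None:
            kw["vfi_pct"] = float(vfi[i])
        visits.append(
            make_test(
                patient_id=pid, eye=eye,
                exam_date=dt.date(2020, 1, 1) + dt.timedelta(days=int(d)),
                tdv=np.asarray(tdv, dtype=float), **kw,
            )
        )
    return vd.EyeSeries(patient_id=pid, eye=eye, visits=tuple(visits))


def flat_series(n=5, gap=180, **kw):
    return make_series([gap * i for i in range(n)], [np.zeros(52)] * n, **kw)


class TestOlsSlope:
    def test_exact_line(self):
        t = np.array([0, 0.5, 1, 1.5, 2])
        fit = vd.ols_slope(t, 2.0 - 0.5 * t)
        assert fit.slope == pytest.approx(-0.5, abs=1e-12)
        assert fit.intercept == pytest.approx(2.0, abs=1e-12)
        assert fit.p_value == 0.0  # perfect fit, n > 2

    def test_constant(self):
        fit = vd.ols_slope([0, 1, 2], [3.0, 3.0, 3.0])
        assert fit.slope == 0.0

    def test_hand_computed_normal_equations(self):
        # t=(0,.5,1,1.5), y=(1,.9,.7,.6): Sxy=-.35, Sxx=1.25 -> slope -0.28
        fit = vd.ols_slope([0, 0.5, 1, 1.5], [1.0, 0.9, 0.7, 0.6])
        assert fit.slope == pytest.approx(-0.28, abs=1e-12)

    def test_two_point_p_is_one(self):
        fit = vd.ols_slope([0, 1], [5.0, 3.0])
        assert fit.slope == pytest.approx(-2.0)
        assert fit.p_value == 1.0

    def test_matches_scipy_on_noisy_data(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        t = np.arange(8) / 2.0
        y = -0.7 * t + rng.normal(scale=0.5, size=8)
        fit = vd.ols_slope(t, y)
        ref = stats.linregress(t, y)
        assert fit.slope == pytest.approx(ref.slope, rel=1e-10)
        assert fit.p_value == pytest.approx(ref.pvalue, rel=1e-8)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            vd.ols_slope([0], [1.0])
        with pytest.raises(ValueError):
            vd.ols_slope([1, 1, 1], [1.0, 2.0, 3.0])


class TestMdVfiCriteria:
    def test_negative_significant_progresses(self):
        rng = np.random.default_rng(1)
        md = -0.8 * np.arange(7) * 0.5 + rng.normal(scale=0.05, size=7)
        s = make_series(np.arange(7) * 182, [np.zeros(52)] * 7, md=md)
        flag, fit = vd.md_progression(s)
        assert flag and fit.slope < 0 and fit.p_value < 0.05

    def test_negative_but_insignificant(self):
        rng = np.random.default_rng(2)
        md = -0.05 * np.arange(5) * 0.5 + rng.normal(scale=1.5, size=5)
        s = make_series(np.arange(5) * 182, [np.zeros(52)] * 5, md=md)
        flag, fit = vd.md_progression(s)
        assert fit.p_value >= 0.05 and not flag

    def test_improvement_never_progresses(self):
        md = 0.3 * np.arange(6) * 0.5
        s = make_series(np.arange(6) * 182, [np.zeros(52)] * 6, md=md)
        flag, fit = vd.md_progression(s)
        assert fit.slope > 0 and fit.p_value == 0.0 and not flag

    def test_decision_consistent_with_strict_rule(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            md = rng.normal(scale=1.0, size=6) - rng.uniform(0, 1) * np.arange(6)
            s = make_series(np.arange(6) * 182, [np.zeros(52)] * 6, md=md)
            flag, fit = vd.md_progression(s)
            assert flag == (fit.slope < 0.0 and fit.p_value < 0.05)

    def test_vfi_matches_md_under_affine_link(self):
        rng = np.random.default_rng(4)
        md = -1.0 * np.arange(7) * 0.5 + rng.normal(scale=0.2, size=7)
        vfi = np.clip(100 + 1.5 * md, 0, 100)  # affine in MD, unclipped in range
        s = make_series(np.arange(7) * 182, [np.zeros(52)] * 7, md=md, vfi=vfi)
        assert vd.vfi_progression(s)[0] == vd.md_progression(s)[0]

    def test_flat_vfi_not_progressing(self):
        s = flat_series(6, vfi=[95.0] * 6)
        assert not vd.vfi_progression(s)[0]


class TestPlr:
    def _decaying(self, n_points, rate, n_visits=7, noise=0.02, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n_visits) * 182 / 365.25  # true elapsed years
        rows = []
        for ti in t:
            tdv = np.zeros(52)
            tdv[:n_points] = rate * ti
            rows.append(tdv + rng.normal(scale=noise, size=52))
        return make_series(np.arange(n_visits) * 182, rows)

    def test_three_decaying_points_progress(self):
        flag, fits = vd.plr_progression(self._decaying(3, -2.0))
        assert flag

    def test_two_points_insufficient(self):
        flag, _ = vd.plr_progression(self._decaying(2, -2.0))
        assert not flag

    def test_boundary_slope_counts(self):
        # exactly -1.0 dB/year decay, near-noiseless: inclusive threshold
        flag, fits = vd.plr_progression(self._decaying(3, -1.0, noise=0.0))
        assert all(f.slope == pytest.approx(-1.0, abs=1e-10) for f in fits[:3])
        assert all(f.p_value == 0.0 for f in fits[:3])
        assert flag

    def test_monotone_in_defect_depth(self):
        shallow = vd.plr_progression(self._decaying(3, -1.5))[0]
        deep = vd.plr_progression(self._decaying(3, -4.0))[0]
        assert (not shallow) or deep


class TestCoefficientSlopes:
    def test_slopes_sum_to_zero(self, bank_atset, small_longitudinal):
        series, _ = small_longitudinal
        for s in series[:6]:
            for dec in (aa_decomposer(bank_atset), fcm_decomposer(bank_atset)):
                fits = vd.coefficient_slopes(s, dec)
                assert abs(sum(f.slope for f in fits)) < 1e-8

    def test_stationary_eye_slopes_near_zero(self, bank, bank_atset):
        cfg = vd.SimulationConfig(
            n_patients=3, progression_fraction=0.0, noise_sd_db=0.3, seed=21
        )
        series, _ = vd.simulate_longitudinal(bank, cfg)
        s = vd.drop_learning_tests(series[0], 2)
        fits = vd.coefficient_slopes(s, fcm_decomposer(bank_atset))
        assert max(abs(f.slope) for f in fits) < 0.05

    def test_drift_direction_recovered(self, bank, bank_atset):
        cfg = vd.SimulationConfig(
            n_patients=4, progression_fraction=1.0, progression_target_at=12,
            progression_rate=0.12, noise_sd_db=0.0, seed=22,
        )
        series, truth = vd.simulate_longitudinal(bank, cfg)
        s = vd.drop_learning_tests(series[0], 2)
        # noise-free mixtures: AA recovers the true drifting weights, so the
        # target AT has the (strictly) largest positive slope
        fits_aa = vd.coefficient_slopes(s, aa_decomposer(bank_atset))
        assert fits_aa[12].slope > 0.0
        assert fits_aa[12].slope == max(f.slope for f in fits_aa)
        # FCM memberships: target membership rises, normal membership falls
        fits = vd.coefficient_slopes(s, fcm_decomposer(bank_atset))
        assert fits[12].slope > 0.0
        assert fits[0].slope < 0.0

    def test_two_visit_series_defined(self, bank_atset):
        rows = [np.zeros(52), -0.5 * np.ones(52)]
        s = make_series([0, 182], rows)
        fits = vd.coefficient_slopes(s, fcm_decomposer(bank_atset))
        assert all(f.p_value == 1.0 and f.n == 2 for f in fits)


class TestBaselineDeltas:
    def test_identical_repeat_zero_delta(self, bank_atset):
        tdv = -3.0 * np.ones(52)
        s = make_series([0, 182], [tdv, tdv], md=[-3.0, -3.0])
        dw, dmd = vd.baseline_deltas(s, fcm_decomposer(bank_atset))
        np.testing.assert_allclose(dw, 0.0, atol=1e-12)
        np.testing.assert_allclose(dmd, 0.0)

    def test_counts_and_zero_sum(self, bank_atset):
        rng = np.random.default_rng(5)
        rows = [rng.uniform(-20, 0, size=52) for _ in range(3)]
        s = make_series([0, 182, 364], rows)
        dw, dmd = vd.baseline_deltas(s, aa_decomposer(bank_atset))
        assert dw.shape == (2, 16) and dmd.shape == (2,)
        np.testing.assert_allclose(dw.sum(axis=1), 0.0, atol=1e-8)

    def test_single_visit_empty(self, bank_atset):
        s = make_series([0], [np.zeros(52)])
        dw, dmd = vd.baseline_deltas(s, aa_decomposer(bank_atset))
        assert dw.size == 0 and dmd.size == 0


class TestSlopeMdRelation:
    def test_identity_rho_one(self):
        slopes = np.linspace(-1, 0.2, 20)
        rel = vd.slope_md_relation(slopes, slopes)
        assert rel.rho == pytest.approx(1.0)
        assert rel.line_slope == pytest.approx(1.0, abs=1e-10)

    def test_independent_noise_small_rho(self):
        rng = np.random.default_rng(6)
        rel = vd.slope_md_relation(rng.normal(size=200), rng.normal(size=200))
        assert abs(rel.rho) < 0.2 and rel.p_value > 0.01

    def test_diffuse_at_steeper_than_uninvolved(self, bank, bank_atset):
        # MD decline driven solely by drift toward the total-loss pattern:
        # that AT's slope-MD line is steep, an uninvolved AT's is flat
        cfg = vd.SimulationConfig(
            n_patients=15, progression_fraction=0.5, progression_target_at=12,
            progression_rate=0.1, noise_sd_db=0.5, seed=23,
        )
        series, _ = vd.simulate_longitudinal(bank, cfg)
        dec = fcm_decomposer(bank_atset)
        at_sl, other_sl, md_sl = [], [], []
        for s in series:
            s2 = vd.drop_learning_tests(s, 2)
            fits = vd.coefficient_slopes(s2, dec)
            at_sl.append(fits[12].slope)
            other_sl.append(fits[5].slope)
            md_sl.append(vd.md_progression(s2)[1].slope)
        steep = vd.slope_md_relation(at_sl, md_sl)
        flat = vd.slope_md_relation(other_sl, md_sl)
        assert abs(steep.line_slope) > abs(flat.line_slope)
        assert steep.rho < -0.5  # more AT13 weight gain = faster MD loss

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            vd.slope_md_relation([0.1, 0.2], [0.1, 0.2])
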