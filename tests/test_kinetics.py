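import numpy as np
import pytest

from dynamrs.datatypes import KineticTrace, PeakWindow
from dynamrs.kinetics import (
    GLUCOSE_WINDOW,
    PyruvateTwoPoolModel,
    auc_ratio,
    fit_glucose_uptake,
    fit_glucose_utilization,
    fit_lactate_formation,
    fit_pyruvate_two_pool,
    glucose_lactate_ratio,
    integrate_peak,
)
from dynamrs.synthetic import simulate_pyruvate_series

from conftest import make_real_spectrum


class TestIntegratePeak:
    def test_lorentzian_window_fraction(self):
        # a window of +/-10 half-widths captures (2/pi) arctan(10) ~ 0.937
        # of a unit-area Lorentzian
        n = 20001
        x = np.linspace(-100.0, 100.0, n)  # units of HWHM
        lor = (1.0 / np.pi) / (x**2 + 1.0)
        spec = make_real_spectrum(lor[None, :])
        ppm_per_x = abs(spec.ppm[1] - spec.ppm[0]) / (x[1] - x[0])
        center = float(spec.ppm[n // 2])
        tr = integrate_peak(spec, PeakWindow("pk", center, 10.0 * ppm_per_x))
        frac = tr.values[0] / ppm_per_x  # the full Lorentzian has unit area
        assert frac == pytest.approx((2.0 / np.pi) * np.arctan(10.0), rel=2e-3)
        assert frac == pytest.approx(0.9365, abs=2e-3)

    def test_zero_spectrum_integrates_to_zero(self):
        spec = make_real_spectrum(np.zeros((1, 500)))
        tr = integrate_peak(spec, PeakWindow("pk", 100.0, 5.0))
        assert tr.values[0] == 0.0

    def test_window_outside_axis_rejected(self):
        spec = make_real_spectrum(np.ones((1, 100)))
        with pytest.raises(ValueError):
            integrate_peak(spec, PeakWindow("pk", 400.0, 1.0))


class TestGlucoseUptake:
    def test_noiseless_recovery(self):
        t = np.linspace(0.1, 4.9, 30)
        y = 1.0 * (1 - 0.9 * np.exp(-0.8 * t))
        fit = fit_glucose_uptake(KineticTrace("g", t, y), t0=5.0)
        assert fit.s_total == pytest.approx(1.0, abs=1e-6)
        assert fit.b == pytest.approx(0.9, abs=1e-6)
        assert fit.k_trans == pytest.approx(0.8, abs=1e-6)

    def test_flat_signal_flags_unidentifiable(self):
        t = np.linspace(0.1, 4.9, 20)
        fit = fit_glucose_uptake(KineticTrace("g", t, np.full(20, 3.0)), t0=5.0)
        assert "k_trans_unidentifiable" in fit.flags

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_glucose_uptake(KineticTrace("g", [6.0, 7.0, 8.0, 9.0, 10.0],
                                            np.ones(5)), t0=5.0)


class TestGlucoseUtilization:
    def test_noiseless_recovery(self):
        t = np.linspace(25.5, 60.0, 40)
        y = 80.0 * np.exp(-0.02 * t)
        fit = fit_glucose_utilization(KineticTrace("g", t, y), t_start=25.0)
        assert fit.k_util == pytest.approx(0.02, abs=1e-6)

    def test_constant_trace_zero_rate(self):
        t = np.linspace(26.0, 60.0, 20)
        fit = fit_glucose_utilization(KineticTrace("g", t, np.full(20, 5.0)))
        assert fit.k_util == 0.0
        assert "constant_trace" in fit.flags

    def test_default_window_starts_after_bolus(self):
        # decay window t > 25 min: points before are ignored
        t = np.linspace(0.0, 60.0, 61)
        y = np.where(t > 25, 50.0 * np.exp(-0.03 * t), 999.0)
        fit = fit_glucose_utilization(KineticTrace("g", t, y))
        assert fit.k_util == pytest.approx(0.03, abs=1e-6)


class TestLactateFormation:
    def test_noiseless_recovery(self):
        t = np.linspace(0.5, 60.0, 60)
        y = 30.0 * (1 - np.exp(-0.05 * t))
        rate, lmax, _ = fit_lactate_formation(KineticTrace("l", t, y))
        assert rate == pytest.approx(0.05, abs=1e-6)
        assert lmax == pytest.approx(30.0, abs=1e-4)

    def test_zero_trace(self):
        t = np.linspace(0.5, 30.0, 20)
        rate, lmax, info = fit_lactate_formation(KineticTrace("l", t, np.zeros(20)))
        assert rate == 0.0 and lmax == 0.0
        assert "zero_trace" in info.flags

    def test_rate_order_preserved(self):
        t = np.linspace(0.5, 60.0, 60)
        rng = np.random.default_rng(0)
        slow = 20.0 * (1 - np.exp(-0.02 * t)) + 0.2 * rng.standard_normal(60)
        fast = 20.0 * (1 - np.exp(-0.08 * t)) + 0.2 * rng.standard_normal(60)
        r_slow, *_ = fit_lactate_formation(KineticTrace("l", t, slow))
        r_fast, *_ = fit_lactate_formation(KineticTrace("l", t, fast))
        assert r_fast > r_slow


class TestGlucoseLactateRatio:
    def test_identical_traces(self):
        t = np.linspace(0, 10, 20)
        tr = KineticTrace("x", t, np.sin(t) + 2)
        assert glucose_lactate_ratio(tr, tr) == pytest.approx(1.0)

    def test_double_lactate_halves_ratio(self):
        t = np.linspace(0, 10, 20)
        g = KineticTrace("g", t, np.cos(t) + 3)
        l = KineticTrace("l", t, 2 * (np.cos(t) + 3))
        assert glucose_lactate_ratio(g, l) == pytest.approx(0.5)

    def test_faster_metabolizer_has_lower_ratio(self):
        # equal uptake, different utilization: faster decay -> less glucose
        # on average -> lower glucose/lactate ratio
        from dynamrs.synthetic import glucose_amplitude, saturating_rise

        t = np.linspace(1.0, 60.0, 60)
        lac = KineticTrace("l", t, saturating_rise(t, 30.0, 0.05))
        slow = KineticTrace("g", t, glucose_amplitude(t, 100.0, 0.9, 0.8, 0.01))
        fast = KineticTrace("g", t, glucose_amplitude(t, 100.0, 0.9, 0.8, 0.05))
        assert glucose_lactate_ratio(fast, lac) < glucose_lactate_ratio(slow, lac)

    def test_rescaling_invariance(self):
        t = np.linspace(0, 10, 20)
        g = KineticTrace("g", t, np.cos(t) + 3)
        l = KineticTrace("l", t, np.sin(t) + 4)
        r1 = glucose_lactate_ratio(g, l)
        g2 = KineticTrace("g", t, 7.3 * (np.cos(t) + 3))
        l2 = KineticTrace("l", t, 7.3 * (np.sin(t) + 4))
        assert glucose_lactate_ratio(g2, l2) == pytest.approx(r1, rel=1e-12)


class TestPyruvateTwoPool:
    def test_noiseless_joint_recovery(self):
        pyr, lac = simulate_pyruvate_series(100.0, 0.02, 30.0, 1.0, 240)
        fit = fit_pyruvate_two_pool(pyr, lac)
        assert fit.pyr0 == pytest.approx(100.0, rel=1e-5)
        assert fit.k == pytest.approx(0.02, rel=1e-5)
        assert fit.t1 == pytest.approx(30.0, rel=1e-5)

    def test_decay_rate_is_k_plus_inverse_t1(self):
        pyr, lac = simulate_pyruvate_series(50.0, 0.01, 40.0, 1.0, 200)
        fit = fit_pyruvate_two_pool(pyr, lac)
        assert fit.decay_rate == fit.k + 1.0 / fit.t1

    def test_no_conversion_fits_k_zero(self):
        pyr, lac = simulate_pyruvate_series(100.0, 0.0, 30.0, 1.0, 200)
        fit = fit_pyruvate_two_pool(pyr, lac)
        assert fit.k == pytest.approx(0.0, abs=1e-6)
        assert fit.auc_ratios["lactate/pyruvate"] == pytest.approx(0.0, abs=1e-9)

    def test_mass_balance_limit(self):
        # 1/T1 -> 0: fitted model conserves Pyr + Lac = Pyr(0)
        pyr, lac = simulate_pyruvate_series(100.0, 0.05, 1e9, 1.0, 120)
        model = PyruvateTwoPoolModel().fit(
            pyr.times, np.column_stack([pyr.values, lac.values]))
        mp, ml = model._model(pyr.times, (model.pyr0_, model.k_, model.t1_))
        np.testing.assert_allclose(mp + ml, model.pyr0_, rtol=1e-6)

    def test_k_scaled_form_scales_by_k(self):
        pyr, lac = simulate_pyruvate_series(100.0, 0.05, 30.0, 1.0, 120,
                                            k_scaled_form=True)
        assert pyr.values[0] == pytest.approx(100.0 * 0.05)
        fit = fit_pyruvate_two_pool(pyr, lac, k_scaled_form=True)
        assert fit.k == pytest.approx(0.05, rel=1e-4)

    def test_misaligned_traces_rejected(self):
        pyr, _ = simulate_pyruvate_series(100.0, 0.02, 30.0, 1.0, 100)
        _, lac = simulate_pyruvate_series(100.0, 0.02, 30.0, 1.0, 80)
        with pytest.raises(ValueError):
            fit_pyruvate_two_pool(pyr, lac)


class TestAucRatio:
    def test_equal_traces(self):
        t = np.linspace(0, 100, 50)
        tr = KineticTrace("x", t, np.exp(-t / 30.0))
        assert auc_ratio(tr, tr) == pytest.approx(1.0)

    def test_converges_to_k_t1(self):
        # k*T1 = 0.6; at 10 pyruvate lifetimes the ratio is within 1%
        k, t1 = 0.02, 30.0
        horizon = 10.0 / (k + 1.0 / t1)
        n = int(horizon) + 1
        pyr, lac = simulate_pyruvate_series(100.0, k, t1, 1.0, n)
        assert auc_ratio(lac, pyr) == pytest.approx(k * t1, rel=0.01)

    def test_truncation_underestimates_monotonically(self):
        k, t1 = 0.02, 30.0
        ratios = []
        for n in (60, 120, 240, 480):
            pyr, lac = simulate_pyruvate_series(100.0, k, t1, 1.0, n)
            ratios.append(auc_ratio(lac, pyr))
        assert all(r < k * t1 for r in ratios[:3])
        assert np.all(np.diff(ratios) > 0)

    def test_zero_denominator_rejected(self):
        t = np.linspace(0, 10, 10)
        with pytest.raises(ZeroDivisionError):
            auc_ratio(KineticTrace("l", t, np.ones(10)),
                      KineticTrace("p", t, np.zeros(10)))


class TestNoisyParameterRecovery:
    def test_median_relative_error_under_ten_percent(self):
        """5% peak-amplitude noise: median relative errors stay below 10%."""
        rng = np.random.default_rng(11)
        t_up = np.linspace(0.1, 4.9, 30)
        y_up = 1.0 * (1 - 0.9 * np.exp(-0.8 * t_up))
        t_dec = np.linspace(25.5, 60.0, 45)
        y_dec = 80.0 * np.exp(-0.02 * t_dec)
        errs = {"k_trans": [], "k_util": [], "k": [], "t1": [], "pyr0": []}
        for i in range(30):
            yy = y_up + 0.05 * y_up.max() * rng.standard_normal(t_up.size)
            f = fit_glucose_uptake(KineticTrace("g", t_up, yy), t0=5.0)
            errs["k_trans"].append(abs(f.k_trans - 0.8) / 0.8)
            yy = y_dec + 0.05 * y_dec.max() * rng.standard_normal(t_dec.size)
            f = fit_glucose_utilization(KineticTrace("g", t_dec, yy))
            errs["k_util"].append(abs(f.k_util - 0.02) / 0.02)
            pyr, lac = simulate_pyruvate_series(100.0, 0.02, 30.0, 1.0, 240,
                                                noise_sigma=5.0, seed=2000 + i)
            pf = fit_pyruvate_two_pool(pyr, lac)
            errs["k"].append(abs(pf.k - 0.02) / 0.02)
            errs["t1"].append(abs(pf.t1 - 30.0) / 30.0)
            errs["pyr0"].append(abs(pf.pyr0 - 100.0) / 100.0)
        for name, e in errs.items():
            assert np.median(e) < 0.10, name
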