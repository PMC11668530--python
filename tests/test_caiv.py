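"""Ca2+ IV analysis: leak subtraction, reversal potential, Boltzmann fit."""

import numpy as np
import pytest

import pairsynapse as ps
from pairsynapse.caiv import IvPoint


def model_iv_points(g_max=5.0, v_half=-30.0, slope=7.0, v_rev=60.0,
                    v=np.arange(-70, 71, 5.0)):
    g = g_max / (1 + np.exp((v_half - v) / slope))
    i = g * (v - v_rev)
    return [IvPoint(float(vv), float(ii), float(ii * 10)) for vv, ii in zip(v, i)]


class TestLeakSubtract:
    def test_ohmic_cell_exact_cancellation(self):
        # n = 4, zero noise: leak cancels to machine precision
        truth = ps.GroundTruth(
            seed=1, boltzmann_true=(0.0, -30.0, 7.0, 60.0), leak_g=2.5, noise_sd_pre=0.0
        )
        iv = ps.iv_protocol()
        main = ps.simulate_ca_current(iv, truth)
        pn = ps.simulate_ca_current(ps.pn_protocol(iv, 4, base=-90.0), truth)
        for m, p in zip(main, pn):
            out = ps.leak_subtract(m, [p], 4)
            assert np.max(np.abs(out.i_pre)) < 1e-9

    def test_boltzmann_plus_leak_equals_pure_boltzmann(self):
        truth = ps.GroundTruth(seed=2, leak_g=2.0, noise_sd_pre=3.0)
        pure = ps.GroundTruth(seed=2, leak_g=0.0, noise_sd_pre=0.0)
        iv = ps.iv_protocol()
        main = ps.simulate_ca_current(iv, truth)
        pn = ps.simulate_ca_current(ps.pn_protocol(iv, -4), truth)
        ref = ps.simulate_ca_current(iv, pure)
        # subtracting n x a noisy replica propagates noise as sqrt(1+n^2) sd
        propagated = np.sqrt(1 + 16) * truth.noise_sd_pre
        for m, p, r in zip(main, pn, ref):
            out = ps.leak_subtract(m, [p], -4)
            resid = out.i_pre - r.i_pre
            assert np.std(resid) < 1.5 * propagated
            assert abs(np.mean(resid)) < 0.15 * propagated

    def test_length_mismatch_rejected(self):
        truth = ps.GroundTruth(seed=1)
        iv = ps.iv_protocol()
        main = ps.simulate_ca_current(iv, truth)[0]
        short = ps.simulate_ca_current(ps.iv_protocol(post_ms=5.0), truth)[0]
        with pytest.raises(ValueError):
            ps.leak_subtract(main, [short], 4)


class TestIvCurve:
    def test_constant_step_current(self):
        n = 2000
        dt = 0.02
        i_pre = np.zeros(n)
        i0, i1 = 500, 1000  # 10 ms step
        i_pre[i0:i1] = -100.0
        sw = ps.Sweep(
            0, dt, np.full(n, -58.0), i_pre, np.zeros(n), "IV", [(10.0, 20.0, -20.0)]
        )
        (pt,) = ps.iv_curve([sw])
        assert pt.i_ca == pytest.approx(-100.0, rel=0.01)
        assert pt.q_ca == pytest.approx(-1000.0, rel=0.01)

    def test_step_shorter_than_window_rejected(self):
        n = 2000
        sw = ps.Sweep(
            0, 0.02, np.full(n, -58.0), np.zeros(n), np.zeros(n), "IV",
            [(10.0, 15.0, -20.0)],
        )
        with pytest.raises(ValueError):
            ps.iv_curve([sw])

    def test_minimum_at_peak_current_voltage(self):
        # noiseless: argmin of i_ca matches the analytic argmin of g(V)(V-Vrev)
        truth = ps.GroundTruth(seed=3, noise_sd_pre=0.0, leak_g=0.0)
        pts = ps.iv_curve(ps.simulate_ca_current(ps.iv_protocol(), truth))
        v = np.array([p.v for p in pts])
        i = np.array([p.i_ca for p in pts])
        g_max, v_half, slope, v_rev = truth.boltzmann_true
        vv = np.linspace(-70, 70, 2001)
        ii = g_max / (1 + np.exp((v_half - vv) / slope)) * (vv - v_rev)
        assert v[np.argmin(i)] == pytest.approx(vv[np.argmin(ii)], abs=5.0)


class TestReversal:
    def test_collinear_points(self):
        pts = [IvPoint(-20, -300, 0)] + [
            IvPoint(v, i, 0) for v, i in [(50, -20), (55, -10), (60, 0), (65, 10)]
        ]
        v_rev, extrap = ps.reversal_potential(pts)
        assert v_rev == pytest.approx(60.0, abs=1e-9)
        assert not extrap

    def test_too_few_points_rejected(self):
        pts = [IvPoint(-20, -300, 0), IvPoint(0, -200, 0), IvPoint(5, -150, 0)]
        with pytest.raises(ValueError, match="widen"):
            ps.reversal_potential(pts)

    def test_extrapolation_flagged(self):
        pts = [IvPoint(-20, -300, 0)] + [
            IvPoint(v, -100 + v, 0) for v in (0, 10, 20, 30)
        ]
        v_rev, extrap = ps.reversal_potential(pts)
        assert extrap
        assert v_rev == pytest.approx(100.0, abs=1e-6)


class TestBoltzmann:
    def test_noiseless_exact_recovery(self):
        fit = ps.fit_boltzmann(model_iv_points(), v_rev=60.0)
        assert fit.ok
        assert fit.g_max == pytest.approx(5.0, abs=1e-6)
        assert fit.v_half == pytest.approx(-30.0, abs=1e-6)
        assert fit.slope == pytest.approx(7.0, abs=1e-6)

    def test_half_activation_at_v_half(self):
        fit = ps.fit_boltzmann(model_iv_points(), v_rev=60.0)
        assert fit.activation(fit.v_half) == pytest.approx(0.5, abs=1e-12)
        # conductance is monotone non-decreasing in V
        v = np.linspace(-80, 60, 300)
        g = fit.conductance(v)
        assert np.all(np.diff(g) >= -1e-12)

    def test_threshold_at_5_percent(self):
        fit = ps.fit_boltzmann(model_iv_points(), v_rev=60.0)
        assert fit.activation(fit.threshold_v) == pytest.approx(0.05, abs=1e-9)

    def test_noisy_recovery(self):
        # 5% of g_max conductance noise, 27-point protocol
        rng = np.random.default_rng(5)
        errs_vh, errs_sl = [], []
        for _ in range(60):
            pts = model_iv_points()
            noisy = [
                IvPoint(p.v, p.i_ca + rng.normal(0, 0.05 * 5.0) * (p.v - 60.0), p.q_ca)
                for p in pts
            ]
            fit = ps.fit_boltzmann(noisy, v_rev=60.0)
            errs_vh.append(abs(fit.v_half + 30.0))
            errs_sl.append(abs(fit.slope / 7.0 - 1))
        assert np.median(errs_vh) < 1.0
        assert np.median(errs_sl) < 0.10

    def test_full_pipeline_recovery(self):
        # simulate -> P/n subtract -> IV -> reversal -> Boltzmann at
        # paper-like noise: (g_max 5%, v_half 1 mV, slope 10%)
        truth = ps.GroundTruth(seed=3)
        iv = ps.iv_protocol()
        main = ps.simulate_ca_current(iv, truth)
        pn = ps.simulate_ca_current(ps.pn_protocol(iv, -4), truth)
        pts = ps.iv_curve([ps.leak_subtract(m, [p], -4) for m, p in zip(main, pn)])
        v_rev, _ = ps.reversal_potential(pts)
        fit = ps.fit_boltzmann(pts, v_rev)
        g_max, v_half, slope, _ = truth.boltzmann_true
        assert fit.g_max == pytest.approx(g_max, rel=0.05)
        assert fit.v_half == pytest.approx(v_half, abs=1.0)
        assert fit.slope == pytest.approx(slope, rel=0.10)
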