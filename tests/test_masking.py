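"""Forward masking: averaging, latency, depletion fit, recovery."""

import numpy as np
import pytest

import pairsynapse as ps
from pairsynapse.masking import RecoveryCurve, _dep_model
from pairsynapse.synth import _band_noise


def fm_sweep(latency_ms=None, isi=16.0, seed=0, noise=1.0, probe_scale=1.0,
             masker_amp=-200.0, dt=0.02):
    """One synthetic FM sweep: square current responses to masker and probe."""
    pre, masker, probe_dur, post = 50.0, 100.0, 15.0, 100.0
    dur = pre + masker + isi + probe_dur + post
    n = int(round(dur / dt))
    rng = np.random.default_rng(seed)
    x = _band_noise(rng, noise, n, dt)
    p0 = pre + masker + isi
    if latency_ms is not None:
        k = ps.make_epsc_kernel(masker_amp, 0.12, 0.52, dt)
        i0 = int(round((pre + latency_ms) / dt))
        x[i0 : i0 + k.size] += k
        i1 = int(round((p0 + latency_ms) / dt))
        x[i1 : i1 + k.size] += probe_scale * k
    return ps.Sweep(
        0, dt, np.full(n, -58.0), np.zeros(n), x, "FM",
        [(pre, pre + masker, -19.0), (p0, p0 + probe_dur, -19.0)],
    )


class TestAveraging:
    def test_identical_repetitions(self):
        sw = fm_sweep(latency_ms=2.0, seed=1)
        avg = ps.average_masker_response([sw, sw, sw])
        single = ps.average_masker_response([sw, sw, sw])
        np.testing.assert_allclose(avg.q_cum, single.q_cum)
        assert avg.n_reps == 3 and not avg.low_reps

    def test_linearity_of_cumulative_charge(self):
        # charges 100 and 200 fC average to 150 fC
        dt = 0.02
        n = 20000

        def rect(total_fc):
            x = np.zeros(n)
            i0, i1 = int(55.0 / dt), int(65.0 / dt)  # 10 ms pulse
            x[i0:i1] = -total_fc / 10.0
            return ps.Sweep(
                0, dt, np.full(n, -58.0), np.zeros(n), x, "FM",
                [(50.0, 150.0, -19.0), (166.0, 181.0, -19.0)],
            )

        with pytest.warns(UserWarning, match="repetitions"):
            avg = ps.average_masker_response([rect(100.0), rect(200.0)])
        k50 = int(round(50.0 / dt))
        assert avg.q_cum[k50] == pytest.approx(150.0, rel=0.01)

    def test_low_repetition_warning(self):
        with pytest.warns(UserWarning, match="repetitions"):
            avg = ps.average_masker_response([fm_sweep(latency_ms=2.0)])
        assert avg.low_reps


class TestLatency:
    def test_fixed_latency_zero_jitter(self):
        sweeps = [fm_sweep(latency_ms=1.2, seed=s, noise=0.5) for s in range(5)]
        mean, sd, missing = ps.latency_stats(sweeps)
        assert mean == pytest.approx(1.2, abs=0.15)
        assert sd < 0.05
        assert missing == 0

    def test_exponential_jitter_sampling(self):
        # latencies 1.0 + Exp(0.4): mean ~1.4, SD ~0.4 (n = 20, seed 2)
        rng = np.random.default_rng(2)
        lats = 1.0 + rng.exponential(0.4, 20)
        sweeps = [
            fm_sweep(latency_ms=float(lat), seed=100 + i, noise=0.5)
            for i, lat in enumerate(lats)
        ]
        mean, sd, _ = ps.latency_stats(sweeps)
        assert mean == pytest.approx(1.4, abs=0.3)
        assert sd == pytest.approx(0.4, rel=0.5)

    def test_preset_latency_ordering(self):
        # high-SR synapses respond faster than low-SR ones, seed by seed
        wins = 0
        for seed in range(6):
            fm = ps.fm_protocol(isis=(16.0,), repetitions=5, post_ms=50.0)
            hi, _ = ps.simulate_evoked(fm, ps.preset_high_sr(seed=seed))
            lo, _ = ps.simulate_evoked(fm, ps.preset_low_sr(seed=seed))
            if ps.latency_stats(hi)[0] < ps.latency_stats(lo)[0]:
                wins += 1
        assert wins == 6

    def test_needs_three_repetitions(self):
        with pytest.raises(ValueError):
            ps.latency_stats([fm_sweep(latency_ms=1.0), fm_sweep(latency_ms=1.0)])


class TestDepletionFit:
    def test_noiseless_exact_recovery(self):
        # model identity, parameters at the published scale:
        # A1 980 fC, tau 6.3 ms, slope 30 fC/ms, mean sEPSC charge 70 fC
        t = np.arange(0, 80.0, 0.02)
        q = _dep_model(t, 25.0, 980.0, 1.2, 6.3, 30.0)
        fit = ps.fit_depletion((t, q), 70.0)
        assert fit.fit_ok
        assert fit.a1 == pytest.approx(980.0, rel=1e-6)
        assert fit.tau == pytest.approx(6.3, rel=1e-6)
        assert fit.line_slope == pytest.approx(30.0, rel=1e-6)
        assert fit.rrp_sv == pytest.approx(14.0, rel=1e-6)

    def test_derived_quantity_identities(self):
        t = np.arange(0, 80.0, 0.02)
        q = _dep_model(t, 10.0, 700.0, 0.5, 9.0, 21.0)
        fit = ps.fit_depletion((t, q), 70.0)
        assert fit.rrp_sv == pytest.approx(fit.a1 / 70.0, abs=1e-12)
        assert fit.sustained_rate == pytest.approx(fit.line_slope / 70.0 * 1e3, abs=1e-9)
        assert fit.initial_rate == pytest.approx(
            (fit.a1 / fit.tau + fit.line_slope) / 70.0 * 1e3, rel=1e-12
        )
        assert fit.depression_ratio == pytest.approx(
            fit.initial_rate / fit.sustained_rate, rel=1e-12
        )

    def test_pure_exponential_gives_nan_ratio(self):
        t = np.arange(0, 80.0, 0.02)
        q = _dep_model(t, 0.0, 980.0, 0.0, 6.3, 0.0)
        fit = ps.fit_depletion((t, q), 70.0)
        assert fit.sustained_rate == pytest.approx(0.0, abs=1e-6)
        assert np.isnan(fit.depression_ratio)

    def test_short_trace_rejected(self):
        t = np.arange(0, 30.0, 0.02)
        with pytest.raises(ValueError):
            ps.fit_depletion((t, np.zeros_like(t)), 70.0)

    def test_bad_quantal_charge_rejected(self):
        t = np.arange(0, 80.0, 0.02)
        with pytest.raises(ValueError):
            ps.fit_depletion((t, np.zeros_like(t)), 0.0)

    def test_rrp_monotone_in_pool_size(self):
        # end-to-end: larger simulated RRP -> larger fitted RRP
        fitted = []
        for n_rrp in (7.0, 14.0, 28.0):
            truth = ps.preset_high_sr(seed=6, pool=(n_rrp, 6.3, 450.0, 450.0))
            fm = ps.fm_protocol(isis=(16.0,), repetitions=10, post_ms=50.0)
            sweeps, _ = ps.simulate_evoked(fm, truth)
            avg = ps.average_masker_response(sweeps)
            fitted.append(ps.fit_depletion(avg, truth.mean_charge).rrp_sv)
        assert fitted[0] < fitted[1] < fitted[2]


class TestRecovery:
    def test_identical_probe_and_masker(self):
        sweeps = [
            fm_sweep(latency_ms=1.5, isi=isi, seed=i, probe_scale=1.0)
            for i, isi in enumerate((4.0, 16.0, 64.0, 256.0))
        ]
        curve = ps.recovery_curve(sweeps)
        assert curve.isi_ms[-1] == 20000.0 and curve.ratio[-1] == 1.0
        for r in curve.ratio[:-1]:
            assert r == pytest.approx(1.0, abs=0.15)

    def test_half_sized_probe(self):
        sweeps = [
            fm_sweep(latency_ms=1.5, isi=isi, seed=i, probe_scale=0.5, noise=0.2)
            for i, isi in enumerate((4.0, 16.0, 64.0, 256.0))
        ]
        curve = ps.recovery_curve(sweeps)
        for r in curve.ratio[:-1]:
            assert r == pytest.approx(0.5, abs=0.1)

    def test_exact_exponential_recovery(self):
        t = np.array([16.0, 64.0, 256.0, 20000.0])
        curve = RecoveryCurve(
            isi_ms=list(t), ratio=list(1 - 0.8 * np.exp(-t / 200.0))
        )
        tau = ps.fit_recovery(curve)
        assert tau == pytest.approx(200.0, rel=1e-6)

    def test_no_depression_flagged(self):
        curve = RecoveryCurve(isi_ms=[16.0, 64.0, 256.0, 20000.0], ratio=[1.0] * 4)
        assert np.isnan(ps.fit_recovery(curve))
        assert not curve.ok

    def test_simulated_recovery_increases_with_isi(self):
        # occupancy model at tau_recovery 450 ms: ratios rise for ISI >= 16
        rises = 0
        for seed in range(5):
            fm = ps.fm_protocol(repetitions=6, post_ms=100.0)
            sweeps, _ = ps.simulate_evoked(fm, ps.preset_high_sr(seed=seed))
            c = ps.recovery_curve(sweeps)
            r = dict(zip(c.isi_ms, c.ratio))
            if r[256.0] > r[16.0]:
                rises += 1
        assert rises >= 4
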