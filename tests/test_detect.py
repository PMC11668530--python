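"""Event detection, kinetic measurement and waveform classification."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.signal import savgol_filter

import pairsynapse as ps
from pairsynapse.detect import DetectionConfig
from pairsynapse.synth import _band_noise

from conftest import match_events


def noise_sweep(seed, sd=3.0, dur_ms=2000.0, dt=0.02):
    rng = np.random.default_rng(seed)
    n = int(dur_ms / dt)
    x = _band_noise(rng, sd, n, dt)
    return ps.Sweep(0, dt, np.full(n, -58.0), np.zeros(n), x)


class TestDetection:
    def test_below_threshold_event_not_detected(self):
        # amplitude 3.9 x (smoothed) SD can never cross the 4 x SD
        # threshold; noise is confined to the baseline window so the check
        # at the injection site is deterministic
        sw = noise_sweep(1)
        sw.i_post[sw.sample_at(1100.0) :] = 0.0
        i0, i1 = sw.sample_at(0.0), sw.sample_at(1000.0)
        xs = savgol_filter(sw.i_post, 15, 2)
        b = xs[i0:i1]
        sd_s = 1.4826 * np.median(np.abs(b - np.median(b)))
        k = ps.make_epsc_kernel(-3.9 * sd_s, 0.12, 0.52, sw.dt)
        inject_at = 60000
        sw.i_post[inject_at : inject_at + k.size] += k
        evs = ps.detect_events(sw, (0, 1000), measure=False)
        t_inj = inject_at * sw.dt
        assert not any(abs(e.peak_time - t_inj) < 2.0 for e in evs)

    def test_injected_kernels_recovered(self):
        # 5 kernels of -50 pA on 3 pA noise: exactly 5 events at +-0.2 ms
        sw = noise_sweep(2, dur_ms=3000.0)
        k = ps.make_epsc_kernel(-50.0, 0.12, 0.52, sw.dt)
        times = [1200.0, 1500.0, 1800.0, 2100.0, 2400.0]
        for t in times:
            i = sw.sample_at(t)
            sw.i_post[i : i + k.size] += k
        evs = ps.detect_events(sw, (0, 1000), measure=False)
        assert len(evs) == 5
        for t, e in zip(times, evs):
            assert e.onset == pytest.approx(t, abs=0.2)
            assert e.amplitude < 0

    def test_false_positive_rate_matches_crossing_oracle(self):
        # brute-force oracle: count noise excursions that cross 4xSD and
        # stay below half that level for the minimum event width
        cfg = DetectionConfig()
        det_counts, oracle_counts = 0, 0
        for seed in range(15):
            sw = noise_sweep(seed, dur_ms=5000.0)
            det_counts += len(ps.detect_events(sw, (0, 1000), measure=False))
            xs = savgol_filter(sw.i_post, 15, 2)
            sd = 1.4826 * np.median(np.abs(xs - np.median(xs)))
            below = xs < -0.5 * cfg.threshold_sd * sd
            deep = xs < -cfg.threshold_sd * sd
            # walk the runs of `below`; count those reaching `deep` and
            # lasting at least min_width
            min_w = int(round(cfg.min_width_ms / sw.dt))
            n = 0
            idx = np.flatnonzero(below)
            runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
            for run in runs:
                if run.size >= min_w and deep[run].any():
                    n += 1
            oracle_counts += n
        assert abs(det_counts - oracle_counts) <= 3 * np.sqrt(max(oracle_counts, 1))

    def test_translation_invariance(self):
        sw = noise_sweep(3, dur_ms=3000.0)
        k = ps.make_epsc_kernel(-60.0, 0.12, 0.52, sw.dt)
        i0 = sw.sample_at(1500.0)
        sw.i_post[i0 : i0 + k.size] += k
        evs = ps.detect_events(sw, (0, 1000), measure=False)
        shift = 250  # samples
        sw2 = ps.Sweep(
            0, sw.dt, sw.v_cmd, sw.i_pre, np.roll(sw.i_post, shift)
        )
        evs2 = ps.detect_events(sw2, (0, 1000), measure=False)
        big = [e.onset for e in evs if abs(e.amplitude) > 30]
        big2 = [e.onset for e in evs2 if abs(e.amplitude) > 30]
        assert len(big) == len(big2) == 1
        assert big2[0] - big[0] == pytest.approx(shift * sw.dt, abs=0.05)

    def test_gain_covariance(self):
        # scaling the trace scales the (SD-derived) threshold: same events
        sw = noise_sweep(4, dur_ms=3000.0)
        k = ps.make_epsc_kernel(-60.0, 0.12, 0.52, sw.dt)
        i0 = sw.sample_at(1500.0)
        sw.i_post[i0 : i0 + k.size] += k
        evs = ps.detect_events(sw, (0, 1000), measure=False)
        sw3 = ps.Sweep(0, sw.dt, sw.v_cmd, sw.i_pre, 3.0 * sw.i_post)
        evs3 = ps.detect_events(sw3, (0, 1000), measure=False)
        assert [e.onset for e in evs] == [e.onset for e in evs3]
        for a, b in zip(evs, evs3):
            assert b.amplitude == pytest.approx(3 * a.amplitude, rel=1e-9)

    def test_short_baseline_rejected(self):
        sw = noise_sweep(5)
        with pytest.raises(ValueError, match="baseline"):
            ps.detect_events(sw, (0, 50))

    def test_degenerate_trace_rejected(self):
        n = 60000
        sw = ps.Sweep(0, 0.02, np.full(n, -58.0), np.zeros(n), np.zeros(n))
        with pytest.raises(ValueError, match="degenerate"):
            ps.detect_events(sw, (0, 1000))


class TestMeasurement:
    def test_kernel_kinetics(self, kernel_trace):
        sw, t0, k = kernel_trace
        p = int(np.argmin(sw.i_post))
        ev = ps.EpscEvent(onset=t0, peak_time=p * sw.dt, amplitude=float(k.min()))
        ev = ps.measure_event(sw, ev, noise_sd=0.1)

        # FWHM oracle: root-finding on the analytic kernel
        tr, td = 0.1, 1.0
        t_peak = tr * td / (td - tr) * np.log(td / tr)
        scale = -100.0 / (np.exp(-t_peak / td) - np.exp(-t_peak / tr))
        f = lambda t: scale * (np.exp(-t / td) - np.exp(-t / tr)) + 50.0
        left = brentq(f, 1e-6, t_peak)
        right = brentq(f, t_peak, 20.0)
        assert ev.fwhm == pytest.approx(right - left, rel=0.01)
        # charge oracle: A (tau_d - tau_r)
        assert ev.charge == pytest.approx(abs(scale * (td - tr)), rel=0.005)
        assert ev.amplitude == pytest.approx(-100.0, rel=0.01)
        assert ev.tau_decay == pytest.approx(td, rel=0.05)
        assert ev.rise_10_90 > 0

    def test_triangular_pulse_fwhm(self):
        # symmetric triangle of width 2 ms has half-width exactly 1 ms
        dt = 0.02
        n = 15000
        x = np.zeros(n)
        i0 = 7000
        w = int(1.0 / dt)
        x[i0 : i0 + w] = -np.linspace(0, 100, w)
        x[i0 + w : i0 + 2 * w] = -np.linspace(100, 0, w)
        sw = ps.Sweep(0, dt, np.full(n, -58.0), np.zeros(n), x)
        ev = ps.EpscEvent(onset=i0 * dt, peak_time=(i0 + w) * dt, amplitude=-100.0)
        ev = ps.measure_event(sw, ev, noise_sd=0.1)
        assert ev.fwhm == pytest.approx(1.0, rel=0.02)


class TestClassification:
    def test_clean_kernel_is_monophasic(self, kernel_trace):
        sw, t0, k = kernel_trace
        rng = np.random.default_rng(0)
        sw.i_post += _band_noise(rng, 0.5, sw.n_samples, sw.dt)
        evs = ps.detect_events(sw, (0, 100))
        target = [e for e in evs if abs(e.amplitude) > 50]
        assert len(target) == 1
        assert target[0].phasic_class == "monophasic"
        assert target[0].n_inflections == 0

    def test_two_offset_kernels_multiphasic(self):
        dt = 0.02
        n = 15000
        k = ps.make_epsc_kernel(-100.0, 0.1, 1.0, dt)
        x = np.zeros(n)
        x[7000 : 7000 + k.size] += k
        x[7050 : 7050 + k.size] += k  # second kernel 1 ms later
        rng = np.random.default_rng(1)
        x += _band_noise(rng, 0.5, n, dt)
        sw = ps.Sweep(0, dt, np.full(n, -58.0), np.zeros(n), x)
        evs = [e for e in ps.detect_events(sw, (0, 100)) if abs(e.amplitude) > 50]
        assert len(evs) == 1
        assert evs[0].phasic_class == "multiphasic"
        assert evs[0].n_inflections >= 1

    def test_batch_fraction_matches_binomial_oracle(self):
        # ~420 events at frac_multiphasic 0.5, high SNR
        truth = ps.GroundTruth(
            seed=23, sr_true=20.0, frac_multiphasic=0.5, noise_sd_post=1.0
        )
        sw, _ = ps.simulate_spontaneous(truth, 21000.0)
        evs = ps.detect_events(sw, (0, 1000))
        assert len(evs) > 350
        frac = np.mean([e.phasic_class == "multiphasic" for e in evs])
        assert frac == pytest.approx(0.5, abs=0.07)


class TestDetectorPerformance:
    def test_recall_precision_snr8(self):
        # per-event SNR 8 (amplitude = 8 x noise SD), 20 events/s
        truth = ps.GroundTruth(
            seed=5,
            sr_true=20.0,
            kernel=(24.0, 0.0, 0.0, 0.12, 0.52),
            frac_multiphasic=0.0,
            noise_sd_post=3.0,
        )
        sw, out = ps.simulate_spontaneous(truth, 40000.0)
        evs = ps.detect_events(sw, (0, 1000), measure=False)
        recall, precision = match_events(
            [t for t, _ in out.event_times], [e.onset for e in evs]
        )
        assert recall >= 0.95
        assert precision >= 0.95

    def test_amplitude_unbiased(self):
        # isolated fixed-amplitude events: mean measured amplitude within
        # the noise-limited band around truth
        truth = ps.GroundTruth(
            seed=8,
            sr_true=5.0,
            kernel=(60.0, 0.0, 0.0, 0.12, 0.52),
            frac_multiphasic=0.0,
            noise_sd_post=3.0,
        )
        sw, out = ps.simulate_spontaneous(truth, 60000.0)
        evs = ps.detect_events(sw, (0, 1000))
        amps = np.array([e.amplitude for e in evs])
        se = 3.0 / np.sqrt(len(amps))
        assert amps.mean() == pytest.approx(-60.0, abs=max(3 * se, 1.0))
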