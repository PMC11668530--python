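"""Shared fixtures and synthetic-trace builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import pairsynapse as ps


def rc_testpulse(rs, cm, rm, step=10.0, dt=0.02, noise=0.0, seed=0):
    """Analytic single-RC test-pulse sweep (voltage-clamp circuit equations).

    I(t) = dV/(Rs+Rm) + dV (1/Rs − 1/(Rs+Rm)) exp(−t/tau),
    tau = Cm Rs Rm / (Rs+Rm).  Units: MOhm, pF, mV, pA, ms.
    """
    pre, dur, post = 10.0, 30.0, 10.0
    n = int(round((pre + dur + post) / dt))
    t_on = int(round(pre / dt))
    t_off = int(round((pre + dur) / dt))
    tau = cm * rs * rm / (rs + rm) * 1e-3  # pF*MOhm = 1e-3 ms
    iss = step / (rs + rm) * 1000.0
    i0 = step / rs * 1000.0
    i = np.zeros(n)
    t = np.arange(n - t_on) * dt
    i[t_on:] = iss + (i0 - iss) * np.exp(-t / tau)
    t2 = np.arange(n - t_off) * dt
    i[t_off:] -= iss + (i0 - iss) * np.exp(-t2 / tau)
    if noise:
        i += np.random.default_rng(seed).normal(0, noise, n)
    v = np.full(n, -90.0)
    v[t_on:t_off] += step
    return ps.Sweep(0, dt, v, np.zeros(n), i, "testpulse", [(pre, pre + dur, -80.0)])


def match_events(t_true, t_det, window_ms=0.5):
    """Greedy one-to-one matching of detected onsets to true event times."""
    t_true = np.asarray(t_true, float)
    t_det = np.asarray(t_det, float)
    used = np.zeros(t_det.size, bool)
    tp = 0
    for t in t_true:
        if not t_det.size:
            break
        d = np.abs(t_det - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= window_ms:
            tp += 1
            used[j] = True
    recall = tp / max(t_true.size, 1)
    precision = tp / max(t_det.size, 1)
    return recall, precision


def iv_qca_qepsc(truth, iv=None):
    """Run the IV limb of the pipeline: paired (|Q_Ca|, Q_EPSC) points."""
    from pairsynapse.caiv import iv_curve, leak_subtract

    iv = iv or ps.iv_protocol()
    ev, _ = ps.simulate_evoked(iv, truth)
    ri = ps.release_intensity(ev)
    pn = ps.simulate_ca_current(ps.pn_protocol(iv, -4), truth)
    pts = iv_curve([leak_subtract(s, [p], -4) for s, p in zip(ev, pn)])
    v_to_q = {p.v: abs(p.q_ca) for p in pts if p.q_ca < 0}
    qq = [(v_to_q[v], q) for v, q in ri if v in v_to_q]
    return np.array([x for x, _ in qq]), np.array([y for _, y in qq])


@pytest.fixture
def kernel_trace():
    """Noiseless sweep holding one −100 pA biexponential EPSC."""
    dt = 0.02
    n = 15000
    k = ps.make_epsc_kernel(-100.0, 0.1, 1.0, dt)
    x = np.zeros(n)
    x[7000 : 7000 + k.size] += k
    sw = ps.Sweep(0, dt, np.full(n, -58.0), np.zeros(n), x)
    return sw, 7000 * dt, k
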