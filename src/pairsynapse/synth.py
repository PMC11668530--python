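"""Generative simulator of paired IHC/bouton recordings with known ground truth.

The simulator produces the three ingredients of a paired recording:

* spontaneous EPSC trains — homogeneous Poisson event times with
  right-skewed (gamma) amplitudes and an optional multiphasic fraction
  rendered as jittered sub-event sums;
* whole-cell Ca2+ currents — a Boltzmann-gated conductance with linear
  driving force, ohmic leak and first-order activation kinetics;
* evoked release — an occupancy model of a finite readily releasable pool
  (RRP) depleting through a power-law coupling to the Ca2+ drive and
  replenishing with a single recovery time constant.

Every stochastic output is reproducible from ``GroundTruth.seed``, and every
release event placed in a trace is recorded so detection and parameter
recovery can be scored against the truth.

Default parameter values describe a typical high-SR-like synapse of a
hearing mouse: spontaneous rates of a few events/s (observed range
0-18 events/s), mean sEPSC amplitude about -80 pA with CV 0.68, mean charge
near 70 fC, an RRP of ~14 vesicles depleting with a ~6 ms time constant,
sustained release near 450 vesicles/s and recovery with a ~450 ms time
constant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .recording import PairRecord, Sweep

__all__ = [
    "GroundTruth",
    "Protocol",
    "iv_protocol",
    "fm_protocol",
    "spont_protocol",
    "pn_protocol",
    "make_epsc_kernel",
    "simulate_spontaneous",
    "simulate_ca_current",
    "simulate_evoked",
    "simulate_pair",
    "preset_high_sr",
    "preset_low_sr",
]

HOLDING_V = -58.0  # mV, presumed physiological IHC resting potential


@dataclass
class GroundTruth:
    """True parameters of one simulated paired recording.

    ``kernel`` is (amplitude mean magnitude pA, amplitude CV, amplitude
    skewness implied by the gamma law = 2*CV, rise tau ms, decay tau ms).
    ``boltzmann_true`` is (g_max nS, v_half mV, slope mV, v_rev mV).
    ``pool`` is (n_rrp vesicles, tau_depletion ms, sustained_rate
    vesicles/s, tau_recovery ms).  ``event_times`` lists every release
    event placed in the traces as (time ms, number of sub-events).
    """

    sr_true: float = 3.0
    kernel: tuple = (80.0, 0.68, 1.36, 0.12, 0.52)
    frac_multiphasic: float = 0.5
    boltzmann_true: tuple = (5.0, -30.0, 7.0, 60.0)
    leak_g: float = 1.0
    coupling_m: float = 1.4
    pool: tuple = (14.0, 6.3, 450.0, 450.0)
    latency0: float = 1.2
    latency_jitter: float = 0.2
    noise_sd_post: float = 3.0
    noise_sd_pre: float = 4.0
    seed: int = 0
    event_times: list = field(default_factory=list)

    def __post_init__(self):
        if self.sr_true < 0 or self.noise_sd_post < 0 or self.noise_sd_pre < 0:
            raise ValueError("rates and noise SDs must be non-negative")
        if not 0 <= self.frac_multiphasic <= 1:
            raise ValueError("frac_multiphasic must lie in [0, 1]")
        if self.coupling_m <= 0:
            raise ValueError("coupling_m must be positive")
        if any(p < 0 for p in self.pool):
            raise ValueError("pool parameters must be non-negative")

    @property
    def mean_amp(self) -> float:
        return self.kernel[0]

    @property
    def mean_charge(self) -> float:
        """Expected single-event charge magnitude in fC."""
        amp, _cv, _sk, tr, td = self.kernel
        k = make_epsc_kernel(-1.0, tr, td, 0.002)
        return amp * abs(np.trapezoid(k, dx=0.002))


def preset_high_sr(seed: int = 0, **overrides) -> GroundTruth:
    """High-SR synapse: fast depletion, short latency, shallow Ca2+ coupling."""
    kw = dict(
        sr_true=3.0,
        frac_multiphasic=0.3,
        coupling_m=0.8,
        pool=(14.0, 6.3, 450.0, 450.0),
        latency0=1.17,
        latency_jitter=0.15,
        seed=seed,
    )
    kw.update(overrides)
    return GroundTruth(**kw)


def preset_low_sr(seed: int = 0, **overrides) -> GroundTruth:
    """Low-SR synapse: slower depletion, longer and more variable latency."""
    kw = dict(
        sr_true=0.2,
        frac_multiphasic=0.6,
        coupling_m=1.4,
        pool=(14.0, 20.9, 450.0, 450.0),
        latency0=3.34,
        latency_jitter=0.8,
        seed=seed,
    )
    kw.update(overrides)
    return GroundTruth(**kw)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

@dataclass
class Protocol:
    """A voltage-command protocol: per-sweep epochs on a holding level.

    ``epochs[k]`` lists the depolarizing epochs of sweep ``k`` as
    (start ms, duration ms, level mV); outside epochs the command sits at
    ``holding``.
    """

    kind: str  # IV | FM | spont
    epochs: list  # list (per sweep) of lists of (start, dur, level)
    sweep_dur: float
    holding: float = HOLDING_V
    dt: float = 0.02
    repetitions: int = 1
    inter_sweep_ms: float = 1500.0

    def v_cmd(self, k: int) -> np.ndarray:
        n = int(round(self.sweep_dur / self.dt))
        v = np.full(n, self.holding)
        for start, dur, level in self.epochs[k]:
            i0 = int(round(start / self.dt))
            i1 = int(round((start + dur) / self.dt))
            v[i0:i1] = level
        return v

    @property
    def n_sweeps(self) -> int:
        return len(self.epochs)

    def epoch_table(self, k: int):
        return [(s, s + d, lv) for s, d, lv in self.epochs[k]]


def iv_protocol(
    v_start: float = -70.0,
    v_stop: float = 70.0,
    v_step: float = 5.0,
    step_dur: float = 10.0,
    pre_ms: float = 10.0,
    post_ms: float = 20.0,
    holding: float = HOLDING_V,
    dt: float = 0.02,
    inter_sweep_ms: float = 1500.0,
) -> Protocol:
    """Current-voltage protocol: 10 ms steps from -70 to +70 mV in 5 mV
    increments, 1.5 s between sweeps."""
    levels = np.arange(v_start, v_stop + v_step / 2, v_step)
    epochs = [[(pre_ms, step_dur, float(v))] for v in levels]
    return Protocol(
        kind="IV",
        epochs=epochs,
        sweep_dur=pre_ms + step_dur + post_ms,
        holding=holding,
        dt=dt,
        inter_sweep_ms=inter_sweep_ms,
    )


def fm_protocol(
    isis=(4.0, 16.0, 64.0, 256.0),
    masker_dur: float = 100.0,
    probe_dur: float = 15.0,
    level: float = -19.0,
    pre_ms: float = 50.0,
    post_ms: float = 400.0,
    holding: float = HOLDING_V,
    dt: float = 0.02,
    repetitions: int = 10,
    inter_sweep_ms: float = 20000.0,
) -> Protocol:
    """Forward-masking protocol: 100 ms masker and 15 ms probe to -19 mV,
    interstimulus intervals of 4/16/64/256 ms, 20 s masker-to-masker.

    One sweep per ISI; the protocol is run ``repetitions`` times.  A 400 ms
    window after the probe is retained to observe resumption of
    spontaneous release.
    """
    epochs = []
    dur = pre_ms + masker_dur + max(isis) + probe_dur + post_ms
    for isi in isis:
        probe_start = pre_ms + masker_dur + isi
        epochs.append(
            [(pre_ms, masker_dur, level), (probe_start, probe_dur, level)]
        )
    return Protocol(
        kind="FM",
        epochs=epochs,
        sweep_dur=dur,
        holding=holding,
        dt=dt,
        repetitions=repetitions,
        inter_sweep_ms=inter_sweep_ms,
    )


def spont_protocol(
    duration: float = 10000.0, holding: float = HOLDING_V, dt: float = 0.02
) -> Protocol:
    """Continuous unstimulated recording at the holding potential."""
    return Protocol(kind="spont", epochs=[[]], sweep_dur=duration, holding=holding, dt=dt)


def pn_protocol(
    protocol: Protocol, n: int = -4, base: float = -90.0
) -> Protocol:
    """Scaled-down replica of a protocol for P/n leak subtraction.

    Every epoch amplitude relative to holding is divided by ``n`` and
    delivered from a hyperpolarized ``base`` level (default -90 mV).  The
    inverted sign (default -4) and the hyperpolarized base keep the
    replicas outside the Ca2+-channel activation range — a -58 mV holding
    already carries a tonic Ca2+ current whose deactivation would be
    amplified n-fold in the subtraction.
    """
    epochs = [
        [
            (s, d, base + (lv - protocol.holding) / n)
            for s, d, lv in ep
        ]
        for ep in protocol.epochs
    ]
    return dataclasses.replace(protocol, epochs=epochs, holding=base)


# ---------------------------------------------------------------------------
# EPSC kernel
# ---------------------------------------------------------------------------

def make_epsc_kernel(
    amp: float, tau_rise: float, tau_decay: float, dt: float, n_tau: float = 8.0
) -> np.ndarray:
    """Biexponential EPSC waveform scaled to a given peak amplitude.

    ``k(t) = A (exp(-t/tau_d) - exp(-t/tau_r))`` with A chosen so the
    extremum equals ``amp`` (negative for an inward EPSC).  The analytic
    charge of the kernel is ``A (tau_d - tau_r)``.
    """
    if not 0 < tau_rise < tau_decay:
        raise ValueError("need 0 < tau_rise < tau_decay")
    t_peak = (
        tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    )
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    t = np.arange(0.0, n_tau * tau_decay, dt)
    return amp / peak * (np.exp(-t / tau_decay) - np.exp(-t / tau_rise))


def _band_noise(
    rng: np.random.Generator, sd: float, n: int, dt: float, bw_khz: float = 5.0
) -> np.ndarray:
    """Band-limited Gaussian recording noise of exact standard deviation.

    Acquisition low-pass filters the current signal at 5-10 kHz, so the
    noise is correlated on the sample grid; white noise is filtered with a
    4th-order Butterworth at ``bw_khz`` and rescaled to ``sd``.
    """
    if sd == 0 or n == 0:
        return np.zeros(n)
    from scipy.signal import butter, sosfiltfilt

    white = rng.normal(0.0, 1.0, n)
    nyq_khz = 0.5 / dt  # dt in ms -> fs in kHz
    if bw_khz >= nyq_khz or n < 30:
        return sd * white
    sos = butter(4, bw_khz / nyq_khz, output="sos")
    x = sosfiltfilt(sos, white)
    return sd * x / x.std()


def _draw_amplitudes(rng: np.random.Generator, n: int, mean: float, cv: float):
    """Right-skewed (gamma) amplitude magnitudes; skewness = 2*CV."""
    if cv <= 0:
        return np.full(n, mean)
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean / shape, size=n)


def _add_kernel(trace: np.ndarray, kernel: np.ndarray, idx: int) -> None:
    if idx >= trace.size:
        return
    end = min(idx + kernel.size, trace.size)
    trace[max(idx, 0) : end] += kernel[max(-idx, 0) : end - idx]


def _render_events(
    trace: np.ndarray,
    times_ms: np.ndarray,
    amps: np.ndarray,
    truth: GroundTruth,
    dt: float,
    rng: np.random.Generator,
    multiphasic_mask: np.ndarray | None = None,
) -> list:
    """Place EPSC kernels at given onset times; returns (time, n_sub) records."""
    _amp, _cv, _sk, tr, td = truth.kernel
    records = []
    for t, a, multi in zip(
        times_ms,
        amps,
        multiphasic_mask if multiphasic_mask is not None else np.zeros(len(times_ms), bool),
    ):
        if multi:
            # sub-events are spread within 1.5 ms with a minimum separation
            # and balanced weights so the compound is discernibly multiphasic
            n_sub = int(rng.integers(2, 5))
            max_gap = 1.5 / (n_sub - 1)
            gaps = rng.uniform(0.5, max(max_gap, 0.501), n_sub - 1)
            offsets = np.concatenate([[0.0], np.cumsum(gaps)])
            weights = rng.dirichlet(np.full(n_sub, 5.0))
        else:
            n_sub, weights, offsets = 1, np.array([1.0]), np.array([0.0])
        for w, off in zip(weights, offsets):
            k = make_epsc_kernel(-a * w, tr, td, dt)
            _add_kernel(trace, k, int(round((t + off) / dt)))
        records.append((float(t), n_sub))
    return records


# ---------------------------------------------------------------------------
# spontaneous release
# ---------------------------------------------------------------------------

def simulate_spontaneous(
    truth: GroundTruth,
    duration: float,
    rng: np.random.Generator | None = None,
    dt: float = 0.02,
) -> tuple[Sweep, GroundTruth]:
    """Simulate an unstimulated sweep of spontaneous EPSCs.

    Event times are homogeneous Poisson at ``sr_true``; amplitudes follow
    the gamma law of the kernel tuple; a fraction ``frac_multiphasic`` of
    events is rendered as 2-4 sub-kernels with onsets jittered within
    1.5 ms.  Returns the sweep and a ground-truth copy whose
    ``event_times`` lists every placed event.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    n = int(round(duration / dt))
    n_ev = rng.poisson(truth.sr_true * duration / 1000.0)
    times = np.sort(rng.uniform(0, duration, n_ev))
    amps = _draw_amplitudes(rng, n_ev, truth.kernel[0], truth.kernel[1])
    multi = rng.uniform(size=n_ev) < truth.frac_multiphasic

    i_post = _band_noise(rng, truth.noise_sd_post, n, dt)
    records = _render_events(i_post, times, amps, truth, dt, rng, multi)
    i_pre = _band_noise(rng, truth.noise_sd_pre, n, dt)
    sweep = Sweep(
        t0=0.0,
        dt=dt,
        v_cmd=np.full(n, HOLDING_V),
        i_pre=i_pre,
        i_post=i_post,
        protocol_tag="spont",
        epoch_table=[],
    )
    out = dataclasses.replace(truth, event_times=records)
    return sweep, out


# ---------------------------------------------------------------------------
# Ca2+ current
# ---------------------------------------------------------------------------

def _activation_inf(v, v_half, slope):
    return 1.0 / (1.0 + np.exp((v_half - v) / slope))


def _activation_trace(v: np.ndarray, dt: float, v_half, slope, tau_act, a0=None):
    """First-order activation gating relaxing toward its steady state."""
    a_inf = _activation_inf(v, v_half, slope)
    a = np.empty_like(a_inf)
    decay = np.exp(-dt / tau_act)
    a[0] = a_inf[0] if a0 is None else a0
    # exponential Euler: exact for piecewise-constant commands
    for i in range(1, a.size):
        a[i] = a_inf[i] + (a[i - 1] - a_inf[i]) * decay
    return a


def simulate_ca_current(
    protocol: Protocol,
    truth: GroundTruth,
    tau_act: float = 0.3,
    rng: np.random.Generator | None = None,
) -> list[Sweep]:
    """Simulate presynaptic whole-cell Ca2+ currents for a protocol.

    ``i_pre(t) = g_max a(t) (V - v_rev) + leak_g (V - V_hold) + noise`` with
    first-order activation kinetics (``tau_act`` default 0.3 ms).
    """
    rng = np.random.default_rng(truth.seed + 1) if rng is None else rng
    g_max, v_half, slope, v_rev = truth.boltzmann_true
    sweeps = []
    for k in range(protocol.n_sweeps):
        v = protocol.v_cmd(k)
        a = _activation_trace(v, protocol.dt, v_half, slope, tau_act)
        i_ca = g_max * a * (v - v_rev)
        i_leak = truth.leak_g * (v - protocol.holding)
        i_pre = i_ca + i_leak + _band_noise(rng, truth.noise_sd_pre, v.size, protocol.dt)
        i_post = _band_noise(rng, truth.noise_sd_post, v.size, protocol.dt)
        sweeps.append(
            Sweep(
                t0=k * (protocol.sweep_dur + protocol.inter_sweep_ms),
                dt=protocol.dt,
                v_cmd=v,
                i_pre=i_pre,
                i_post=i_post,
                protocol_tag=protocol.kind,
                epoch_table=protocol.epoch_table(k),
            )
        )
    return sweeps


# ---------------------------------------------------------------------------
# evoked release
# ---------------------------------------------------------------------------

def _ca_drive(v, a, truth: GroundTruth):
    """Magnitude of the instantaneous Ca2+ current (pA), no leak."""
    g_max, _vh, _s, v_rev = truth.boltzmann_true
    return np.abs(g_max * a * np.minimum(v - v_rev, 0.0))


def _drive_rest(holding: float, truth: GroundTruth) -> float:
    """Tonic Ca2+ drive at the holding potential.

    The release coupling uses the drive increment above rest, so the pool
    occupancy has its fixed point at 1 without stimulation; the resting
    drive instead sustains the separate spontaneous-rate term.
    """
    g_max, v_half, slope, v_rev = truth.boltzmann_true
    return g_max * _activation_inf(holding, v_half, slope) * max(v_rev - holding, 0.0)


def _drive_reference(protocol: Protocol, truth: GroundTruth) -> float:
    """Steady-state Ca2+ drive at the strongest protocol level."""
    g_max, v_half, slope, v_rev = truth.boltzmann_true
    levels = {lv for ep in protocol.epochs for _s, _d, lv in ep}
    levels.add(protocol.holding)
    d = [
        g_max * _activation_inf(v, v_half, slope) * max(v_rev - v, 0.0)
        for v in levels
    ]
    return max(d) if d else 1.0


def _integrate_occupancy(
    occ0: float, k_dep: np.ndarray, tau_rec: float, dt: float, chunk: int = 2000
) -> tuple[np.ndarray, float]:
    """Integrate d occ/dt = -k_dep(t) occ + (1 - occ)/tau_rec exactly.

    The ODE is linear with piecewise-constant coefficients, so each sample
    advances in closed form: ``occ -> occ_eq + (occ - occ_eq) exp(-lam dt)``
    with ``lam = k_dep + 1/tau_rec``.  The recurrence is solved with prefix
    products in chunks to bound the dynamic range of the intermediates.

    Returns the occupancy at the start of every sample and the value after
    the final sample.
    """
    inv_rec = 1.0 / tau_rec if tau_rec > 0 else 0.0
    lam = k_dep + inv_rec
    n = lam.size
    out = np.empty(n)
    occ = float(occ0)
    for i0 in range(0, n, chunk):
        lam_c = lam[i0 : i0 + chunk]
        safe = np.where(lam_c > 0, lam_c, 1.0)
        occ_eq = np.where(lam_c > 0, inv_rec / safe, 1.0)
        a = np.exp(-lam_c * dt)
        b = occ_eq * (1.0 - a)
        prod = np.cumprod(a)
        ends = prod * (occ + np.cumsum(b / prod))
        out[i0 : i0 + chunk] = np.concatenate([[occ], ends[:-1]])
        occ = float(ends[-1])
    return out, occ


def simulate_evoked(
    protocol: Protocol,
    truth: GroundTruth,
    tau_act: float = 0.3,
    rng: np.random.Generator | None = None,
    include_ca: bool = True,
) -> tuple[list[Sweep], GroundTruth]:
    """Simulate evoked EPSCs from a depleting, replenishing vesicle pool.

    The instantaneous release probability follows the normalized Ca2+ drive
    raised to ``coupling_m``:  ``p(t) = (drive(t)/drive_ref)**m`` where the
    reference is the drive at the strongest step of the protocol.  Pool
    occupancy obeys

        d occ/dt = -occ p / tau_depletion + (1 - occ) / tau_recovery

    and the total release rate is
    ``r(t) = occ p n_rrp/tau_depletion + p sustained_rate + sr_true``
    (the sustained component is fed by replenishment and gates with the
    same Ca2+ drive; the last term is the stimulus-independent spontaneous
    rate).  Events are drawn as an inhomogeneous Poisson process: the rate
    is constant within each sample bin, so per-bin Poisson counts are exact
    for any expected count — high rates are never clipped.  Each event is
    rendered as an EPSC kernel after ``latency0`` plus exponential jitter.
    Occupancy carries over between sweeps through the inter-sweep interval.

    Repetitions: the protocol's sweep list is repeated ``repetitions``
    times; sweep order is (rep 0: all sweeps, rep 1: all sweeps, ...).
    """
    rng = np.random.default_rng(truth.seed + 2) if rng is None else rng
    g_max, v_half, slope, v_rev = truth.boltzmann_true
    n_rrp, tau_dep, sustained, tau_rec = truth.pool
    d_rest = _drive_rest(protocol.holding, truth)
    d_ref = _drive_reference(protocol, truth) - d_rest
    if d_ref <= 0:
        raise ValueError("protocol never depolarizes above the holding drive")
    dt = protocol.dt
    amp_mean, amp_cv, _sk, tr, td = truth.kernel

    sweeps: list[Sweep] = []
    records: list[tuple[float, int]] = []
    occ = 1.0
    sweep_counter = 0
    for rep in range(protocol.repetitions):
        for k in range(protocol.n_sweeps):
            v = protocol.v_cmd(k)
            a = _activation_trace(v, dt, v_half, slope, tau_act)
            p = (
                np.maximum(_ca_drive(v, a, truth) - d_rest, 0.0) / d_ref
            ) ** truth.coupling_m
            # per-ms rates
            k_dep = p / tau_dep if tau_dep > 0 else np.zeros_like(p)
            r_extra = p * sustained / 1000.0 + truth.sr_true / 1000.0

            n = v.size
            i_post = _band_noise(rng, truth.noise_sd_post, n, dt)
            occ_trace, occ = _integrate_occupancy(occ, k_dep, tau_rec, dt)
            # events / ms at each sample (rate constant within a sample bin,
            # so Poisson counts are exact — no clipping however large)
            rate = occ_trace * n_rrp * k_dep + r_extra
            counts = rng.poisson(rate * dt)
            hot = np.flatnonzero(counts)
            ev_times = np.sort(
                np.concatenate(
                    [ (i + rng.uniform(size=c)) * dt for i, c in zip(hot, counts[hot]) ]
                )
                if hot.size
                else np.empty(0)
            )
            lat = truth.latency0 + rng.exponential(
                truth.latency_jitter, ev_times.size
            )
            onsets = ev_times + lat
            amps = _draw_amplitudes(rng, ev_times.size, amp_mean, amp_cv)
            t0 = sweep_counter * (protocol.sweep_dur + protocol.inter_sweep_ms)
            recs = _render_events(i_post, onsets, amps, truth, dt, rng)
            records.extend((t0 + t, ns) for t, ns in recs)

            if include_ca:
                i_pre = (
                    g_max * a * (v - v_rev)
                    + truth.leak_g * (v - protocol.holding)
                    + _band_noise(rng, truth.noise_sd_pre, n, dt)
                )
            else:
                i_pre = _band_noise(rng, truth.noise_sd_pre, n, dt)
            sweeps.append(
                Sweep(
                    t0=t0,
                    dt=dt,
                    v_cmd=v,
                    i_pre=i_pre,
                    i_post=i_post,
                    protocol_tag=protocol.kind,
                    epoch_table=protocol.epoch_table(k),
                )
            )
            # recovery during the inter-sweep interval
            if tau_rec > 0:
                occ = 1.0 - (1.0 - occ) * np.exp(-protocol.inter_sweep_ms / tau_rec)
            sweep_counter += 1
    out = dataclasses.replace(truth, event_times=records)
    return sweeps, out


# ---------------------------------------------------------------------------
# whole-pair convenience
# ---------------------------------------------------------------------------

def simulate_pair(
    truth: GroundTruth,
    pair_id: str = "sim",
    position: str = "unknown",
    spont_duration: float = 10000.0,
    iv: Protocol | None = None,
    fm: Protocol | None = None,
) -> tuple[PairRecord, GroundTruth]:
    """Simulate a complete paired recording: spontaneous, IV and FM blocks.

    The IV block includes evoked EPSCs on the postsynaptic channel and the
    Boltzmann + leak Ca2+ current (plus a P/4 leak-replica set tagged
    ``"IV_pn"``) on the presynaptic channel.
    """
    rng = np.random.default_rng(truth.seed)
    iv = iv or iv_protocol(dt=0.02)
    fm = fm or fm_protocol(dt=0.02, repetitions=5)

    spont_sweep, truth_sp = simulate_spontaneous(truth, spont_duration, rng=rng)
    iv_sweeps, truth_iv = simulate_evoked(iv, truth, rng=rng)
    pn_sweeps = simulate_ca_current(pn_protocol(iv, -4), truth, rng=rng)
    for s in pn_sweeps:
        s.protocol_tag = "IV_pn"
    fm_sweeps, truth_fm = simulate_evoked(fm, truth, rng=rng)

    pair = PairRecord(pair_id=pair_id, position=position)
    pair.sweeps = [spont_sweep] + iv_sweeps + pn_sweeps + fm_sweeps
    events = list(truth_sp.event_times)
    events += truth_iv.event_times
    events += truth_fm.event_times
    out = dataclasses.replace(truth, event_times=events)
    return pair, out
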