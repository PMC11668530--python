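"""Forward-masking analysis: pool depletion, eEPSC latency and recovery.

A 100 ms *masker* depolarization depletes the readily releasable pool
(RRP); a 15 ms *probe* after a variable interstimulus interval (ISI)
reports its recovery.  Pool dynamics are quantified by fitting

    Q(x) = y0 + A1 (1 - exp(-(x - x0)/tau)) + (x - x0) slope

to the first 50 ms of the trial-averaged cumulative EPSC charge after
masker onset.  Quantal conversion uses the mean spontaneous EPSC charge of
the same pair: RRP (in vesicles) = A1 / <Q_sEPSC>, sustained rate =
slope / <Q_sEPSC>, initial rate = (A1/tau + slope) / <Q_sEPSC>.

Recovery is the ratio Q_probe/Q_masker over the first 10 ms of each
stimulus, fitted with a single exponential over ISIs from 16 ms to the
20 s masker-to-masker interval (the 4 ms point is excluded: about half of
the synapses show a non-monotonic dip there).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit

from .recording import Sweep, integrate_charge

__all__ = [
    "DepletionFit",
    "RecoveryCurve",
    "AveragedResponse",
    "group_by_isi",
    "average_masker_response",
    "latency_stats",
    "fit_depletion",
    "recovery_curve",
    "fit_recovery",
]

MASKER_TO_MASKER_MS = 20000.0


@dataclass
class DepletionFit:
    """Exponential-plus-line fit of cumulative release and quantal rates.

    Identities (held exactly by construction): ``rrp_sv = a1 / q_sepsc``,
    ``sustained_rate = slope / q_sepsc`` (converted to vesicles/s),
    ``initial_rate = (a1/tau + slope) / q_sepsc``,
    ``depression_ratio = initial_rate / sustained_rate`` (NaN when the
    sustained rate is zero).
    """

    y0: float = np.nan  # fC
    a1: float = np.nan  # fC, exponential amplitude
    x0: float = np.nan  # ms, fit onset offset
    tau: float = np.nan  # ms, depletion time constant
    line_slope: float = np.nan  # fC/ms
    q_sepsc: float = np.nan  # fC, mean sEPSC charge used for conversion
    rmse: float = np.nan
    fit_ok: bool = False

    @property
    def rrp_sv(self) -> float:
        return self.a1 / self.q_sepsc

    @property
    def sustained_rate(self) -> float:
        """Sustained release rate in vesicles/s."""
        return self.line_slope / self.q_sepsc * 1000.0

    @property
    def initial_rate(self) -> float:
        """Initial release rate in vesicles/s (slope of the fit at x0)."""
        return (self.a1 / self.tau + self.line_slope) / self.q_sepsc * 1000.0

    @property
    def depression_ratio(self) -> float:
        s = self.sustained_rate
        # a vanishing sustained rate makes the ratio infinite; report NaN
        if not np.isfinite(s) or s <= 1e-9 * max(abs(self.initial_rate), 1.0):
            return np.nan
        return self.initial_rate / s


@dataclass
class RecoveryCurve:
    """Probe/masker charge ratios per ISI plus recovery kinetics."""

    isi_ms: list = field(default_factory=list)
    ratio: list = field(default_factory=list)
    tau_recovery: float = np.nan
    time_to_first_sepsc: float = np.nan
    ok: bool = True


@dataclass
class AveragedResponse:
    """Trial-averaged cumulative EPSC charge aligned to masker onset."""

    t: np.ndarray  # ms from masker onset
    q_cum: np.ndarray  # fC, positive magnitude of cumulative charge
    n_reps: int
    isi_ms: float
    masker_onset: float  # ms within the sweep
    masker_dur: float
    probe_onset: float
    probe_dur: float
    low_reps: bool = False  # fewer than 3 repetitions


def _fm_epochs(sweep: Sweep) -> tuple[tuple, tuple]:
    if len(sweep.epoch_table) < 2:
        raise ValueError("forward-masking sweep needs masker and probe epochs")
    masker, probe = sweep.epoch_table[0], sweep.epoch_table[1]
    return masker, probe


def group_by_isi(sweeps: list[Sweep]) -> dict[float, list[Sweep]]:
    """Group FM sweeps (repetitions) by their masker-probe interval."""
    groups: dict[float, list[Sweep]] = {}
    for s in sweeps:
        (m0, m1, _lv), (p0, _p1, _lv2) = _fm_epochs(s)
        isi = round(p0 - m1, 6)
        groups.setdefault(isi, []).append(s)
    return dict(sorted(groups.items()))


def average_masker_response(sweeps: list[Sweep]) -> AveragedResponse:
    """Average aligned repetitions and integrate to cumulative charge.

    The per-sample mean of the baseline-subtracted postsynaptic current is
    integrated (trapezoidal running integral) from masker onset; the
    magnitude is returned so depletion appears as a rising charge trace.
    Fewer than 3 repetitions flags ``low_reps`` but analysis proceeds.
    """
    if not sweeps:
        raise ValueError("no sweeps to average")
    (m0, m1, _lv), (p0, p1, _lv2) = _fm_epochs(sweeps[0])
    dt = sweeps[0].dt
    n = min(s.n_samples for s in sweeps)
    traces = []
    for s in sweeps:
        i0 = s.sample_at(m0)
        base = float(np.mean(s.i_post[: max(i0, 1)]))
        traces.append(s.i_post[:n] - base)
    mean_trace = np.mean(traces, axis=0)
    i_on = sweeps[0].sample_at(m0)
    seg = mean_trace[i_on:]
    q_cum = -cumulative_trapezoid(seg, dx=dt, initial=0.0)  # inward -> positive
    t = np.arange(seg.size) * dt
    low = len(sweeps) < 3
    if low:
        warnings.warn(
            f"only {len(sweeps)} repetitions (< 3); averaging proceeds",
            stacklevel=2,
        )
    return AveragedResponse(
        t=t,
        q_cum=q_cum,
        n_reps=len(sweeps),
        isi_ms=round(p0 - m1, 6),
        masker_onset=m0,
        masker_dur=m1 - m0,
        probe_onset=p0,
        probe_dur=p1 - p0,
        low_reps=low,
    )


def _first_event_onset(
    x: np.ndarray,
    dt: float,
    start_ms: float,
    end_ms: float,
    sd: float,
    thr_sd: float = 4.0,
    peak_sd: float | None = None,
) -> float:
    """Onset time (ms) of the first EPSC-like excursion in a window.

    The onset is the last crossing of the ``thr_sd``xSD threshold before
    the first qualifying negative peak.  ``peak_sd`` (default = thr_sd)
    raises the peak requirement; long search windows use 5xSD so that
    single-sample noise dips do not masquerade as events.  NaN when the
    window holds no qualifying excursion.
    """
    from scipy.signal import find_peaks

    thr = thr_sd * sd
    peak_req = (peak_sd if peak_sd is not None else thr_sd) * sd
    i0, i1 = int(round(start_ms / dt)), int(round(end_ms / dt))
    i1 = min(i1, x.size)
    seg = x[i0:i1]
    peaks, _ = find_peaks(-seg, height=peak_req)
    if peaks.size == 0:
        return np.nan
    p = int(peaks[0])
    before = np.flatnonzero(seg[: p + 1] > -thr)
    onset = int(before[-1]) if before.size else 0
    return (i0 + onset) * dt


def latency_stats(
    sweeps: list[Sweep], threshold_sd: float = 4.0
) -> tuple[float, float, int]:
    """Mean synaptic latency and jitter of the masker-evoked EPSC.

    Per repetition the latency is the time from masker onset to the first
    crossing of the 4xSD(baseline) detection threshold.  Returns
    (mean latency ms, SD of latencies ms, number of repetitions without a
    detectable eEPSC — excluded from the statistics).
    """
    if len(sweeps) < 3:
        raise ValueError("need >= 3 repetitions for latency statistics")
    lats = []
    missing = 0
    for s in sweeps:
        (m0, m1, _lv), _probe = _fm_epochs(s)
        i_on = s.sample_at(m0)
        base = float(np.mean(s.i_post[: max(i_on, 1)]))
        sd = float(np.std(s.i_post[: max(i_on, 1)]))
        lat_t = _first_event_onset(
            s.i_post - base, s.dt, m0, m1, sd, thr_sd=threshold_sd
        )
        if np.isfinite(lat_t):
            lats.append(lat_t - m0)
        else:
            missing += 1
    if not lats:
        return (np.nan, np.nan, missing)
    lats = np.asarray(lats)
    return (float(lats.mean()), float(lats.std(ddof=1)) if lats.size > 1 else 0.0, missing)


def _dep_model(x, y0, a1, x0, tau, slope):
    z = np.maximum(x - x0, 0.0)
    return y0 + a1 * (1.0 - np.exp(-z / tau)) + z * slope


def fit_depletion(
    response: AveragedResponse | tuple[np.ndarray, np.ndarray],
    mean_sepsc_charge: float,
    fit_window_ms: float = 50.0,
    x0_max_ms: float = 5.0,
) -> DepletionFit:
    """Fit the exponential-plus-line depletion model to cumulative charge.

    The fit covers the first ``fit_window_ms`` (50 ms) after masker onset;
    ``x0`` is constrained to [0, 5] ms so the line term cannot absorb the
    exponential.  Quantal quantities are derived with the pair's mean
    sEPSC charge (must be positive).
    """
    if mean_sepsc_charge <= 0 or not np.isfinite(mean_sepsc_charge):
        raise ValueError("mean sEPSC charge must be positive")
    if isinstance(response, AveragedResponse):
        t, q = response.t, response.q_cum
    else:
        t, q = np.asarray(response[0], float), np.asarray(response[1], float)
    if t[-1] < fit_window_ms:
        raise ValueError(
            f"trace covers only {t[-1]:.1f} ms, need {fit_window_ms} ms"
        )
    mask = t <= fit_window_ms
    tt, qq = t[mask], q[mask]

    span = float(qq.max() - qq.min())
    if span <= 0:
        return DepletionFit(q_sepsc=mean_sepsc_charge, fit_ok=False)
    slope0 = max((qq[-1] - qq[qq.size // 2]) / (tt[-1] - tt[tt.size // 2]), 0.0)
    a1_0 = max(span - slope0 * tt[-1], 0.1 * span)
    best, best_cost = None, np.inf
    for tau0 in (3.0, 6.0, 15.0, 30.0):
        try:
            popt, _ = curve_fit(
                _dep_model,
                tt,
                qq,
                p0=[qq[0], a1_0, min(1.0, x0_max_ms / 2), tau0, slope0],
                bounds=(
                    [-np.inf, 0.0, 0.0, 0.05, 0.0],
                    [np.inf, np.inf, x0_max_ms, 500.0, np.inf],
                ),
                maxfev=30000,
            )
        except (RuntimeError, ValueError):
            continue
        cost = float(np.sum((qq - _dep_model(tt, *popt)) ** 2))
        if cost < best_cost:
            best, best_cost = popt, cost
    if best is None:
        return DepletionFit(q_sepsc=mean_sepsc_charge, fit_ok=False)
    y0, a1, x0, tau, slope = (float(p) for p in best)
    return DepletionFit(
        y0=y0,
        a1=a1,
        x0=x0,
        tau=tau,
        line_slope=slope,
        q_sepsc=mean_sepsc_charge,
        rmse=float(np.sqrt(best_cost / tt.size)),
        fit_ok=True,
    )


def recovery_curve(
    sweeps: list[Sweep],
    charge_window_ms: float = 10.0,
    post_probe_window_ms: float = 400.0,
    post_probe_start_ms: float = 10.0,
    threshold_sd: float = 4.0,
) -> RecoveryCurve:
    """Probe/masker charge ratios across ISIs plus post-probe silence.

    For each ISI the trial-averaged postsynaptic charge of the first
    ``charge_window_ms`` (10 ms) of masker and probe is compared; the
    masker-to-masker interval (20 s) is appended with ratio 1 by
    definition.  ``time_to_first_sepsc`` is the mean delay from probe
    offset to the first threshold crossing within the 400 ms post-probe
    window (NaN when no repetition shows one).
    """
    groups = group_by_isi(sweeps)
    if not groups:
        raise ValueError("no forward-masking sweeps")
    curve = RecoveryCurve()
    first_delays = []
    for isi, reps in groups.items():
        dt = reps[0].dt
        (m0, m1, _lv), (p0, p1, _lv2) = _fm_epochs(reps[0])
        n = min(s.n_samples for s in reps)
        traces = []
        for s in reps:
            i_on = s.sample_at(m0)
            base = float(np.mean(s.i_post[: max(i_on, 1)]))
            traces.append(s.i_post[:n] - base)
        mean_trace = np.mean(traces, axis=0)
        q_m = abs(
            integrate_charge(mean_trace, dt, (m0, m0 + charge_window_ms))
        )
        q_p = abs(
            integrate_charge(mean_trace, dt, (p0, p0 + charge_window_ms))
        )
        if q_m == 0:
            curve.ok = False
            ratio = np.nan
        else:
            ratio = q_p / q_m
        curve.isi_ms.append(float(isi))
        curve.ratio.append(float(ratio))

        for s in reps:
            i_on = s.sample_at(m0)
            sd = float(np.std(s.i_post[: max(i_on, 1)]))
            base = float(np.mean(s.i_post[: max(i_on, 1)]))
            end = min(p1 + post_probe_window_ms, s.duration - s.dt)
            # search starts 10 ms after probe offset so delayed probe-evoked
            # EPSCs (synaptic latency of several ms) are not counted as
            # resumed spontaneous release; 5xSD peak requirement because a
            # 400 ms noise window would otherwise yield order-one spurious
            # single-sample crossings
            t_first = _first_event_onset(
                s.i_post - base, s.dt, p1 + post_probe_start_ms, end, sd,
                thr_sd=threshold_sd, peak_sd=threshold_sd + 1.0,
            )
            if np.isfinite(t_first):
                first_delays.append(t_first - p1)
    curve.isi_ms.append(MASKER_TO_MASKER_MS)
    curve.ratio.append(1.0)
    if first_delays:
        curve.time_to_first_sepsc = float(np.mean(first_delays))
    return curve


def fit_recovery(
    curve: RecoveryCurve, min_isi_ms: float = 16.0
) -> float:
    """Single-exponential recovery time constant from the ratio curve.

    Fits ``R(t) = 1 - (1 - R0) exp(-t/tau)`` to the ratios at ISIs from
    ``min_isi_ms`` (16 ms, excluding the non-monotonic 4 ms point) to the
    20 s masker-to-masker interval, with full recovery (R_inf = 1) imposed
    by the masker-to-masker definition.  Stores and returns ``tau``;
    NaN (with ``curve.ok = False``) for degenerate or non-depressed data.
    """
    t = np.asarray(curve.isi_ms, dtype=float)
    r = np.asarray(curve.ratio, dtype=float)
    mask = (t >= min_isi_ms) & np.isfinite(r)
    t, r = t[mask], r[mask]
    if t.size < 3:
        curve.ok = False
        return np.nan
    if np.allclose(r, 1.0, atol=1e-9):
        curve.ok = False  # no depression to recover from
        return np.nan

    def model(tt, r0, tau):
        return 1.0 - (1.0 - r0) * np.exp(-tt / tau)

    best, best_cost = None, np.inf
    for tau0 in (100.0, 450.0, 2000.0):
        try:
            popt, _ = curve_fit(
                model,
                t,
                r,
                p0=[max(min(r[0], 0.95), 0.0), tau0],
                bounds=([0.0, 1.0], [1.0, 1e5]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        cost = float(np.sum((r - model(t, *popt)) ** 2))
        if cost < best_cost:
            best, best_cost = popt, cost
    if best is None or best[1] <= 0:
        curve.ok = False
        return np.nan
    curve.tau_recovery = float(best[1])
    return curve.tau_recovery
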