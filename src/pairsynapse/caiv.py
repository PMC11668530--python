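"""Ca2+ current analysis: P/n leak subtraction, IV curve, reversal
potential and Boltzmann activation fit.

Fractional activation of the Ca2+ channels is obtained from the normalized
chord conductance g = I/(V - V_rev).  The activation curve is approximated
by a first-order Boltzmann equation

    g(V) = g_max / (1 + exp((V_half - V)/S))

with g_max the maximum chord conductance, V_half the potential of
half-activation and S the slope factor (voltage sensitivity).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .recording import Sweep, integrate_charge

__all__ = [
    "IvPoint",
    "BoltzmannFit",
    "leak_subtract",
    "iv_curve",
    "reversal_potential",
    "fit_boltzmann",
]


@dataclass
class IvPoint:
    """One IV-protocol step: mean current and charge during the step."""

    v: float  # step potential, mV
    i_ca: float  # mean Ca2+ current over the averaging window, pA
    q_ca: float  # integral over the same window, fC


@dataclass
class BoltzmannFit:
    """Fitted Boltzmann activation parameters."""

    g_max: float  # nS
    v_half: float  # mV
    slope: float  # mV
    v_rev: float  # mV
    threshold_v: float = np.nan  # potential of 5% fractional activation
    rmse: float = np.nan
    ok: bool = True

    def activation(self, v) -> np.ndarray:
        """Fractional activation at potential(s) v."""
        return 1.0 / (1.0 + np.exp((self.v_half - np.asarray(v, float)) / self.slope))

    def conductance(self, v) -> np.ndarray:
        return self.g_max * self.activation(v)


def leak_subtract(main: Sweep, pn_sweeps: list[Sweep], n: int) -> Sweep:
    """P/n leak subtraction of the presynaptic current.

    ``pn_sweeps`` carry scaled-down (1/n amplitude) replicas of the main
    command; the averaged replica current times n is subtracted
    sample-by-sample, cancelling any linear (ohmic + capacitive)
    component.  ``n`` is signed: a negative value marks inverted
    (hyperpolarizing) replicas, for which ``main - n*avg`` adds back
    ``|n|`` times the mirrored leak.
    """
    if not pn_sweeps:
        raise ValueError("need at least one P/n sweep")
    for s in pn_sweeps:
        if s.n_samples != main.n_samples:
            raise ValueError("P/n sweep length does not match the main sweep")
    pn_mean = np.mean([s.i_pre for s in pn_sweeps], axis=0)
    corrected = main.i_pre - n * pn_mean
    return dataclasses.replace(main, i_pre=corrected)


def iv_curve(
    sweeps: list[Sweep], avg_window_ms: float = 10.0
) -> list[IvPoint]:
    """Build the IV curve from leak-subtracted IV sweeps.

    For each sweep the evoked Ca2+ current is averaged during
    ``avg_window_ms`` (default 10 ms) after the start of the depolarizing
    epoch; the charge is the integral over the same window.  The baseline
    (pre-step mean) is subtracted.  Points are returned sorted by voltage.
    """
    points = []
    for s in sweeps:
        if not s.epoch_table:
            raise ValueError("IV sweep without stimulation epoch")
        start, end, level = s.epoch_table[0]
        if end - start < avg_window_ms:
            raise ValueError(
                f"step of {end - start} ms shorter than the "
                f"{avg_window_ms} ms averaging window"
            )
        i0 = s.sample_at(start)
        i1 = s.sample_at(start + avg_window_ms)
        base = float(np.mean(s.i_pre[: max(i0, 1)]))
        seg = s.i_pre[i0:i1] - base
        i_ca = float(np.mean(seg))
        q_ca = integrate_charge(
            s.i_pre, s.dt, (start, start + avg_window_ms), baseline=base
        )
        points.append(IvPoint(v=float(level), i_ca=i_ca, q_ca=q_ca))
    points.sort(key=lambda p: p.v)
    return points


def reversal_potential(iv: list[IvPoint]) -> tuple[float, bool]:
    """Reversal potential from the outward limb of the IV curve.

    A line is fitted through the points between (voltage of peak inward
    current + 10 mV) and the maximal depolarization; V_rev is its zero
    crossing.  Returns ``(v_rev, extrapolated)`` where the flag marks a
    crossing outside the fitted voltage range.
    """
    if len(iv) < 3:
        raise ValueError("need at least 3 IV points")
    v = np.array([p.v for p in iv])
    i = np.array([p.i_ca for p in iv])
    v_peak = v[int(np.argmin(i))]
    mask = v >= v_peak + 10.0
    if mask.sum() < 3:
        raise ValueError(
            "fewer than 3 points above I_peak + 10 mV; widen the IV protocol"
        )
    slope, intercept = np.polyfit(v[mask], i[mask], 1)
    if slope == 0:
        raise ValueError("flat outward limb: reversal potential undefined")
    v_rev = -intercept / slope
    extrapolated = not (v[mask].min() <= v_rev <= v[mask].max())
    return float(v_rev), extrapolated


def _boltzmann(v, g_max, v_half, slope):
    return g_max / (1.0 + np.exp((v_half - v) / slope))


def fit_boltzmann(
    iv: list[IvPoint],
    v_rev: float,
    exclude_near_rev_mv: float = 5.0,
    threshold_activation: float = 0.05,
) -> BoltzmannFit:
    """Fit the Boltzmann activation curve to chord conductances.

    Chord conductance g = I/(V - V_rev) is computed for every IV point at
    least ``exclude_near_rev_mv`` away from V_rev (division blow-up guard);
    a first-order Boltzmann is fitted by least squares with multi-start
    initialization (V_half from the half-maximum crossing, S from the
    25-75% span).  ``threshold_v`` reports the potential of 5% fractional
    activation, the package's operational "threshold of Ca2+ influx".
    """
    v = np.array([p.v for p in iv])
    i = np.array([p.i_ca for p in iv])
    mask = np.abs(v - v_rev) > exclude_near_rev_mv
    if mask.sum() < 4:
        return BoltzmannFit(np.nan, np.nan, np.nan, v_rev, ok=False)
    vv = v[mask]
    g = i[mask] / (vv - v_rev)  # pA/mV = nS
    g = np.maximum(g, 0.0)

    g_max0 = float(np.percentile(g, 95))
    if g_max0 <= 0:
        return BoltzmannFit(np.nan, np.nan, np.nan, v_rev, ok=False)
    half = np.flatnonzero(g >= 0.5 * g_max0)
    v_half0 = float(vv[half[0]]) if half.size else float(np.median(vv))
    q25 = np.flatnonzero(g >= 0.25 * g_max0)
    q75 = np.flatnonzero(g >= 0.75 * g_max0)
    slope0 = (
        max((vv[q75[0]] - vv[q25[0]]) / 2.2, 1.0) if q25.size and q75.size else 7.0
    )

    best, best_cost = None, np.inf
    for vh0, s0 in [
        (v_half0, slope0),
        (v_half0 - 10, slope0),
        (v_half0 + 10, slope0),
        (v_half0, 2 * slope0),
    ]:
        try:
            popt, _ = curve_fit(
                _boltzmann,
                vv,
                g,
                p0=[g_max0, vh0, s0],
                bounds=([0, -120, 0.1], [np.inf, 80, 60]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        cost = float(np.sum((g - _boltzmann(vv, *popt)) ** 2))
        if cost < best_cost:
            best, best_cost = popt, cost
    if best is None:
        return BoltzmannFit(np.nan, np.nan, np.nan, v_rev, ok=False)
    g_max, v_half, slope = best
    rmse = float(np.sqrt(best_cost / vv.size))
    # activation = threshold_activation at V_half - S ln(1/act - 1)
    thr_v = v_half - slope * np.log(1.0 / threshold_activation - 1.0)
    return BoltzmannFit(
        g_max=float(g_max),
        v_half=float(v_half),
        slope=float(slope),
        v_rev=float(v_rev),
        threshold_v=float(thr_v),
        rmse=rmse,
        ok=True,
    )
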