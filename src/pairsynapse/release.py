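"""Release-intensity curves and apparent Ca2+ cooperativity.

The release-intensity curve (EPSC charge vs step potential) is fitted with
a sigmoid

    Q(V) = Q_max / (1 + exp((Q50 - V)/rate))

whose closed-form identities give the 10% and 90% release voltages
(Q10 = Q50 - rate ln 9, Q90 = Q50 + rate ln 9) and the dynamic range
Q90 - Q10 = rate ln 81.

The apparent Ca2+ cooperativity m is the exponent of the power law
Q_EPSC = a (Q_Ca)^m fitted on the raw scale (zeros in Q_EPSC at
subthreshold steps are legal there, unlike in log-log space).  Pairs with
release saturation are truncated at the plateau before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .recording import Sweep, integrate_charge

LN9 = float(np.log(9.0))
LN81 = float(np.log(81.0))

__all__ = [
    "SigmoidFit",
    "PowerLawFit",
    "release_intensity",
    "fit_release_sigmoid",
    "fit_cooperativity",
    "pooled_cooperativity",
    "LN9",
    "LN81",
]


@dataclass
class SigmoidFit:
    """Sigmoidal release-intensity fit (charges normalized to the max).

    The reported Q10/Q90/dynamic range are exact identities of the fitted
    model: ``q10 = q50 - slope ln 9``, ``q90 = q50 + slope ln 9``,
    ``dynamic_range = slope ln 81``.
    """

    q_max: float = 1.0
    q50: float = np.nan  # voltage of half-maximal release, mV
    slope: float = np.nan  # "rate" slope factor, mV
    rmse: float = np.nan
    r2: float = np.nan
    fit_ok: bool = False

    @property
    def q10(self) -> float:
        return self.q50 - self.slope * LN9

    @property
    def q90(self) -> float:
        return self.q50 + self.slope * LN9

    @property
    def dynamic_range(self) -> float:
        return self.q90 - self.q10

    def predict(self, v) -> np.ndarray:
        return self.q_max / (1.0 + np.exp((self.q50 - np.asarray(v, float)) / self.slope))


@dataclass
class PowerLawFit:
    """Power-law fit Q_EPSC = a (Q_Ca)^m; m is the Ca2+ cooperativity."""

    a: float = np.nan
    m: float = np.nan
    n_used: int = 0
    truncated: bool = False
    rmse: float = np.nan
    fit_ok: bool = False


def release_intensity(
    sweeps: list[Sweep], tail_ms: float = 2.0
) -> list[tuple[float, float]]:
    """EPSC charge per voltage step of an IV protocol.

    ``q_epsc`` is the magnitude of the integral of the baseline-subtracted
    postsynaptic current from step onset to step end plus a short tail
    (default 2 ms) capturing release triggered at the end of the step.

    Returns (v, q_epsc_fC) tuples sorted by voltage.
    """
    if not sweeps:
        raise ValueError("no sweeps given")
    out = []
    for s in sweeps:
        if not s.epoch_table:
            raise ValueError("sweep without stimulation epoch")
        start, end, level = s.epoch_table[0]
        end = min(end + tail_ms, s.duration - s.dt)
        i0 = s.sample_at(start)
        base = float(np.mean(s.i_post[: max(i0, 1)]))
        q = integrate_charge(s.i_post, s.dt, (start, end), baseline=base)
        out.append((float(level), abs(q)))
    out.sort(key=lambda p: p[0])
    return out


def _sigmoid(v, q_max, q50, slope):
    return q_max / (1.0 + np.exp((q50 - v) / slope))


def fit_release_sigmoid(
    points: list[tuple[float, float]], r2_min: float = 0.5
) -> SigmoidFit:
    """Fit the release-intensity sigmoid to (voltage, charge) points.

    Charges are normalized to their maximum before fitting.  ``fit_ok`` is
    False (the pair is excluded from group statistics) when the fit does
    not converge or explains less than ``r2_min`` of the variance — the
    automated surrogate for by-eye exclusion of ill-behaved curves.
    """
    if len(points) < 5:
        raise ValueError("need at least 5 points for the sigmoid fit")
    pts = sorted(points)
    v = np.array([p[0] for p in pts], dtype=float)
    q = np.array([p[1] for p in pts], dtype=float)
    q_peak = q.max()
    if q_peak <= 0:
        return SigmoidFit(fit_ok=False)
    # the saturating sigmoid describes the rising limb only: past the
    # voltage of maximal release the Ca2+ driving force (and with it the
    # EPSC charge) declines again toward the reversal potential
    k_max = int(np.argmax(q))
    if k_max + 1 >= 5:
        v, q = v[: k_max + 1], q[: k_max + 1]
    qn = q / q_peak

    half = np.flatnonzero(qn >= 0.5)
    q50_0 = float(v[half[0]]) if half.size else float(np.median(v))
    best, best_cost = None, np.inf
    for q50_init, s0 in [(q50_0, 4.0), (q50_0 - 10, 4.0), (q50_0, 8.0), (q50_0 + 10, 2.0)]:
        try:
            popt, _ = curve_fit(
                _sigmoid,
                v,
                qn,
                p0=[1.0, q50_init, s0],
                bounds=([0.2, -120, 0.2], [2.0, 60, 40]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        cost = float(np.sum((qn - _sigmoid(v, *popt)) ** 2))
        if cost < best_cost:
            best, best_cost = popt, cost
    if best is None:
        return SigmoidFit(fit_ok=False)
    q_max, q50, slope = best
    ss_tot = float(np.sum((qn - qn.mean()) ** 2))
    r2 = 1.0 - best_cost / ss_tot if ss_tot > 0 else 0.0
    return SigmoidFit(
        q_max=float(q_max),
        q50=float(q50),
        slope=float(slope),
        rmse=float(np.sqrt(best_cost / v.size)),
        r2=float(r2),
        fit_ok=bool(r2 >= r2_min),
    )


def _truncate_plateau(
    q_ca: np.ndarray, q_epsc: np.ndarray, plateau_frac: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Drop trailing points after release first reaches the plateau.

    Points are ordered by Q_Ca; once Q_EPSC first exceeds
    ``plateau_frac`` of its maximum, later points are discarded (the
    automated surrogate for by-eye plateau determination).
    """
    order = np.argsort(q_ca)
    q_ca, q_epsc = q_ca[order], q_epsc[order]
    cut = np.flatnonzero(q_epsc >= plateau_frac * q_epsc.max())
    if cut.size == 0 or cut[0] == q_ca.size - 1:
        return q_ca, q_epsc, False
    k = cut[0]
    return q_ca[: k + 1], q_epsc[: k + 1], True


def _power(q, a, m):
    return a * np.power(q, m)


def fit_cooperativity(
    q_ca,
    q_epsc,
    plateau_frac: float = 0.95,
    truncate: bool = True,
) -> PowerLawFit:
    """Fit the power law Q_EPSC = a (Q_Ca)^m for one pair.

    Fitting is unweighted least squares on the raw scale (not log-log, so
    zero EPSC charges at subthreshold steps are permitted).  With
    ``truncate`` (default) trailing points beyond the release plateau are
    dropped first.  Requires >= 4 usable points.
    """
    q_ca = np.abs(np.asarray(q_ca, dtype=float))
    q_epsc = np.abs(np.asarray(q_epsc, dtype=float))
    if q_ca.size != q_epsc.size:
        raise ValueError("q_ca and q_epsc must have equal length")
    keep = q_ca > 0
    q_ca, q_epsc = q_ca[keep], q_epsc[keep]
    truncated = False
    if truncate and q_epsc.size and q_epsc.max() > 0:
        q_ca, q_epsc, truncated = _truncate_plateau(q_ca, q_epsc, plateau_frac)
    if q_ca.size < 4:
        return PowerLawFit(n_used=int(q_ca.size), truncated=truncated, fit_ok=False)

    # initial guess from the log-log slope of the strictly positive points
    pos = q_epsc > 0
    if pos.sum() >= 2:
        m0, loga0 = np.polyfit(np.log(q_ca[pos]), np.log(q_epsc[pos]), 1)
        m0 = float(np.clip(m0, 0.1, 8.0))
        a0 = float(np.exp(loga0))
    else:
        m0, a0 = 1.0, 1.0
    try:
        popt, _ = curve_fit(
            _power,
            q_ca,
            q_epsc,
            p0=[a0, m0],
            bounds=([0, 0.05], [np.inf, 10.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return PowerLawFit(n_used=int(q_ca.size), truncated=truncated, fit_ok=False)
    resid = q_epsc - _power(q_ca, *popt)
    return PowerLawFit(
        a=float(popt[0]),
        m=float(popt[1]),
        n_used=int(q_ca.size),
        truncated=truncated,
        rmse=float(np.sqrt(np.mean(resid**2))),
        fit_ok=True,
    )


def pooled_cooperativity(
    pairs: list[tuple[np.ndarray, np.ndarray, str]],
    plateau_frac: float = 0.95,
) -> dict[str, PowerLawFit]:
    """Pooled power-law fits per SR class.

    ``pairs`` lists (q_ca, q_epsc, sr_class) per recording.  Within each
    pair, Q_EPSC is normalized by its maximum and Q_Ca by its value at the
    plateau-truncation point (or its maximum when no plateau is found);
    normalized points are pooled within each SR class and a single power
    law is fitted per class.  Empty classes are skipped.
    """
    pooled: dict[str, list[np.ndarray]] = {}
    for q_ca, q_epsc, sr_class in pairs:
        q_ca = np.abs(np.asarray(q_ca, dtype=float))
        q_epsc = np.abs(np.asarray(q_epsc, dtype=float))
        keep = q_ca > 0
        q_ca, q_epsc = q_ca[keep], q_epsc[keep]
        if q_ca.size == 0 or q_epsc.max() <= 0:
            continue
        qc_t, qe_t, _trunc = _truncate_plateau(q_ca, q_epsc, plateau_frac)
        qn_ca = qc_t / qc_t.max()
        qn_epsc = qe_t / qe_t.max()
        pooled.setdefault(sr_class, []).append(np.column_stack([qn_ca, qn_epsc]))

    out: dict[str, PowerLawFit] = {}
    for sr_class, blocks in pooled.items():
        if len(blocks) < 2:
            continue
        data = np.concatenate(blocks)
        out[sr_class] = fit_cooperativity(
            data[:, 0], data[:, 1], truncate=False
        )
    return out
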