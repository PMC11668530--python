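"""Spontaneous-release statistics: rate, SR class and sEPSC distributions.

A synapse is classified by its spontaneous rate (SR) of sEPSCs measured in
unstimulated windows: *low* SR below 1 event/s, *high* SR at or above
1 event/s.  Amplitude and charge distributions are summarized by their
mean, CV (SD/mean) and adjusted Fisher-Pearson sample skewness, computed on
magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .detect import EpscEvent

__all__ = ["SpontSummary", "spontaneous_rate", "summarize_events", "SR_CUTOFF"]

SR_CUTOFF = 1.0  # events/s; >= cutoff classifies a synapse as high SR


@dataclass
class SpontSummary:
    """Summary of spontaneous activity for one paired recording."""

    sr: float = np.nan
    sr_class: str = "unset"  # low | high
    n_events: int = 0
    analyzed_time: float = np.nan  # s
    mean_amp: float = np.nan  # pA, negative
    mean_charge: float = np.nan  # fC, magnitude
    skew_amp: float = np.nan
    cv_amp: float = np.nan
    skew_charge: float = np.nan
    cv_charge: float = np.nan
    frac_monophasic: float = np.nan
    mean_rise: float = np.nan
    mean_tau_decay: float = np.nan
    mean_fwhm: float = np.nan
    windows: list = field(default_factory=list)


def spontaneous_rate(
    events: list[EpscEvent],
    windows: list[tuple[float, float]],
    summary: SpontSummary | None = None,
) -> SpontSummary:
    """Spontaneous rate and SR class from events inside unstimulated windows.

    Parameters
    ----------
    events : list of EpscEvent
        Detected events; only those whose onset falls inside a window count.
    windows : list of (start_ms, end_ms)
        Unstimulated segments; total duration must be positive.

    Returns
    -------
    SpontSummary with ``sr`` (events/s), ``sr_class`` and bookkeeping
    fields filled.  The class boundary is exactly 1 event/s, with >= 1
    classified as high.
    """
    total_ms = sum(e - s for s, e in windows)
    if total_ms <= 0:
        raise ValueError("total window duration must be positive")
    inside = [
        ev for ev in events if any(s <= ev.onset < e for s, e in windows)
    ]
    out = summary or SpontSummary()
    out.n_events = len(inside)
    out.analyzed_time = total_ms / 1000.0
    out.sr = out.n_events / out.analyzed_time
    out.sr_class = "high" if out.sr >= SR_CUTOFF else "low"
    out.windows = list(windows)
    return out


def _sample_skewness(x: np.ndarray) -> float:
    """Adjusted Fisher-Pearson skewness (the bias-corrected g1)."""
    if x.size < 3:
        return np.nan
    if np.ptp(x) < 1e-12 * max(abs(float(np.mean(x))), 1.0):
        return 0.0  # constant sample: symmetric by convention
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(sstats.skew(x, bias=False))


def summarize_events(
    events: list[EpscEvent], summary: SpontSummary | None = None
) -> SpontSummary:
    """Distribution summary of sEPSC amplitudes, charges and kinetics.

    CV and skewness are computed on magnitudes; ``mean_amp`` keeps the
    negative sign convention.  With fewer than 3 events the skewness is NaN
    and a warning is issued.
    """
    if not events:
        raise ValueError("need at least one event to summarize")
    out = summary or SpontSummary()
    amps = np.array([ev.amplitude for ev in events], dtype=float)
    mags = np.abs(amps)
    charges = np.array([ev.charge for ev in events], dtype=float)
    charges = charges[np.isfinite(charges)]

    out.mean_amp = float(amps.mean())
    out.cv_amp = float(mags.std() / mags.mean()) if mags.mean() else np.nan
    if len(events) < 3:
        warnings.warn("fewer than 3 events: skewness undefined", stacklevel=2)
        out.skew_amp = np.nan
        out.skew_charge = np.nan
    else:
        out.skew_amp = _sample_skewness(mags)
        out.skew_charge = _sample_skewness(charges) if charges.size >= 3 else np.nan
    if charges.size:
        out.mean_charge = float(charges.mean())
        out.cv_charge = (
            float(charges.std() / charges.mean()) if charges.mean() else np.nan
        )

    classified = [ev for ev in events if ev.phasic_class != "unclassified"]
    if classified:
        out.frac_monophasic = sum(
            ev.phasic_class == "monophasic" for ev in classified
        ) / len(classified)

    for attr, name in [
        ("rise_10_90", "mean_rise"),
        ("tau_decay", "mean_tau_decay"),
        ("fwhm", "mean_fwhm"),
    ]:
        vals = np.array([getattr(ev, attr) for ev in events], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            setattr(out, name, float(vals.mean()))
    if not events:
        return out
    out.n_events = out.n_events or len(events)
    return out


def unstimulated_windows(
    sweep, margin_ms: float = 50.0
) -> list[tuple[float, float]]:
    """Windows of a sweep outside stimulation epochs (epoch_table masking).

    A ``margin_ms`` guard after each epoch excludes evoked tails from the
    spontaneous count.
    """
    edges = sorted((s, e) for s, e, _lv in sweep.epoch_table)
    windows = []
    cursor = 0.0
    for s, e in edges:
        if s > cursor:
            windows.append((cursor, s))
        cursor = max(cursor, e + margin_ms)
    if cursor < sweep.duration:
        windows.append((cursor, sweep.duration))
    return windows
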