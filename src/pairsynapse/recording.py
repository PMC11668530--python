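"""Data model for paired IHC/bouton voltage-clamp recordings.

Units are fixed package-wide: potentials in mV, currents in pA, time in ms,
charge in fC (1 pA * 1 ms = 1 fC), resistances in MOhm, capacitances in pF,
conductances in nS.  Inward currents are negative; EPSC amplitudes are
therefore negative while summary tables report charge magnitudes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.optimize import curve_fit

CONTAINER_VERSION = 1

__all__ = [
    "Sweep",
    "QcResult",
    "PairRecord",
    "CorruptContainerError",
    "ContainerVersionError",
    "save_pair",
    "load_pair",
    "integrate_charge",
    "estimate_access",
    "qc_pair",
]


class CorruptContainerError(IOError):
    """A required dataset or group is missing from a pair container."""


class ContainerVersionError(IOError):
    """The container was written by an incompatible format version."""


@dataclass
class Sweep:
    """One synchronized triple of command voltage and pre/postsynaptic current.

    Parameters
    ----------
    t0 : float
        Start time of the sweep (ms).
    dt : float
        Sampling interval (ms); 20-50 kHz acquisition corresponds to
        0.02-0.05 ms.
    v_cmd, i_pre, i_post : ndarray
        Command potential (mV), presynaptic current (pA) and postsynaptic
        current (pA), all of equal length.
    protocol_tag : str
        Protocol label, e.g. ``"IV"``, ``"FM"``, ``"spont"``, ``"testpulse"``.
    epoch_table : list of (start_ms, end_ms, level_mV)
        Piecewise-constant description of the command waveform.
    """

    t0: float
    dt: float
    v_cmd: np.ndarray
    i_pre: np.ndarray
    i_post: np.ndarray
    protocol_tag: str = ""
    epoch_table: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.v_cmd = np.asarray(self.v_cmd, dtype=float)
        self.i_pre = np.asarray(self.i_pre, dtype=float)
        self.i_post = np.asarray(self.i_post, dtype=float)
        n = self.v_cmd.size
        if n < 2 or self.i_pre.size != n or self.i_post.size != n:
            raise ValueError("v_cmd, i_pre and i_post must share length >= 2")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_samples(self) -> int:
        return self.v_cmd.size

    @property
    def duration(self) -> float:
        """Sweep duration in ms."""
        return self.n_samples * self.dt

    def time(self) -> np.ndarray:
        """Sample times in ms (relative to t0)."""
        return np.arange(self.n_samples) * self.dt

    def sample_at(self, t_ms: float) -> int:
        """Index of the sample at time ``t_ms`` (relative to t0)."""
        return int(round(t_ms / self.dt))


@dataclass
class QcResult:
    """Quality-control summary for one paired recording.

    ``passed`` is False when either leak current is more negative than the
    exclusion limits (-60 pA for the IHC, -100 pA for the bouton) or when an
    access estimate is undefined.
    """

    leak_pre: float = np.nan
    leak_post: float = np.nan
    rs_pre: float = np.nan
    rs_post: float = np.nan
    cm_post: float = np.nan
    rm_post: float = np.nan
    passed: bool = False
    reasons: list[str] = field(default_factory=list)


@dataclass
class PairRecord:
    """All sweeps plus metadata of one paired IHC-bouton recording.

    Reported potentials are already corrected for the liquid junction
    potential; the correction constants (19 mV IHC, 4 mV bouton) are stored
    for provenance and never re-applied.
    """

    pair_id: str
    sweeps: list[Sweep] = field(default_factory=list)
    position: str = "unknown"  # pillar | modiolar | unknown
    holding_v_pre: float = -58.0
    holding_v_post: float = -94.0
    ljp_pre: float = 19.0
    ljp_post: float = 4.0
    qc: QcResult | None = None
    sr_class: str = "unset"  # low | high | unset

    def sweeps_by_tag(self, tag: str) -> list[Sweep]:
        return [s for s in self.sweeps if s.protocol_tag == tag]


def integrate_charge(
    samples: np.ndarray,
    dt: float,
    window: tuple[float, float],
    baseline: float = 0.0,
) -> float:
    """Trapezoidal integral of a baseline-subtracted current over a window.

    Parameters
    ----------
    samples : ndarray
        Current trace in pA.
    dt : float
        Sampling interval in ms.
    window : (start_ms, end_ms)
        Integration window relative to the first sample.
    baseline : float
        Baseline current (pA) subtracted before integration.

    Returns
    -------
    float
        Charge in fC (pA*ms).  The sign of the current is preserved, so an
        inward (negative) current yields a negative charge.
    """
    samples = np.asarray(samples, dtype=float)
    if not np.isfinite(baseline):
        raise ValueError("baseline must be finite")
    start, end = window
    if start > end:
        raise ValueError("window start must not exceed end")
    i0 = int(round(start / dt))
    i1 = int(round(end / dt))
    if i0 < 0 or i1 >= samples.size:
        raise IndexError(
            f"window [{start}, {end}] ms outside trace of "
            f"{samples.size * dt:.3f} ms"
        )
    if i1 == i0:
        return 0.0
    return float(np.trapezoid(samples[i0 : i1 + 1] - baseline, dx=dt))


def _double_exp(t, a_f, tau_f, a_s, tau_s, i_ss):
    return a_f * np.exp(-t / tau_f) + a_s * np.exp(-t / tau_s) + i_ss


def estimate_access(
    testpulse: Sweep, step_mv: float = 10.0
) -> tuple[float, float, float]:
    """Estimate access resistance, capacitance and membrane resistance.

    The decay of the capacitive transient in response to a small voltage
    step is fitted with a double exponential
    ``I(t) = A_f exp(-t/tau_f) + A_s exp(-t/tau_s) + I_ss`` (t = 0 at step
    onset).  Then

    * ``rs = step / I(0+)`` with ``I(0+) = A_f + A_s + I_ss``,
    * ``cm`` from the charge under the fast component, corrected for the
      attenuation by the Rs-Rm divider so that an ideal single-RC cell is
      recovered exactly,
    * ``rm = step / I_ss - rs``.

    Returns ``(rs_MOhm, cm_pF, rm_MOhm)``; all NaN when no transient can be
    fitted (the caller should record a QC reason).
    """
    # the test pulse may live on either channel; use the one that moves
    if np.ptp(testpulse.i_post) >= np.ptp(testpulse.i_pre):
        i = np.asarray(testpulse.i_post, dtype=float)
    else:
        i = np.asarray(testpulse.i_pre, dtype=float)
    v = testpulse.v_cmd
    dt = testpulse.dt

    dv = np.flatnonzero(np.abs(np.diff(v)) > 1e-9)
    if dv.size == 0:
        return (np.nan, np.nan, np.nan)
    onset = dv[0] + 1
    step_end = dv[1] + 1 if dv.size > 1 else i.size
    base = float(np.mean(i[: max(onset - 1, 1)]))
    seg = i[onset:step_end] - base
    if seg.size < 8 or np.ptp(seg) < 1e-12:
        return (np.nan, np.nan, np.nan)

    sign = 1.0 if abs(seg.max()) >= abs(seg.min()) else -1.0
    y = sign * seg
    k_peak = int(np.argmax(y))
    t = (np.arange(seg.size) - 0.0) * dt  # t=0 at step onset
    tf, yf = t[k_peak:], y[k_peak:]
    i_ss0 = float(np.mean(yf[-max(3, yf.size // 10) :]))
    a0 = max(yf[0] - i_ss0, 1e-9)
    tau0 = max(dt, _decay_guess(tf, yf, i_ss0))

    params = None
    try:
        p, _ = curve_fit(
            _double_exp,
            tf,
            yf,
            p0=[0.9 * a0, tau0, 0.1 * a0, 5 * tau0, i_ss0],
            bounds=([0, dt / 10, 0, dt / 10, -np.inf], [np.inf] * 4 + [np.inf]),
            maxfev=20000,
        )
        if p[1] > p[3]:  # enforce tau_f < tau_s by swapping
            p = [p[2], p[3], p[0], p[1], p[4]]
        params = p
    except (RuntimeError, ValueError):
        # fall back to single exponential (A_s = 0)
        try:
            p1, _ = curve_fit(
                lambda tt, a, tau, iss: a * np.exp(-tt / tau) + iss,
                tf,
                yf,
                p0=[a0, tau0, i_ss0],
                bounds=([0, dt / 10, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            params = [p1[0], p1[1], 0.0, p1[1], p1[2]]
        except (RuntimeError, ValueError):
            return (np.nan, np.nan, np.nan)

    a_f, tau_f, a_s, tau_s, i_ss = params
    i0 = a_f + a_s + i_ss
    if i0 <= 0 or i_ss <= 0:
        return (np.nan, np.nan, np.nan)
    step = abs(step_mv)
    rs = step / i0 * 1000.0  # mV/pA = GOhm -> MOhm
    rm = step / i_ss * 1000.0 - rs
    cm = (a_f * tau_f + a_s * tau_s) / step  # fC/mV = pF
    # divider correction: the transient charge is attenuated by (Rm/(Rs+Rm))^2
    if rm > 0:
        cm *= ((rs + rm) / rm) ** 2
    return (float(rs), float(cm), float(rm))


def _decay_guess(t: np.ndarray, y: np.ndarray, y_ss: float) -> float:
    """Crude time constant from the 1/e crossing of a decaying trace."""
    target = y_ss + (y[0] - y_ss) / np.e
    below = np.flatnonzero(y <= target)
    if below.size == 0:
        return (t[-1] - t[0]) / 3 if t.size > 1 else 1.0
    return max(t[below[0]] - t[0], t[1] - t[0] if t.size > 1 else 1e-3)


def qc_pair(
    pair: PairRecord,
    leak_pre: float,
    leak_post: float,
    access: tuple[float, float, float] | None = None,
    leak_limit_pre: float = -60.0,
    leak_limit_post: float = -100.0,
) -> QcResult:
    """Apply the leak-current exclusion rule and record access estimates.

    A pair fails QC when the IHC leak is more negative than -60 pA, the
    bouton leak more negative than -100 pA, or an access estimate is NaN.
    """
    reasons: list[str] = []
    if leak_pre < leak_limit_pre:
        reasons.append(f"IHC leak {leak_pre:.1f} pA exceeds {leak_limit_pre} pA")
    if leak_post < leak_limit_post:
        reasons.append(f"bouton leak {leak_post:.1f} pA exceeds {leak_limit_post} pA")
    rs, cm, rm = access if access is not None else (np.nan, np.nan, np.nan)
    if access is not None and not (
        np.isfinite(rs) and np.isfinite(cm) and np.isfinite(rm)
    ):
        reasons.append("access estimate undefined")
    qc = QcResult(
        leak_pre=leak_pre,
        leak_post=leak_post,
        rs_post=rs,
        cm_post=cm,
        rm_post=rm,
        passed=not reasons,
        reasons=reasons,
    )
    pair.qc = qc
    return qc


# ---------------------------------------------------------------------------
# container round-trip
# ---------------------------------------------------------------------------

def save_pair(pair: PairRecord, path, truth=None) -> None:
    """Write a PairRecord to an HDF5 container.

    Layout: ``/meta`` attributes carry identity and holding metadata;
    ``/sweeps/<k>`` holds ``v_cmd``, ``i_pre``, ``i_post`` datasets with
    ``t0``, ``dt``, ``protocol_tag`` and ``epoch_table`` attributes.  An
    optional simulator ground truth is stored under ``/truth``.
    """
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["version"] = CONTAINER_VERSION
        meta.attrs["pair_id"] = pair.pair_id
        meta.attrs["position"] = pair.position
        meta.attrs["holding_v_pre"] = pair.holding_v_pre
        meta.attrs["holding_v_post"] = pair.holding_v_post
        meta.attrs["ljp_pre"] = pair.ljp_pre
        meta.attrs["ljp_post"] = pair.ljp_post
        meta.attrs["sr_class"] = pair.sr_class
        if pair.qc is not None:
            qg = f.create_group("qc")
            for k in ("leak_pre", "leak_post", "rs_pre", "rs_post", "cm_post", "rm_post"):
                qg.attrs[k] = getattr(pair.qc, k)
            qg.attrs["passed"] = pair.qc.passed
            qg.attrs["reasons"] = "\n".join(pair.qc.reasons)
        sg = f.create_group("sweeps")
        for k, sw in enumerate(pair.sweeps):
            g = sg.create_group(str(k))
            g.create_dataset("v_cmd", data=sw.v_cmd)
            g.create_dataset("i_pre", data=sw.i_pre)
            g.create_dataset("i_post", data=sw.i_post)
            g.attrs["t0"] = sw.t0
            g.attrs["dt"] = sw.dt
            g.attrs["protocol_tag"] = sw.protocol_tag
            g.attrs["epoch_table"] = np.asarray(sw.epoch_table, dtype=float).reshape(
                -1, 3
            )
        if truth is not None:
            tg = f.create_group("truth")
            for k, v in dataclasses.asdict(truth).items():
                if v is None:
                    continue
                if k == "event_times":
                    tg.create_dataset(
                        "event_times", data=np.asarray(v, dtype=float).reshape(-1, 2)
                    )
                elif isinstance(v, (tuple, list)):
                    tg.attrs[k] = np.asarray(v, dtype=float)
                else:
                    tg.attrs[k] = v


def load_pair(path, with_truth: bool = False):
    """Read a PairRecord (and optionally its ground truth) back from HDF5.

    Raises
    ------
    CorruptContainerError
        When a required group or dataset is missing (the message names it).
    ContainerVersionError
        When the container version differs from the supported one.
    """
    from .synth import GroundTruth  # local import to avoid a cycle

    with h5py.File(path, "r") as f:
        if "meta" not in f:
            raise CorruptContainerError(f"{path}: missing /meta group")
        meta = f["meta"]
        version = int(meta.attrs.get("version", -1))
        if version != CONTAINER_VERSION:
            raise ContainerVersionError(
                f"{path}: container version {version}, expected {CONTAINER_VERSION}"
            )
        if "sweeps" not in f:
            raise CorruptContainerError(f"{path}: missing /sweeps group")
        pair = PairRecord(
            pair_id=str(meta.attrs["pair_id"]),
            position=str(meta.attrs["position"]),
            holding_v_pre=float(meta.attrs["holding_v_pre"]),
            holding_v_post=float(meta.attrs["holding_v_post"]),
            ljp_pre=float(meta.attrs["ljp_pre"]),
            ljp_post=float(meta.attrs["ljp_post"]),
            sr_class=str(meta.attrs["sr_class"]),
        )
        for k in sorted(f["sweeps"], key=int):
            g = f["sweeps"][k]
            for ds in ("v_cmd", "i_pre", "i_post"):
                if ds not in g:
                    raise CorruptContainerError(
                        f"{path}: missing /sweeps/{k}/{ds} dataset"
                    )
            pair.sweeps.append(
                Sweep(
                    t0=float(g.attrs["t0"]),
                    dt=float(g.attrs["dt"]),
                    v_cmd=g["v_cmd"][...],
                    i_pre=g["i_pre"][...],
                    i_post=g["i_post"][...],
                    protocol_tag=str(g.attrs["protocol_tag"]),
                    epoch_table=[tuple(row) for row in g.attrs["epoch_table"]],
                )
            )
        if "qc" in f:
            qg = f["qc"]
            pair.qc = QcResult(
                leak_pre=float(qg.attrs["leak_pre"]),
                leak_post=float(qg.attrs["leak_post"]),
                rs_pre=float(qg.attrs["rs_pre"]),
                rs_post=float(qg.attrs["rs_post"]),
                cm_post=float(qg.attrs["cm_post"]),
                rm_post=float(qg.attrs["rm_post"]),
                passed=bool(qg.attrs["passed"]),
                reasons=[r for r in str(qg.attrs["reasons"]).split("\n") if r],
            )
        truth = None
        if with_truth and "truth" in f:
            tg = f["truth"]
            kwargs = {}
            for k in tg.attrs:
                v = tg.attrs[k]
                if isinstance(v, np.ndarray):
                    kwargs[k] = tuple(float(x) for x in v)
                elif isinstance(v, (np.floating, float)):
                    kwargs[k] = float(v)
                elif isinstance(v, (np.integer, int)):
                    kwargs[k] = int(v)
                else:
                    kwargs[k] = v
            if "event_times" in tg:
                kwargs["event_times"] = [tuple(r) for r in tg["event_times"][...]]
            truth = GroundTruth(**kwargs)
    if with_truth:
        return pair, truth
    return pair
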