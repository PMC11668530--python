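"""Whole-cohort orchestration: per-pair analysis, cohort table, group stats.

``analyze_pair`` runs the full per-recording chain — sEPSC detection,
spontaneous-rate classification, Ca2+ IV and Boltzmann activation,
release-intensity and cooperativity fits, and forward-masking pool
dynamics — and returns a flat dict of scalar results.  ``run_pipeline``
maps it over a cohort (loaded from containers or simulated on the fly),
writes a cohort CSV, per-pair JSON and a log, and compares every variable
between low- and high-SR synapses with the gated statistical rule.
Per-pair failures are logged and skipped, never abort the cohort.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .caiv import fit_boltzmann, iv_curve, leak_subtract, reversal_potential
from .detect import DetectionConfig, detect_events
from .masking import (
    average_masker_response,
    fit_depletion,
    fit_recovery,
    latency_stats,
    recovery_curve,
)
from .recording import PairRecord, load_pair
from .release import fit_cooperativity, fit_release_sigmoid, release_intensity
from .spont import spontaneous_rate, summarize_events, unstimulated_windows
from .stats import compare_groups
from .synth import preset_high_sr, preset_low_sr, simulate_pair

__all__ = ["analyze_pair", "run_pipeline", "COHORT_VARIABLES"]

logger = logging.getLogger("pairsynapse")

COHORT_VARIABLES = [
    "sr",
    "mean_amp",
    "mean_charge",
    "frac_monophasic",
    "mean_rise",
    "v_half_ica",
    "ca_threshold_v",
    "q50_epsc",
    "q10_epsc",
    "dynamic_range",
    "cooperativity_m",
    "latency_mean",
    "latency_jitter",
    "rrp_sv",
    "tau_depletion",
    "initial_rate",
    "sustained_rate",
    "depression_ratio",
    "tau_recovery",
    "time_to_first_sepsc",
]


def analyze_pair(
    pair: PairRecord,
    detection: DetectionConfig | None = None,
    pn_factor: int = -4,
) -> dict:
    """Run the complete single-pair analysis chain.

    Expects sweeps tagged ``"spont"``, ``"IV"``, ``"IV_pn"`` and ``"FM"``.
    Stages whose inputs are absent are skipped (their fields stay NaN).
    Returns a dict of scalar results plus the fitted objects under
    ``"_fits"``.
    """
    cfg = detection or DetectionConfig()
    res: dict = {"pair_id": pair.pair_id, "position": pair.position}
    fits: dict = {}
    res["_fits"] = fits

    # --- spontaneous activity -------------------------------------------
    spont_sweeps = pair.sweeps_by_tag("spont")
    if spont_sweeps:
        events = []
        windows = []
        offset = 0.0
        for s in spont_sweeps:
            evs = detect_events(s, (0.0, min(s.duration, 500.0)), cfg)
            for ev in evs:
                ev.onset += offset
                ev.peak_time += offset
            events.extend(evs)
            windows.extend(
                [(w0 + offset, w1 + offset) for w0, w1 in unstimulated_windows(s)]
            )
            offset += s.duration
        summary = spontaneous_rate(events, windows)
        if events:
            summarize_events(events, summary)
        pair.sr_class = summary.sr_class
        fits["spont"] = summary
        res.update(
            sr=summary.sr,
            sr_class=summary.sr_class,
            n_sepsc=summary.n_events,
            mean_amp=summary.mean_amp,
            mean_charge=summary.mean_charge,
            frac_monophasic=summary.frac_monophasic,
            mean_rise=summary.mean_rise,
            skew_amp=summary.skew_amp,
            cv_amp=summary.cv_amp,
        )

    # --- Ca2+ IV and activation -----------------------------------------
    iv_sweeps = pair.sweeps_by_tag("IV")
    pn_sweeps = pair.sweeps_by_tag("IV_pn")
    iv_points = None
    if iv_sweeps:
        if pn_sweeps and len(pn_sweeps) == len(iv_sweeps):
            corrected = [
                leak_subtract(s, [pn], pn_factor)
                for s, pn in zip(iv_sweeps, pn_sweeps)
            ]
        else:
            corrected = iv_sweeps
        iv_points = iv_curve(corrected)
        v_rev, extrap = reversal_potential(iv_points)
        bfit = fit_boltzmann(iv_points, v_rev)
        fits["boltzmann"] = bfit
        res.update(
            v_rev=v_rev,
            v_rev_extrapolated=extrap,
            g_max=bfit.g_max,
            v_half_ica=bfit.v_half,
            ca_slope=bfit.slope,
            ca_threshold_v=bfit.threshold_v,
            peak_i_ca=min(p.i_ca for p in iv_points),
        )

    # --- release intensity and cooperativity ----------------------------
    if iv_sweeps:
        ri = release_intensity(iv_sweeps)
        sfit = fit_release_sigmoid(ri)
        fits["sigmoid"] = sfit
        if sfit.fit_ok:
            res.update(
                q50_epsc=sfit.q50,
                q10_epsc=sfit.q10,
                q90_epsc=sfit.q90,
                dynamic_range=sfit.dynamic_range,
            )
        if iv_points is not None:
            # inward Ca2+ charge only: above the reversal potential the
            # integral turns outward and carries no release drive
            v_to_q = {p.v: abs(p.q_ca) for p in iv_points if p.q_ca < 0}
            qq = [(v_to_q[v], q) for v, q in ri if v in v_to_q]
            pfit = fit_cooperativity(
                [x for x, _ in qq], [y for _, y in qq]
            )
            fits["cooperativity"] = pfit
            if pfit.fit_ok:
                res["cooperativity_m"] = pfit.m
            res["_qca_qepsc"] = (
                np.array([x for x, _ in qq]),
                np.array([y for _, y in qq]),
            )

    # --- forward masking -------------------------------------------------
    fm_sweeps = pair.sweeps_by_tag("FM")
    if fm_sweeps:
        lat_mean, lat_sd, n_missing = latency_stats(fm_sweeps)
        res.update(
            latency_mean=lat_mean, latency_jitter=lat_sd, reps_no_eepsc=n_missing
        )
        avg = average_masker_response(fm_sweeps)
        q_sepsc = res.get("mean_charge", np.nan)
        if np.isfinite(q_sepsc) and q_sepsc > 0:
            dfit = fit_depletion(avg, q_sepsc)
            fits["depletion"] = dfit
            if dfit.fit_ok:
                res.update(
                    rrp_sv=dfit.rrp_sv,
                    tau_depletion=dfit.tau,
                    initial_rate=dfit.initial_rate,
                    sustained_rate=dfit.sustained_rate,
                    depression_ratio=dfit.depression_ratio,
                )
        curve = recovery_curve(fm_sweeps)
        tau_rec = fit_recovery(curve)
        fits["recovery"] = curve
        res.update(
            tau_recovery=tau_rec,
            time_to_first_sepsc=curve.time_to_first_sepsc,
        )
    return res


def _simulated_cohort(sim_cfg: dict, seed: int) -> list[tuple[PairRecord, object]]:
    """Build a simulated cohort of high- and low-SR pairs."""
    n_high = int(sim_cfg.get("n_high", 10))
    n_low = int(sim_cfg.get("n_low", 21))
    spont_s = float(sim_cfg.get("spont_duration_ms", 10000.0))
    pairs = []
    for k in range(n_high):
        truth = preset_high_sr(seed=seed + k)
        pairs.append(
            simulate_pair(
                truth, pair_id=f"high_{k:02d}", position="pillar",
                spont_duration=spont_s,
            )
        )
    for k in range(n_low):
        truth = preset_low_sr(seed=seed + 1000 + k)
        pairs.append(
            simulate_pair(
                truth, pair_id=f"low_{k:02d}", position="modiolar",
                spont_duration=spont_s,
            )
        )
    return pairs


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the cohort pipeline from a configuration dict or JSON file.

    Config keys: ``pairs`` (list of container paths) and/or ``simulate``
    (``{"n_high", "n_low", "seed", "spont_duration_ms"}``), ``out_dir``,
    ``detection`` (threshold multiplier etc.).  Returns a report dict with
    the cohort DataFrame (``"cohort"``), per-pair results
    (``"per_pair"``) and high-vs-low-SR group comparisons
    (``"comparisons"``).  When an output directory is given, writes
    ``cohort.csv``, ``comparisons.csv``, ``per_pair.json`` and ``run.log``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = json.load(fh)
    out_dir = Path(out_dir or config.get("out_dir", ".")) if (
        out_dir or config.get("out_dir")
    ) else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    det_cfg = DetectionConfig(
        threshold_sd=float(config.get("detection", {}).get("threshold_sd", 4.0))
    )
    seed = int(config.get("seed", 0))

    inputs: list[tuple[PairRecord, object]] = []
    for path in config.get("pairs", []):
        inputs.append((load_pair(path), None))
    if "simulate" in config:
        inputs.extend(_simulated_cohort(config["simulate"], seed))

    log_lines = [
        f"pairsynapse {__version__}",
        f"seed={seed} threshold_sd={det_cfg.threshold_sd} "
        f"sr_cutoff=1.0 n_pairs={len(inputs)}",
    ]
    rows, per_pair = [], {}
    for pair, _truth in inputs:
        try:
            res = analyze_pair(pair, detection=det_cfg)
        except Exception as exc:  # per-pair failures never abort the cohort
            logger.warning("pair %s failed: %s", pair.pair_id, exc)
            log_lines.append(f"FAILED {pair.pair_id}: {exc}")
            continue
        per_pair[pair.pair_id] = {
            k: v for k, v in res.items() if not k.startswith("_")
        }
        rows.append(per_pair[pair.pair_id])
        log_lines.append(f"OK {pair.pair_id} sr_class={res.get('sr_class')}")

    cohort = pd.DataFrame(rows)
    comparisons = []
    if not cohort.empty and "sr_class" in cohort:
        hi = cohort[cohort.sr_class == "high"]
        lo = cohort[cohort.sr_class == "low"]
        for var in COHORT_VARIABLES:
            if var not in cohort:
                continue
            a = hi[var].dropna().to_numpy()
            b = lo[var].dropna().to_numpy()
            if a.size < 3 or b.size < 3:
                continue
            gc = compare_groups(a, b, variable=var)
            comparisons.append(
                dict(
                    variable=var,
                    n_high=a.size,
                    n_low=b.size,
                    test=gc.test_used,
                    p_value=gc.p_value,
                    mean_high=gc.mean_a,
                    sem_high=gc.sem_a,
                    mean_low=gc.mean_b,
                    sem_low=gc.sem_b,
                    median_high=gc.median_a,
                    median_low=gc.median_b,
                )
            )
    comp_df = pd.DataFrame(comparisons)

    if not inputs:
        logger.warning("empty cohort: nothing to analyze")
        log_lines.append("WARNING empty cohort")
    if out_dir:
        cohort.to_csv(out_dir / "cohort.csv", index=False)
        comp_df.to_csv(out_dir / "comparisons.csv", index=False)
        with open(out_dir / "per_pair.json", "w") as fh:
            json.dump(per_pair, fh, indent=1, default=_json_default)
        (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return {"cohort": cohort, "per_pair": per_pair, "comparisons": comp_df}


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)
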