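# Methods

This note documents the models, estimators and numerical choices behind
`pairsynapse`, and what the simulator-based tests do and do not establish.

## Data model and units

A `Sweep` is one synchronized triple of command potential (mV),
presynaptic current (pA) and postsynaptic current (pA) sampled at
20–50 kHz (default 50 kHz, `dt = 0.02 ms`), with a piecewise-constant
`epoch_table` describing the command. A `PairRecord` collects the sweeps
of one paired recording with holding potentials (IHC −58 mV, bouton
−94 mV, both already corrected for liquid junction potentials of 19 and
4 mV — the constants are stored, never re-applied) and a position label.
Charge is the trapezoidal integral of baseline-subtracted current, in fC
(pA·ms); the sign of the current is preserved, so inward synaptic events
integrate to negative charge and summaries report magnitudes.

Containers are HDF5: `/meta` attributes, `/sweeps/<k>/{v_cmd,i_pre,i_post}`
with per-sweep attributes, `/qc`, and `/truth` for simulator ground truth.
Round trips are bit-exact.

### Access-resistance estimation

The decay of the capacitive transient after a 10 mV test pulse is fitted
with `A_f·exp(−t/τ_f) + A_s·exp(−t/τ_s) + I_ss` (t = 0 at step onset;
single-exponential fallback when the second component is degenerate).
Then `R_s = ΔV/I(0⁺)` and `R_m = ΔV/I_ss − R_s`. The membrane capacitance
comes from the transient charge, corrected for the R_s–R_m divider:
`C_m = (A_f τ_f + A_s τ_s)/ΔV · ((R_s+R_m)/R_m)²`. Without the correction
the estimate is low by `(R_m/(R_s+R_m))²` — up to 12% at R_s = 100 MΩ —
which is why the corrected form is used; on ideal RC cells all three
parameters are recovered exactly. Cells are excluded when the leak current
is more negative than −60 pA (IHC) or −100 pA (bouton), or when an access
estimate is undefined.

## The simulator: a stated world with known ground truth

`GroundTruth` fixes every generative parameter. Defaults describe a
typical high-SR-like synapse of a hearing mouse; two presets
(`preset_high_sr`, `preset_low_sr`) carry the group-level values used in
recovery tests.

| parameter | default | high-SR preset | low-SR preset | why |
|---|---|---|---|---|
| spontaneous rate (events/s) | 3 | 3 | 0.2 | observed range 0–18/s, median 0.2; ≥1/s defines high SR |
| amplitude mean (pA) / CV | 80 / 0.68 | — | — | pooled sEPSC histograms: mean ≈ −70…−87 pA, CV 0.68 |
| kernel τ_rise / τ_decay (ms) | 0.12 / 0.52 | — | — | gives ~0.3–0.4 ms 10–90% rise, ~0.5 ms FWHM, ~65 fC mean charge |
| multiphasic fraction | 0.5 | 0.3 | 0.6 | high-SR synapses are more monophasic |
| Boltzmann (g_max nS, V_half, S, V_rev mV) | 5, −30, 7, +60 | — | — | whole-cell Ca²⁺ current peaking near −19 mV at ≈ −300 pA |
| leak conductance (nS) | 1 | — | — | leak within the exclusion limits |
| coupling exponent m | 1.4 | 0.8 | 1.4 | pooled cooperativity of the two SR classes |
| pool (n_rrp, τ_dep ms, sustained SV/s, τ_rec ms) | 14, 6.3, 450, 450 | 14, 6.3, 450, 450 | 14, 20.9, 450, 450 | RRP ≈ 14 SV; τ depletion 6.3/20.9 ms; sustained ≈ initial/5.9; recovery ≈ 450 ms |
| latency0 (ms) / jitter scale | 1.2 / 0.2 | 1.17 / 0.15 | 3.34 / 0.8 | group-mean synaptic delays and their jitter |
| noise SD post/pre (pA) | 3 / 4 | — | — | recording noise at a 4×SD threshold of ≈ 12 pA |

Noise is Gaussian, low-passed at 5 kHz (4th-order Butterworth, rescaled to
the requested SD) — the acquisition chain filters at 5–10 kHz, and white
noise on a 50 kHz grid would overstate threshold crossings by an order of
magnitude.

**Spontaneous trains.** Homogeneous Poisson event times; amplitude
magnitudes are gamma-distributed with the requested mean and CV (the gamma
law ties skewness to 2·CV = 1.36; the empirically reported amplitude
skewness of ~1.06 cannot be matched simultaneously with CV 0.68 by a
two-parameter law — CV is matched, skewness is approximate). A fraction of
events is rendered multiphasic: 2–4 sub-kernels with Dirichlet(α=5)
weights, onsets spread within 1.5 ms with a minimum 0.5 ms separation —
closer sub-events are unresolvable after 0.3 ms smoothing and would
contradict the event's own label.

**Ca²⁺ currents.** `i_pre = g_max·a(t)·(V−V_rev) + g_leak·(V−V_hold)` with
first-order activation (τ_act = 0.3 ms, exponential-Euler, exact for
piecewise-constant commands). P/n replicas default to inverted scaling
(−P/4) from a hyperpolarized −90 mV base: depolarizing replicas from
−58 mV would activate the conductance, and the tonic resting Ca²⁺
current's deactivation would be amplified n-fold in the subtraction.

**Evoked release.** The release probability follows the Ca²⁺-drive
*increment above rest*, normalized to the strongest protocol step and
raised to `m`: `p(t) = ((d(t) − d_rest)/(d_ref − d_rest))^m`, so pool
occupancy has its fixed point at 1 without stimulation. Occupancy obeys
`d occ/dt = −occ·p/τ_dep + (1 − occ)/τ_rec` (integrated in closed form —
the ODE is linear with piecewise-constant coefficients), and the total
release rate is `occ·p·n_rrp/τ_dep + p·sustained + sr_true`. Events are an
inhomogeneous Poisson process drawn per sample bin (exact for any expected
count; high rates are never clipped), each rendered as an EPSC kernel
after `latency0` plus exponentially distributed jitter. Occupancy carries
across sweeps through the inter-sweep interval (1.5 s for IV, 20 s
masker-to-masker).

## Event detection and classification

Baseline drift is removed with a 20 ms running median (evaluated on a
decimated grid and interpolated — drift is slow by definition). A light
Savitzky-Golay low-pass (0.3 ms window, order 2) precedes thresholding.
The noise SD of the designated baseline window is estimated robustly
(1.4826·MAD): spontaneous events inside the window would inflate a plain
SD several-fold. Events are negative peaks of the smoothed trace beyond
4×SD; overlapping excursions split where the trace re-crosses half the
threshold; each event must stay below half-threshold for ≥ 0.3 ms
(band-limited noise peaks beyond 4×SD occur about once per second but are
an order of magnitude narrower — without the width rule the detector's
false positives would be comparable to a low-SR synapse's true rate).
Onset is the last threshold crossing before the peak; amplitude is read
from the raw trace (smoothing attenuates sharp peaks).

Kinetics: 10–90% rise time by linear interpolation on the rising limb;
FWHM from the half-amplitude crossings; decay τ from a single-exponential
fit between 90% of peak and the return to baseline; charge from onset to
the smoothed trace's return to the noise floor (max(0.5·SD, 0.5% of
peak)) — integrating to a fixed fraction of the peak would truncate slow
tails and bias the quantal RRP estimate upward through the mean sEPSC
charge in its denominator.

An event is **monophasic** when the smoothed derivative shows no
qualifying sign reversal (beyond 2× the derivative's noise SD) between the
10% and 90% amplitude points of either limb *and* the decay is
single-exponential with R² ≥ 0.90; otherwise multiphasic. The limb windows
matter: at the peak itself the true derivative vanishes and noise alone
would register reversals. The R² cut and the smoothing window are
configurable (`DetectionConfig`).

What a green detection test establishes: recall and precision ≥ 0.95 for
unitary events of per-event SNR ≥ 8 at rates ≤ 20/s. It does not
establish: recall of events below threshold (gamma-tail amplitudes under
~4 SD are undetectable, so measured SR underestimates the true rate when
the amplitude CV is large), nor exact event counts for multiphasic
compounds — the 50% re-crossing rule splits well-separated sub-events,
which can overcount SR by ~10% at a multiphasic fraction of 0.5.

## Ca²⁺ IV analysis

Evoked Ca²⁺ current is averaged over 10 ms from step onset (charge is the
integral over the same window). The reversal potential is the zero
crossing of a least-squares line through the IV points from (voltage of
peak current + 10 mV) to the maximal depolarization; activation curvature
below ~+20 mV biases it a few mV hyperpolarized (≈ −2 mV at the default
parameters) — documented, and harmless to the activation fit. Chord
conductances `g = I/(V − V_rev)` exclude points within 5 mV of V_rev
(division blow-up); the Boltzmann fit is multi-start (V_half from the
half-max crossing, S from the 25–75% span). The "threshold of Ca²⁺
influx" is reported as the potential of 5% fractional activation — a
documented, configurable operational definition.

## Release intensity and cooperativity

`Q_EPSC` per step integrates the postsynaptic current from step onset to
step end plus a 2 ms tail. The saturating sigmoid is fitted to the rising
limb only (points up to maximal release): over a full IV the release
charge is bell-shaped, falling again as the driving force collapses
toward V_rev. Fits with R² < 0.5 set `fit_ok = False` and exclude the
pair from group statistics — the automated surrogate for exclusion of
visually unfittable curves. Q10/Q90/dynamic range are exact closed-form
identities of the fitted model, never re-measured from data.

The power law `Q_EPSC = a·(Q_Ca)^m` is fitted by unweighted least squares
on the raw scale (log-log would discard the informative zero-release
points below threshold), pairing each step's EPSC charge with its inward
Ca²⁺ charge (points above the reversal potential are excluded — their
outward |charge| carries no release drive). Trailing points are dropped
once release first exceeds 95% of its maximum (plateau truncation, the
surrogate for by-eye restriction). Pooled fits normalize per pair
(release by its max, Ca²⁺ charge by the truncation point) and fit one law
per SR class.

Known limitation: pool depletion during the 10 ms steps compresses the
upper release curve, so the *apparent* cooperativity underestimates the
true exponent when m ≳ 2 (median fitted ≈ 1.6 at true 2.0 under the
default pool). Recovery is accurate at the physiological values (0.8 and
1.4, within ±0.2 in 50-seed medians), and the monotone link (larger true
m ⇒ larger fitted m) holds throughout. Per-pair fits on low-count
recordings scatter upward; pooled fits are the more reliable group-level
estimator.

## Forward masking

All repetitions are baseline-subtracted, averaged per sample, and
integrated into a cumulative charge trace aligned to masker onset (fewer
than 3 repetitions flags a warning, analysis proceeds). The
exponential-plus-line model is fitted to the first 50 ms with `x0`
constrained to [0, 5] ms so the line cannot absorb the exponential, and
multi-start τ initialization. Quantal conversions divide by the pair's
mean sEPSC charge: `RRP = A1/⟨Q⟩`, `sustained = slope/⟨Q⟩`,
`initial = (A1/τ + slope)/⟨Q⟩` (the fit's derivative at x0 — the adopted
reading of "initial release rate", flagged in output), and
`depression = initial/sustained` (NaN when sustained vanishes). On
noiseless model traces the fitter is exact to ≤ 1e-6 relative error. When
τ approaches the 50 ms window (the low-SR regime, τ ≈ 21 ms) the
exponential and line become weakly identifiable under trial noise:
medians stay accurate but single fits occasionally land on a degenerate
large-τ/zero-slope solution — mirroring the large dispersion this
analysis shows on real slow-depleting synapses.

eEPSC latency is the time from masker onset to the first
threshold-crossing event per repetition (mean ± SD across repetitions;
repetitions without an eEPSC are excluded and counted). The estimate
includes the first-release waiting time (~1/initial rate ≈ 0.4 ms), as in
the experimental definition.

Recovery: `ratio(ISI) = Q_probe/Q_masker` over the first 10 ms of each
stimulus from the averaged traces, with the 20 s masker-to-masker ratio
defined as 1. The single-exponential recovery fit spans 16 ms – 20 s with
full recovery imposed (R_inf = 1); the 4 ms point is excluded — about
half of real synapses show a non-monotonic dip there. The time to the
first spontaneous EPSC after the probe is searched from 10 ms after probe
offset (earlier crossings are probe-evoked, given synaptic latencies of
several ms) to 400 ms, with a 5×SD peak requirement so the long window
does not harvest single-sample noise dips.

## Group statistics and pipeline

Two-sided unpaired t-test when both groups pass Shapiro-Wilk (α 0.05) and
an F test finds no variance difference (α 0.05); otherwise Mann-Whitney U.
No multiple-testing correction (variables are reported individually).
`run_pipeline` maps the per-pair analysis over a cohort (containers or
simulated pairs), classifies SR, writes `cohort.csv` / `per_pair.json` /
`run.log`, and compares every cohort variable between SR classes;
per-pair failures are logged and skipped. All randomness is seeded; rerun
with the same config is byte-identical.

## What the simulator does not emulate

Receptor desensitization and postsynaptic saturation; Ca²⁺-channel gating
noise and facilitation; multi-compartment filtering of the bouton; slow
drift and seal instability; true multivesicular coordination (multiphasic
events are independent sub-quanta, not a fusion-pore model). Green
recovery tests therefore establish estimator correctness under the stated
generative assumptions — not that real recordings satisfy them.
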