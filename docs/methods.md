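# Methods

## Scope and data model

`mbwqc` operates on single trials of infant SF₆ multiple-breath washout:
a washin of 4% SF₆ to equilibration followed by a washout with
tracer-free gas, recorded as uniformly sampled flow and gas channels at
the airway opening. Two trace dialects are supported. The
*spiroware-like* dialect carries unprocessed flow, molar mass (MM), O₂
and CO₂; the *wbreath-like* dialect carries corrected flow and MM only.
The vendor export layouts are proprietary and not fully documented, so
this package defines its own open tab-separated formats (see
`trace_io`); they are not byte-compatible with vendor exports.
Signals are assumed BTPS-corrected upstream; the gas model is dry-gas
throughout and ignores water vapour, sensor cross-talk and
respiratory-exchange-ratio effects.

## Tracer reconstruction

With O₂ and CO₂ available, the SF₆ dry fraction follows exactly from
the linear mixture identity

    MM = F_sf6·M_sf6 + F_o2·M_o2 + F_co2·M_co2 + F_bal·M_bal,

with M_sf6 = 146.06, M_o2 = 31.999, M_co2 = 44.01 and the balance gas
(N₂ with Ar lumped) at 28.16 g/mol; all constants configurable
(`gas.*`). With MM alone, a two-point linear calibration maps MM to the
tracer fraction, anchored at a tracer-free baseline and the equilibrated
plateau of known concentration (0.04). Because the anchors need phase
knowledge and phases need a tracer signal, the pipeline calibrates in
two passes: decile-median provisional anchors, then the median MM over
the pre-washin baseline and over the ten breaths preceding washout
start. The two-point route silently attributes any O₂/CO₂-driven MM
variation to the tracer; it is accurate only where upstream processing
compensates those channels, which is exactly the situation the
wbreath-like dialect represents.

## Breath segmentation

Breaths are delimited at inspiration-onset zero crossings of flow
(inspiration positive) using a hysteresis band, by default 2% of the
running-median peak flow (median of one-second block maxima), to
suppress sensor-noise crossings; each onset is backtracked to the first
sample after the last negative sample, so on noise-free signals the
boundary is sample-exact. Candidate breaths with expiratory volume below
10% of the running-median (11-breath window) are merged into a
neighbour. Volumes are trapezoidal integrals of clipped flow; tidal
volume means expiratory volume everywhere (leak-robust). The end-tidal
concentration is the volume-weighted tracer mean over the last 5% of
expired volume — volume-based rather than time-based so end-expiratory
pauses do not dilute it — and the mean inspired concentration is the
inspiration volume-weighted tracer mean. An end-expiratory pause
belongs to the *following* breath's span under the backtracking rule;
this convention is shared with the simulator's ground truth.

## Phase detection

* **washin start** — first breath whose mean inspired tracer exceeds
  0.005 (configurable);
* **equilibration** — first breath of the first run of three
  consecutive breaths with |c_insp_mean − c_et| < 0.0004 while washin
  gas is present (c_insp_mean > 0.005). The presence guard is needed
  because tracer-free breaths satisfy the difference criterion
  trivially; without it a washin that never equilibrates could alias a
  late-washout run;
* **washout start** — first breath after equilibration with mean
  inspired tracer below half the equilibrated concentration;
* **c_start** — the measured end-tidal tracer of the last breath before
  washout start (not the nominal 4%);
* **test end** — first breath at which the end-tidal tracer sits below
  c_start/40 for three consecutive breaths. The 1/40 divisor is the
  2.5% criterion; the three-breath run follows consensus practice and
  adds noise robustness (on monotone washouts it coincides with the
  single-crossing rule). No qualifying run before the trace ends marks
  the washout *incomplete*.

Critical windows are [start − 5, end event + 5] breaths, clamped to the
trial: for the washin the end event is the equilibration breath, for
the washout the test-end breath. The equilibration tolerance reads the
"< 0.04%" criterion as absolute concentration points (0.0004); a config
switch (`equilibration_relative`) reinterprets it relative to the mean
inspired concentration, a genuinely ambiguous wording.

## Artefact detectors

Only the sigh factor (1.5× median VT, inclusive) and the breath-hold
length (2 regular tidal breaths) are fixed by the QC criteria; all
other thresholds are package defaults, configurable in `RunConfig`:

| parameter | default | meaning |
|---|---|---|
| `sigh_factor` | 1.5 | sigh threshold, × median VT |
| `breath_hold_breaths` | 2.0 | pause length, × median breath duration |
| `flow_eps_frac` | 0.05 | "flow pause" band, × median peak flow |
| `leak_step_frac` | 0.5 | end-expiratory level step, × median VT |
| `leak_drift_frac` | 0.05 | level drift per breath, × median VT |
| `leak_insp_drop_frac` | 0.10 | inspired-tracer drop between equilibrated breaths |
| `irregular_window` / `irregular_cv_max` | 10 / 0.25 | CV window and threshold |
| `mm_step_max` | 0.3 g/mol | baseline vs post-test-end MM step (strict >) |

Leak detection watches the cumulative flow integral at each breath end
(the end-expiratory volume level): a step between consecutive breaths,
a drifting least-squares slope over 10-breath windows, or — during the
equilibrated washin — a sudden relative drop of the inspired tracer
concentration. Irregular breathing is advisory: the reviewer makes the
final call. Coughing and trapped-gas release have no operational
definition for infants and appear only as manual checklist items in the
report.

## Decision workflow

Washin and washout are assessed separately. A phase is suggested
*reject* when any sigh/breath-hold/irregular/leak event overlaps its
critical window, when a leak overlaps the phase at all (the leak
criterion carries no critical-phase qualifier), or when the phase is
incomplete; *error* (empty or erroneous signals) suppresses everything
downstream. Events strictly outside the critical window become
advisories on an accepted phase. Note that because the washout critical
window encloses the whole washout span with five-breath margins, the
leak-anywhere rule only adds bite during the washin (between
equilibration + 5 and washout start). Reviewer overrides require a
reason and are stamped `manual`. FRC/CEV/LCI are computed and reported
only for an accepted washout.

## Outcomes

FRC follows from tracer mass balance over the washout: the net expired
tracer volume (expired minus re-inspired, per breath, trapezoidal)
divided by (c_start − c_end), with c_end the end-tidal tracer at the
test-end breath. CEV sums expiratory volumes from washout start through
the test-end breath inclusive, with no dead-space subtraction (standard
LCI convention); LCI = CEV/FRC.

## Agreement statistics

Multi-rater percent agreement is the mean pairwise agreement over all
unordered rater pairs. Cohen's κ (two raters) uses marginal-based
expected agreement and the large-sample standard error
√(p_o(1−p_o)/(n(1−p_e)²)); it is reported as undefined when both raters
are constant on the same category. The Brennan–Prediger κ assumes
uniform chance, κ_BP = (p_o − 1/q)/(1 − 1/q) = 2·p_o − 1 for two
categories; its confidence interval is a seeded nonparametric bootstrap
over trials (2,000 resamples, percentile method) since no analytic CI
convention is established for the multi-rater case.

## Simulator

The generator is a breath-discrete single-compartment model chosen so
that every QC rule has a closed-form oracle; it is not a physiological
lung model. Flow is a half-sine inspiration and expiration of equal
volume; the alveolar tracer fraction obeys

    C_n = c_ins + (C_{n−1} − c_ins) · FRC / (FRC + VT − VD),

the geometric washout decay and its washin mirror. The expirate shows
dead-space gas for the first VD of expired volume and alveolar gas
after, joined by a symmetric linear mixing front (width 0.4·VD) — the
symmetry preserves exact tracer mass balance while keeping the sampled
signals trapezoid-friendly. O₂/CO₂ swing between inspired (0.21, 0) and
alveolar (0.17, 0.038) values in the spiroware-like dialect; the
wbreath-like dialect holds them fixed in the forward mixture, emulating
upstream compensation, so MM is linear in tracer. Defaults are
plausible six-week-infant values: FRC 100 mL, VT 25 mL, VD 5 mL,
40 breaths/min, 200 Hz, noise off; optional per-sample multiplicative
flow noise and additive MM noise. Identical configuration and seed give
bit-identical traces.

Injected artefacts modify the breath plan before synthesis (so mass
balance stays consistent): sighs scale a breath's volume (default
1.8×), breath holds insert an end-expiratory zero-flow pause, leaks add
a constant flow bias over a breath span, irregular breathing multiplies
a span's tidal volumes by seeded lognormal factors. A σ = 0.5 lognormal
span occasionally (≈1% of seeds) realizes a tidal-volume CV below the
0.25 irregularity definition — such a span is genuinely not irregular
and the detector correctly stays silent.

What the simulator does **not** emulate: ventilation inhomogeneity
(multi-compartment washout, Scond/Sacin phenomena), REM-sleep breathing
variability, BTPS/temperature dynamics, sensor cross-talk, drifting
baselines or apparatus dead-space rebreathing. Passing tests therefore
demonstrate the correctness of the QC rules and outcome algebra under
the stated model, not detector performance on real infant recordings.

## Numerical choices and problem sizes

Trapezoidal integration on the uniform grid throughout; breath spans
are half-open sample intervals sharing boundary samples (flow ≈ 0
there, so volumes do not double-count). Trace files serialize floats
with shortest round-tripping representation and parse with
`float_precision="round_trip"`, making write→read bit-identical. Test
problem sizes: full trials of ~50–70 breaths (≈20 k samples); the
heavier property sweeps use 100-seed batches and 300–1,000 random
breath tables, keeping the whole suite under a minute of CPU.

## Known limitations

* Single-trial scope: no between-trial baseline-return check.
* The error taxonomy maps empty/erroneous traces to an *error* class
  but cannot distinguish hardware faults from export corruption.
* The two-point calibration is undefined when a trial never
  equilibrates (no plateau anchor).
* Cohen's κ CI is the simple large-sample form, adequate for the panel
  sizes in question but not exact in small samples.
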