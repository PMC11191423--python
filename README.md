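# mbwqc

Quality control for infant SF₆ multiple-breath washout (MBW) measurements.

MBW estimates lung volume and ventilation inhomogeneity by washing an
inert tracer gas (4% SF₆) into a sleeping infant's lungs until
equilibration and then following its clearance over many tidal breaths.
The two main outcomes — functional residual capacity (FRC) and the lung
clearance index (LCI) — are exquisitely sensitive to measurement
artefacts: a single sigh, face-mask leak or apnoea near the end of the
washout can move the LCI substantially. Visual quality control of the
raw signal traces is therefore mandatory, but slow and subjective when
done inside the acquisition software.

`mbwqc` is a headless QC engine for researchers and trained MBW
reviewers. It

* reads signal traces in two open tab-separated dialects — one with
  flow, molar mass, O₂ and CO₂ channels, one with corrected flow and
  molar mass only;
* reconstructs the SF₆ fraction from molar mass (exact dry-mixture
  inversion, or a two-point calibration when only molar mass is
  available);
* segments the flow signal into breaths and computes tidal volumes,
  end-tidal and mean-inspired tracer concentrations, and a heat-map
  statistic (tidal-volume deviation from the median);
* locates the critical test phases automatically: washin start,
  equilibration, washout start, and the test-end breath where the
  end-tidal tracer falls below 1/40th of its starting concentration
  (the 2.5% criterion) for three consecutive breaths; the critical
  window runs from five breaths before the phase start to five breaths
  after its end event;
* detects the four visual artefact classes — **sigh** (tidal volume
  ≥ 1.5× the median), **breath hold/apnoea** (flow pause ≥ 2 regular
  breath durations), **leak** (step or drift of the end-expiratory
  volume level, or a sudden drop of the inspired tracer concentration),
  and **irregular breathing** (elevated tidal-volume variation,
  advisory) — plus molar-mass-step and equilibration (< 0.04%)
  advisories;
* applies the systematic accept/reject workflow per phase (artefact in
  the critical window ⇒ reject; leak anywhere in the phase ⇒ reject;
  incomplete washout ⇒ reject) with file-based reviewer overrides;
* computes FRC by tracer mass balance, FRC = V_tr / (C_start − C_end),
  and LCI = CEV / FRC, only for accepted washouts;
* evaluates inter-rater agreement: percent agreement, Cohen's κ and the
  Brennan–Prediger κ (= 2·p_o − 1 for two categories) with confidence
  intervals;
* ships a trial simulator — single-compartment washin/washout with
  injectable artefacts and analytic ground truth — used throughout the
  test suite.

## Worked example

Simulate a clean trial (FRC 100 mL, VT 25 mL, VD 5 mL, 40 breaths/min)
and one with a sigh injected into the washout, then analyze both:

```sh
mbwqc simulate --seed 3 --out-dir .
mbwqc simulate --seed 7 --out-dir . --artefact sigh:48:1.8
mbwqc analyze sim-0003.mbw.tsv sim-0007.mbw.tsv --out-dir .
```

The clean trial's report (`sim-0003.qc.json`) carries an accepted
washout and the outcome block:

```json
{
 "frc_ml": 100.00401163891868,
 "cev_ml": 524.980808962251,
 "lci": 5.249597494726337,
 "n_washout_breaths": 21,
 "c_start": 0.03993228008884566,
 "c_end": 0.0008679964353426881
}
```

The recovered FRC matches the simulated compartment volume to 0.004%,
and the LCI equals the closed form for this geometry:
ceil(ln 40 / ln((FRC+VT−VD)/FRC)) · VT / FRC = 21 · 25 / 100 = 5.25
turnovers. The sigh trial is rejected instead and carries no outcomes:

```text
events:   [('sigh', 48, 48, in_critical_washout=True)]
washout:  reject — "sigh in critical phase of the washout (breaths 48-48)"
```

Agreement between reviewers is computed from a ratings CSV
(`trial_id,r1,r2,...` with `accept`/`reject` cells):

```sh
mbwqc agree ratings.csv --method both
```

## Layout

```
src/mbwqc/
  trace_io.py    file dialects, annotations
  gas_model.py   SF6 reconstruction from molar mass
  breaths.py     breath segmentation, tidal volumes, heat-map statistic
  phases.py      washin/washout boundaries, test end, critical windows
  artefacts.py   sigh / breath-hold / leak / irregular detectors, advisories
  outcomes.py    FRC, CEV, LCI
  qc.py          decision workflow, QC report, schema validation
  agreement.py   percent agreement, Cohen and Brennan-Prediger kappas
  simulator.py   synthetic trials with ground truth
  cli.py         mbwqc analyze / simulate / agree / report / convert
```

See `docs/methods.md` for the model, the thresholds and their defaults,
and known limitations.
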