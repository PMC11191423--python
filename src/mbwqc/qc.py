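"""Systematic accept/reject workflow and QC report assembly.

Washin and washout are assessed separately. A phase is suggested for
rejection when an artefact overlaps its critical window, when a leak
occurs anywhere during the phase (the leak criterion carries no
critical-phase qualifier), or when the phase is incomplete. Sigh,
breath-hold and irregular-breathing events strictly outside the critical
window yield an accepted phase with an advisory note. An *error* trial
(empty or erroneous signals) suppresses all downstream computation.
Reviewers may override any suggestion, with a mandatory reason; outcome
parameters are reported only for an accepted washout.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .artefacts import ArtefactEvent, check_equilibration, detect_all, mm_step_check
from .breaths import BreathTable, detect_breaths, tidal_volume_deviation
from .config import RunConfig
from .errors import ErrorTrial, MbwError, PhaseError, ValidationError
from .gas_model import sf6_from_full_gas, sf6_from_mm_twopoint
from .outcomes import MbwOutcomes, compute_outcomes
from .phases import PhaseMarkers, detect_phases
from .trace_io import GasTrace

log = logging.getLogger("mbwqc")

#: Table-2 items with no operational definition; surfaced for the reviewer.
MANUAL_CHECKLIST = (
    "no evidence of significant trapped gas release with larger breaths",
    "no coughing",
    "sufficient interval between trials for tracer return to baseline",
)

REJECTING_IN_CRITICAL = ("sigh", "breath_hold", "irregular_breathing", "leak")


@dataclass
class QcDecision:
    """Accept/reject decision for one phase, with provenance."""

    phase: str
    suggested: str                      # accept | reject | error
    final: str | None = None            # None = pending
    reasons: list[str] = field(default_factory=list)
    advisories: list[str] = field(default_factory=list)
    origin: str = "auto"                # auto | manual (overridden)
    reviewer_id: str = ""
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "phase": self.phase, "suggested": self.suggested, "final": self.final,
            "reasons": self.reasons, "advisories": self.advisories,
            "origin": self.origin, "reviewer_id": self.reviewer_id,
            "reason": self.reason,
        }


def _phase_span(markers: PhaseMarkers, phase: str) -> tuple[int, int] | None:
    if phase == "washin":
        if markers.washin_start is None:
            return None
        hi = (markers.washout_start - 1 if markers.washout_start
              else markers.n_breaths)
        return markers.washin_start, hi
    if markers.washout_start is None:
        return None
    return markers.washout_start, (markers.test_end or markers.n_breaths)


def suggest_decision(events: list[ArtefactEvent], markers: PhaseMarkers,
                     phase: str) -> QcDecision:
    """Apply the acceptability rules to one phase.

    Reject when (a) an artefact overlaps the phase's critical window,
    (b) a leak overlaps the phase at all, or (c) the phase is incomplete;
    error when an error event is present or the markers are absent.
    """
    if phase not in ("washin", "washout"):
        raise ValidationError("phase must be washin or washout")
    d = QcDecision(phase=phase, suggested="accept")
    if any(ev.kind == "error" for ev in events) or markers is None:
        d.suggested = "error"
        d.reasons.append("error trial: empty or erroneous signal trace")
        return d
    incomplete = (markers.incomplete_washin if phase == "washin"
                  else markers.incomplete_washout)
    if incomplete or _phase_span(markers, phase) is None:
        d.suggested = "reject"
        d.reasons.append(f"incomplete trial: {phase} end event never reached")
    critical = (markers.critical_washin if phase == "washin"
                else markers.critical_washout)
    span = _phase_span(markers, phase)
    for ev in events:
        if ev.kind not in REJECTING_IN_CRITICAL:
            continue
        in_critical = critical is not None and ev.overlaps(*critical)
        in_phase = span is not None and ev.overlaps(*span)
        if in_critical:
            d.suggested = "reject"
            d.reasons.append(
                f"{ev.kind.replace('_', ' ')} in critical phase of the {phase} "
                f"(breaths {ev.first_breath}-{ev.last_breath})")
        elif ev.kind == "leak" and in_phase:
            d.suggested = "reject"
            d.reasons.append(
                f"leak during the {phase} (breaths {ev.first_breath}-{ev.last_breath})")
        else:
            d.advisories.append(
                f"{ev.kind.replace('_', ' ')} outside the critical window "
                f"(breaths {ev.first_breath}-{ev.last_breath})")
    return d


def finalize_decision(decision: QcDecision, override: str | None = None,
                      override_reason: str = "", reviewer_id: str = "") -> QcDecision:
    """Record the final decision; overriding a suggestion requires a reason."""
    d = dataclasses.replace(decision, reasons=list(decision.reasons),
                            advisories=list(decision.advisories))
    d.reviewer_id = reviewer_id
    if override is None or override == d.suggested:
        d.final = d.suggested
        d.origin = "auto"
        d.reason = override_reason
        return d
    if override not in ("accept", "reject", "error"):
        raise ValidationError(f"override must be accept/reject/error, got {override!r}")
    if not override_reason:
        raise ValidationError("overriding a suggested decision requires a reason")
    d.final = override
    d.origin = "manual"
    d.reason = override_reason
    return d


# --------------------------------------------------------------------------
# pipeline

def reconstruct_tracer(trace: GasTrace, cfg: RunConfig = RunConfig(),
                       table: BreathTable | None = None,
                       markers: PhaseMarkers | None = None) -> GasTrace:
    """Fill the derived tracer channel.

    Spiroware-like traces use the exact full-gas inversion. WBreath-like
    traces use the two-point molar-mass calibration: provisionally
    anchored at the lowest/highest-decile MM medians, then (when breath
    table and phase markers are available) refined to the median MM over
    the pre-washin baseline and over the 10 breaths preceding washout
    start.
    """
    if trace.setup_kind == "spiroware_like":
        trace.tracer = sf6_from_full_gas(trace.mm, trace.o2, trace.co2, cfg.gas)
        return trace
    mm = trace.mm
    if markers is not None and table is not None and markers.washout_start is not None:
        base_end = int(table.insp_start[markers.washin_start - 1])
        mm_base = float(np.median(mm[:base_end])) if base_end > 1 else float(np.min(mm))
        lo_b = max(markers.washin_start - 1, markers.washout_start - 11)
        s = int(table.insp_start[lo_b])
        e = int(table.exp_end[markers.washout_start - 2])
        mm_eq = float(np.median(mm[s:e]))
    else:
        lo_thr, hi_thr = np.percentile(mm, [10, 90])
        mm_base = float(np.median(mm[mm <= lo_thr]))
        mm_eq = float(np.median(mm[mm >= hi_thr]))
    trace.tracer = sf6_from_mm_twopoint(mm, mm_base, mm_eq,
                                        trace.nominal_tracer_start)
    return trace


def analyze_trace(trace: GasTrace, cfg: RunConfig = RunConfig(),
                  overrides: dict | None = None, reviewer_id: str = "") -> dict:
    """Run the full QC pipeline on one trace and return the report dict.

    ``overrides`` maps phase -> (decision, reason) for file-based manual
    review. Outcome parameters are included only when the washout's
    final decision is accept.
    """
    trace.validate()
    if not np.any(trace.flow != 0):
        raise ErrorTrial(f"{trace.trial_id}: flow signal identically zero")

    reconstruct_tracer(trace, cfg)
    table = detect_breaths(trace, cfg.min_volume_frac, None,
                           cfg.hysteresis_frac, cfg.et_volume_frac)
    if len(table) == 0:
        raise ErrorTrial(f"{trace.trial_id}: no breaths detected")
    markers = detect_phases(table, trace.nominal_tracer_start, cfg)
    if trace.setup_kind == "wbreath_like":
        # refine the two-point calibration now that phases are known
        reconstruct_tracer(trace, cfg, table, markers)
        table = detect_breaths(trace, cfg.min_volume_frac, None,
                               cfg.hysteresis_frac, cfg.et_volume_frac)
        markers = detect_phases(table, trace.nominal_tracer_start, cfg)

    events = detect_all(trace, table, markers, cfg)
    advisories = {
        "mm_step": mm_step_check(trace, table, markers, cfg.mm_step_max),
        "equilibration": check_equilibration(
            table, markers, cfg.equilibration_tol, cfg.equilibration_relative),
        "manual_checklist": list(MANUAL_CHECKLIST),
    }
    overrides = overrides or {}
    decisions = {}
    for phase in ("washin", "washout"):
        suggested = suggest_decision(events, markers, phase)
        ov = overrides.get(phase)
        decisions[phase] = finalize_decision(
            suggested, override=ov[0] if ov else None,
            override_reason=ov[1] if ov else "", reviewer_id=reviewer_id)
        log.info("%s %s: suggested %s (%s)", trace.trial_id, phase,
                 suggested.suggested, "; ".join(suggested.reasons) or "clean")

    outcomes = None
    if decisions["washout"].final == "accept" and markers.test_end is not None:
        outcomes = compute_outcomes(trace, table, markers)
    return build_report(trace, table, markers, events, decisions, outcomes, cfg)


def error_report(trial_id: str, setup_kind: str, message: str,
                 cfg: RunConfig = RunConfig()) -> dict:
    """Report for a trial classified *error*; nothing downstream is computed."""
    decisions = {
        phase: QcDecision(phase=phase, suggested="error", final="error",
                          reasons=[message]).to_dict()
        for phase in ("washin", "washout")
    }
    return {
        "trial_id": trial_id, "setup_kind": setup_kind, "sample_rate_hz": 0.0,
        "status": "error", "error": message, "n_breaths": 0, "markers": None,
        "breath_table": [], "heatmap_deviation": [],
        "events": [ArtefactEvent("error", 1, 1, detail=message).to_dict()],
        "advisories": {"mm_step": {}, "equilibration": {},
                       "manual_checklist": list(MANUAL_CHECKLIST)},
        "decisions": decisions, "outcomes": None,
        "thresholds": _thresholds_dict(cfg),
    }


def _thresholds_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["gas"] = dataclasses.asdict(cfg.gas)
    return d


def _clean(x):
    """JSON-safe: numpy scalars to python, NaN to None."""
    if isinstance(x, dict):
        return {k: _clean(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_clean(v) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating, float)):
        return None if not np.isfinite(x) else float(x)
    if isinstance(x, np.bool_):
        return bool(x)
    return x


def build_report(trace: GasTrace, table: BreathTable, markers: PhaseMarkers,
                 events: list[ArtefactEvent], decisions: dict[str, QcDecision],
                 outcomes: MbwOutcomes | None = None,
                 cfg: RunConfig = RunConfig()) -> dict:
    """Assemble the single-trial QC report document.

    The outcomes block is present only when the washout's final decision
    is accept; an inconsistent set of inputs raises an assembly error.
    """
    if outcomes is not None and decisions["washout"].final != "accept":
        raise ValidationError("outcomes may only be reported for an accepted washout")
    if markers.n_breaths not in (0, len(table)):
        raise ValidationError("phase markers and breath table disagree on breath count")
    dev = tidal_volume_deviation(table) if len(table) and table.median_vt > 0 else []
    df = table.to_dataframe()
    report = {
        "trial_id": trace.trial_id,
        "setup_kind": trace.setup_kind,
        "sample_rate_hz": trace.sample_rate,
        "status": "ok",
        "error": None,
        "n_breaths": len(table),
        "markers": markers.to_dict(),
        "breath_table": df.to_dict(orient="records"),
        "heatmap_deviation": list(dev),
        "events": [e.to_dict() for e in events],
        "advisories": {
            "mm_step": mm_step_check(trace, table, markers, cfg.mm_step_max),
            "equilibration": check_equilibration(
                table, markers, cfg.equilibration_tol, cfg.equilibration_relative),
            "manual_checklist": list(MANUAL_CHECKLIST),
        },
        "decisions": {p: d.to_dict() for p, d in decisions.items()},
        "outcomes": outcomes.to_dict() if outcomes is not None else None,
        "thresholds": _thresholds_dict(cfg),
    }
    return _clean(report)


def write_report(report: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=1) + "\n", encoding="utf-8")
    return path


def read_report(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


# --------------------------------------------------------------------------
# schema validation (small subset validator; schema shipped with the package)

def load_schema() -> dict:
    return json.loads(resources.files("mbwqc").joinpath("report_schema.json").read_text())


def _check(value, schema, path="$") -> list[str]:
    errors = []
    types = schema.get("type")
    if types is not None:
        if isinstance(types, str):
            types = [types]
        type_map = {"object": dict, "array": list, "string": str,
                    "boolean": bool, "null": type(None)}
        ok = False
        for t in types:
            if t == "number":
                ok |= isinstance(value, (int, float)) and not isinstance(value, bool)
            elif t == "integer":
                ok |= isinstance(value, int) and not isinstance(value, bool)
            else:
                ok |= isinstance(value, type_map[t])
        if not ok:
            return [f"{path}: expected {types}, got {type(value).__name__}"]
    if "enum" in schema and value is not None and value not in schema["enum"]:
        errors.append(f"{path}: {value!r} not in {schema['enum']}")
    if isinstance(value, dict):
        for req in schema.get("required", []):
            if req not in value:
                errors.append(f"{path}: missing required key {req!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                errors += _check(value[key], sub, f"{path}.{key}")
    if isinstance(value, list) and "items" in schema:
        for i, item in enumerate(value):
            errors += _check(item, schema["items"], f"{path}[{i}]")
    return errors


def validate_report(report: dict) -> list[str]:
    """Return a list of schema violations (empty when the report validates)."""
    return _check(report, load_schema())


def plot_report(trace: GasTrace, table: BreathTable, markers: PhaseMarkers,
                path) -> Path:
    """Static signal-panel export with shaded critical windows
    (blue washin, green washout)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.arange(trace.n_samples) / trace.sample_rate
    channels = [("flow (mL/s)", trace.flow), ("molar mass (g/mol)", trace.mm)]
    if trace.tracer is not None:
        channels.append(("SF6 fraction", trace.tracer))
    fig, axes = plt.subplots(len(channels), 1, sharex=True,
                             figsize=(10, 2.2 * len(channels)))
    axes = np.atleast_1d(axes)
    for ax, (label, y) in zip(axes, channels):
        ax.plot(t, y, lw=0.6, color="k")
        ax.set_ylabel(label)
        for window, color in ((markers.critical_washin, "tab:blue"),
                              (markers.critical_washout, "tab:green")):
            if window is not None and len(table):
                lo = table.insp_start[window[0] - 1] / trace.sample_rate
                hi = table.exp_end[window[1] - 1] / trace.sample_rate
                ax.axvspan(lo, hi, alpha=0.15, color=color)
    axes[-1].set_xlabel("time (s)")
    fig.suptitle(trace.trial_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
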