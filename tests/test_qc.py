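"""Accept/reject workflow, report assembly and schema validation."""

import numpy as np
import pytest

from mbwqc.artefacts import ArtefactEvent
from mbwqc.errors import ErrorTrial, ValidationError
from mbwqc.phases import PhaseMarkers, stamp_critical_flags
from mbwqc.qc import (analyze_trace, error_report, finalize_decision,
                      read_report, suggest_decision, validate_report,
                      write_report)
from mbwqc.simulator import ArtefactSpec, SimConfig, inject_artefact, simulate_trial
from mbwqc.trace_io import GasTrace


def markers_60() -> PhaseMarkers:
    return PhaseMarkers(washin_start=6, equilibration=20, washout_start=31,
                        test_end=50, c_start=0.04, critical_washin=(1, 25),
                        critical_washout=(26, 55), n_breaths=60)


def ev(kind, first, last, markers=None):
    e = ArtefactEvent(kind, first, last)
    if markers is not None:
        stamp_critical_flags([e], markers)
    return e


def test_sigh_in_critical_washout_suggests_reject():
    m = markers_60()
    d = suggest_decision([ev("sigh", 40, 40, m)], m, "washout")
    assert d.suggested == "reject"
    assert any("sigh in critical phase" in r for r in d.reasons)


def test_no_events_suggests_accept():
    d = suggest_decision([], markers_60(), "washout")
    assert d.suggested == "accept" and d.reasons == []


def test_sigh_outside_critical_accept_with_advisory():
    m = markers_60()
    d = suggest_decision([ev("sigh", 58, 58, m)], m, "washout")
    assert d.suggested == "accept"
    assert any("outside the critical window" in a for a in d.advisories)


def test_leak_rejects_anywhere_in_phase():
    """The leak criterion has no critical-phase qualifier: breaths 26-30
    are washin-phase but outside the washin critical window, yet a leak
    there still rejects the washin (a sigh there would not)."""
    m = markers_60()
    d = suggest_decision([ev("leak", 27, 28, m)], m, "washin")
    assert d.suggested == "reject"
    d = suggest_decision([ev("sigh", 27, 28, m)], m, "washin")
    assert d.suggested == "accept"
    # a leak beyond the washout's end event rejects nothing
    d = suggest_decision([ev("leak", 58, 59, m)], m, "washout")
    assert d.suggested == "accept"


def test_incomplete_phase_suggests_reject():
    m = markers_60()
    m.test_end = None
    m.incomplete_washout = True
    d = suggest_decision([], m, "washout")
    assert d.suggested == "reject"
    assert any("incomplete" in r for r in d.reasons)


def test_error_event_propagates():
    d = suggest_decision([ArtefactEvent("error", 1, 1)], markers_60(), "washout")
    assert d.suggested == "error"


def test_adding_critical_event_never_unrejects():
    """Decision monotonicity under added in-critical artefacts."""
    rng = np.random.default_rng(12)
    m = markers_60()
    kinds = ("sigh", "breath_hold", "irregular_breathing", "leak")
    for _ in range(200):
        events = []
        for _ in range(rng.integers(0, 4)):
            a = int(rng.integers(1, 61))
            b = min(60, a + int(rng.integers(0, 3)))
            events.append(ev(str(rng.choice(kinds)), a, b, m))
        before = suggest_decision(events, m, "washout").suggested
        a = int(rng.integers(m.critical_washout[0], m.critical_washout[1] + 1))
        extra = events + [ev(str(rng.choice(kinds)), a, a, m)]
        after = suggest_decision(extra, m, "washout").suggested
        assert after == "reject"
        if before == "reject":
            assert after == "reject"


def test_finalize_auto_and_override():
    d = suggest_decision([], markers_60(), "washout")
    final = finalize_decision(d, reviewer_id="rev1")
    assert final.final == "accept" and final.origin == "auto"

    overridden = finalize_decision(d, override="reject",
                                   override_reason="suspected leak",
                                   reviewer_id="rev1")
    assert overridden.final == "reject" and overridden.origin == "manual"

    with pytest.raises(ValidationError, match="reason"):
        finalize_decision(d, override="reject")


def test_accepted_trial_report_contains_outcomes(clean_trial):
    trace, _ = clean_trial
    report = analyze_trace(trace)
    assert report["status"] == "ok"
    assert report["outcomes"] is not None
    assert report["outcomes"]["lci"] == pytest.approx(5.25, abs=0.01)


def test_rejected_washout_report_has_no_outcomes():
    trace, _ = inject_artefact(SimConfig(seed=9), ArtefactSpec("sigh", 48, 1.8))
    report = analyze_trace(trace)
    assert report["decisions"]["washout"]["final"] == "reject"
    assert report["outcomes"] is None


def test_manual_override_via_annotations():
    trace, _ = clean_trial_for_override()
    report = analyze_trace(trace, overrides={
        "washout": ("reject", "operator noted face-mask leak")})
    assert report["decisions"]["washout"]["final"] == "reject"
    assert report["decisions"]["washout"]["origin"] == "manual"
    assert report["outcomes"] is None


def clean_trial_for_override():
    return simulate_trial(SimConfig(seed=21))


def test_zero_flow_is_error_trial():
    trace = GasTrace(200.0, np.zeros(1000), np.full(1000, 28.7),
                     setup_kind="wbreath_like")
    with pytest.raises(ErrorTrial):
        analyze_trace(trace)
    report = error_report("t0", "wbreath_like", "flow signal identically zero")
    assert report["status"] == "error"
    assert report["outcomes"] is None
    assert validate_report(report) == []


def test_reports_validate_and_round_trip(tmp_path):
    """Every emitted report validates; reloading reproduces decisions and
    outcomes exactly."""
    for seed in range(10):
        artefacts = (ArtefactSpec("sigh", 44, 1.8),) if seed % 2 else ()
        trace, _ = simulate_trial(SimConfig(seed=seed, artefacts=artefacts))
        report = analyze_trace(trace)
        assert validate_report(report) == [], f"seed {seed}"
        path = write_report(report, tmp_path / f"r{seed}.qc.json")
        assert read_report(path) == report
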