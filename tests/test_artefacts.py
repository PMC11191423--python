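"""Artefact detectors against direct rule application and brute force."""

import numpy as np
import pytest

from conftest import make_table
from mbwqc.artefacts import (check_equilibration, detect_breath_holds,
                             detect_irregular_breathing, detect_leaks,
                             detect_sighs, mm_step_check)
from mbwqc.breaths import detect_breaths
from mbwqc.errors import UndefinedStatisticError
from mbwqc.phases import PhaseMarkers, detect_phases
from mbwqc.qc import reconstruct_tracer
from mbwqc.simulator import ArtefactSpec, SimConfig, inject_artefact, simulate_trial
from mbwqc.trace_io import GasTrace


# ---------------------------------------------------------------- sighs

def test_sigh_direct_rule():
    """v_exp = [25 x 9, 40]: threshold 37.5 -> breath 10 flagged."""
    events = detect_sighs(make_table([25.0] * 9 + [40.0]))
    assert [(e.first_breath, e.last_breath) for e in events] == [(10, 10)]


def test_sigh_constant_volumes_silent():
    assert detect_sighs(make_table([25.0] * 12)) == []


def test_sigh_threshold_inclusive():
    """'At least 1.5-fold' -> a breath at exactly 1.5x the median flags."""
    events = detect_sighs(make_table([25.0] * 9 + [37.5]))
    assert [e.first_breath for e in events] == [10]


def test_sigh_zero_median_undefined():
    with pytest.raises(UndefinedStatisticError):
        detect_sighs(make_table([0.0] * 5))


def test_sigh_flagged_set_matches_brute_force():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = rng.integers(3, 40)
        v = rng.lognormal(np.log(25), 0.4, n)
        events = detect_sighs(make_table(v))
        flagged = {b for e in events for b in range(e.first_breath, e.last_breath + 1)}
        med = float(np.median(v))
        oracle = {i + 1 for i in range(n) if v[i] >= 1.5 * med}
        assert flagged == oracle


# ---------------------------------------------------------- breath holds

def test_breath_hold_detected_above_two_breath_rule():
    trace, truth = inject_artefact(SimConfig(seed=2),
                                   ArtefactSpec("breath_hold", 20, 2.5))
    table = detect_breaths(trace)
    events = detect_breath_holds(trace, table)
    assert len(events) == 1
    span = truth.artefact_spans[0]
    assert events[0].first_breath <= span["first_breath"]
    assert events[0].last_breath >= span["last_breath"] - 1


def test_breath_hold_below_rule_silent():
    trace, _ = inject_artefact(SimConfig(seed=2), ArtefactSpec("breath_hold", 20, 1.0))
    table = detect_breaths(trace)
    assert detect_breath_holds(trace, table) == []


def test_uninterrupted_sine_has_no_holds(clean_trial):
    trace, _ = clean_trial
    table = detect_breaths(trace)
    assert detect_breath_holds(trace, table) == []


# ----------------------------------------------------------------- leaks

def test_leak_flow_bias_drift_detected():
    """+5 mL/s over ~10 s drifts the end-expiratory volume level."""
    trace, truth = inject_artefact(SimConfig(seed=4), ArtefactSpec("leak", 20, 5.0))
    table = detect_breaths(trace)
    events = detect_leaks(trace, table)
    assert events
    span = truth.artefact_spans[0]
    covered = set()
    for e in events:
        covered |= set(range(e.first_breath, e.last_breath + 1))
    assert set(range(span["first_breath"], span["last_breath"] + 1)) <= covered


def test_leak_single_sample_volume_step_detected(clean_trial):
    """An impulse adding 0.6 median-VT of volume between breaths is a step leak."""
    trace, _ = clean_trial
    flow = trace.flow.copy()
    table = detect_breaths(trace)
    k = int(table.insp_start[30]) + 5
    flow[k] += 0.6 * table.median_vt * trace.sample_rate  # impulse of 15 mL
    bumped = GasTrace(trace.sample_rate, flow, trace.mm, o2=trace.o2,
                      co2=trace.co2, setup_kind=trace.setup_kind)
    table2 = detect_breaths(bumped)
    events = detect_leaks(bumped, table2)
    assert any("step" in e.detail for e in events)


def test_clean_trace_has_no_leaks(clean_trial):
    trace, _ = clean_trial
    table = detect_breaths(trace)
    assert detect_leaks(trace, table) == []


def test_leak_inspired_concentration_drop():
    """A >10% drop of inspired tracer between equilibrated breaths."""
    n = 12
    c_insp = [0.04] * 6 + [0.034] + [0.04] * 5
    table = make_table([25.0] * n, c_et=[0.04] * n, c_insp=c_insp)
    equil = np.ones(n, dtype=bool)
    events = detect_leaks_with_gas(table, equil)
    assert [(e.first_breath, e.last_breath) for e in events] == [(6, 7)]


def detect_leaks_with_gas(table, equilibrated):
    """Leak detection needs a trace for the volume branches; build a flat
    flow trace so only the concentration branch can fire."""
    n_samples = int(table.exp_end[-1]) + 1
    t = np.arange(n_samples) / 200.0
    flow = 25.0 * np.pi / 1.5 * np.sin(2 * np.pi * t / 1.5)
    trace = GasTrace(200.0, flow, np.full(n_samples, 28.7), setup_kind="wbreath_like")
    return [e for e in detect_leaks(trace, table, equilibrated=equilibrated)
            if "tracer drop" in e.detail]


# --------------------------------------------------- irregular breathing

def test_irregular_constant_silent():
    assert detect_irregular_breathing(make_table([25.0] * 20)) == []


def test_irregular_alternating_volumes_flagged():
    """Alternating 20/40 mL gives CV ~= 0.34 > 0.25."""
    v = [20.0, 40.0] * 10
    events = detect_irregular_breathing(make_table(v))
    assert events
    assert events[0].first_breath == 1 and events[-1].last_breath == 20


def test_irregular_null_lognormal_never_flags():
    """sigma = 0.05 tidal volumes stay below the CV threshold in 100 seeds."""
    for seed in range(100):
        rng = np.random.default_rng(seed)
        v = 25.0 * rng.lognormal(0.0, 0.05, 30)
        assert detect_irregular_breathing(make_table(v)) == []


def test_irregular_matches_brute_force_windows():
    rng = np.random.default_rng(9)
    for _ in range(100):
        n = int(rng.integers(10, 35))
        v = rng.lognormal(np.log(25), rng.uniform(0.05, 0.5), n)
        events = detect_irregular_breathing(make_table(v), window=10, cv_max=0.25)
        flagged = {b for e in events for b in range(e.first_breath, e.last_breath + 1)}
        oracle = set()
        for i in range(n - 9):
            seg = v[i:i + 10]
            if np.std(seg, ddof=1) / np.mean(seg) > 0.25:
                oracle |= set(range(i + 1, i + 11))
        assert flagged == oracle


# ------------------------------------------------------------ advisories

def _analyzed(trace):
    reconstruct_tracer(trace)
    table = detect_breaths(trace)
    markers = detect_phases(table, trace.nominal_tracer_start)
    return table, markers


def test_mm_step_zero_for_identical_segments(clean_trial):
    trace, _ = clean_trial
    table, markers = _analyzed(trace)
    flat = GasTrace(trace.sample_rate, trace.flow, np.full(trace.n_samples, 28.7),
                    o2=trace.o2, co2=trace.co2, setup_kind=trace.setup_kind)
    res = mm_step_check(flat, table, markers)
    assert res["evaluable"] and not res["flag"]
    assert res["delta_gmol"] == 0.0


def test_mm_step_clean_trial_below_threshold(clean_trial):
    trace, _ = clean_trial
    table, markers = _analyzed(trace)
    res = mm_step_check(trace, table, markers)
    assert res["evaluable"] and not res["flag"]
    assert abs(res["delta_gmol"]) < 0.3


def test_mm_step_offset_flagged_strict(clean_trial):
    trace, _ = clean_trial
    table, markers = _analyzed(trace)
    tail = int(table.exp_end[markers.test_end - 1])

    mm = trace.mm.copy()
    mm[tail:] += 0.5
    shifted = GasTrace(trace.sample_rate, trace.flow, mm, o2=trace.o2,
                       co2=trace.co2, setup_kind=trace.setup_kind)
    res = mm_step_check(shifted, table, markers)
    assert res["flag"] and res["delta_gmol"] == pytest.approx(0.5, abs=1e-6)

    # an offset exactly at the limit is not flagged (strict >)
    res = mm_step_check(shifted, table, markers, mm_step_max=0.5)
    assert not res["flag"]


def test_mm_step_not_evaluable_without_tail():
    trace, _ = simulate_trial(SimConfig(seed=6, n_washout_breaths=18))
    table, markers = _analyzed(trace)
    # the test-end run (washout breath 21 + two below) never fits in 18 breaths
    assert markers.test_end is None
    res = mm_step_check(trace, table, markers)
    assert not res["evaluable"]


def test_equilibration_check_pass_and_strictness():
    n = 12
    markers = PhaseMarkers(washin_start=1, equilibration=3, washout_start=11,
                           n_breaths=n)
    perfect = make_table([25.0] * n, c_et=[0.04] * n, c_insp=[0.04] * n)
    res = check_equilibration(perfect, markers)
    assert res["pass"] and res["statistic"] == 0.0

    off = make_table([25.0] * n, c_et=[0.039] * n, c_insp=[0.04] * n)
    assert not check_equilibration(off, markers)["pass"]  # 0.001 > 4e-4

    # statistic exactly equal to the tolerance fails (strict <)
    exact = make_table([25.0] * n, c_et=[0.25] * n, c_insp=[0.75] * n)
    res = check_equilibration(exact, markers, tol=0.5)
    assert res["statistic"] == 0.5 and not res["pass"]


def test_equilibration_not_evaluable_without_washout():
    table = make_table([25.0] * 5, c_et=[0.04] * 5, c_insp=[0.04] * 5)
    res = check_equilibration(table, PhaseMarkers(n_breaths=5))
    assert not res["evaluable"]
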