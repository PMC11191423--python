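"""Automatic detectors for visual artefacts in MBW trials.

Four artefact classes are detected, following the published visual QC
criteria for infant SF6 washout:

* sigh — a breath with tidal volume at least 1.5x the median tidal
  volume (inclusive threshold).
* breath hold / apnoea — a flow pause lasting at least two regular
  tidal breath durations.
* leak — a step change or drifting slope of the end-expiratory volume
  level, or a sudden drop of the inspired tracer concentration between
  equilibrated washin breaths.
* irregular breathing — advisory: windows where the tidal-volume
  coefficient of variation is elevated; the final call remains with the
  reviewer.

Two numeric advisories accompany them: the molar-mass step check between
the pre-washin baseline and the post-test-end tail, and the washin
equilibration check (|c_insp_mean - c_et| below tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .config import RunConfig
from .errors import UndefinedStatisticError, ValidationError

if TYPE_CHECKING:  # pragma: no cover - type hints only
    from .breaths import BreathTable
    from .phases import PhaseMarkers
    from .trace_io import GasTrace

ARTEFACT_KINDS = ("sigh", "breath_hold", "leak", "irregular_breathing", "error")


@dataclass
class ArtefactEvent:
    """A detected or operator-declared artefact.

    ``first_breath``/``last_breath`` span breaths inclusively (1-based).
    The in-critical flags are stamped from the phase markers; ``origin``
    records whether the event came from a detector or a reviewer.
    """

    kind: str
    first_breath: int
    last_breath: int
    in_critical_washin: bool = False
    in_critical_washout: bool = False
    origin: str = "auto"
    detail: str = ""

    def __post_init__(self):
        if self.kind not in ARTEFACT_KINDS:
            raise ValidationError(
                f"unknown artefact kind {self.kind!r}; allowed: {', '.join(ARTEFACT_KINDS)}"
            )
        if self.origin not in ("auto", "manual"):
            raise ValidationError("origin must be 'auto' or 'manual'")
        if not (1 <= self.first_breath <= self.last_breath):
            raise ValidationError("breath span must satisfy 1 <= first <= last")

    def overlaps(self, lo: int, hi: int) -> bool:
        """True when the breath span intersects the inclusive range [lo, hi]."""
        return self.first_breath <= hi and self.last_breath >= lo

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "first_breath": self.first_breath,
            "last_breath": self.last_breath,
            "in_critical_washin": self.in_critical_washin,
            "in_critical_washout": self.in_critical_washout,
            "origin": self.origin,
            "detail": self.detail,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArtefactEvent":
        return cls(**{k: d[k] for k in (
            "kind", "first_breath", "last_breath", "in_critical_washin",
            "in_critical_washout", "origin", "detail") if k in d})


def _runs_to_events(flags: np.ndarray, kind: str, detail_fn) -> list[ArtefactEvent]:
    """One event per maximal run of consecutive flagged breaths (1-based)."""
    events = []
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return events
    start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            events.append(ArtefactEvent(kind, int(start) + 1, int(prev) + 1,
                                        detail=detail_fn(start, prev)))
            start = i
        prev = i
    events.append(ArtefactEvent(kind, int(start) + 1, int(prev) + 1,
                                detail=detail_fn(start, prev)))
    return events


def detect_sighs(table: "BreathTable", sigh_factor: float = 1.5) -> list[ArtefactEvent]:
    """Flag breaths with v_exp >= sigh_factor * median tidal volume.

    The threshold is inclusive ("at least 1.5-fold"); consecutive flagged
    breaths are merged into one event.
    """
    if table.median_vt <= 0:
        raise UndefinedStatisticError("median tidal volume is zero; sigh threshold undefined")
    v = table.v_exp
    thr = sigh_factor * table.median_vt
    flags = v >= thr
    return _runs_to_events(
        flags, "sigh",
        lambda a, b: f"v_exp up to {v[a:b + 1].max():.1f} mL >= {thr:.1f} mL "
                     f"({sigh_factor:g} x median VT {table.median_vt:.1f} mL)")


def detect_breath_holds(trace: "GasTrace", table: "BreathTable",
                        flow_eps_frac: float = 0.05,
                        breath_hold_breaths: float = 2.0) -> list[ArtefactEvent]:
    """Flag flow pauses lasting at least two regular tidal breaths.

    A pause is a maximal sample interval with |flow| below
    ``flow_eps_frac`` times the median peak flow; its event spans the
    breaths the interval overlaps.
    """
    if len(table) == 0 or table.median_duration <= 0:
        return []
    eps = flow_eps_frac * float(np.median(table.peak_flow))
    min_samples = breath_hold_breaths * table.median_duration * trace.sample_rate
    quiet = np.abs(trace.flow) < eps
    events: list[ArtefactEvent] = []
    # maximal runs of quiet samples
    padded = np.diff(np.concatenate(([0], quiet.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)  # exclusive
    for s, e in zip(starts, ends):
        if e - s >= min_samples:
            span = table.breaths_overlapping_samples(int(s), int(e))
            if span is None:
                continue
            dur = (e - s) / trace.sample_rate
            events.append(ArtefactEvent(
                "breath_hold", span[0], span[1],
                detail=f"flow pause {dur:.2f} s >= {breath_hold_breaths:g} x "
                       f"median breath duration {table.median_duration:.2f} s"))
    return events


def detect_leaks(trace: "GasTrace", table: "BreathTable",
                 step_frac: float = 0.5, drift_frac: float = 0.05,
                 insp_drop_frac: float = 0.10,
                 equilibrated: np.ndarray | None = None) -> list[ArtefactEvent]:
    """Flag step changes or drift of the end-expiratory volume level.

    The end-expiratory level L_i is the cumulative flow integral at each
    breath's end. Three branches fire a leak event:

    (a) step — |L_{i+1} - L_i| > step_frac * median VT;
    (b) drift — |least-squares slope of L over a 10-breath window|
        > drift_frac * median VT per breath;
    (c) washin — a relative drop of c_insp_mean by more than
        ``insp_drop_frac`` between consecutive equilibrated breaths
        (pass a boolean mask of equilibrated breaths to enable).
    """
    n = len(table)
    if n < 4 or table.median_vt <= 0:
        return []
    dt = 1.0 / trace.sample_rate
    cumvol = np.concatenate(([0.0], np.cumsum((trace.flow[1:] + trace.flow[:-1]) * 0.5 * dt)))
    levels = cumvol[np.minimum(table.exp_end, len(cumvol) - 1)]
    events: list[ArtefactEvent] = []

    step_thr = step_frac * table.median_vt
    dL = np.diff(levels)
    step_flags = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(np.abs(dL) > step_thr):
        step_flags[i:i + 2] = True
    events += _runs_to_events(
        step_flags, "leak",
        lambda a, b: f"end-expiratory volume step > {step_thr:.1f} mL")

    w = 10
    drift_thr = drift_frac * table.median_vt
    drift_flags = np.zeros(n, dtype=bool)
    if n >= w:
        x = np.arange(w, dtype=float)
        x = x - x.mean()
        denom = float(np.dot(x, x))
        for i in range(n - w + 1):
            slope = float(np.dot(x, levels[i:i + w])) / denom
            if abs(slope) > drift_thr:
                drift_flags[i:i + w] = True
    events += _runs_to_events(
        drift_flags, "leak",
        lambda a, b: f"end-expiratory volume drift > {drift_thr:.2f} mL/breath")

    if equilibrated is not None and table.has_gas:
        c = table.c_insp_mean
        for i in range(n - 1):
            if equilibrated[i] and equilibrated[i + 1] and c[i] > 0:
                drop = (c[i] - c[i + 1]) / c[i]
                if drop > insp_drop_frac:
                    events.append(ArtefactEvent(
                        "leak", i + 1, i + 2,
                        detail=f"inspired tracer drop {100 * drop:.1f}% between "
                               f"equilibrated breaths"))
    return events


def detect_irregular_breathing(table: "BreathTable", window: int = 10,
                               cv_max: float = 0.25) -> list[ArtefactEvent]:
    """Advisory: flag windows with elevated tidal-volume variability.

    Slides a window over v_exp and flags it when the coefficient of
    variation (sample SD / mean) exceeds ``cv_max``; overlapping flagged
    windows merge into one event. The reviewer makes the final call.
    """
    if window < 5:
        raise ValidationError("window must be >= 5 breaths")
    n = len(table)
    if n < window:
        return []
    v = table.v_exp
    flags = np.zeros(n, dtype=bool)
    cvs = []
    for i in range(n - window + 1):
        seg = v[i:i + window]
        mean = seg.mean()
        cv = float(seg.std(ddof=1) / mean) if mean > 0 else np.inf
        cvs.append(cv)
        if cv > cv_max:
            flags[i:i + window] = True
    return _runs_to_events(
        flags, "irregular_breathing",
        lambda a, b: f"tidal volume CV > {cv_max:g} within a {window}-breath window")


def mm_step_check(trace: "GasTrace", table: "BreathTable", markers: "PhaseMarkers",
                  mm_step_max: float = 0.3, min_seconds: float = 2.0) -> dict:
    """Advisory molar-mass step between baseline and post-test-end tail.

    Compares the median MM over the pre-washin baseline with the median
    over the post-test-end tail; flags when |delta| strictly exceeds
    ``mm_step_max`` g/mol. Returns ``{"evaluable", "flag", "delta_gmol"}``.
    """
    fs = trace.sample_rate
    not_eval = {"evaluable": False, "flag": False, "delta_gmol": None}
    if markers.washin_start is None or markers.test_end is None:
        return not_eval
    base_end = table.insp_start[markers.washin_start - 1]
    tail_start = table.exp_end[markers.test_end - 1]
    if base_end < min_seconds * fs or (len(trace.mm) - tail_start) < min_seconds * fs:
        return not_eval
    delta = float(np.median(trace.mm[tail_start:]) - np.median(trace.mm[:base_end]))
    return {"evaluable": True, "flag": abs(delta) > mm_step_max, "delta_gmol": delta}


def check_equilibration(table: "BreathTable", markers: "PhaseMarkers",
                        tol: float = 0.0004, relative: bool = False,
                        n_breaths: int = 5) -> dict:
    """Washin equilibration check over the breaths preceding washout start.

    Computes max |c_insp_mean - c_et| over the ``n_breaths`` breaths
    before washout start; pass iff strictly below ``tol``. With
    ``relative=True`` the difference is divided by the mean inspired
    concentration first. Returns ``{"evaluable", "pass", "statistic"}``.
    """
    if markers.washout_start is None or markers.equilibration is None:
        return {"evaluable": False, "pass": False, "statistic": None}
    hi = markers.washout_start - 1
    lo = max(markers.equilibration, hi - n_breaths + 1)
    diffs = np.abs(table.c_insp_mean[lo - 1:hi] - table.c_et[lo - 1:hi])
    if relative:
        ci = table.c_insp_mean[lo - 1:hi]
        diffs = np.where(ci > 0, diffs / ci, np.inf)
    stat = float(diffs.max()) if diffs.size else float("inf")
    return {"evaluable": True, "pass": stat < tol, "statistic": stat}


def detect_all(trace: "GasTrace", table: "BreathTable", markers: "PhaseMarkers",
               cfg: RunConfig = RunConfig()) -> list[ArtefactEvent]:
    """Run every detector with the configured thresholds and stamp flags."""
    from .phases import stamp_critical_flags

    equilibrated = None
    if markers.equilibration is not None and table.has_gas:
        equilibrated = np.zeros(len(table), dtype=bool)
        end = markers.washout_start - 1 if markers.washout_start else len(table)
        equilibrated[markers.equilibration - 1:end] = True
    events = (
        detect_sighs(table, cfg.sigh_factor)
        + detect_breath_holds(trace, table, cfg.flow_eps_frac, cfg.breath_hold_breaths)
        + detect_leaks(trace, table, cfg.leak_step_frac, cfg.leak_drift_frac,
                       cfg.leak_insp_drop_frac, equilibrated)
        + detect_irregular_breathing(table, cfg.irregular_window, cfg.irregular_cv_max)
    )
    stamp_critical_flags(events, markers)
    return sorted(events, key=lambda e: (e.first_breath, e.kind))
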