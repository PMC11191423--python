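"""Automated identification of the critical test phases.

Locates washin start, equilibration, washout start, the test-end breath
(end-tidal tracer below 1/40th of the starting concentration for three
consecutive breaths) and the critical windows — five breaths before
washin/washout start to five breaths after the phase's end event —
within which artefacts force rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .config import RunConfig
from .errors import PhaseError

if TYPE_CHECKING:  # pragma: no cover
    from .breaths import BreathTable


@dataclass
class PhaseMarkers:
    """Breath-indexed washin/washout boundaries and critical windows.

    All indices are 1-based breath numbers; ``None`` marks an absent
    event. ``incomplete`` is set when the washout never reaches the
    test-end criterion (or the washin never equilibrates).
    """

    washin_start: int | None = None
    equilibration: int | None = None
    washout_start: int | None = None
    test_end: int | None = None
    c_start: float | None = None
    critical_washin: tuple[int, int] | None = None
    critical_washout: tuple[int, int] | None = None
    incomplete_washin: bool = False
    incomplete_washout: bool = False
    n_breaths: int = 0

    @property
    def incomplete(self) -> bool:
        return self.incomplete_washin or self.incomplete_washout

    def to_dict(self) -> dict:
        return {
            "washin_start": self.washin_start,
            "equilibration": self.equilibration,
            "washout_start": self.washout_start,
            "test_end": self.test_end,
            "c_start": self.c_start,
            "critical_washin": list(self.critical_washin) if self.critical_washin else None,
            "critical_washout": list(self.critical_washout) if self.critical_washout else None,
            "incomplete_washin": self.incomplete_washin,
            "incomplete_washout": self.incomplete_washout,
            "n_breaths": self.n_breaths,
        }


def critical_window(start: int, end_event: int, n_breaths: int,
                    margin: int = 5) -> tuple[int, int]:
    """Inclusive breath range [start - margin, end_event + margin],
    clamped to [1, n_breaths]."""
    if not (1 <= start <= end_event <= n_breaths):
        raise PhaseError(
            f"need 1 <= start ({start}) <= end_event ({end_event}) <= n ({n_breaths})")
    return max(1, start - margin), min(n_breaths, end_event + margin)


def find_phase_boundaries(table: "BreathTable", nominal_tracer_start: float = 0.04,
                          cfg: RunConfig = RunConfig()) -> PhaseMarkers:
    """Locate washin start, equilibration, washout start and c_start.

    * washin start — first breath with mean inspired tracer above 0.5%;
    * equilibration — first breath of the first run of three consecutive
      washin breaths with |c_insp_mean - c_et| below the equilibration
      tolerance (and washin gas actually present);
    * washout start — first breath after equilibration whose mean
      inspired tracer falls below half the equilibrated concentration;
    * c_start — end-tidal tracer of the last breath before washout start.
    """
    n = len(table)
    if n == 0 or not table.has_gas:
        raise PhaseError("no washin: trace carries no tracer signal")
    ci = table.c_insp_mean
    cet = table.c_et
    m = PhaseMarkers(n_breaths=n)

    washin = np.flatnonzero(ci > cfg.washin_detect_c)
    if washin.size == 0:
        raise PhaseError("no washin: inspired tracer never exceeds "
                         f"{cfg.washin_detect_c:g}")
    m.washin_start = int(washin[0]) + 1

    run = cfg.equilibration_run
    diffs = np.abs(ci - cet)
    if cfg.equilibration_relative:
        diffs = np.where(ci > 0, diffs / np.where(ci > 0, ci, 1.0), np.inf)
    ok = (diffs < cfg.equilibration_tol) & (ci > cfg.washin_detect_c)
    for i in range(m.washin_start - 1, n - run + 1):
        if ok[i:i + run].all():
            m.equilibration = i + 1
            break
    if m.equilibration is None:
        m.incomplete_washin = True
        return m

    c_equil = float(ci[m.equilibration - 1])
    after = np.flatnonzero(ci[m.equilibration:] < cfg.washout_detect_frac * c_equil)
    if after.size == 0:
        m.incomplete_washout = True
        return m
    m.washout_start = m.equilibration + 1 + int(after[0])
    m.c_start = float(cet[m.washout_start - 2])
    m.critical_washin = critical_window(
        m.washin_start, m.equilibration, n, cfg.critical_window_breaths)
    return m


def find_test_end(table: "BreathTable", markers: PhaseMarkers,
                  cfg: RunConfig = RunConfig()) -> int | None:
    """First breath e >= washout start with end-tidal tracer below
    c_start / 40 for ``test_end_run`` consecutive breaths; ``None`` (and
    ``incomplete_washout``) when no such run exists before the trace ends."""
    if markers.washout_start is None or markers.c_start is None:
        raise PhaseError("washout start and c_start must be set before test end")
    n = len(table)
    thr = markers.c_start / cfg.test_end_divisor
    run = cfg.test_end_run
    below = table.c_et < thr
    for e in range(markers.washout_start - 1, n - run + 1):
        if below[e:e + run].all():
            markers.test_end = e + 1
            markers.incomplete_washout = False
            markers.critical_washout = critical_window(
                markers.washout_start, markers.test_end, n, cfg.critical_window_breaths)
            return markers.test_end
    markers.test_end = None
    markers.incomplete_washout = True
    # a provisional critical window (washout start to trace end) still lets
    # artefact events be stamped on incomplete washouts
    markers.critical_washout = critical_window(
        markers.washout_start, n, n, cfg.critical_window_breaths)
    return None


def detect_phases(table: "BreathTable", nominal_tracer_start: float = 0.04,
                  cfg: RunConfig = RunConfig()) -> PhaseMarkers:
    """Full phase detection: boundaries, then the test-end criterion."""
    markers = find_phase_boundaries(table, nominal_tracer_start, cfg)
    if markers.washout_start is not None:
        find_test_end(table, markers, cfg)
    return markers


def stamp_critical_flags(events, markers: PhaseMarkers) -> None:
    """Set each event's in-critical flags from the phase markers."""
    for ev in events:
        if markers.critical_washin is not None:
            ev.in_critical_washin = ev.overlaps(*markers.critical_washin)
        if markers.critical_washout is not None:
            ev.in_critical_washout = ev.overlaps(*markers.critical_washout)
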