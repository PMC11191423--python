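"""MBW outcome parameters: FRC, CEV, LCI and washout breath count.

FRC follows from tracer mass balance over the washout: the net expired
tracer volume divided by the end-tidal concentration drop between
washout start and test end. LCI is the cumulative expired volume through
the test-end breath expressed in FRC turnovers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .errors import DegenerateWashoutError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .breaths import BreathTable
    from .phases import PhaseMarkers
    from .trace_io import GasTrace


@dataclass(frozen=True)
class MbwOutcomes:
    frc: float           # mL
    cev: float           # mL
    lci: float           # turnovers
    n_washout_breaths: int
    c_start: float
    c_end: float

    def __post_init__(self):
        if not (self.frc > 0 and self.cev > 0 and self.n_washout_breaths >= 1):
            raise ValidationError("outcomes require frc > 0, cev > 0, >= 1 washout breath")
        if abs(self.lci - self.cev / self.frc) > 1e-9 * max(1.0, self.lci):
            raise ValidationError("lci must equal cev/frc")

    def to_dict(self) -> dict:
        return {
            "frc_ml": self.frc, "cev_ml": self.cev, "lci": self.lci,
            "n_washout_breaths": self.n_washout_breaths,
            "c_start": self.c_start, "c_end": self.c_end,
        }


def compute_frc(trace: "GasTrace", table: "BreathTable", markers: "PhaseMarkers") -> float:
    """FRC (mL) by tracer mass balance over the washout.

    V_tr = sum over washout breaths of (expired - re-inspired tracer
    volume); FRC = V_tr / (c_start - c_end) with c_end the end-tidal
    tracer at the test-end breath.
    """
    if markers.test_end is None:
        raise DegenerateWashoutError("test end absent; washout incomplete")
    if trace.tracer is None:
        raise ValidationError("tracer channel required; run the gas model first")
    c_start = markers.c_start
    c_end = float(table.c_et[markers.test_end - 1])
    if not c_start > c_end:
        raise DegenerateWashoutError(
            f"tracer does not decay (c_start {c_start:.4f} <= c_end {c_end:.4f})")
    dt = 1.0 / trace.sample_rate
    v_tr = 0.0
    for b in range(markers.washout_start - 1, markers.test_end):
        s = int(table.insp_start[b])
        e = min(int(table.exp_end[b]) + 1, trace.n_samples)
        flow = trace.flow[s:e]
        c = trace.tracer[s:e]
        expired = np.trapezoid(c * np.maximum(-flow, 0.0), dx=dt)
        inspired = np.trapezoid(c * np.maximum(flow, 0.0), dx=dt)
        v_tr += expired - inspired
    return float(v_tr / (c_start - c_end))


def compute_lci(table: "BreathTable", markers: "PhaseMarkers", frc: float) -> MbwOutcomes:
    """CEV (mL) from washout start through the test-end breath inclusive;
    LCI = CEV / FRC. No dead-space subtraction (standard LCI convention)."""
    if markers.test_end is None:
        raise DegenerateWashoutError("test end absent; washout incomplete")
    if not frc > 0:
        raise ValidationError("frc must be positive")
    lo, hi = markers.washout_start - 1, markers.test_end
    cev = float(table.v_exp[lo:hi].sum())
    return MbwOutcomes(
        frc=frc, cev=cev, lci=cev / frc, n_washout_breaths=hi - lo,
        c_start=float(markers.c_start), c_end=float(table.c_et[hi - 1]))


def compute_outcomes(trace: "GasTrace", table: "BreathTable",
                     markers: "PhaseMarkers") -> MbwOutcomes:
    """FRC then LCI in one call."""
    frc = compute_frc(trace, table, markers)
    return compute_lci(table, markers, frc)
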