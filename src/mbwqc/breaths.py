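"""Breath segmentation of the tidal flow signal.

Breaths are delimited at inspiration-onset zero crossings of flow
(inspiration positive) with a hysteresis band to suppress sensor-noise
crossings. Per-breath features cover the tidal volumes, duration,
end-tidal and volume-weighted mean inspired tracer concentrations, and
the heat-map deviation statistic (tidal-volume difference of each breath
to the median tidal volume over the measurement).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterator

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError

if TYPE_CHECKING:  # pragma: no cover
    from .trace_io import GasTrace


@dataclass(frozen=True)
class Breath:
    """One breath: half-open sample spans [insp_start, exp_start) and
    [exp_start, exp_end), analysis features attached."""

    index: int
    insp_start: int
    exp_start: int
    exp_end: int
    v_insp: float
    v_exp: float
    duration: float
    peak_flow: float
    c_et: float | None = None
    c_insp_mean: float | None = None


class BreathTable:
    """Ordered per-breath segmentation record (columnar, 1-based indices)."""

    _COLUMNS = ("insp_start", "exp_start", "exp_end", "v_insp", "v_exp",
                "duration", "peak_flow", "c_et", "c_insp_mean")

    def __init__(self, insp_start, exp_start, exp_end, v_insp, v_exp,
                 duration, peak_flow, c_et=None, c_insp_mean=None):
        n = len(insp_start)
        self.insp_start = np.asarray(insp_start, dtype=int)
        self.exp_start = np.asarray(exp_start, dtype=int)
        self.exp_end = np.asarray(exp_end, dtype=int)
        self.v_insp = np.asarray(v_insp, dtype=float)
        self.v_exp = np.asarray(v_exp, dtype=float)
        self.duration = np.asarray(duration, dtype=float)
        self.peak_flow = np.asarray(peak_flow, dtype=float)
        self.c_et = np.full(n, np.nan) if c_et is None else np.asarray(c_et, dtype=float)
        self.c_insp_mean = (np.full(n, np.nan) if c_insp_mean is None
                            else np.asarray(c_insp_mean, dtype=float))

    def __len__(self) -> int:
        return len(self.insp_start)

    def __iter__(self) -> Iterator[Breath]:
        for i in range(len(self)):
            yield Breath(i + 1, int(self.insp_start[i]), int(self.exp_start[i]),
                         int(self.exp_end[i]), float(self.v_insp[i]),
                         float(self.v_exp[i]), float(self.duration[i]),
                         float(self.peak_flow[i]),
                         None if np.isnan(self.c_et[i]) else float(self.c_et[i]),
                         None if np.isnan(self.c_insp_mean[i]) else float(self.c_insp_mean[i]))

    @property
    def has_gas(self) -> bool:
        return len(self) > 0 and not np.all(np.isnan(self.c_et))

    @property
    def median_vt(self) -> float:
        """Median expiratory tidal volume over the whole measurement, mL."""
        return float(np.median(self.v_exp)) if len(self) else 0.0

    @property
    def median_duration(self) -> float:
        return float(np.median(self.duration)) if len(self) else 0.0

    def breaths_overlapping_samples(self, s: int, e: int) -> tuple[int, int] | None:
        """Inclusive 1-based breath range overlapping sample interval [s, e)."""
        hits = np.flatnonzero((self.insp_start < e) & (self.exp_end > s))
        if hits.size == 0:
            return None
        return int(hits[0]) + 1, int(hits[-1]) + 1

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({c: getattr(self, c) for c in self._COLUMNS})
        df.insert(0, "breath_index", np.arange(1, len(self) + 1))
        if len(self):
            df["deviation"] = tidal_volume_deviation(self)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _trapz(y: np.ndarray, dt: float) -> float:
    return float(np.trapezoid(y, dx=dt)) if len(y) > 1 else 0.0


def _hysteresis_threshold(flow: np.ndarray, sample_rate: float, frac: float) -> float:
    """frac times the running-median peak flow (median of 1-s block maxima)."""
    block = max(1, int(round(sample_rate)))
    n = len(flow)
    maxima = [np.max(np.abs(flow[i:i + block])) for i in range(0, n, block)]
    return frac * float(np.median(maxima)) if maxima else 0.0


def _insp_onsets(flow: np.ndarray, h: float) -> list[int]:
    """Debounced negative-to-positive crossings, backtracked to the true
    zero crossing (first sample after the last negative sample)."""
    onsets = []
    state = -1  # treat trace start as expiratory so a leading inspiration counts
    for i in range(len(flow)):
        f = flow[i]
        if state < 0 and f > h:
            j = i
            while j > 0 and flow[j - 1] >= 0:
                j -= 1
            if not onsets or j > onsets[-1]:
                onsets.append(j)
            state = 1
        elif state > 0 and f < -h:
            state = -1
    return onsets


def detect_breaths(trace: "GasTrace", min_volume_frac: float = 0.10,
                   hysteresis_flow: float | None = None,
                   hysteresis_frac: float = 0.02,
                   et_volume_frac: float = 0.05) -> BreathTable:
    """Segment the flow signal into breaths and compute per-breath features.

    Parameters
    ----------
    min_volume_frac : candidate breaths with v_exp below this fraction of
        the running-median v_exp are merged into a neighbour.
    hysteresis_flow : absolute hysteresis band in mL/s; when None it is
        ``hysteresis_frac`` times the running-median peak flow.
    et_volume_frac : the end-tidal concentration is the volume-weighted
        tracer mean over this last fraction of expired volume.

    A trace with no qualifying zero crossings yields an empty table (not
    an exception). Without a tracer channel, concentration features are
    reported as NaN.
    """
    flow = np.asarray(trace.flow, dtype=float)
    fs = float(trace.sample_rate)
    dt = 1.0 / fs
    h = (_hysteresis_threshold(flow, fs, hysteresis_frac)
         if hysteresis_flow is None else float(hysteresis_flow))

    onsets = _insp_onsets(flow, h)
    if not onsets:
        return BreathTable(*[[]] * 7)

    # raw breath spans: [onset_k, onset_{k+1}); the final breath runs to the
    # end of the trace if an expiration started
    spans: list[tuple[int, int, int]] = []  # (insp_start, exp_start, exp_end)
    bounds = onsets + [len(flow)]
    for k in range(len(onsets)):
        s, e = bounds[k], bounds[k + 1]
        neg = np.flatnonzero(flow[s:e] < -h)
        if neg.size == 0:
            continue  # inspiration without expiration (trailing partial)
        j = s + int(neg[0])
        while j > s and flow[j - 1] <= 0:
            j -= 1
        spans.append((s, j, e))

    if not spans:
        return BreathTable(*[[]] * 7)

    def vexp_of(span):
        s, _, e = span
        seg = flow[s:min(e + 1, len(flow))]
        return -_trapz(np.minimum(seg, 0.0), dt)

    # merge low-volume candidates into a neighbour (smaller-volume fragments
    # from noise crossings); running median over an 11-breath window
    changed = True
    while changed and len(spans) > 1:
        changed = False
        vexps = np.array([vexp_of(sp) for sp in spans])
        for i in range(len(spans)):
            lo, hi = max(0, i - 5), min(len(spans), i + 6)
            if vexps[i] < min_volume_frac * np.median(vexps[lo:hi]):
                if i > 0:  # extend previous breath over this fragment
                    s_prev, j_prev, _ = spans[i - 1]
                    spans[i - 1] = (s_prev, j_prev, spans[i][2])
                    del spans[i]
                else:      # absorb leading fragment into the next breath
                    s0 = spans[0][0]
                    s1, j1, e1 = spans[1]
                    spans[0:2] = [(s0, j1, e1)]
                changed = True
                break

    has_tracer = trace.tracer is not None
    tracer = np.asarray(trace.tracer, dtype=float) if has_tracer else None

    cols = {c: [] for c in ("insp_start", "exp_start", "exp_end", "v_insp",
                            "v_exp", "duration", "peak_flow", "c_et", "c_insp_mean")}
    for s, j, e in spans:
        seg = flow[s:min(e + 1, len(flow))]
        v_insp = _trapz(np.maximum(seg, 0.0), dt)
        v_exp = -_trapz(np.minimum(seg, 0.0), dt)
        cols["insp_start"].append(s)
        cols["exp_start"].append(j)
        cols["exp_end"].append(e)
        cols["v_insp"].append(v_insp)
        cols["v_exp"].append(v_exp)
        cols["duration"].append((e - s) * dt)
        cols["peak_flow"].append(float(seg.max()) if len(seg) else 0.0)
        if has_tracer:
            cols["c_insp_mean"].append(_weighted_conc(
                tracer[s:min(e + 1, len(flow))], np.maximum(seg, 0.0), dt))
            # stop at e (exclusive): sample e is the next breath's first
            # inspiration sample and already carries the next inspirate's gas
            cols["c_et"].append(_end_tidal(
                tracer[j:e], -np.minimum(flow[j:e], 0.0),
                dt, v_exp, et_volume_frac))
        else:
            cols["c_insp_mean"].append(np.nan)
            cols["c_et"].append(np.nan)
    return BreathTable(**cols)


def _weighted_conc(c: np.ndarray, w_flow: np.ndarray, dt: float) -> float:
    """Volume-weighted mean concentration: trapz(c*flow) / trapz(flow)."""
    denom = _trapz(w_flow, dt)
    if denom <= 0:
        return np.nan
    return _trapz(c * w_flow, dt) / denom


def _end_tidal(c: np.ndarray, eflow: np.ndarray, dt: float,
               v_exp: float, tail_frac: float) -> float:
    """Mean tracer over the last ``tail_frac`` of expired volume."""
    if v_exp <= 0 or len(c) < 2:
        return np.nan
    dv = (eflow[1:] + eflow[:-1]) * 0.5 * dt
    cmid = (c[1:] + c[:-1]) * 0.5
    cum = np.cumsum(dv)
    tail = cum >= (1.0 - tail_frac) * cum[-1]
    wsum = dv[tail].sum()
    if wsum <= 0:
        return float(c[-1])
    return float(np.dot(cmid[tail], dv[tail]) / wsum)


def tidal_volume_deviation(table: BreathTable) -> np.ndarray:
    """Heat-map statistic: (v_exp_i - median VT) / median VT per breath."""
    if len(table) == 0:
        raise UndefinedStatisticError("no breaths")
    if table.median_vt == 0:
        raise UndefinedStatisticError("median tidal volume is zero")
    return (table.v_exp - table.median_vt) / table.median_vt
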