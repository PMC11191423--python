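"""Synthetic infant SF6 multiple-breath washout trials with ground truth.

The generator emulates the measurement this package's QC rules were
designed for: a sleeping infant breathing tidally through an ultrasonic
flowmeter while 4% SF6 is washed in to equilibration and then washed out
with tracer-free gas.

Model structure (deliberately simple so every QC rule has a closed-form
oracle):

* flow — half-sine inspiration then half-sine expiration of equal
  volume per breath;
* lung — a single well-mixed alveolar compartment of volume FRC with a
  serial dead space VD; per breath the alveolar tracer fraction obeys
  C_n = c_ins + (C_{n-1} - c_ins) * FRC / (FRC + VT - VD),
  the washout geometric decay and its washin mirror image;
* sensor gas — inspirate carries the inspired mixture; the expirate
  shows dead-space gas for the first VD of expired volume, alveolar gas
  after, with a symmetric linear mixing front (width 0.4 VD) that keeps
  tracer mass balance exact;
* channels — O2/CO2 swing between inspired and alveolar values for the
  spiroware-like dialect; for the wbreath-like dialect they are held
  constant in the forward mixture (emulating the upstream vendor signal
  compensation) so molar mass is linear in tracer.

Artefacts are injectable with recorded ground-truth spans: sigh
(volume-scaled breath, mass balance conserved), breath hold (inserted
zero-flow pause), leak (constant flow bias over a breath span) and
irregular breathing (lognormal tidal-volume factors). Identical
configuration and seed reproduce bit-identical traces.

Default parameters are plausible six-week-infant values: FRC 100 mL,
VT 25 mL, VD 5 mL, 40 breaths/min, 4% SF6, 200 Hz sampling, noise off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .config import GasConstants
from .errors import ValidationError
from .gas_model import forward_mixture
from .trace_io import GasTrace

#: alveolar dry fractions used for the spiroware-like gas dynamics
O2_INSPIRED = 0.21
O2_ALVEOLAR = 0.17
CO2_ALVEOLAR = 0.038

_SPAN_DEFAULTS = {"sigh": 1, "breath_hold": 1, "leak": 7, "irregular_breathing": 10}
_MAGNITUDE_DEFAULTS = {"sigh": 1.8, "breath_hold": 2.5, "leak": 5.0,
                       "irregular_breathing": 0.5}


@dataclass(frozen=True)
class ArtefactSpec:
    """An artefact to inject: kind, first target breath (1-based), magnitude.

    Magnitude semantics by kind: sigh — tidal-volume factor; breath_hold
    — pause length in median breath durations; leak — flow bias in mL/s;
    irregular_breathing — lognormal sigma of the tidal-volume factors.
    ``n_breaths`` is the span length (defaults: sigh/hold 1, leak 7,
    irregular 10).
    """

    kind: str
    breath: int
    magnitude: float | None = None
    n_breaths: int | None = None

    def __post_init__(self):
        if self.kind not in _SPAN_DEFAULTS:
            raise ValidationError(f"cannot inject artefact kind {self.kind!r}")
        if self.breath < 1:
            raise ValidationError("target breath must be >= 1")

    @property
    def mag(self) -> float:
        return _MAGNITUDE_DEFAULTS[self.kind] if self.magnitude is None else self.magnitude

    @property
    def span(self) -> tuple[int, int]:
        n = _SPAN_DEFAULTS[self.kind] if self.n_breaths is None else self.n_breaths
        return self.breath, self.breath + n - 1


@dataclass(frozen=True)
class SimConfig:
    """Trial generator configuration (volumes in mL, rate in breaths/min)."""

    frc: float = 100.0
    vt: float = 25.0
    vd: float = 5.0
    rr: float = 40.0
    c0: float = 0.04
    n_baseline_breaths: int = 5
    n_washin_breaths: int = 35
    n_washout_breaths: int | None = None  # default: analytic test end + 8
    sample_rate: float = 200.0
    flow_noise_sd: float = 0.0   # relative, multiplicative per sample
    mm_noise_sd: float = 0.0     # g/mol, additive per sample
    setup_kind: str = "spiroware_like"
    artefacts: tuple[ArtefactSpec, ...] = ()
    seed: int = 0
    gas: GasConstants = field(default_factory=GasConstants)
    trial_id: str = "sim"

    def __post_init__(self):
        if not (self.frc > 0 and self.rr > 0 and 0 <= self.vd < self.vt):
            raise ValidationError("require frc > 0, rr > 0, 0 <= vd < vt")
        if not 0 < self.c0 < 1:
            raise ValidationError("c0 must lie in (0, 1)")
        if self.setup_kind not in ("spiroware_like", "wbreath_like"):
            raise ValidationError("setup_kind must be spiroware_like or wbreath_like")
        spans = sorted(s.span for s in self.artefacts)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValidationError(
                    f"overlapping artefact injections at breaths {a2}..{b1}")


@dataclass
class GroundTruth:
    """Everything the generator knows about the emitted trace."""

    breath_starts: list[int]          # inspiration-onset sample indices
    exp_starts: list[int]
    exp_ends: list[int]
    vt_breaths: list[float]           # per-breath tidal volume, mL
    c_alv: list[float]                # alveolar tracer after each breath
    c_ins: list[float]                # inspired tracer of each breath
    washin_start: int                 # 1-based breath indices
    washout_start: int
    equilibration: int | None
    test_end: int | None
    analytic_test_end: int            # washout breath count from the closed form
    analytic_lci: float
    c_start: float
    artefact_spans: list[dict]        # {kind, first_breath, last_breath}

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def analytic_test_end_breaths(frc: float, vt: float, vd: float = 0.0,
                              divisor: float = 40.0) -> int:
    """Closed-form washout breath count: ceil(ln d / ln((FRC+VT-VD)/FRC))."""
    return math.ceil(math.log(divisor) / math.log((frc + vt - vd) / frc))


def analytic_lci(frc: float, vt: float, vd: float = 0.0, divisor: float = 40.0) -> float:
    """Closed-form LCI for constant-VT, zero-noise trials."""
    return analytic_test_end_breaths(frc, vt, vd, divisor) * vt / frc


def _expirate_profile(vcum: np.ndarray, vd: float, c_ds: float, c_alv: float) -> np.ndarray:
    """Concentration vs cumulative expired volume: dead-space gas, then a
    symmetric linear front of width 0.4 VD centred at VD, then alveolar gas."""
    if vd <= 0:
        return np.full_like(vcum, c_alv)
    w = 0.4 * vd
    lo, hi = vd - w / 2, vd + w / 2
    out = np.where(vcum <= lo, c_ds,
                   np.where(vcum >= hi, c_alv,
                            c_ds + (c_alv - c_ds) * (vcum - lo) / w))
    return out


def simulate_trial(cfg: SimConfig) -> tuple[GasTrace, GroundTruth]:
    """Generate one trial; same config (incl. seed) -> bit-identical output."""
    rng = np.random.default_rng(cfg.seed)
    fs, dt = cfg.sample_rate, 1.0 / cfg.sample_rate
    dur = 60.0 / cfg.rr
    half = max(2, int(round(fs * dur / 2)))

    n_te = analytic_test_end_breaths(cfg.frc, cfg.vt, cfg.vd)
    n_washout = cfg.n_washout_breaths if cfg.n_washout_breaths is not None else n_te + 8
    n_total = cfg.n_baseline_breaths + cfg.n_washin_breaths + n_washout
    washin_start = cfg.n_baseline_breaths + 1
    washout_start = cfg.n_baseline_breaths + cfg.n_washin_breaths + 1

    # ---- breath plan -----------------------------------------------------
    vt_b = np.full(n_total, float(cfg.vt))
    hold_after = np.zeros(n_total)
    leak_spans: list[tuple[int, int, float]] = []
    artefact_spans: list[dict] = []
    for spec in cfg.artefacts:
        b1, b2 = spec.span
        if b2 > n_total:
            raise ValidationError(f"artefact span {b1}..{b2} beyond trial ({n_total} breaths)")
        if spec.kind == "sigh":
            vt_b[b1 - 1:b2] *= spec.mag
            artefact_spans.append({"kind": "sigh", "first_breath": b1, "last_breath": b2})
        elif spec.kind == "breath_hold":
            hold_after[b1 - 1] = spec.mag * dur
            artefact_spans.append({"kind": "breath_hold", "first_breath": b1,
                                   "last_breath": min(b1 + 1, n_total)})
        elif spec.kind == "leak":
            leak_spans.append((b1, b2, spec.mag))
            artefact_spans.append({"kind": "leak", "first_breath": b1, "last_breath": b2})
        else:  # irregular_breathing
            factors = rng.lognormal(mean=0.0, sigma=spec.mag, size=b2 - b1 + 1)
            vt_b[b1 - 1:b2] *= factors
            artefact_spans.append({"kind": "irregular_breathing",
                                   "first_breath": b1, "last_breath": b2})

    # ---- alveolar compartment recursion ----------------------------------
    c_ins = np.zeros(n_total)
    c_ins[washin_start - 1:washout_start - 1] = cfg.c0
    c_alv = np.zeros(n_total)
    c = 0.0
    for i in range(n_total):
        va = vt_b[i] - cfg.vd
        if va <= 0:
            raise ValidationError("per-breath tidal volume fell to the dead space")
        c = c_ins[i] + (c - c_ins[i]) * cfg.frc / (cfg.frc + va)
        c_alv[i] = c

    # ---- sample synthesis ------------------------------------------------
    t_half = np.arange(half) * dt
    sine = np.sin(np.pi * t_half / (half * dt))
    flow_parts, sf6_parts, o2_parts, co2_parts = [], [], [], []
    breath_starts, exp_starts, exp_ends = [], [], []
    spiro = cfg.setup_kind == "spiroware_like"
    pos = 0
    prev_et = (cfg.c0 * 0.0, O2_INSPIRED, 0.0)  # held values during a pause
    for i in range(n_total):
        amp = vt_b[i] * np.pi / (2 * half * dt)
        breath_starts.append(pos)
        # inspiration
        flow_parts.append(amp * sine)
        sf6_parts.append(np.full(half, c_ins[i]))
        o2_parts.append(np.full(half, O2_INSPIRED))
        co2_parts.append(np.zeros(half))
        pos += half
        exp_starts.append(pos)
        # expiration: cumulative expired volume, analytic half-sine form
        vcum = vt_b[i] * (1.0 - np.cos(np.pi * t_half / (half * dt))) / 2.0
        flow_parts.append(-amp * sine)
        sf6_parts.append(_expirate_profile(vcum, cfg.vd, c_ins[i], c_alv[i]))
        if spiro:
            o2_parts.append(_expirate_profile(vcum, cfg.vd, O2_INSPIRED, O2_ALVEOLAR))
            co2_parts.append(_expirate_profile(vcum, cfg.vd, 0.0, CO2_ALVEOLAR))
        else:
            o2_parts.append(np.full(half, O2_INSPIRED))
            co2_parts.append(np.zeros(half))
        pos += half
        exp_ends.append(pos)
        prev_et = (c_alv[i], O2_ALVEOLAR if spiro else O2_INSPIRED,
                   CO2_ALVEOLAR if spiro else 0.0)
        if hold_after[i] > 0:
            nh = int(round(hold_after[i] * fs))
            flow_parts.append(np.zeros(nh))
            sf6_parts.append(np.full(nh, prev_et[0]))
            o2_parts.append(np.full(nh, prev_et[1]))
            co2_parts.append(np.full(nh, prev_et[2]))
            pos += nh

    flow = np.concatenate(flow_parts)
    sf6 = np.concatenate(sf6_parts)
    o2 = np.concatenate(o2_parts)
    co2 = np.concatenate(co2_parts)

    for b1, b2, bias in leak_spans:
        s, e = breath_starts[b1 - 1], exp_ends[b2 - 1]
        flow[s:e] += bias

    if cfg.flow_noise_sd > 0:
        flow = flow * (1.0 + cfg.flow_noise_sd * rng.standard_normal(len(flow)))

    if not spiro:
        mm = forward_mixture(sf6, O2_INSPIRED, 0.0, cfg.gas)
    else:
        mm = forward_mixture(sf6, o2, co2, cfg.gas)
    mm = np.asarray(mm, dtype=float)
    if cfg.mm_noise_sd > 0:
        mm = mm + cfg.mm_noise_sd * rng.standard_normal(len(mm))

    trace = GasTrace(
        sample_rate=fs, flow=flow, mm=mm,
        o2=o2 if spiro else None, co2=co2 if spiro else None,
        setup_kind=cfg.setup_kind, nominal_tracer_start=cfg.c0,
        trial_id=f"{cfg.trial_id}-{cfg.seed:04d}",
    ).validate()

    # ---- ground-truth phase markers --------------------------------------
    c_start = float(c_alv[washout_start - 2])
    equil = None
    for i in range(washin_start - 1, washout_start - 3):
        if all(abs(c_ins[j] - c_alv[j]) < 0.0004 for j in range(i, i + 3)):
            equil = i + 1
            break
    test_end = None
    thr = c_start / 40.0
    for e in range(washout_start - 1, n_total - 2):
        if all(c_alv[j] < thr for j in range(e, e + 3)):
            test_end = e + 1
            break

    truth = GroundTruth(
        breath_starts=breath_starts, exp_starts=exp_starts, exp_ends=exp_ends,
        vt_breaths=vt_b.tolist(), c_alv=c_alv.tolist(), c_ins=c_ins.tolist(),
        washin_start=washin_start, washout_start=washout_start,
        equilibration=equil, test_end=test_end,
        analytic_test_end=n_te, analytic_lci=analytic_lci(cfg.frc, cfg.vt, cfg.vd),
        c_start=c_start, artefact_spans=artefact_spans,
    )
    return trace, truth


def inject_artefact(cfg: SimConfig, spec: ArtefactSpec) -> tuple[GasTrace, GroundTruth]:
    """Re-generate the trial with one more injected artefact.

    Regeneration (rather than editing emitted samples) keeps the
    compartment mass balance and ground truth consistent by
    construction; overlapping injections raise a validation error.
    """
    return simulate_trial(replace(cfg, artefacts=cfg.artefacts + (spec,)))
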