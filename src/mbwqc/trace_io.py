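"""Reading and writing MBW signal traces and reviewer annotations.

The original vendor export layouts are proprietary, so this package
defines two open tab-separated dialects (extension ``.mbw.tsv``):

* ``spiroware_like`` — columns ``flow_mls  mm_gmol  o2_frac  co2_frac``
  (unprocessed flow, molar mass, O2 and CO2 fractions);
* ``wbreath_like`` — columns ``flow_mls  mm_gmol`` (corrected flow and
  molar mass).

Files are UTF-8 with ``#``-prefixed header lines carrying ``format``,
``sample_rate_hz``, ``trial_id`` and ``tracer_start_frac``, then the
column header row and one row per sample. Decimal separator is ``.``;
NaN cells are forbidden. Flow is signed, inspiration positive, mL/s.

Reviewer annotations are stored as a JSON array of records (decision,
artefacts, reason, comment per trial/reviewer/phase).
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .artefacts import ARTEFACT_KINDS, ArtefactEvent
from .errors import ErrorTrial, FormatError, ParseError, SchemaError, ValidationError

log = logging.getLogger("mbwqc")

DIALECTS = ("spiroware_like", "wbreath_like")
_COLUMNS = {
    "spiroware_like": ["flow_mls", "mm_gmol", "o2_frac", "co2_frac"],
    "wbreath_like": ["flow_mls", "mm_gmol"],
}
TRACE_SUFFIX = ".mbw.tsv"


@dataclass
class GasTrace:
    """Uniformly sampled multichannel MBW recording.

    ``tracer`` is the derived SF6 dry fraction; it starts absent and is
    filled by the gas model. ``nominal_tracer_start`` is the inspired
    tracer fraction of the washin mixture (0.04 for 4% SF6).
    """

    sample_rate: float
    flow: np.ndarray
    mm: np.ndarray
    o2: np.ndarray | None = None
    co2: np.ndarray | None = None
    tracer: np.ndarray | None = None
    setup_kind: str = "spiroware_like"
    nominal_tracer_start: float = 0.04
    trial_id: str = "trial"

    def __post_init__(self):
        self.flow = np.asarray(self.flow, dtype=float)
        self.mm = np.asarray(self.mm, dtype=float)
        for ch in ("o2", "co2", "tracer"):
            v = getattr(self, ch)
            if v is not None:
                setattr(self, ch, np.asarray(v, dtype=float))

    @property
    def n_samples(self) -> int:
        return len(self.flow)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def channels(self) -> dict[str, np.ndarray]:
        out = {"flow": self.flow, "mm": self.mm}
        for ch in ("o2", "co2", "tracer"):
            v = getattr(self, ch)
            if v is not None:
                out[ch] = v
        return out

    def validate(self) -> "GasTrace":
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if self.setup_kind not in DIALECTS:
            raise ValidationError(f"setup_kind must be one of {DIALECTS}")
        n = self.n_samples
        if n < 1:
            raise ValidationError("trace must contain at least one sample")
        for name, ch in self.channels().items():
            if len(ch) != n:
                raise ValidationError(
                    f"channel {name!r} has {len(ch)} samples, flow has {n}")
            if np.any(~np.isfinite(ch)):
                raise ValidationError(f"channel {name!r} contains non-finite samples")
        if self.setup_kind == "spiroware_like":
            if self.o2 is None or self.co2 is None:
                raise ValidationError("spiroware_like traces require o2 and co2 channels")
        else:
            if self.o2 is not None or self.co2 is not None:
                raise ValidationError("wbreath_like traces must not carry o2/co2 channels")
        for name in ("o2", "co2", "tracer"):
            ch = getattr(self, name)
            if ch is not None and (np.any(ch < 0) or np.any(ch > 1)):
                raise ValidationError(f"fraction channel {name!r} outside [0, 1]")
        return self

    def allclose(self, other: "GasTrace", rtol: float = 1e-6) -> bool:
        if (self.setup_kind != other.setup_kind
                or not np.isclose(self.sample_rate, other.sample_rate)):
            return False
        a, b = self.channels(), other.channels()
        a.pop("tracer", None), b.pop("tracer", None)
        if a.keys() != b.keys():
            return False
        return all(np.allclose(a[k], b[k], rtol=rtol, atol=1e-12) for k in a)


def read_trace(path, dialect: str | None = None) -> GasTrace:
    """Read a trace file in either documented dialect.

    ``dialect`` may be omitted; it is then taken from the file's
    ``# format:`` header. Unknown extra columns are ignored with a
    warning; a missing mandatory column raises :class:`FormatError`; a
    non-numeric cell raises :class:`ParseError` with the line number; an
    empty data section raises :class:`ErrorTrial`.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    header_line_no = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#"):
            if ":" in line:
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
            continue
        if not line.strip():
            continue
        if header_line_no is None:
            header_line_no = lineno
        body_lines.append(line)

    if not body_lines:
        raise ErrorTrial(f"{path.name}: empty signal trace")

    file_dialect = meta.get("format")
    if dialect is None:
        dialect = file_dialect
    if dialect not in DIALECTS:
        raise FormatError(f"unknown or missing dialect {dialect!r}; expected one of {DIALECTS}")
    if file_dialect is not None and file_dialect != dialect:
        raise FormatError(
            f"requested dialect {dialect!r} but file declares {file_dialect!r}")

    columns = body_lines[0].split("\t")
    required = _COLUMNS[dialect]
    for col in required:
        if col not in columns:
            raise FormatError(f"missing mandatory column {col!r} for dialect {dialect!r}")
    extra = [c for c in columns if c not in required]
    if extra:
        log.warning("%s: ignoring unknown columns %s", path.name, extra)
    if len(body_lines) == 1:
        raise ErrorTrial(f"{path.name}: empty signal trace (no data rows)")

    # round_trip float parsing keeps write -> read bit-identical
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep="\t",
                     float_precision="round_trip")
    for col in required:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric or missing value {df[col].iloc[row]!r} in column {col!r}",
                line=(header_line_no or 0) + 1 + row)
        df[col] = numeric

    try:
        sample_rate = float(meta.get("sample_rate_hz", 200.0))
    except ValueError as exc:
        raise FormatError(f"bad sample_rate_hz header: {meta['sample_rate_hz']!r}") from exc
    trace = GasTrace(
        sample_rate=sample_rate,
        flow=df["flow_mls"].to_numpy(),
        mm=df["mm_gmol"].to_numpy(),
        o2=df["o2_frac"].to_numpy() if "o2_frac" in required else None,
        co2=df["co2_frac"].to_numpy() if "co2_frac" in required else None,
        setup_kind=dialect,
        nominal_tracer_start=float(meta.get("tracer_start_frac", 0.04)),
        trial_id=meta.get("trial_id", path.name.removesuffix(TRACE_SUFFIX)),
    )
    return trace.validate()


def write_trace(trace: GasTrace, path) -> Path:
    """Write a trace in its own dialect; the file re-reads to an equal
    trace (floats serialized with shortest round-tripping repr)."""
    trace.validate()
    path = Path(path)
    cols = {"flow_mls": trace.flow, "mm_gmol": trace.mm}
    if trace.setup_kind == "spiroware_like":
        cols["o2_frac"] = trace.o2
        cols["co2_frac"] = trace.co2
    header = (
        f"# format: {trace.setup_kind}\n"
        f"# sample_rate_hz: {trace.sample_rate!r}\n"
        f"# trial_id: {trace.trial_id}\n"
        f"# tracer_start_frac: {trace.nominal_tracer_start!r}\n"
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header)
        pd.DataFrame(cols).to_csv(fh, sep="\t", index=False, lineterminator="\n")
    return path


# --------------------------------------------------------------------------
# reviewer annotations

PHASES = ("washin", "washout")
DECISIONS = ("accept", "reject")


@dataclass
class AnnotationRecord:
    """One reviewer's decision for one phase of one trial."""

    trial_id: str
    reviewer_id: str
    phase: str
    decision: str
    artefacts: list[ArtefactEvent] = field(default_factory=list)
    reason: str = ""
    comment: str = ""

    def __post_init__(self):
        if self.phase not in PHASES:
            raise SchemaError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if self.decision not in DECISIONS:
            raise SchemaError(f"decision must be one of {DECISIONS}, got {self.decision!r}")
        if self.decision == "reject" and not self.reason and not self.artefacts:
            raise SchemaError("a reject decision requires a reason or artefacts")

    def to_dict(self) -> dict:
        return {
            "trial_id": self.trial_id,
            "reviewer_id": self.reviewer_id,
            "phase": self.phase,
            "decision": self.decision,
            "artefacts": [a.to_dict() for a in self.artefacts],
            "reason": self.reason,
            "comment": self.comment,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationRecord":
        artefacts = []
        for a in d.get("artefacts", []):
            if a.get("kind") not in ARTEFACT_KINDS:
                raise SchemaError(
                    f"unknown artefact kind {a.get('kind')!r}; "
                    f"allowed: {', '.join(ARTEFACT_KINDS)}")
            artefacts.append(ArtefactEvent.from_dict(a))
        return cls(
            trial_id=d["trial_id"], reviewer_id=d["reviewer_id"], phase=d["phase"],
            decision=d["decision"], artefacts=artefacts,
            reason=d.get("reason", ""), comment=d.get("comment", ""))


def read_annotations(path) -> list[AnnotationRecord]:
    """Read a JSON annotation file; duplicate (trial, reviewer, phase)
    tuples are rejected."""
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, list):
        raise SchemaError("annotation file must contain a JSON array of records")
    records = [AnnotationRecord.from_dict(d) for d in raw]
    seen = set()
    for r in records:
        key = (r.trial_id, r.reviewer_id, r.phase)
        if key in seen:
            raise SchemaError(f"duplicate annotation for {key}")
        seen.add(key)
    return records


def write_annotations(records: list[AnnotationRecord], path) -> Path:
    seen = set()
    for r in records:
        key = (r.trial_id, r.reviewer_id, r.phase)
        if key in seen:
            raise SchemaError(f"duplicate annotation for {key}")
        seen.add(key)
    path = Path(path)
    path.write_text(json.dumps([r.to_dict() for r in records], indent=1) + "\n",
                    encoding="utf-8")
    return path
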