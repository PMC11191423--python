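"""Run configuration: gas constants and every QC threshold in one place.

Defaults reproduce the published criteria for infant SF6 washout quality
control: sigh at 1.5x the median tidal volume, breath hold at 2 regular
tidal breath durations, test end at 1/40th of the starting tracer
concentration, critical windows of 5 breaths either side, and an
equilibration tolerance of 0.04 concentration points (%).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError

log = logging.getLogger("mbwqc")


@dataclass(frozen=True)
class GasConstants:
    """Molar masses of the dry-gas mixture components, g/mol.

    The balance gas lumps N2 with Ar at 28.16 g/mol, the usual
    respiratory mass-balance convention.
    """

    m_o2: float = 31.999
    m_co2: float = 44.01
    m_sf6: float = 146.06
    m_balance: float = 28.16
    c_equil: float = 0.04  # equilibrated SF6 fraction of the washin mixture

    def __post_init__(self):
        if not (self.m_sf6 > self.m_balance > 0 and self.m_o2 > 0 and self.m_co2 > 0):
            raise ValidationError("gas constants must be positive with m_sf6 > m_balance")


@dataclass
class RunConfig:
    """All tunable thresholds of the QC pipeline.

    Attributes
    ----------
    sigh_factor : sigh threshold as a multiple of the median tidal volume.
    breath_hold_breaths : minimum pause length in units of the median
        breath duration.
    test_end_divisor : the test-end criterion, end-tidal tracer below
        ``c_start / test_end_divisor`` (40 -> the 2.5% criterion).
    test_end_run : consecutive sub-threshold breaths required for test end.
    critical_window_breaths : breaths added either side of a phase.
    equilibration_tol : maximum |c_insp_mean - c_et| (absolute fraction).
    equilibration_run : consecutive breaths required at tolerance.
    equilibration_relative : interpret the tolerance relative to the mean
        inspired concentration instead of as absolute points.
    """

    # published constants
    sigh_factor: float = 1.5
    breath_hold_breaths: float = 2.0
    test_end_divisor: float = 40.0
    critical_window_breaths: int = 5
    equilibration_tol: float = 0.0004
    # documented package defaults
    test_end_run: int = 3
    equilibration_run: int = 3
    equilibration_relative: bool = False
    washin_detect_c: float = 0.005
    washout_detect_frac: float = 0.5
    min_volume_frac: float = 0.10
    hysteresis_frac: float = 0.02
    flow_eps_frac: float = 0.05
    leak_step_frac: float = 0.5
    leak_drift_frac: float = 0.05
    leak_insp_drop_frac: float = 0.10
    irregular_window: int = 10
    irregular_cv_max: float = 0.25
    mm_step_max: float = 0.3
    et_volume_frac: float = 0.05
    gas: GasConstants = field(default_factory=GasConstants)

    def __post_init__(self):
        if self.sigh_factor <= 1.0:
            raise ValidationError("sigh_factor must exceed 1")
        if self.test_end_divisor <= 1.0:
            raise ValidationError("test_end_divisor must exceed 1")
        if self.critical_window_breaths < 0:
            raise ValidationError("critical_window_breaths must be >= 0")
        if not 0 < self.min_volume_frac < 1:
            raise ValidationError("min_volume_frac must lie in (0, 1)")
        if self.irregular_window < 5:
            raise ValidationError("irregular_window must be >= 5")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config file; unknown keys are rejected, missing keys default.

        Gas constants live under the ``gas.*`` keys (``gas.m_o2`` etc.).
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValidationError("config file must contain a mapping")
        gas_kwargs = {}
        kwargs = {}
        valid = {f.name for f in dataclasses.fields(cls)}
        gas_valid = {f.name for f in dataclasses.fields(GasConstants)}
        for key, value in raw.items():
            if key == "gas" and isinstance(value, dict):
                for gk, gv in value.items():
                    if gk not in gas_valid:
                        raise ValidationError(f"unknown gas constant {gk!r}")
                    gas_kwargs[gk] = float(gv)
            elif key.startswith("gas."):
                gk = key[4:]
                if gk not in gas_valid:
                    raise ValidationError(f"unknown gas constant {gk!r}")
                gas_kwargs[gk] = float(value)
            elif key in valid:
                kwargs[key] = value
            else:
                raise ValidationError(f"unknown config key {key!r}")
        if gas_kwargs:
            kwargs["gas"] = GasConstants(**gas_kwargs)
        return cls(**kwargs)

    def replace(self, **overrides) -> "RunConfig":
        return dataclasses.replace(self, **overrides)
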