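"""SF6 tracer-fraction reconstruction from molar mass.

Two reconstructions are provided, matching the two export dialects:

* full-gas inversion — the molar mass of a dry mixture of SF6, O2, CO2
  and balance gas is linear in the component fractions, so with measured
  O2 and CO2 the SF6 fraction follows by inverting the mixture identity.
* two-point calibration — with only a molar-mass channel available, the
  tracer fraction is obtained from a linear map anchored at a tracer-free
  baseline and at the equilibrated washin plateau of known concentration.

Both operate samplewise on numpy arrays and clip to the physical [0, 1]
range. Water vapour is ignored (signals are assumed BTPS-handled
upstream); the model is dry-gas throughout.
"""

from __future__ import annotations

import numpy as np

from .config import GasConstants
from .errors import CalibrationError, SignalQualityError

#: physical plausibility band for a respiratory molar-mass signal, g/mol
MM_BAND = (20.0, 150.0)


def forward_mixture(sf6, o2, co2, constants: GasConstants = GasConstants()):
    """Molar mass (g/mol) of a dry SF6/O2/CO2/balance mixture.

    The balance-gas fraction is ``1 - sf6 - o2 - co2``. This is the
    forward model whose inversion is :func:`sf6_from_full_gas`.
    """
    sf6 = np.asarray(sf6, dtype=float)
    o2 = np.asarray(o2, dtype=float)
    co2 = np.asarray(co2, dtype=float)
    c = constants
    bal = 1.0 - sf6 - o2 - co2
    return c.m_sf6 * sf6 + c.m_o2 * o2 + c.m_co2 * co2 + c.m_balance * bal


def sf6_from_full_gas(mm, o2, co2, constants: GasConstants = GasConstants()):
    """Invert the dry-mixture identity for the SF6 fraction.

    F_sf6 = [mm - m_bal - o2 (m_o2 - m_bal) - co2 (m_co2 - m_bal)]
            / (m_sf6 - m_bal), clipped to [0, 1].

    Raises :class:`SignalQualityError` when mm leaves the [20, 150] g/mol
    plausibility band.
    """
    mm = np.asarray(mm, dtype=float)
    o2 = np.asarray(o2, dtype=float)
    co2 = np.asarray(co2, dtype=float)
    if np.any(mm < MM_BAND[0]) or np.any(mm > MM_BAND[1]):
        bad = mm[(mm < MM_BAND[0]) | (mm > MM_BAND[1])]
        raise SignalQualityError(
            f"molar mass outside plausibility band {MM_BAND}: e.g. {bad.flat[0]:.3f} g/mol"
        )
    c = constants
    num = mm - c.m_balance - o2 * (c.m_o2 - c.m_balance) - co2 * (c.m_co2 - c.m_balance)
    frac = num / (c.m_sf6 - c.m_balance)
    return np.clip(frac, 0.0, 1.0)


def sf6_from_mm_twopoint(mm, mm_baseline: float, mm_equil: float, c_equil: float = 0.04):
    """Two-point linear tracer calibration from molar mass alone.

    F_sf6 = c_equil * (mm - mm_baseline) / (mm_equil - mm_baseline),
    clipped to [0, 1]. ``mm_baseline`` is the tracer-free level,
    ``mm_equil`` the equilibrated-washin level at known fraction
    ``c_equil`` (0.04 for a 4% SF6 mixture).
    """
    if not mm_equil > mm_baseline:
        raise CalibrationError(
            f"mm_equil ({mm_equil:.4f}) must exceed mm_baseline ({mm_baseline:.4f})"
        )
    if not 0 < c_equil <= 1:
        raise CalibrationError("c_equil must lie in (0, 1]")
    mm = np.asarray(mm, dtype=float)
    frac = c_equil * (mm - mm_baseline) / (mm_equil - mm_baseline)
    return np.clip(frac, 0.0, 1.0)
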