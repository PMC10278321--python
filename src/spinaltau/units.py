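"""Unit conventions and conversion helpers.

The canonical unit system throughout the package is cm / s / g / ml, with
pressure expressed in cmH2O. A fluid column of density ``rho`` (g/ml) and
height ``h`` (cm) exerts ``rho * h`` cmH2O; for CSF-like fluids (rho ~ 1)
heights and pressures numerically coincide.

Viscosity enters Poiseuille's law as a pressure x time quantity and is
therefore carried in cmH2O.s. Vendor data sheets quote mPa.s, hence the
converter below.
"""

from __future__ import annotations

#: Pressure exerted by a 1 cm column of water, in pascal.
PA_PER_CMH2O = 98.0665

MM_PER_CM = 10.0


def viscosity_cmh2o_s(viscosity_mpa_s: float) -> float:
    """Convert a dynamic viscosity from mPa.s to cmH2O.s.

    1 mPa.s = 1e-3 Pa.s = 1e-3 / 98.0665 cmH2O.s, so water-like CSF
    (1.002 mPa.s at 20 C) is ~1.0218e-5 cmH2O.s.
    """
    return viscosity_mpa_s * 1e-3 / PA_PER_CMH2O


def mm_to_cm(value_mm: float) -> float:
    """Convert millimetres to the canonical centimetres."""
    return value_mm / MM_PER_CM
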