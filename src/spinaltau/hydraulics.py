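"""Core physics of the spinal needle-spinal manometer assembly.

A spinal manometer connected to a spinal needle behaves as a first-order
hydraulic system: flow through the needle is driven by the difference
between the CSF pressure ``P_CSF`` and the back-pressure ``rho*h(t)`` of
the fluid column already standing in the manometer,

    Q(t) = (P_CSF - rho*h(t)) / R,

and the column accumulates that flow over the manometer cross-section A,

    A dh/dt = (P_CSF - rho*h) / R.

The characteristic time constant is ``tau = R*A/rho`` and the step
response is the exponential saturation curve

    h(t) = (P_CSF/rho) * (1 - exp(-t/tau)).

All quantities use the canonical cm/s/g/ml system (see :mod:`spinaltau.units`):
pressures in cmH2O, resistances in cmH2O.s/ml, areas in cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import DomainError
from .units import viscosity_cmh2o_s


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise DomainError(f"{name} must be strictly positive, got {value!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluidProperties:
    """Density (g/ml) and dynamic viscosity (cmH2O.s) of the working fluid.

    Defaults describe CSF: density 1.0006 g/ml and viscosity 1.002 mPa.s
    at 20 C converted to the canonical pressure unit. Use
    :meth:`from_viscosity_mpa_s` when starting from a data-sheet value.
    """

    density: float = 1.0006
    dynamic_viscosity: float = viscosity_cmh2o_s(1.002)

    def __post_init__(self) -> None:
        _require_positive(density=self.density, dynamic_viscosity=self.dynamic_viscosity)

    @classmethod
    def from_viscosity_mpa_s(cls, density: float, viscosity_mpa_s: float) -> "FluidProperties":
        return cls(density=density, dynamic_viscosity=viscosity_cmh2o_s(viscosity_mpa_s))


#: CSF at 20 C (density 1.0006 g/ml, viscosity 1.002 mPa.s).
CSF = FluidProperties()

#: Round-number CSF used in desk calculations and table reproduction:
#: unit density and the conventional viscosity 1e-5 cmH2O.s.
CSF_NOMINAL = FluidProperties(density=1.0, dynamic_viscosity=1.0e-5)


@dataclass(frozen=True)
class NeedleSpec:
    """Geometry and/or measured hydraulic resistance of a spinal needle.

    At least one of ``inner_diameter`` (cm) or ``resistance``
    (cmH2O.s/ml) must be given: manufacturers publish outer diameters
    only, so the resistance is usually a bench measurement rather than a
    Poiseuille prediction.
    """

    name: str
    gauge: str
    length: float  # cm
    inner_diameter: Optional[float] = None  # cm
    outer_diameter: Optional[float] = None  # cm, informational
    resistance: Optional[float] = None  # cmH2O.s/ml, measured

    def __post_init__(self) -> None:
        _require_positive(length=self.length)
        if self.inner_diameter is None and self.resistance is None:
            raise DomainError(
                f"needle {self.name!r}: at least one of inner_diameter or "
                "resistance must be provided"
            )
        if self.inner_diameter is not None:
            _require_positive(inner_diameter=self.inner_diameter)
        if self.resistance is not None:
            _require_positive(resistance=self.resistance)
        if self.inner_diameter is not None and self.outer_diameter is not None:
            if not self.inner_diameter < self.outer_diameter:
                raise DomainError(
                    f"needle {self.name!r}: inner_diameter must be smaller "
                    "than outer_diameter"
                )

    def effective_resistance(self, fluid: FluidProperties = CSF) -> float:
        """Measured resistance if available, else the Poiseuille prediction."""
        if self.resistance is not None:
            return self.resistance
        return poiseuille_resistance(self.inner_diameter, self.length, fluid.dynamic_viscosity)


@dataclass(frozen=True)
class ManometerSpec:
    """A graduated manometer tube of circular bore."""

    bore_diameter: float  # cm

    def __post_init__(self) -> None:
        _require_positive(bore_diameter=self.bore_diameter)

    @property
    def area(self) -> float:
        """Inner cross-sectional area, cm^2."""
        return math.pi * self.bore_diameter**2 / 4.0


@dataclass(frozen=True)
class ReservoirSpec:
    """Constant-head supply reservoir feeding the needle.

    An adequate reservoir is much wider than the manometer
    (``diameter >= 10 x`` the manometer bore) so that filling the
    manometer drops the supply head by under 1%.
    """

    diameter: float  # cm
    height: float = 30.0  # cm

    def __post_init__(self) -> None:
        _require_positive(diameter=self.diameter)

    @property
    def area(self) -> float:
        return math.pi * self.diameter**2 / 4.0


@dataclass(frozen=True)
class DropMeasurement:
    """A gravimetric flow measurement: drops collected over a timed interval."""

    n_drops: int
    total_mass: float  # g
    duration: float  # s
    applied_pressure: float  # cmH2O

    def __post_init__(self) -> None:
        if not isinstance(self.n_drops, (int, np.integer)):
            raise DomainError(f"n_drops must be an integer, got {self.n_drops!r}")
        _require_positive(
            n_drops=self.n_drops,
            total_mass=self.total_mass,
            duration=self.duration,
            applied_pressure=self.applied_pressure,
        )


@dataclass(frozen=True)
class AssemblyModel:
    """A needle + manometer + fluid combination with its derived time constant."""

    needle: NeedleSpec
    manometer: ManometerSpec
    fluid: FluidProperties = CSF
    tau: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "tau",
            time_constant(self.resistance, self.manometer.area, self.fluid.density),
        )

    @property
    def resistance(self) -> float:
        return self.needle.effective_resistance(self.fluid)

    @classmethod
    def from_resistance(
        cls,
        resistance: float,
        bore_diameter: float,
        fluid: FluidProperties = CSF,
        name: str = "needle",
        gauge: str = "?",
        length: float = 9.0,
    ) -> "AssemblyModel":
        """Convenience constructor from a measured R and a manometer bore."""
        needle = NeedleSpec(name=name, gauge=gauge, length=length, resistance=resistance)
        return cls(needle=needle, manometer=ManometerSpec(bore_diameter=bore_diameter), fluid=fluid)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def poiseuille_resistance(d: float, L: float, mu: float) -> float:
    """Laminar-flow resistance 128*mu*L/(pi*d^4) of a cylindrical needle.

    Parameters are the inner diameter ``d`` (cm), length ``L`` (cm) and
    dynamic viscosity ``mu`` (cmH2O.s); the result is in cmH2O.s/ml.
    Resistance scales with the inverse fourth power of the bore, which is
    why nominally identical gauges from different brands can differ
    substantially.
    """
    _require_positive(d=d, L=L, mu=mu)
    return 128.0 * mu * L / (math.pi * d**4)


def flow_rate_from_drops(measurement: DropMeasurement, fluid: FluidProperties = CSF) -> float:
    """Volumetric flow rate (ml/s) from a drop-weight measurement.

    Q = m / (rho * dt): total collected mass divided by fluid density and
    collection time.
    """
    if not measurement.duration > 0:
        raise DomainError("duration must be strictly positive")
    return measurement.total_mass / (fluid.density * measurement.duration)


def resistance_from_flow(delta_p: float, q: float) -> float:
    """Hydraulic resistance R = dP/Q (cmH2O.s/ml) from a driving pressure and flow."""
    if not q > 0:
        raise DomainError(f"q must be strictly positive, got {q!r}")
    return delta_p / q


def time_constant(R: float, A: float, rho: float) -> float:
    """Time constant tau = R*A/rho (s) of a needle-manometer assembly."""
    _require_positive(R=R, A=A, rho=rho)
    return R * A / rho


def rise_height(t, p_csf: float, tau: float, rho: float = 1.0):
    """Manometer column height h(t) = (P/rho)(1 - exp(-t/tau)) in cm.

    Accepts scalar or array ``t`` (s). Monotone nondecreasing, h(0) = 0,
    asymptote ``p_csf/rho``.
    """
    _require_positive(tau=tau, rho=rho)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be nonnegative")
    h = (p_csf / rho) * (1.0 - np.exp(-t / tau))
    return float(h) if h.ndim == 0 else h


def time_to_fraction(r: float, tau: float) -> float:
    """Time (s) to reach a fraction ``r`` in (0, 1) of the equilibrium height.

    t = -tau*ln(1 - r); independent of the equilibrium pressure itself,
    which is what makes early-reading extrapolation possible. r = 1 is
    rejected: equilibrium is approached only asymptotically.
    """
    _require_positive(tau=tau)
    if not 0.0 < r < 1.0:
        raise DomainError(f"r must lie strictly inside (0, 1), got {r!r}")
    return -tau * math.log1p(-r)


def extrapolate_equilibrium(h: float, t: float, tau: float, rho: float = 1.0) -> float:
    """Equilibrium CSF pressure (cmH2O) inferred from one early reading.

    Inverts the step response: P = rho*h / (1 - exp(-t/tau)). On a
    noiseless first-order rise this recovers the true equilibrium
    pressure from a reading at any t > 0, so there is no need to wait
    for the column to stop.
    """
    _require_positive(tau=tau, rho=rho)
    if not t > 0:
        raise DomainError(f"t must be strictly positive, got {t!r}")
    if not h > 0:
        raise DomainError(f"h must be strictly positive, got {h!r}")
    return rho * h / (-math.expm1(-t / tau))


def cutoff_frequency(tau: float) -> float:
    """3 dB cut-off frequency f_c = 1/(2*pi*tau) in Hz of the assembly."""
    _require_positive(tau=tau)
    return 1.0 / (2.0 * math.pi * tau)


def gain(f, tau: float):
    """Normalized low-pass magnitude response |H(f)|/|H(0)| = 1/sqrt(1+(2*pi*f*tau)^2).

    Equals 1/sqrt(2) at the cut-off frequency. At respiratory (~0.3 Hz)
    and cardiac (>1 Hz) frequencies the attenuation is so strong that
    physiological pulsation is invisible in the manometer column.
    """
    _require_positive(tau=tau)
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise DomainError("f must be nonnegative")
    g = 1.0 / np.sqrt(1.0 + (2.0 * math.pi * f * tau) ** 2)
    return float(g) if g.ndim == 0 else g


def reservoir_pressure_drop_fraction(
    reservoir: ReservoirSpec,
    manometer: ManometerSpec,
    h_eq: float,
    supply_height: Optional[float] = None,
) -> float:
    """Fractional supply-head drop caused by filling the manometer.

    Volume conservation at equilibrium: the manometer takes up
    ``A * h_eq`` of fluid, lowering the reservoir level by
    ``(A/A*) * h_eq``. Relative to the supply head ``supply_height``
    (defaults to ``h_eq``, i.e. a reservoir set exactly to the target
    pressure) the drop is ``(A/A*) * h_eq / supply_height``. A reservoir
    at least 10x the manometer bore keeps this under 1%.
    """
    _require_positive(h_eq=h_eq)
    if supply_height is None:
        supply_height = h_eq
    _require_positive(supply_height=supply_height)
    if not reservoir.area > 0:
        raise DomainError("reservoir area must be strictly positive")
    return (manometer.area / reservoir.area) * h_eq / supply_height
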