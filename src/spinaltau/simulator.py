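"""Numerical simulation of the manometer rise and synthetic data generation.

The governing balance ``A dh/dt = (P(t) - rho*h)/R`` is integrated with a
fixed-step classic Runge-Kutta (RK4) scheme, optionally under pulsatile
forcing (sinusoidal cardiac and respiratory components superimposed on
the mean CSF pressure). A graduation-reading emulator converts traces
into the same (height, time) records produced at the bench, and a seeded
generator adds observation noise for parameter-recovery studies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List

import numpy as np

from .exceptions import ConfigurationError, DomainError
from .hydraulics import AssemblyModel
from .estimation import RiseDataset

logger = logging.getLogger(__name__)

__all__ = [
    "PulsatileForcing",
    "SimulationConfig",
    "SimulatedTrace",
    "simulate_rise",
    "crossing_times",
    "generate_noisy_rise",
]


@dataclass(frozen=True)
class PulsatileForcing:
    """CSF pressure waveform: mean level plus sinusoidal pulsations.

    Amplitudes are column heights in cm. Defaults carry the typical
    lumbar values — cardiac pulsation of 1-2 mm at just over 1 Hz and
    respiratory swing of 2-5 mm at ~0.3 Hz (20 breaths/min) — but both
    amplitudes must be switched on explicitly via
    :meth:`physiological`; :meth:`constant` describes the constant-head
    bench reservoir.
    """

    mean_pressure: float  # cmH2O
    cardiac_amplitude: float = 0.0  # cm
    cardiac_frequency: float = 1.2  # Hz
    respiratory_amplitude: float = 0.0  # cm
    respiratory_frequency: float = 0.3  # Hz

    def __post_init__(self) -> None:
        if self.cardiac_amplitude < 0 or self.respiratory_amplitude < 0:
            raise DomainError("pulsation amplitudes must be nonnegative")
        if self.cardiac_amplitude > 0 and not self.cardiac_frequency > 0:
            raise DomainError("cardiac_frequency must be positive when its amplitude is set")
        if self.respiratory_amplitude > 0 and not self.respiratory_frequency > 0:
            raise DomainError("respiratory_frequency must be positive when its amplitude is set")

    @classmethod
    def constant(cls, mean_pressure: float) -> "PulsatileForcing":
        return cls(mean_pressure=mean_pressure)

    @classmethod
    def physiological(cls, mean_pressure: float, deep_breathing: bool = False) -> "PulsatileForcing":
        """Typical lumbar pulsation: 1.5 mm cardiac, 3.5 mm (or 7.5 mm deep) respiratory."""
        return cls(
            mean_pressure=mean_pressure,
            cardiac_amplitude=0.15,
            cardiac_frequency=1.2,
            respiratory_amplitude=0.75 if deep_breathing else 0.35,
            respiratory_frequency=0.3,
        )

    def pressure(self, t) -> np.ndarray:
        """Instantaneous driving pressure P(t) in cmH2O."""
        t = np.asarray(t, dtype=float)
        p = np.full_like(t, self.mean_pressure)
        if self.cardiac_amplitude > 0:
            p = p + self.cardiac_amplitude * np.sin(2 * math.pi * self.cardiac_frequency * t)
        if self.respiratory_amplitude > 0:
            p = p + self.respiratory_amplitude * np.sin(2 * math.pi * self.respiratory_frequency * t)
        return p


@dataclass(frozen=True)
class SimulationConfig:
    """Integration grid, reading protocol and noise settings."""

    time_step: float  # s
    duration: float  # s
    observation_noise_sd: float = 0.0  # cm, meniscus-reading error
    rng_seed: int = 0
    graduation_step: float = 1.0  # cm

    def __post_init__(self) -> None:
        if not self.time_step > 0:
            raise ConfigurationError("time_step must be strictly positive")
        if not self.duration > self.time_step:
            raise ConfigurationError("duration must exceed time_step")
        if self.observation_noise_sd < 0:
            raise ConfigurationError("observation_noise_sd must be nonnegative")
        if not self.graduation_step > 0:
            raise ConfigurationError("graduation_step must be strictly positive")


@dataclass(frozen=True)
class SimulatedTrace:
    """A sampled h(t) trajectory with its provenance."""

    times: np.ndarray
    heights: np.ndarray
    forcing: PulsatileForcing
    assembly_description: str

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        heights = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "heights", heights)
        if times.shape != heights.shape:
            raise DomainError("times and heights must have the same length")


def simulate_rise(
    assembly: AssemblyModel,
    forcing: PulsatileForcing,
    config: SimulationConfig,
) -> SimulatedTrace:
    """Integrate A dh/dt = (P(t) - rho*h)/R from a dry manometer, h(0) = 0.

    Classic fixed-step RK4; the step must not exceed tau/10 (accuracy
    guard — with constant forcing the local behaviour is governed by
    exp(-t/tau), and a coarser grid under-resolves it).
    """
    tau = assembly.tau
    if config.time_step > tau / 10.0:
        raise ConfigurationError(
            f"time_step {config.time_step} s exceeds tau/10 = {tau / 10.0:.4g} s"
        )
    rho = assembly.fluid.density
    RA = assembly.resistance * assembly.manometer.area

    def dhdt(t: float, h: float) -> float:
        return (float(forcing.pressure(t)) - rho * h) / RA

    n_steps = int(math.floor(config.duration / config.time_step))
    dt = config.time_step
    times = np.empty(n_steps + 1)
    heights = np.empty(n_steps + 1)
    t, h = 0.0, 0.0
    times[0] = t
    heights[0] = h
    for i in range(1, n_steps + 1):
        k1 = dhdt(t, h)
        k2 = dhdt(t + dt / 2.0, h + dt * k1 / 2.0)
        k3 = dhdt(t + dt / 2.0, h + dt * k2 / 2.0)
        k4 = dhdt(t + dt, h + dt * k3)
        h = h + dt * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
        t = i * dt
        times[i] = t
        heights[i] = h
    desc = (
        f"R={assembly.resistance:g} cmH2O.s/ml, bore={assembly.manometer.bore_diameter:g} cm, "
        f"rho={rho:g} g/ml, tau={tau:g} s"
    )
    return SimulatedTrace(times=times, heights=heights, forcing=forcing, assembly_description=desc)


def crossing_times(
    trace: SimulatedTrace,
    graduation_step: float,
    max_height: float,
    needle_label: str = "sim",
    replicate_label: str = "M1",
) -> RiseDataset:
    """First-passage times of the trace through each graduation line.

    For every level ``k*graduation_step <= max_height`` the first time the
    trace reaches it is located and refined by linear interpolation
    between the bracketing samples. Graduations the trace never attains
    are logged as missing and omitted — never fabricated.
    """
    if not graduation_step > 0:
        raise DomainError("graduation_step must be strictly positive")
    levels = np.arange(graduation_step, max_height + graduation_step / 2.0, graduation_step)
    t, h = trace.times, trace.heights
    times_out: List[float] = []
    heights_out: List[float] = []
    missing: List[float] = []
    for level in levels:
        idx = np.argmax(h >= level)
        if h[idx] < level:  # argmax returned 0 because no sample qualifies
            missing.append(float(level))
            continue
        if idx == 0:
            crossing = t[0]
        else:
            h0, h1 = h[idx - 1], h[idx]
            crossing = t[idx - 1] + (level - h0) / (h1 - h0) * (t[idx] - t[idx - 1])
        times_out.append(float(crossing))
        heights_out.append(float(level))
    if missing:
        logger.warning(
            "graduations never reached within the trace duration: %s",
            ", ".join(f"{m:g} cm" for m in missing),
        )
    return RiseDataset.from_arrays(needle_label, replicate_label, times_out, heights_out)


def generate_noisy_rise(
    assembly: AssemblyModel,
    p_csf: float,
    config: SimulationConfig,
    n_replicates: int = 1,
) -> List[RiseDataset]:
    """Seeded synthetic graduation readings from a constant-head rise.

    The noiseless constant-forcing solution is evaluated on the
    configured grid and read at each graduation; the observation noise
    (sd in cm) models the meniscus-reading error and is mapped to a time
    jitter through the local slope of the rise curve, keeping graduation
    heights exact as at the bench. Zero noise reduces to
    :func:`crossing_times` of the closed form. Deterministic for a given
    ``rng_seed``.
    """
    if not p_csf > 0:
        raise DomainError("p_csf must be strictly positive")
    tau = assembly.tau
    if config.time_step > tau / 10.0:
        raise ConfigurationError(
            f"time_step {config.time_step} s exceeds tau/10 = {tau / 10.0:.4g} s"
        )
    rho = assembly.fluid.density
    h_inf = p_csf / rho
    grid = np.arange(0.0, config.duration + config.time_step / 2.0, config.time_step)
    heights = h_inf * (1.0 - np.exp(-grid / tau))
    trace = SimulatedTrace(
        times=grid,
        heights=heights,
        forcing=PulsatileForcing.constant(p_csf),
        assembly_description=f"closed-form rise, tau={tau:g} s",
    )
    max_height = float(heights[-1])
    rng = np.random.default_rng(config.rng_seed)
    datasets: List[RiseDataset] = []
    for rep in range(n_replicates):
        base = crossing_times(
            trace,
            config.graduation_step,
            max_height,
            needle_label="synthetic",
            replicate_label=f"M{rep + 1}",
        )
        t_obs = base.times
        h_obs = base.heights
        if config.observation_noise_sd > 0:
            slope = (h_inf - h_obs) / tau  # dh/dt at each graduation
            eps = rng.normal(0.0, config.observation_noise_sd, size=len(t_obs))
            t_obs = t_obs + eps / slope
            # a reading cannot precede the previous graduation's reading
            t_obs = np.maximum.accumulate(np.maximum(t_obs, 1e-9))
            t_obs += np.arange(len(t_obs)) * 1e-9  # break exact ties
        datasets.append(
            RiseDataset.from_arrays("synthetic", f"M{rep + 1}", t_obs, h_obs)
        )
    return datasets
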