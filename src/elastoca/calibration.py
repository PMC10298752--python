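"""Physical time/length-scale calibration of the lattice model.

The lattice length scale is fixed by biology: the minimum tropoelastin-sphere
diameter is ~1 um, so one cell is lambda_l = 1 um. The time scale follows
from the random-walk relation the model adopts,

    lambda_l^2 = 2 D lambda_t                                   (walk relation)

with the diffusion coefficient of a 1-um particle in the extracellular fluid
given by the Stokes-Einstein form used there,

    D = k_B T / (3 pi eta d).                                   (Stokes-Einstein)

With eta = 1.9 Pa.s, d = 1 um and body temperature this gives
D ~ 2.4e-16 m^2/s and lambda_t ~ 2072 s ~ 0.024 days per step, so a 500-step
production window corresponds to ~12 days of postnatal development.

Note the factor 2 in the walk relation is the model's fixed convention,
although the per-axis convention for a 2-D walk would read 4 D lambda_t;
the calibration is a convention, not a physical claim, and changing it would
silently rescale every day-denominated output.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "BOLTZMANN",
    "PhysicalScales",
    "stokes_einstein_D",
    "time_scale",
    "steps_to_days",
    "days_to_steps",
    "standard_scales",
]

#: Boltzmann constant, J/K (2018 CODATA exact value)
BOLTZMANN = 1.380649e-23

#: defaults: body temperature, extracellular-fluid viscosity, 1-um particle
DEFAULT_T = 310.0
DEFAULT_ETA = 1.9
DEFAULT_D_PARTICLE = 1e-6
DEFAULT_LAMBDA_L = 1e-6

SECONDS_PER_DAY = 86400.0


def _require_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")


def stokes_einstein_D(T: float = DEFAULT_T, eta: float = DEFAULT_ETA,
                      d: float = DEFAULT_D_PARTICLE) -> float:
    """Diffusion coefficient k_B T / (3 pi eta d) in m^2/s.

    Parameters are temperature (K), dynamic viscosity (Pa.s) and particle
    diameter (m).
    """
    _require_positive(T=T, eta=eta, d=d)
    import math

    return BOLTZMANN * T / (3.0 * math.pi * eta * d)


def time_scale(lambda_l: float = DEFAULT_LAMBDA_L, D: float | None = None) -> float:
    """Seconds per simulation step from lambda_l^2 = 2 D lambda_t."""
    if D is None:
        D = stokes_einstein_D()
    _require_positive(lambda_l=lambda_l, D=D)
    return lambda_l**2 / (2.0 * D)


def steps_to_days(steps: float, lambda_t: float) -> float:
    """Convert a step count to days at lambda_t seconds per step."""
    if steps < 0:
        raise ValueError("steps must be >= 0")
    _require_positive(lambda_t=lambda_t)
    return steps * lambda_t / SECONDS_PER_DAY


def days_to_steps(days: float, lambda_t: float) -> float:
    """Inverse of :func:`steps_to_days` (real-valued; round as needed)."""
    if days < 0:
        raise ValueError("days must be >= 0")
    _require_positive(lambda_t=lambda_t)
    return days * SECONDS_PER_DAY / lambda_t


@dataclass(frozen=True)
class PhysicalScales:
    """Bundle of the physical constants behind the step/pixel units."""

    T: float = DEFAULT_T
    eta: float = DEFAULT_ETA
    d: float = DEFAULT_D_PARTICLE
    lambda_l: float = DEFAULT_LAMBDA_L
    k_B: float = BOLTZMANN

    def __post_init__(self) -> None:
        _require_positive(T=self.T, eta=self.eta, d=self.d, lambda_l=self.lambda_l)

    @property
    def D(self) -> float:
        return stokes_einstein_D(self.T, self.eta, self.d)

    @property
    def lambda_t(self) -> float:
        return time_scale(self.lambda_l, self.D)

    def steps_to_days(self, steps: float) -> float:
        return steps_to_days(steps, self.lambda_t)

    def days_to_steps(self, days: float) -> float:
        return days_to_steps(days, self.lambda_t)


def standard_scales() -> PhysicalScales:
    """Scales at the default constants (310 K, 1.9 Pa.s, 1-um particle/pixel)."""
    return PhysicalScales()
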