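"""Physical constants for air and aerosol particles.

Air properties are for room-temperature inhaled air; particle density
defaults to unit density (1000 kg/m^3) so that the geometric diameter of a
sphere equals its aerodynamic diameter.
"""

AIR_DENSITY = 1.204
"""Air density, kg/m^3."""

AIR_VISCOSITY = 1.825e-5
"""Dynamic viscosity of air, kg/(m s)."""

PARTICLE_DENSITY = 1000.0
"""Default particle density, kg/m^3 (unit-density sphere)."""

GRAVITY = 9.81
"""Gravitational acceleration magnitude, m/s^2."""

LPM_TO_M3S = 1e-3 / 60.0
"""Conversion factor: L/min -> m^3/s."""

LPM_TO_MLS = 1000.0 / 60.0
"""Conversion factor: L/min -> mL/s."""


def relaxation_time(d_p: float, rho_p: float = PARTICLE_DENSITY,
                    mu: float = AIR_VISCOSITY) -> float:
    """Particle relaxation time tau = rho_p d_p^2 / (18 mu), seconds."""
    return rho_p * d_p * d_p / (18.0 * mu)


def stokes_settling_velocity(d_p: float, rho_p: float = PARTICLE_DENSITY,
                             mu: float = AIR_VISCOSITY,
                             g: float = GRAVITY) -> float:
    """Stokes terminal settling velocity rho_p d_p^2 g / (18 mu), m/s."""
    return relaxation_time(d_p, rho_p, mu) * g
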