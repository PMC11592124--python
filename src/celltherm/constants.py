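"""Physical constants, SI throughout.

The defaults are the rounded values conventional in membrane
electrophysiology (R = 8.314 J mol⁻¹ K⁻¹, F = 96485 C mol⁻¹); a
:class:`PhysicalConstants` instance with different values can be passed to
any operation that takes a ``constants`` argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["PhysicalConstants", "CONSTANTS", "celsius_to_kelvin", "kelvin_to_celsius"]

KELVIN_OFFSET = 273.15

_EPS0 = 8.854e-12
_MU0 = 4e-7 * math.pi
# Derived so that c = 1/sqrt(mu0*eps0) holds to machine precision with the
# rounded eps0 above; differs from the defined SI value by ~1e-5 relative.
_C0 = 1.0 / math.sqrt(_MU0 * _EPS0)


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + KELVIN_OFFSET


def kelvin_to_celsius(t_kelvin: float) -> float:
    return t_kelvin - KELVIN_OFFSET


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of the physical constants the model uses.

    Attributes
    ----------
    gas_constant : float
        Universal gas constant R, J mol⁻¹ K⁻¹.
    faraday : float
        Faraday constant F, C mol⁻¹.
    vacuum_permittivity : float
        ε₀, A s N⁻¹ m⁻² (≡ F m⁻¹).
    vacuum_permeability : float
        μ₀, H m⁻¹.
    light_speed : float
        c, m s⁻¹; must satisfy c = 1/√(μ₀ε₀) to a relative 1e-4.
    """

    gas_constant: float = 8.314
    faraday: float = 96485.0
    vacuum_permittivity: float = _EPS0
    vacuum_permeability: float = _MU0
    light_speed: float = _C0

    def __post_init__(self) -> None:
        for name in ("gas_constant", "faraday", "vacuum_permittivity",
                     "vacuum_permeability", "light_speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        c_derived = 1.0 / math.sqrt(self.vacuum_permeability * self.vacuum_permittivity)
        if abs(self.light_speed - c_derived) / c_derived > 1e-4:
            raise ValueError(
                "light_speed inconsistent with 1/sqrt(mu0*eps0): "
                f"{self.light_speed:.6e} vs {c_derived:.6e}"
            )


#: Default constants shared by every operation.
CONSTANTS = PhysicalConstants()
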