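"""First-law energy balance of sodium transport across the cell membrane.

This module links the Na⁺ flux density through the membrane, the electric
power it dissipates, the resulting cell temperature change, the convective
heat exchange with the bath, and the temperature dependence of the sodium
equilibrium potential.  The chain identity at its core is

    Q̇ = −α (T − T₀) A = ρ c V dT/dt = J_Na · E · 4πR² · d_memb

for a spherical cell of radius R, membrane thickness d_memb, area
A = 4πR² and volume V = 4πR³/3.

Sign conventions (the single authoritative table)
-------------------------------------------------
===================  ====================================================
quantity             convention
===================  ====================================================
membrane potential   cytosol minus bath; negative at rest (≈ −70 mV)
membrane field       potential / thickness; negative at rest
heat power Q̇         positive INTO the cell; outflow to a cooler bath < 0
Na⁺ flux density J   positive for INFLOW of Na⁺
===================  ====================================================

Under these conventions "the cell exports heat ⟹ Na⁺ flows out"
(Q̇ < 0 ⟹ J < 0).  Because the product J·E couples two signed
magnitudes whose physical pairing is through their moduli, the heat→flux
inversion :func:`sodium_flux_from_heat` divides by the *magnitude* of the
field so that sign(J) = sign(Q̇) holds for every field orientation; its
exact inverse is ``electric_power_sodium(J, abs(E), geometry)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .constants import CONSTANTS, PhysicalConstants
from .membrane_electro import IonSpecies, Orientation, oriented_concentrations

__all__ = [
    "CellGeometry",
    "ThermoEnvironment",
    "SodiumTransferResult",
    "electric_power_sodium",
    "temperature_rate",
    "convection_coefficient",
    "heat_outflow",
    "sodium_flux_from_heat",
    "potential_temperature_curve",
    "inflammation_heat",
    "sodium_moles",
]


@dataclass(frozen=True)
class CellGeometry:
    """Spherical cell geometry (SI).

    ``surface_area``, ``volume`` and ``mean_radius`` (= V/A = R/3 for a
    sphere) are derived properties.  The membrane must be thin relative to
    the cell (d_memb < R/10).
    """

    radius: float
    membrane_thickness: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if self.membrane_thickness <= 0:
            raise ValueError(
                f"membrane_thickness must be positive, got {self.membrane_thickness}"
            )
        if self.membrane_thickness >= self.radius / 10:
            raise ValueError(
                "membrane_thickness must be small relative to the radius "
                f"(got d={self.membrane_thickness}, R={self.radius})"
            )

    @property
    def surface_area(self) -> float:
        """Membrane area 4πR², m²."""
        return 4.0 * math.pi * self.radius**2

    @property
    def volume(self) -> float:
        """Cell volume 4πR³/3, m³."""
        return 4.0 * math.pi * self.radius**3 / 3.0

    @property
    def mean_radius(self) -> float:
        """V/A, the convective length scale; R/3 for a sphere."""
        return self.volume / self.surface_area


@dataclass(frozen=True)
class ThermoEnvironment:
    """Thermal properties of the cell and its bath.

    Defaults are the standard soft-tissue values: water-like density and
    specific heat, tissue conductivity 0.56 W m⁻¹ K⁻¹, creeping-flow
    Reynolds number 0.2, Prandtl number 0.7, a cell at 37.4 °C in a 37.0 °C
    bath (the normal-condition operating point).
    """

    density: float = 1.0e3            # kg m^-3
    specific_heat: float = 4186.0     # J kg^-1 K^-1
    conductivity: float = 0.56        # W m^-1 K^-1
    reynolds: float = 0.2
    prandtl: float = 0.7
    cell_temperature: float = 310.55  # K (37.4 C)
    bath_temperature: float = 310.15  # K (37.0 C)

    def __post_init__(self) -> None:
        for name in ("density", "specific_heat", "conductivity",
                     "cell_temperature", "bath_temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.reynolds < 0 or self.prandtl < 0:
            raise ValueError("reynolds and prandtl must be nonnegative")


@dataclass(frozen=True)
class SodiumTransferResult:
    """Sodium moles transferred to shed an inflammatory heat excess.

    ``moles`` is the Δn of the mole balance, ``heat`` the inflammatory heat
    excess ρcΔTV (J) it dissipates; the remaining fields echo the driving
    potential Δϕ_Na (V), molar enthalpy change Δh_Na (J mol⁻¹), trans-membrane
    ΔpH and, when available, the flux density (A m⁻²).
    """

    moles: float
    heat: float
    delta_phi_na: float
    delta_h: float
    delta_ph: float
    flux_density: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.moles):
            raise ValueError("moles must be finite")


def electric_power_sodium(
    flux_density: float, field: float, geometry: CellGeometry
) -> float:
    """Electric power of the Na⁺ flux, J·E·4πR²·d_memb, in W (signed product)."""
    return flux_density * field * geometry.surface_area * geometry.membrane_thickness


def temperature_rate(
    power: float, env: ThermoEnvironment, geometry: CellGeometry
) -> float:
    """Cell temperature rate dT/dt = power / (ρ c V), in K s⁻¹."""
    return power / (env.density * env.specific_heat * geometry.volume)


def convection_coefficient(env: ThermoEnvironment, mean_radius: float) -> float:
    """Convective exchange coefficient α = 0.023 Re⁰·⁸ Pr⁰·³⁵ λ / ⟨R⟩, W m⁻² K⁻¹.

    A Dittus-Boelter-style correlation with the cell's volume-to-area ratio
    ⟨R⟩ as the length scale.
    """
    if mean_radius <= 0:
        raise ValueError(f"mean_radius must be positive, got {mean_radius}")
    return (
        0.023
        * env.reynolds**0.8
        * env.prandtl**0.35
        * env.conductivity
        / mean_radius
    )


def heat_outflow(env: ThermoEnvironment, geometry: CellGeometry) -> float:
    """Convective heat power Q̇ = −α (T − T₀) A, in W.

    Negative when the cell is warmer than the bath (net outflow).
    """
    alpha = convection_coefficient(env, geometry.mean_radius)
    return -alpha * (env.cell_temperature - env.bath_temperature) * geometry.surface_area


def sodium_flux_from_heat(
    heat_power: float, field: float, geometry: CellGeometry
) -> float:
    """Na⁺ flux density sustaining a given heat power, A m⁻².

    Inverts the chain identity using the field magnitude,
    J = Q̇ / (|E| · 4πR² · d_memb), so that the sign of the flux follows the
    sign of the heat power: heat export (Q̇ < 0) implies Na⁺ outflow (J < 0)
    regardless of the field orientation.
    """
    if field == 0:
        raise ValueError("field must be nonzero to couple heat power to ion flux")
    flux = heat_power / (
        abs(field) * geometry.surface_area * geometry.membrane_thickness
    )
    # Sign rule: flux and heat power always share a sign.
    assert flux == 0 or math.copysign(1, flux) == math.copysign(1, heat_power)
    return flux


def potential_temperature_curve(
    temperatures: Sequence[float],
    ion: IonSpecies,
    reference_temperature: float = 310.55,
    orientation: Orientation = "physiological",
    delta_h: float = 0.0,
    delta_ph: float = 0.0,
    constants: PhysicalConstants = CONSTANTS,
) -> list[float]:
    """Decrease of the ion's equilibrium potential below its reference value, in V.

    The equilibrium (Nernst) potential is linear in absolute temperature, so
    relative to a reference temperature T_ref the decrease at temperature T is

        Δϕ(T) = (R / zF) · ln(c_out / c_in) · (T_ref − T),

    zero at T_ref and, for c_out > c_in, positive below it (cooling lowers
    the potential).  For Na⁺ with 150/18 mol m⁻³ and T_ref = 37.4 °C this
    reproduces decreases of 3.36, 2.27 and 1.17 mV at 19, 25 and 31 °C.

    ``delta_h`` (J mol⁻¹) and ``delta_ph`` add the optional enthalpy and pH
    contributions (−Δh + 2.3·R·T_ref·ΔpH)/(zF) as a constant offset; both
    default to zero.
    """
    if reference_temperature <= 0 or reference_temperature > 400:
        raise ValueError("reference_temperature outside the physical range (0, 400] K")
    for t in temperatures:
        if t <= 0 or t > 400:
            raise ValueError(f"temperature {t} K outside the physical range (0, 400] K")
    c_out, c_in = oriented_concentrations(ion, orientation)
    zf = ion.valence * constants.faraday
    slope = constants.gas_constant * math.log(c_out / c_in) / zf
    offset = (-delta_h + 2.3 * constants.gas_constant * reference_temperature * delta_ph) / zf
    return [slope * (reference_temperature - t) + offset for t in temperatures]


def inflammation_heat(
    env: ThermoEnvironment, geometry: CellGeometry, t_high: float
) -> float:
    """Inflammatory heat excess ρ c (T_high − T) V, in J.

    The sensible heat stored by the cell when inflammation raises its
    temperature from the normal operating point T to T_high; this is the
    'extra' heat that must flow out to restore normal conditions.
    """
    if t_high < env.cell_temperature:
        raise ValueError(
            f"t_high ({t_high} K) below the normal cell temperature "
            f"({env.cell_temperature} K): no inflammatory excess"
        )
    return (
        env.density
        * env.specific_heat
        * (t_high - env.cell_temperature)
        * geometry.volume
    )


def sodium_moles(
    env: ThermoEnvironment,
    geometry: CellGeometry,
    t_high: float,
    delta_phi_na: float = 0.056,
    delta_h: float = -261.89e3,
    delta_ph: float = 0.0,
    constants: PhysicalConstants = CONSTANTS,
) -> SodiumTransferResult:
    """Moles of Na⁺ whose transfer dissipates the inflammatory heat excess.

    Δn_Na = ρ c (T_high − T) V / (F·Δϕ_Na − Δh_Na + 2.3·R·T·ΔpH_Na),
    with T the normal cell temperature.  Defaults take the sodium
    equilibrium potential (+56 mV) and hydration chemical potential
    (−261.89 kJ mol⁻¹) of the packaged ion table and ΔpH = 0.
    """
    heat = inflammation_heat(env, geometry, t_high)
    term_phi = constants.faraday * delta_phi_na
    term_h = -delta_h
    term_ph = 2.3 * constants.gas_constant * env.cell_temperature * delta_ph
    denominator = term_phi + term_h + term_ph
    if denominator == 0:
        raise ValueError(
            "zero denominator in the sodium mole balance: "
            f"F*delta_phi = {term_phi} J/mol, -delta_h = {term_h} J/mol, "
            f"2.3*R*T*delta_pH = {term_ph} J/mol sum to zero"
        )
    return SodiumTransferResult(
        moles=heat / denominator,
        heat=heat,
        delta_phi_na=delta_phi_na,
        delta_h=delta_h,
        delta_ph=delta_ph,
    )
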