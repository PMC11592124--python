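"""Electromagnetic-wave mechanics at the cell membrane and ELF resonance dosimetry.

A plane electromagnetic wave exerts a radiation pressure p = εE²/2 = B²/2μ
on the membrane; the resulting elastic force and the induced perturbation of
the membrane potential are modelled by the literal force/potential readings

    F  = p · A / (2πr),        Δϕ = F · A / (π ε r),

with A the illuminated membrane area and r the internal cell radius.  These
two maps are deliberately isolated here: their absolute scale is a modelling
choice (see docs/methods.md) and downstream code relies only on their
structural properties (linearity in pressure/force, monotonicity in E²).

The extremely-low-frequency resonance predictor is a calibrated
inverse-square law in the cell diameter, f(d) = f_ref · (d_ref/d)², anchored
by default at (20 µm, 13.5 Hz); harmonic/subharmonic companions are
generated at the empirical ratio set {1/7, 1/3, 1, 2, 4, 6}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import CONSTANTS, PhysicalConstants

__all__ = [
    "PlaneWave",
    "SpectrumMember",
    "FrequencySpectrum",
    "radiation_pressure",
    "membrane_force",
    "potential_perturbation",
    "resonance_fundamental",
    "harmonic_series",
    "DEFAULT_CALIBRATION",
    "DEFAULT_HARMONIC_RATIOS",
]

#: (reference diameter m, reference fundamental Hz) anchoring the inverse-square law.
DEFAULT_CALIBRATION: tuple[float, float] = (20e-6, 13.5)

#: Ratio set of the harmonic/subharmonic companions of the fundamental.
DEFAULT_HARMONIC_RATIOS: tuple[float, ...] = (1 / 7, 1 / 3, 1.0, 2.0, 4.0, 6.0)


@dataclass(frozen=True)
class PlaneWave:
    """A monochromatic plane wave in a linear medium (vacuum by default).

    At least one field amplitude must be set; when both are given they must
    satisfy B = E/c (c = 1/√(με) of the medium) to a relative 1e-6.
    """

    electric_amplitude: float | None = None   # V m^-1
    magnetic_amplitude: float | None = None   # T
    frequency: float | None = None            # Hz
    permittivity: float = CONSTANTS.vacuum_permittivity
    permeability: float = CONSTANTS.vacuum_permeability

    def __post_init__(self) -> None:
        if self.permittivity <= 0 or self.permeability <= 0:
            raise ValueError("permittivity and permeability must be positive")
        for name in ("electric_amplitude", "magnetic_amplitude"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.frequency is not None and self.frequency <= 0:
            raise ValueError("frequency must be positive")
        e, b = self.electric_amplitude, self.magnetic_amplitude
        if e is not None and b is not None and e > 0:
            expected_b = e / self.wave_speed
            if abs(b - expected_b) > 1e-6 * expected_b:
                raise ValueError(
                    f"amplitudes inconsistent: B={b!r} but E/c={expected_b!r}"
                )

    @property
    def wave_speed(self) -> float:
        """Phase velocity 1/√(με) of the medium, m s⁻¹."""
        return 1.0 / math.sqrt(self.permeability * self.permittivity)


@dataclass(frozen=True)
class SpectrumMember:
    ratio: float
    frequency: float
    band: float


@dataclass(frozen=True)
class FrequencySpectrum:
    """A fundamental with an uncertainty band and its ratio-labelled companions."""

    fundamental: float
    uncertainty: float
    members: tuple[SpectrumMember, ...]

    def __post_init__(self) -> None:
        if self.fundamental <= 0:
            raise ValueError("fundamental must be positive")
        ratios = [m.ratio for m in self.members]
        if ratios != sorted(ratios):
            raise ValueError("member ratios must be sorted ascending")
        for m in self.members:
            if m.frequency != m.ratio * self.fundamental:
                raise ValueError(
                    f"member at ratio {m.ratio} has frequency {m.frequency}, "
                    f"expected {m.ratio * self.fundamental}"
                )


def radiation_pressure(wave: PlaneWave) -> float:
    """Radiation pressure of the wave, εE²/2 (= B²/2μ), in Pa.

    The electric form is used when the electric amplitude is set; otherwise
    the magnetic form.  The two agree to 1e-6 by the plane-wave constraint.
    """
    if wave.electric_amplitude is not None:
        return wave.permittivity * wave.electric_amplitude**2 / 2.0
    if wave.magnetic_amplitude is not None:
        return wave.magnetic_amplitude**2 / (2.0 * wave.permeability)
    raise ValueError("radiation pressure needs at least one field amplitude")


def membrane_force(pressure: float, illuminated_area: float, internal_radius: float) -> float:
    """Elastic force on the membrane, p·A/(2πr), in N."""
    if illuminated_area <= 0:
        raise ValueError("illuminated_area must be positive")
    if internal_radius <= 0:
        raise ValueError("internal_radius must be positive")
    return pressure * illuminated_area / (2.0 * math.pi * internal_radius)


def potential_perturbation(
    force: float,
    illuminated_area: float,
    internal_radius: float,
    permittivity: float = CONSTANTS.vacuum_permittivity,
) -> float:
    """Membrane-potential perturbation induced by the elastic force, F·A/(πεr), in V."""
    if illuminated_area <= 0:
        raise ValueError("illuminated_area must be positive")
    if internal_radius <= 0:
        raise ValueError("internal_radius must be positive")
    if permittivity <= 0:
        raise ValueError("permittivity must be positive")
    return force * illuminated_area / (math.pi * permittivity * internal_radius)


def resonance_fundamental(
    diameter: float,
    calibration: tuple[float, float] = DEFAULT_CALIBRATION,
) -> float:
    """Fundamental anti-inflammatory resonance frequency for a cell diameter, Hz.

    Inverse-square diameter law f = f_ref · (d_ref/d)².  With the default
    calibration (20 µm, 13.5 Hz) a 100 µm cell lands at 0.54 Hz.
    Diameters outside [5, 500] µm are outside the model's cellular regime
    and rejected.
    """
    d_ref, f_ref = calibration
    if d_ref <= 0 or f_ref <= 0:
        raise ValueError("calibration diameter and frequency must be positive")
    if diameter <= 0:
        raise ValueError(f"diameter must be positive, got {diameter}")
    if not 5e-6 <= diameter <= 500e-6:
        raise ValueError(
            f"diameter {diameter} m outside the supported cellular range [5, 500] um"
        )
    return f_ref * (d_ref / diameter) ** 2


def harmonic_series(
    fundamental: float,
    uncertainty_fraction: float = 0.10,
    ratios: tuple[float, ...] = DEFAULT_HARMONIC_RATIOS,
) -> FrequencySpectrum:
    """Harmonic/subharmonic companions of a fundamental frequency.

    Members sit at ``ratios``·f₀ (default {1/7, 1/3, 1, 2, 4, 6}), each with
    a ±``uncertainty_fraction``·f band (default 10%).
    """
    if fundamental <= 0:
        raise ValueError(f"fundamental must be positive, got {fundamental}")
    if uncertainty_fraction < 0:
        raise ValueError("uncertainty_fraction must be nonnegative")
    members = tuple(
        SpectrumMember(
            ratio=r,
            frequency=r * fundamental,
            band=uncertainty_fraction * r * fundamental,
        )
        for r in sorted(ratios)
    )
    return FrequencySpectrum(
        fundamental=fundamental,
        uncertainty=uncertainty_fraction * fundamental,
        members=members,
    )
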