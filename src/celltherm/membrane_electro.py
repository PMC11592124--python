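"""Electrochemical potentials of the cell membrane.

Per-ion Nernst equilibrium potentials, the Goldman–Hodgkin–Katz (GHK)
resting potential of a monovalent-ion mixture, the trans-membrane electric
field, and the decomposition of a sodium potential change into the
compensating Cl⁻/K⁺/Ca²⁺ shares.

Sign convention: the membrane potential is cytosol minus bath, so a resting
cell sits near −70 mV and its field (potential / membrane thickness) is
negative, on the order of −1.75×10⁷ V m⁻¹.

Ion tables in the physiology literature are sometimes printed with the
intra/extracellular columns of Na⁺ and K⁺ interchanged relative to the sign
of the tabulated equilibrium potentials.  The default ``"physiological"``
orientation rule therefore re-assigns each known monovalent species to its
physiological high side (Na⁺ high outside, K⁺ high inside, Cl⁻ high
outside) before evaluating any logarithmic quotient; ``"as-labeled"`` takes
the stored columns at face value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .constants import CONSTANTS, PhysicalConstants

__all__ = [
    "IonSpecies",
    "MembraneState",
    "nernst_potential",
    "ghk_potential",
    "membrane_field",
    "compensating_potential_split",
    "oriented_concentrations",
]

Orientation = Literal["physiological", "as-labeled"]
GhkDialect = Literal["default", "paper-literal"]
DivalentPolicy = Literal["ignore", "reject"]

# Side on which each species is more concentrated in a healthy mammalian cell.
_PHYSIOLOGICAL_HIGH_SIDE: dict[str, str] = {
    "Na+": "out",
    "K+": "in",
    "Cl-": "out",
    "Ca2+": "out",
}


@dataclass(frozen=True)
class IonSpecies:
    """One membrane-permeant ion species.

    Concentrations are in mol m⁻³ (numerically equal to mM), the chemical
    potential in J mol⁻¹ and the tabulated equilibrium potential in V; the
    last two are optional annotations carried through from an ion table and
    never used in any computation.
    """

    name: str
    valence: int
    conc_out: float
    conc_in: float
    permeability: float = 0.0
    chemical_potential: float | None = None
    tabulated_potential: float | None = None

    def __post_init__(self) -> None:
        if self.valence == 0:
            raise ValueError(f"ion {self.name!r}: valence must be nonzero")
        if self.conc_out <= 0 or self.conc_in <= 0:
            raise ValueError(
                f"ion {self.name!r}: concentrations must be positive "
                f"(got out={self.conc_out}, in={self.conc_in} mol/m^3)"
            )
        if self.permeability < 0:
            raise ValueError(f"ion {self.name!r}: permeability must be >= 0")


@dataclass(frozen=True)
class MembraneState:
    """Membrane potential (V, cytosol minus bath), field (V m⁻¹) and thickness (m).

    The field is derived as potential / thickness when not given; when both
    are supplied they must agree to a relative 1e-12.
    """

    potential: float
    membrane_thickness: float
    field: float | None = None

    def __post_init__(self) -> None:
        if self.membrane_thickness <= 0:
            raise ValueError("membrane_thickness must be positive")
        derived = self.potential / self.membrane_thickness
        if self.field is None:
            object.__setattr__(self, "field", derived)
        elif not math.isclose(self.field, derived, rel_tol=1e-12, abs_tol=0.0):
            raise ValueError(
                f"field {self.field!r} inconsistent with potential/thickness {derived!r}"
            )


def oriented_concentrations(ion: IonSpecies, orientation: Orientation) -> tuple[float, float]:
    """Return ``(c_out, c_in)`` after applying the side-assignment rule."""
    if orientation == "as-labeled":
        return ion.conc_out, ion.conc_in
    if orientation != "physiological":
        raise ValueError(f"unknown orientation rule {orientation!r}")
    high = _PHYSIOLOGICAL_HIGH_SIDE.get(ion.name)
    if high is None:
        return ion.conc_out, ion.conc_in
    hi, lo = max(ion.conc_out, ion.conc_in), min(ion.conc_out, ion.conc_in)
    return (hi, lo) if high == "out" else (lo, hi)


def nernst_potential(
    ion: IonSpecies,
    temperature: float = 310.15,
    orientation: Orientation = "physiological",
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Nernst equilibrium potential (RT / zF) · ln(c_out / c_in), in volts.

    Parameters
    ----------
    ion : IonSpecies
        The species; its concentrations are oriented by ``orientation``
        before the quotient is formed.
    temperature : float
        Absolute temperature in K (default 310.15, i.e. 37 °C).
    orientation : {"physiological", "as-labeled"}
        Side-assignment rule, see the module docstring.
    """
    if temperature <= 0:
        raise ValueError(
            f"ion {ion.name!r}: temperature must be positive, got {temperature}"
        )
    c_out, c_in = oriented_concentrations(ion, orientation)
    rt_over_zf = constants.gas_constant * temperature / (ion.valence * constants.faraday)
    return rt_over_zf * math.log(c_out / c_in)


def ghk_potential(
    ions: Iterable[IonSpecies],
    temperature: float = 310.15,
    dialect: GhkDialect = "default",
    orientation: Orientation = "physiological",
    divalent: DivalentPolicy = "ignore",
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Goldman–Hodgkin–Katz resting potential of a monovalent-ion mixture, in volts.

    The ``"default"`` dialect is the standard GHK arrangement with the
    natural logarithm: cations contribute their outside concentration to the
    numerator and inside to the denominator; anions the other way round::

        (RT/F) · ln[ (Σ_cat P·c_out + Σ_an P·c_in) / (Σ_cat P·c_in + Σ_an P·c_out) ]

    The ``"paper-literal"`` dialect evaluates the occasionally-typeset
    all-outside-over-all-inside arrangement with log₁₀ and as-labeled sides.
    It is provided for documentation and comparison; it does not reproduce
    physiological resting potentials.

    Divalent species never enter the quotient: they are dropped when
    ``divalent="ignore"`` (default) or raise when ``divalent="reject"``.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    ions = list(ions)
    non_mono = [i for i in ions if abs(i.valence) != 1]
    if non_mono and divalent == "reject":
        names = ", ".join(i.name for i in non_mono)
        raise ValueError(f"non-monovalent ions not allowed in the GHK quotient: {names}")
    mono = [i for i in ions if abs(i.valence) == 1]
    if not any(i.permeability > 0 for i in mono):
        raise ValueError("GHK potential undefined: all monovalent permeabilities are zero")

    rt_over_f = constants.gas_constant * temperature / constants.faraday
    if dialect == "paper-literal":
        num = sum(i.permeability * i.conc_out for i in mono)
        den = sum(i.permeability * i.conc_in for i in mono)
        return rt_over_f * math.log10(num / den)
    if dialect != "default":
        raise ValueError(f"unknown GHK dialect {dialect!r}")

    num = den = 0.0
    for ion in mono:
        c_out, c_in = oriented_concentrations(ion, orientation)
        if ion.valence > 0:
            num += ion.permeability * c_out
            den += ion.permeability * c_in
        else:
            num += ion.permeability * c_in
            den += ion.permeability * c_out
    return rt_over_f * math.log(num / den)


def membrane_field(potential: float, thickness: float) -> float:
    """Trans-membrane electric field, potential / thickness, in V m⁻¹.

    With the resting −70 mV across a 4 nm membrane this is −1.75×10⁷ V m⁻¹.
    """
    if thickness <= 0:
        raise ValueError(f"membrane thickness must be positive, got {thickness}")
    return potential / thickness


def compensating_potential_split(
    delta_phi_na: float,
    weights: Sequence[float],
) -> tuple[float, float, float]:
    """Split a Na⁺ potential change into compensating (Cl⁻, K⁺, Ca²⁺) shares.

    The conservation identity Δϕ_Na = Δϕ_Cl + Δϕ_K + Δϕ_Ca holds exactly:
    the last share is computed as the residual so the three outputs sum to
    the input to the last bit.

    Parameters
    ----------
    weights : sequence of 3 floats
        Nonnegative shares over (Cl⁻, K⁺, Ca²⁺), summing to 1 (tolerance 1e-9).
    """
    if len(weights) != 3:
        raise ValueError("weights must have exactly three entries (Cl-, K+, Ca2+)")
    w = [float(x) for x in weights]
    if any(x < 0 for x in w):
        raise ValueError(f"weights must be nonnegative, got {w}")
    if abs(sum(w) - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 within 1e-9, got sum {sum(w)!r}")
    first = w[0] * delta_phi_na
    second = w[1] * delta_phi_na
    third = delta_phi_na - first - second
    return first, second, third
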