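"""Orchestration of the model stages into a reproducible run report.

A :class:`RunReport` bundles, for one configuration: the per-ion check of
the reference table's equilibrium-potential column, the GHK resting
potential and trans-membrane field, the potential-vs-temperature curve over
19–40 °C, the ELF resonance spectrum for the configured cell diameter, and
the sodium mole balance of a 0.4 K inflammatory excursion.  The report is a
pure function of the configuration and serializes losslessly to JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import Any

from .constants import celsius_to_kelvin
from .em_wave import harmonic_series, resonance_fundamental
from .io import default_config, load_reference_ion_table
from .membrane_electro import ghk_potential, membrane_field, nernst_potential
from .thermo_balance import (
    CellGeometry,
    ThermoEnvironment,
    potential_temperature_curve,
    sodium_moles,
)

__all__ = ["RunReport", "run_report", "temperature_scan", "config_digest"]

CURVE_T_MIN_C = 19.0
CURVE_T_MAX_C = 40.0
CURVE_STEP_C = 0.5


@dataclass(frozen=True)
class RunReport:
    """Serializable results of one model run; every key names its unit."""

    config: dict[str, Any]
    config_sha256: str
    table1_check: list[dict[str, Any]]
    ghk_mV: float
    field_V_per_m: float
    curve: list[dict[str, float]]          # rows: temperature_C, delta_phi_mV
    spectrum: dict[str, Any]               # fundamental_hz, uncertainty_hz, members
    sodium: dict[str, float]

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunReport":
        return cls(**data)


def config_digest(config: dict[str, Any]) -> str:
    """SHA-256 of the canonical JSON form of the configuration."""
    canonical = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


def temperature_scan(
    t_min_c: float = CURVE_T_MIN_C,
    t_max_c: float = CURVE_T_MAX_C,
    step_c: float = CURVE_STEP_C,
    reference_c: float = 37.4,
) -> list[dict[str, float]]:
    """Potential-decrease curve rows over a Celsius grid.

    Uses the sodium species of the packaged reference table; returns rows
    ``{"temperature_C": ..., "delta_phi_mV": ...}`` at ``step_c`` spacing
    (endpoints included).
    """
    if step_c <= 0:
        raise ValueError("step_c must be positive")
    if t_max_c < t_min_c:
        raise ValueError("t_max_c must be >= t_min_c")
    sodium = next(i for i in load_reference_ion_table() if i.name == "Na+")
    n_steps = int(round((t_max_c - t_min_c) / step_c))
    grid_c = [t_min_c + k * step_c for k in range(n_steps + 1)]
    decreases = potential_temperature_curve(
        [celsius_to_kelvin(t) for t in grid_c],
        sodium,
        reference_temperature=celsius_to_kelvin(reference_c),
    )
    return [
        {"temperature_C": t, "delta_phi_mV": dphi * 1e3}
        for t, dphi in zip(grid_c, decreases)
    ]


def run_report(config: dict[str, Any] | None = None) -> RunReport:
    """Evaluate the full model for one configuration.

    Deterministic: two calls with equal configurations produce
    byte-identical JSON.
    """
    if config is None:
        config = default_config()

    ions = load_reference_ion_table()
    cell = config["cell"]
    env_cfg = config["environment"]
    na_cfg = config["sodium"]

    geometry = CellGeometry(
        radius=cell["radius_um"] * 1e-6,
        membrane_thickness=cell["membrane_nm"] * 1e-9,
    )
    env = ThermoEnvironment(
        density=env_cfg["density_kg_m3"],
        specific_heat=env_cfg["specific_heat_J_kg_K"],
        conductivity=env_cfg["conductivity_W_m_K"],
        reynolds=env_cfg["reynolds"],
        prandtl=env_cfg["prandtl"],
        cell_temperature=celsius_to_kelvin(env_cfg["T_cell_C"]),
        bath_temperature=celsius_to_kelvin(env_cfg["T_bath_C"]),
    )

    t_bath_k = celsius_to_kelvin(env_cfg["T_bath_C"])
    table1_check = []
    for ion in ions:
        computed_mv = nernst_potential(ion, temperature=t_bath_k) * 1e3
        tabulated_mv = (ion.tabulated_potential or 0.0) * 1e3
        table1_check.append(
            {
                "species": ion.name,
                "tabulated_mV": tabulated_mv,
                "computed_mV": computed_mv,
                "error_mV": computed_mv - tabulated_mv,
            }
        )

    ghk_v = ghk_potential(ions, temperature=t_bath_k)
    field = membrane_field(ghk_v, geometry.membrane_thickness)

    curve = temperature_scan(reference_c=env_cfg["T_cell_C"])

    spectrum = harmonic_series(resonance_fundamental(2.0 * geometry.radius))
    spectrum_dict = {
        "fundamental_hz": spectrum.fundamental,
        "uncertainty_hz": spectrum.uncertainty,
        "members": [
            {"ratio": m.ratio, "frequency_hz": m.frequency, "band_hz": m.band}
            for m in spectrum.members
        ],
    }

    sodium = sodium_moles(
        env,
        geometry,
        t_high=celsius_to_kelvin(na_cfg["T_high_C"]),
        delta_phi_na=na_cfg["delta_phi_mV"] * 1e-3,
        delta_h=na_cfg["delta_h_kJ_mol"] * 1e3,
        delta_ph=na_cfg["delta_pH"],
    )
    sodium_dict = {
        "moles_mol": sodium.moles,
        "heat_J": sodium.heat,
        "delta_phi_mV": sodium.delta_phi_na * 1e3,
        "delta_h_kJ_mol": sodium.delta_h * 1e-3,
        "delta_pH": sodium.delta_ph,
    }

    return RunReport(
        config=config,
        config_sha256=config_digest(config),
        table1_check=table1_check,
        ghk_mV=ghk_v * 1e3,
        field_V_per_m=field,
        curve=curve,
        spectrum=spectrum_dict,
        sodium=sodium_dict,
    )
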