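"""File I/O: ion tables (CSV) and run configuration (TOML).

The ion-table format is a strict CSV with header::

    species,valence,conc_out_mM,conc_in_mM,rel_permeability,chem_potential_kJ_mol,equil_potential_mV

Concentrations are given in mM (1 mM ≡ 1 mol m⁻³), chemical potentials in
kJ mol⁻¹ and equilibrium potentials in mV; everything is converted to SI on
read.  A reference table of the four classical species (Na⁺, K⁺, Cl⁻, Ca²⁺)
with their textbook concentrations, hydration chemical potentials and
equilibrium potentials ships with the package (``load_reference_ion_table``).
"""

from __future__ import annotations

import csv
import importlib.resources
import tomllib
from pathlib import Path
from typing import Any, Iterable, Sequence

from .membrane_electro import IonSpecies

__all__ = [
    "ION_TABLE_HEADER",
    "IonTableError",
    "ConfigError",
    "read_ion_table",
    "write_ion_table",
    "load_reference_ion_table",
    "default_config",
    "load_config",
]

ION_TABLE_HEADER = [
    "species",
    "valence",
    "conc_out_mM",
    "conc_in_mM",
    "rel_permeability",
    "chem_potential_kJ_mol",
    "equil_potential_mV",
]


class IonTableError(ValueError):
    """Malformed ion-table file."""


class ConfigError(ValueError):
    """Invalid run configuration; aggregates all offending keys."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration: " + "; ".join(self.problems))


def read_ion_table(path: str | Path) -> list[IonSpecies]:
    """Read an ion table CSV into :class:`IonSpecies` (SI units)."""
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise IonTableError(f"{path}: empty file") from None
        if header != ION_TABLE_HEADER:
            bad = [c for c in header if c not in ION_TABLE_HEADER]
            missing = [c for c in ION_TABLE_HEADER if c not in header]
            raise IonTableError(
                f"{path}: bad header; unexpected columns {bad or 'none'}, "
                f"missing columns {missing or 'none'} "
                f"(expected exactly {','.join(ION_TABLE_HEADER)})"
            )
        ions: list[IonSpecies] = []
        seen: set[str] = set()
        for row_number, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(ION_TABLE_HEADER):
                raise IonTableError(
                    f"{path}, row {row_number}: expected {len(ION_TABLE_HEADER)} "
                    f"fields, got {len(row)}"
                )
            species = row[0]
            if species in seen:
                raise IonTableError(
                    f"{path}, row {row_number}: duplicate species {species!r}"
                )
            seen.add(species)
            values: dict[str, float] = {}
            for column, cell in zip(ION_TABLE_HEADER[1:], row[1:]):
                try:
                    values[column] = float(cell)
                except ValueError:
                    raise IonTableError(
                        f"{path}, row {row_number}, column {column!r}: "
                        f"non-numeric value {cell!r}"
                    ) from None
            valence = values["valence"]
            if valence != int(valence):
                raise IonTableError(
                    f"{path}, row {row_number}, column 'valence': "
                    f"must be an integer, got {valence!r}"
                )
            ions.append(
                IonSpecies(
                    name=species,
                    valence=int(valence),
                    conc_out=values["conc_out_mM"],      # mM == mol/m^3
                    conc_in=values["conc_in_mM"],
                    permeability=values["rel_permeability"],
                    chemical_potential=values["chem_potential_kJ_mol"] * 1e3,
                    tabulated_potential=values["equil_potential_mV"] * 1e-3,
                )
            )
    return ions


def _fmt(x: float) -> str:
    return format(x, ".12g")


def write_ion_table(ions: Iterable[IonSpecies], path: str | Path) -> None:
    """Write an ion table CSV; write∘read is the identity on valid tables."""
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(ION_TABLE_HEADER)
        for ion in ions:
            writer.writerow(
                [
                    ion.name,
                    str(ion.valence),
                    _fmt(ion.conc_out),
                    _fmt(ion.conc_in),
                    _fmt(ion.permeability),
                    _fmt((ion.chemical_potential or 0.0) * 1e-3),
                    _fmt((ion.tabulated_potential or 0.0) * 1e3),
                ]
            )


def load_reference_ion_table() -> list[IonSpecies]:
    """The packaged reference ion table (Na⁺, K⁺, Cl⁻, Ca²⁺)."""
    resource = importlib.resources.files("celltherm") / "data" / "table1.csv"
    with importlib.resources.as_file(resource) as path:
        return read_ion_table(path)


# ---------------------------------------------------------------------------
# Run configuration

def default_config() -> dict[str, dict[str, float]]:
    """Default run configuration (user-facing units: µm, nm, °C, mV, kJ/mol)."""
    return {
        "cell": {
            "radius_um": 10.0,
            "membrane_nm": 4.0,
        },
        "environment": {
            "density_kg_m3": 1.0e3,
            "specific_heat_J_kg_K": 4186.0,
            "conductivity_W_m_K": 0.56,
            "reynolds": 0.2,
            "prandtl": 0.7,
            "T_cell_C": 37.4,
            "T_bath_C": 37.0,
        },
        "sodium": {
            "T_high_C": 37.8,
            "delta_phi_mV": 56.0,
            "delta_h_kJ_mol": -261.89,
            "delta_pH": 0.0,
        },
    }


_POSITIVE_KEYS = {
    ("cell", "radius_um"),
    ("cell", "membrane_nm"),
    ("environment", "density_kg_m3"),
    ("environment", "specific_heat_J_kg_K"),
    ("environment", "conductivity_W_m_K"),
}


def _validate(config: dict[str, Any]) -> None:
    problems: list[str] = []
    defaults = default_config()
    for section, values in config.items():
        if section not in defaults:
            problems.append(f"unknown section [{section}]")
            continue
        for key, value in values.items():
            if key not in defaults[section]:
                problems.append(f"unknown key {section}.{key}")
            elif not isinstance(value, (int, float)) or isinstance(value, bool):
                problems.append(f"{section}.{key} must be a number, got {value!r}")
            elif (section, key) in _POSITIVE_KEYS and value <= 0:
                problems.append(f"{section}.{key} must be positive, got {value!r}")
    if problems:
        raise ConfigError(problems)


def load_config(path: str | Path | None = None) -> dict[str, dict[str, float]]:
    """Load a TOML run configuration, merged over the defaults.

    Raises a single :class:`ConfigError` listing every offending key.
    """
    config = default_config()
    if path is not None:
        with Path(path).open("rb") as handle:
            user = tomllib.load(handle)
        _validate(user)
        for section, values in user.items():
            config[section].update(values)
    _validate(config)
    return config
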