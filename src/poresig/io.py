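"""Boundary I/O: unit conversion, event CSVs, and YAML/JSON configs.

Internally everything is SI; files and configs use the field's conventional
units (nm, mV, nA, ms, mol/L).  Event CSVs carry the columns
``condition, V_ps_mV, I_ps_nA, t_ic_ms`` (plus optional baseline context
``V_bs_mV, I_bs_nA``).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import InvalidInputError
from .baseline import NanoporeGeometry
from .ions import ElectrolyteSolution, IonSpecies, ion_from_table
from .perturbation import Analyte

__all__ = [
    "events_to_si",
    "events_from_si",
    "read_events_csv",
    "write_events_csv",
    "load_config",
    "solution_from_config",
    "pore_from_config",
    "analyte_from_config",
]

_UNIT_MAP = {
    "V_ps_mV": ("V_ps_V", 1e-3),
    "I_ps_nA": ("I_ps_A", 1e-9),
    "t_ic_ms": ("t_ic_s", 1e-3),
    "V_bs_mV": ("V_bs_V", 1e-3),
    "I_bs_nA": ("I_bs_A", 1e-9),
}


def events_to_si(events: pd.DataFrame) -> pd.DataFrame:
    """Convert a conventional-unit event table to SI columns."""
    out = events.copy()
    for col, (si_col, factor) in _UNIT_MAP.items():
        if col in out:
            out[si_col] = out.pop(col) * factor
    return out


def events_from_si(events: pd.DataFrame) -> pd.DataFrame:
    """Convert an SI event table to conventional units for CSV output."""
    out = events.copy()
    for col, (si_col, factor) in _UNIT_MAP.items():
        if si_col in out:
            out[col] = out.pop(si_col) / factor
    return out


def read_events_csv(path) -> pd.DataFrame:
    """Read an event CSV (conventional units) and return SI columns."""
    return events_to_si(pd.read_csv(path))


def write_events_csv(events: pd.DataFrame, path) -> None:
    """Write an SI event table as a conventional-unit CSV."""
    events_from_si(events).to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def _ion_from_entry(entry) -> tuple[IonSpecies, float]:
    """One electrolyte species entry: either ``{name, concentration_M}``
    using the shipped table, or a fully explicit species."""
    if "concentration_M" not in entry:
        raise InvalidInputError("species entry needs concentration_M")
    conc = float(entry["concentration_M"])
    if set(entry) <= {"name", "concentration_M", "mobility_m2_per_Vs"}:
        ion = ion_from_table(
            entry["name"], mobility=entry.get("mobility_m2_per_Vs")
        )
    else:
        ion = IonSpecies(
            name=entry["name"],
            molecular_weight=float(entry["molecular_weight_g_per_mol"]),
            radius=float(entry["radius_nm"]) * 1e-9,
            valence=int(entry["valence"]),
            mobility=entry.get("mobility_m2_per_Vs"),
        )
    return ion, conc


def solution_from_config(cfg: dict) -> ElectrolyteSolution:
    """Build an electrolyte from a config mapping.

    Expected shape::

        electrolyte:
          temperature_K: 298        # optional
          majority_override: Na+    # optional
          species:
            - {name: Na+, concentration_M: 1e-3}
            - {name: F-,  concentration_M: 1e-3}
    """
    block = cfg.get("electrolyte", cfg)
    species = tuple(_ion_from_entry(e) for e in block["species"])
    return ElectrolyteSolution(
        species=species,
        temperature=float(block.get("temperature_K", 298.0)),
        majority_override=block.get("majority_override"),
    )


def pore_from_config(cfg: dict) -> NanoporeGeometry:
    """Pore geometry from ``{pore: {radius_nm, length_nm, metal_length_nm}}``."""
    block = cfg.get("pore", cfg)
    return NanoporeGeometry(
        r_np=float(block["radius_nm"]) * 1e-9,
        L=float(block.get("length_nm", 55.0)) * 1e-9,
        L_Au=float(block.get("metal_length_nm", 5.0)) * 1e-9,
    )


def analyte_from_config(cfg: dict) -> Analyte:
    """Analyte from ``{analyte: {name, radius_nm, valence, ...}}``."""
    block = cfg.get("analyte", cfg)
    return Analyte(
        name=block.get("name", "analyte"),
        r_analyte=float(block["radius_nm"]) * 1e-9,
        z_analyte=int(block["valence"]),
        water_layer=float(block.get("water_layer_nm", 0.14)) * 1e-9,
        use_stokes=bool(block.get("use_stokes", True)),
    )
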