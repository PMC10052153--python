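"""Component registries and dataset fixtures: readers and writers.

The packaged fixture ``data/components.csv`` carries the measured fusion
properties, glass transitions and PC-SAFT parameter sets of the five
APIs studied (indomethacin, ibuprofen, naproxen, paracetamol, probucol);
``data/liquidus_experimental.csv`` and ``data/eutectic_experimental.csv``
carry the DSC liquidus/eutectic measurements for the four binary blends.
User files with the same schemas load through the same functions.
"""
from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import celsius_to_kelvin, kelvin_to_celsius
from .parameters import (BinaryInteraction, ComponentRecord,
                         FusionProperties, PcSaftParameters)
from .sle import BinarySystem, EutecticPoint, PhaseDiagram

__all__ = [
    "load_registry", "load_default_registry", "write_registry",
    "binary_system", "load_experimental_liquidus",
    "load_experimental_eutectics", "load_reference_eutectics",
    "load_reference_deviations", "load_reference_tg_fits",
    "write_phase_diagram_csv", "write_eutectic_json", "SYSTEMS",
]

#: The four binary blends studied, as (component 1, component 2).
SYSTEMS = (("NAP", "IND"), ("NAP", "IBU"), ("NAP", "PRO"), ("IND", "PAR"))

_NUMERIC = ["Tm_C", "dHfus_kJmol", "dCp_JKmol"]
_SAFT_COLS = ["m", "sigma_A", "eps_k_K", "eps_assoc_k_K", "kappa_assoc",
              "donor_sites", "acceptor_sites"]


def _data_path(name: str):
    return resources.files("camphase.data").joinpath(name)


def _record_from_row(row: pd.Series, index) -> ComponentRecord:
    for col in _NUMERIC:
        if col not in row or pd.isna(row[col]):
            raise ValueError(f"row {index}: missing required field {col!r}")
    saft = None
    if "m" in row and not pd.isna(row.get("m")):
        saft = PcSaftParameters(
            segment_number=float(row["m"]),
            segment_diameter=float(row["sigma_A"]),
            dispersion_energy=float(row["eps_k_K"]),
            association_energy=float(row.get("eps_assoc_k_K", 0) or 0),
            association_volume=float(row.get("kappa_assoc", 0) or 0),
            donor_sites=int(row.get("donor_sites", 0) or 0),
            acceptor_sites=int(row.get("acceptor_sites", 0) or 0),
        )
    tg = row.get("Tg_C")
    return ComponentRecord(
        name=str(row.get("name", row["abbr"])),
        abbreviation=str(row["abbr"]),
        polymorph=None if pd.isna(row.get("polymorph")) else str(row["polymorph"]),
        structure_id=(None if pd.isna(row.get("structure_id"))
                      else str(row["structure_id"])),
        fusion=FusionProperties(
            melting_temperature=celsius_to_kelvin(float(row["Tm_C"])),
            fusion_enthalpy=float(row["dHfus_kJmol"]) * 1e3,
            heat_capacity_difference=float(row["dCp_JKmol"]),
        ),
        pcsaft=saft,
        glass_transition=(None if tg is None or pd.isna(tg)
                          else celsius_to_kelvin(float(tg))),
    )


def load_registry(path) -> dict[str, ComponentRecord]:
    """Read a component table (CSV or JSON) into {abbreviation: record}.

    Temperatures are read in degC and enthalpies in kJ/mol (the table
    convention) and stored internally in K and J/mol.  Duplicate
    abbreviations and malformed rows are rejected with the offending
    row named.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            return {}
    registry: dict[str, ComponentRecord] = {}
    for index, row in df.iterrows():
        try:
            rec = _record_from_row(row, index)
        except Exception as err:
            raise ValueError(f"invalid component row {index}: {err}") from err
        if rec.abbreviation in registry:
            raise ValueError(
                f"duplicate component abbreviation {rec.abbreviation!r}")
        registry[rec.abbreviation] = rec
    return registry


def load_default_registry() -> dict[str, ComponentRecord]:
    """The packaged five-API registry."""
    with resources.as_file(_data_path("components.csv")) as p:
        return load_registry(p)


def write_registry(registry: Mapping[str, ComponentRecord], path) -> None:
    """Write a registry back to CSV with the same schema it is read from."""
    rows = []
    for rec in registry.values():
        row = {
            "name": rec.name, "abbr": rec.abbreviation,
            "polymorph": rec.polymorph, "structure_id": rec.structure_id,
            "Tm_C": kelvin_to_celsius(rec.fusion.melting_temperature),
            "dHfus_kJmol": rec.fusion.fusion_enthalpy / 1e3,
            "dCp_JKmol": rec.fusion.heat_capacity_difference,
            "Tg_C": (None if rec.glass_transition is None
                     else kelvin_to_celsius(rec.glass_transition)),
        }
        if rec.pcsaft is not None:
            p = rec.pcsaft
            row.update(m=p.segment_number, sigma_A=p.segment_diameter,
                       eps_k_K=p.dispersion_energy,
                       eps_assoc_k_K=p.association_energy,
                       kappa_assoc=p.association_volume,
                       donor_sites=p.donor_sites,
                       acceptor_sites=p.acceptor_sites)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def binary_system(name_1: str, name_2: str,
                  registry: Mapping[str, ComponentRecord] | None = None,
                  k_ij: float = 0.0) -> BinarySystem:
    """Build a :class:`BinarySystem` from registry abbreviations."""
    reg = registry if registry is not None else load_default_registry()
    return BinarySystem(reg[name_1], reg[name_2],
                        BinaryInteraction(k_ij=k_ij))


def load_experimental_liquidus(system: str | None = None) -> pd.DataFrame:
    """Measured liquidus temperatures: columns system, x1, TL_C."""
    with resources.as_file(_data_path("liquidus_experimental.csv")) as p:
        df = pd.read_csv(p)
    if system is not None:
        df = df[df["system"] == system].reset_index(drop=True)
    return df


def load_experimental_eutectics() -> pd.DataFrame:
    """Measured eutectic temperatures and Tammann x_E estimates."""
    with resources.as_file(_data_path("eutectic_experimental.csv")) as p:
        return pd.read_csv(p)


def load_reference_eutectics() -> pd.DataFrame:
    """Published model eutectics used as regression references."""
    with resources.as_file(_data_path("reference_eutectics.csv")) as p:
        return pd.read_csv(p)


def load_reference_deviations() -> pd.DataFrame:
    """Published per-point liquidus deviations (regression references)."""
    with resources.as_file(_data_path("reference_deviations.csv")) as p:
        return pd.read_csv(p)


def load_reference_tg_fits() -> pd.DataFrame:
    """Published Gordon-Taylor/Kwei parameters and pure-NAP Tg estimates."""
    with resources.as_file(_data_path("reference_tg_fits.csv")) as p:
        return pd.read_csv(p)


def write_phase_diagram_csv(diagram: PhaseDiagram, path) -> None:
    """Phase diagram as {x1, TL_C_branch1, TL_C_branch2, stable_branch}."""
    x = diagram.branch_1.compositions
    t1 = diagram.branch_1.temperatures
    t2 = diagram.branch_2.temperatures
    stable = np.where(np.fmax(t1, t2) == t1, 1, 2)
    stable = np.where(np.isnan(t1) & np.isnan(t2), 0, stable)
    pd.DataFrame({
        "x1": x,
        "TL_C_branch1": [kelvin_to_celsius(t) if np.isfinite(t) else np.nan
                         for t in t1],
        "TL_C_branch2": [kelvin_to_celsius(t) if np.isfinite(t) else np.nan
                         for t in t2],
        "stable_branch": stable,
    }).to_csv(path, index=False)


def write_eutectic_json(eutectic: EutecticPoint, path) -> None:
    Path(path).write_text(json.dumps({
        "TE_C": round(kelvin_to_celsius(eutectic.temperature), 4),
        "xE": round(eutectic.composition, 6),
    }, indent=2) + "\n")
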