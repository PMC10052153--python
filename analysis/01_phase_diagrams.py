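#!/usr/bin/env python
"""Compute ideal and PC-SAFT phase diagrams for the four blends.

Writes per-system liquidus curves and a pooled eutectic table under
results/, and prints the comparison with the published eutectics.
"""
from pathlib import Path

import pandas as pd

from camphase import phase_diagram
from camphase.constants import kelvin_to_celsius
from camphase.registry import (SYSTEMS, binary_system,
                               load_reference_eutectics,
                               write_phase_diagram_csv)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    rows = []
    for c1, c2 in SYSTEMS:
        system = binary_system(c1, c2)
        for model in ("ideal", "pcsaft"):
            d = phase_diagram(system, model, grid=101)
            write_phase_diagram_csv(
                d, OUT / f"phase_diagram_{system.name}_{model}.csv")
            rows.append({"system": system.name, "model": model,
                         "TE_C": round(kelvin_to_celsius(
                             d.eutectic.temperature), 2),
                         "xE": round(d.eutectic.composition, 4)})
            print(f"{system.name} {model}: T_E {rows[-1]['TE_C']} C, "
                  f"x_E {rows[-1]['xE']}")
    table = pd.DataFrame(rows)
    ref = load_reference_eutectics().rename(
        columns={"TE_C": "TE_C_ref", "xE": "xE_ref"})
    table = table.merge(ref, on=["system", "model"])
    table["dTE_C"] = (table["TE_C"] - table["TE_C_ref"]).round(2)
    table.to_csv(OUT / "eutectics.csv", index=False)
    print(f"\n{table.to_string(index=False)}")
    print(f"\nwrote {OUT}/eutectics.csv and 8 phase-diagram CSVs")


if __name__ == "__main__":
    main()
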