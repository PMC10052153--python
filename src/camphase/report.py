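"""Regression report: recompute the published phase-behavior numbers.

``run_reproduction`` recomputes every eutectic (ideal and PC-SAFT) and
every liquidus deviation table from the packaged fixtures, compares them
against the published reference values at the stated tolerances, and
writes a pass/fail table.  It is the package's end-to-end self check.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import registry as reg
from . import sle
from .constants import celsius_to_kelvin, kelvin_to_celsius

__all__ = ["run_reproduction", "ReproductionResult", "TOL_TE_IDEAL_C",
           "TOL_TE_PCSAFT_C", "TOL_XE", "TOL_XE_PCSAFT"]

TOL_TE_IDEAL_C = 0.3
TOL_TE_PCSAFT_C = 1.0
TOL_XE = 0.01
TOL_XE_PCSAFT = 0.02
TOL_SIGMA_IDEAL_C = 0.2
TOL_SIGMA_PCSAFT_C = 1.0


@dataclass
class ReproductionResult:
    eutectics: pd.DataFrame
    deviations: pd.DataFrame
    n_failed: int

    @property
    def passed(self) -> bool:
        return self.n_failed == 0


def compute_eutectics(models=("ideal", "pcsaft"),
                      registry=None) -> pd.DataFrame:
    """Model eutectics (degC, mole fraction) for all four blends."""
    rows = []
    for c1, c2 in reg.SYSTEMS:
        system = reg.binary_system(c1, c2, registry)
        for model in models:
            try:
                e = sle.eutectic_point(system, model)
                rows.append({"system": system.name, "model": model,
                             "TE_C": kelvin_to_celsius(e.temperature),
                             "xE": e.composition})
            except RuntimeError as err:
                rows.append({"system": system.name, "model": model,
                             "TE_C": np.nan, "xE": np.nan,
                             "note": str(err)})
    return pd.DataFrame(rows)


def compute_deviation_table(models=("ideal", "pcsaft"),
                            registry=None) -> pd.DataFrame:
    """Recomputed liquidus deviations at the measured compositions."""
    exp = reg.load_experimental_liquidus()
    rows = []
    for c1, c2 in reg.SYSTEMS:
        system = reg.binary_system(c1, c2, registry)
        sub = exp[exp["system"] == system.name]
        for model in models:
            calc = []
            for x1 in sub["x1"]:
                try:
                    calc.append(kelvin_to_celsius(
                        sle.liquidus_at(system, float(x1), model)))
                except RuntimeError:
                    calc.append(np.nan)
            report = sle.deviation_statistics(
                calc, sub["x1"].to_numpy(), sub["TL_C"].to_numpy())
            for x1, dt, tl in zip(sub["x1"], report.per_point_deviation,
                                  calc):
                rows.append({"system": system.name, "model": model,
                             "x1": float(x1), "TL_calc_C": tl,
                             "dT_C": dt})
            rows.append({"system": system.name, "model": model,
                         "x1": np.nan, "TL_calc_C": np.nan,
                         "dT_C": report.average_absolute_deviation,
                         "is_sigma": True})
    return pd.DataFrame(rows)


def run_reproduction(path=None, models=("ideal", "pcsaft"),
                     registry=None) -> ReproductionResult:
    """Recompute eutectics and deviation statistics; compare to references.

    Writes a CSV comparison table when ``path`` is given.  A row fails
    when |recomputed - reference| exceeds the tolerance for its class
    (eutectic temperature: 0.3 degC ideal / 1.0 degC PC-SAFT; eutectic
    composition: 0.01 / 0.02; pooled deviation sigma: 0.2 / 1.0 degC).
    """
    ref_e = reg.load_reference_eutectics()
    eut = compute_eutectics(models, registry)
    eut = eut.merge(ref_e, on=["system", "model"], suffixes=("", "_ref"))
    tol_t = eut["model"].map({"ideal": TOL_TE_IDEAL_C,
                              "pcsaft": TOL_TE_PCSAFT_C})
    tol_x = eut["model"].map({"ideal": TOL_XE, "pcsaft": TOL_XE_PCSAFT})
    eut["TE_pass"] = (eut["TE_C"] - eut["TE_C_ref"]).abs() <= tol_t
    eut["xE_pass"] = (eut["xE"] - eut["xE_ref"]).abs() <= tol_x

    dev = compute_deviation_table(models, registry)
    ref_d = reg.load_reference_deviations()
    sig = dev[dev.get("is_sigma", pd.Series(dtype=bool)) == True]  # noqa: E712
    ref_sigma = {}
    for model, col in (("ideal", "dT_ideal_C"), ("pcsaft", "dT_pcsaft_C")):
        for system, grp in ref_d.groupby("system"):
            ref_sigma[(system, model)] = grp[col].abs().mean()
    checks = []
    for _, row in sig.iterrows():
        key = (row["system"], row["model"])
        if key not in ref_sigma:
            continue
        tol = TOL_SIGMA_IDEAL_C if row["model"] == "ideal" \
            else TOL_SIGMA_PCSAFT_C
        checks.append({
            "system": key[0], "model": key[1],
            "sigma_C": row["dT_C"], "sigma_ref_C": ref_sigma[key],
            "sigma_pass": abs(row["dT_C"] - ref_sigma[key]) <= tol,
        })
    sigma_df = pd.DataFrame(checks)

    n_failed = int((~eut["TE_pass"]).sum() + (~eut["xE_pass"]).sum()
                   + (~sigma_df["sigma_pass"]).sum())
    if path is not None:
        eut.to_csv(str(path), index=False)
    return ReproductionResult(eutectics=eut, deviations=sigma_df,
                              n_failed=n_failed)
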