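"""Solid-liquid equilibrium: liquidus curves, eutectic points, deviations.

The saturation (liquidus) condition for a crystalline component i in a
binary melt is

    ln(x_i * gamma_i) = -dHfus/(R T) (1 - T/Tm)
                        - 1/(R T) int_Tm^T dCp dT + 1/R int_Tm^T dCp/T dT,

with a temperature-independent heat-capacity difference dCp, so the two
integral terms reduce to -(dCp/(R T))(T - Tm) + (dCp/R) ln(T/Tm).  The
activity coefficient gamma_i is 1 for the ideal model or evaluated from
PC-SAFT at ambient pressure.  A binary eutectic is the intersection of
the two liquidus branches.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq, root

from .constants import R
from .parameters import BinaryInteraction, ComponentRecord, FusionProperties
from .pcsaft import NoDensityRootError, PcSaftMixture

__all__ = [
    "ActivityModel", "BinarySystem", "LiquidusCurve", "EutecticPoint",
    "DeviationReport", "PhaseDiagram", "solubility_rhs",
    "liquidus_temperature", "eutectic_point", "phase_diagram",
    "deviation_statistics",
]

ActivityModel = Literal["ideal", "pcsaft"]

#: Ambient pressure assumed for all liquid-phase calculations, Pa.
DEFAULT_PRESSURE = 101325.0

#: Lowest temperature considered when bracketing a liquidus root, K.
T_FLOOR = 150.0


class BinarySystem:
    """Two API records plus an optional binary interaction correction."""

    def __init__(self, component_1: ComponentRecord,
                 component_2: ComponentRecord,
                 interaction: BinaryInteraction | None = None,
                 pressure: float = DEFAULT_PRESSURE):
        self.components = (component_1, component_2)
        self.interaction = interaction or BinaryInteraction()
        self.pressure = pressure
        self._mixture: PcSaftMixture | None = None

    @property
    def name(self) -> str:
        return "-".join(c.abbreviation for c in self.components)

    @property
    def mixture(self) -> PcSaftMixture:
        if self._mixture is None:
            self._mixture = PcSaftMixture(
                [c.require_pcsaft() for c in self.components],
                self.interaction)
        return self._mixture

    def fusion(self, i: int) -> FusionProperties:
        return self.components[i].fusion


@dataclass(frozen=True)
class LiquidusCurve:
    """One liquidus branch T_L(x1) with the solid it belongs to."""

    compositions: np.ndarray        # mole fraction of component 1
    temperatures: np.ndarray        # K; NaN where the branch is not solvable
    solid: int                      # 0 or 1: index of the governing solid
    metastable: np.ndarray = field(default=None)  # True beyond the eutectic


@dataclass(frozen=True)
class EutecticPoint:
    temperature: float              # K
    composition: float              # mole fraction of component 1


@dataclass(frozen=True)
class DeviationReport:
    """Per-point deviations dT_i = T_calc - T_exp and their mean |dT|."""

    compositions: np.ndarray
    calculated: np.ndarray          # K
    experimental: np.ndarray        # K
    per_point_deviation: np.ndarray  # K

    @property
    def average_absolute_deviation(self) -> float:
        return float(np.mean(np.abs(self.per_point_deviation)))


@dataclass(frozen=True)
class PhaseDiagram:
    branch_1: LiquidusCurve
    branch_2: LiquidusCurve
    eutectic: EutecticPoint


def _rhs_raw(fusion: FusionProperties, T: float) -> float:
    # analytic form, no stability-domain guard (used inside root searches
    # whose iterates may transiently overshoot the melting point)
    tm = fusion.melting_temperature
    dh = fusion.fusion_enthalpy
    dcp = fusion.heat_capacity_difference
    return (-dh / (R * T) * (1.0 - T / tm)
            - dcp / (R * T) * (T - tm)
            + dcp / R * np.log(T / tm))


def solubility_rhs(fusion: FusionProperties, T: float) -> float:
    """Right-hand side ln(x*gamma) of the solubility equation at T (K)."""
    if T <= 0:
        raise ValueError("T must be positive")
    if T > fusion.melting_temperature:
        raise ValueError(
            f"T={T:.2f} K above the melting point "
            f"{fusion.melting_temperature:.2f} K: the solid is not stable")
    return _rhs_raw(fusion, T)


def _ln_x_gamma(system: BinarySystem, solid: int, x_solid: float,
                T: float, model: ActivityModel) -> float:
    if model == "ideal":
        return np.log(x_solid)
    x = np.array([x_solid, 1.0 - x_solid]) if solid == 0 \
        else np.array([1.0 - x_solid, x_solid])
    lg = system.mixture.ln_gamma(T, system.pressure, x, component=solid)
    return np.log(x_solid) + lg


def liquidus_temperature(system: BinarySystem, solid: int, x_solid: float,
                         model: ActivityModel = "ideal",
                         t_guess: float | None = None) -> float:
    """Temperature (K) at which solid ``solid`` saturates at x_solid.

    Solves ln(x*gamma(T, x)) = rhs(T) by bracketed root search below the
    melting point.  ``t_guess`` (K) narrows the initial bracket, which
    speeds up scans along a branch.
    """
    if not 0.0 < x_solid <= 1.0:
        raise ValueError("x must be in (0, 1]")
    tm = system.fusion(solid).melting_temperature
    if x_solid == 1.0:
        return tm

    def f(T):
        return (_ln_x_gamma(system, solid, x_solid, T, model)
                - solubility_rhs(system.fusion(solid), T))

    if model != "ideal" and t_guess is None:
        # anchor at the ideal-model root: the RHS is non-monotonic in T
        # (the dCp terms dominate at low T), so a cold bracket walk can
        # land on a spurious lower root of the saturation condition
        try:
            t_guess = liquidus_temperature(system, solid, x_solid, "ideal")
        except RuntimeError:
            t_guess = None

    if t_guess is not None and T_FLOOR < t_guess < tm:
        half = 2.0
        while half < 64.0:
            lo = max(t_guess - half, T_FLOOR)
            hi = min(t_guess + half, tm - 1e-9)
            try:
                flo, fhi = f(lo), f(hi)
            except NoDensityRootError:
                break
            if flo * fhi < 0:
                return brentq(f, lo, hi, xtol=1e-4)
            half *= 2.0

    # walk down from the melting point until the residual changes sign
    hi = tm - 1e-9
    fhi = f(hi)
    lo = hi
    step = 5.0
    while lo > T_FLOOR:
        lo = max(lo - step, T_FLOOR)
        try:
            flo = f(lo)
        except NoDensityRootError as err:
            raise RuntimeError(
                f"liquidus bracketing failed below {hi:.1f} K for "
                f"{system.name} solid {solid} at x={x_solid:.3f}: {err}"
            ) from err
        if flo * fhi < 0:
            return brentq(f, lo, hi, xtol=1e-4)
        hi, fhi = lo, flo
        step = min(step * 1.5, 10.0)
    raise RuntimeError(
        f"no liquidus root above {T_FLOOR:.0f} K for {system.name} solid "
        f"{solid} at x={x_solid:.3f}; the composition may lie beyond the "
        "eutectic for this solid")


def _liquidus_or_nan(system, solid, x_solid, model, t_guess=None):
    try:
        return liquidus_temperature(system, solid, x_solid, model,
                                    t_guess=t_guess)
    except (RuntimeError, ValueError):
        return np.nan


def eutectic_point(system: BinarySystem,
                   model: ActivityModel = "ideal",
                   method: str = "newton") -> EutecticPoint:
    """Locate the intersection of the two liquidus branches.

    ``method='newton'`` (default) solves the two saturation conditions
    simultaneously for (T_E, x_E), starting from the ideal-model
    intersection; ``method='scan'`` brackets the branch-difference root in
    composition directly.  Both locate the same intersection; the scan is
    the slower but assumption-free fallback, and is always used for the
    ideal model where single-branch solves are cheap.
    """
    if model == "ideal" or method == "scan":
        return _eutectic_scan(system, model)
    guess = _eutectic_scan(system, "ideal")

    def res(v):
        T, x1 = v
        x1 = min(max(x1, 1e-6), 1.0 - 1e-6)
        return [
            _ln_x_gamma(system, 0, x1, T, model)
            - _rhs_raw(system.fusion(0), T),
            _ln_x_gamma(system, 1, 1.0 - x1, T, model)
            - _rhs_raw(system.fusion(1), T),
        ]

    sol = root(res, [guess.temperature, guess.composition], method="hybr",
               options={"xtol": 1e-10})
    x_e = float(sol.x[1])
    t_e = float(sol.x[0])
    tms = [system.fusion(i).melting_temperature for i in range(2)]
    if (not sol.success or not 0.0 < x_e < 1.0
            or not T_FLOOR < t_e < min(tms)):
        return _eutectic_scan(system, model)
    return EutecticPoint(temperature=t_e, composition=x_e)


def _eutectic_scan(system: BinarySystem, model: ActivityModel,
                   xtol: float = 1e-6) -> EutecticPoint:
    t1 = t2 = None

    def diff(x1):
        nonlocal t1, t2
        t1 = _liquidus_or_nan(system, 0, x1, model, t_guess=t1)
        t2 = _liquidus_or_nan(system, 1, 1.0 - x1, model, t_guess=t2)
        return t1 - t2

    grid = np.concatenate([[0.002, 0.005, 0.01],
                           np.linspace(0.02, 0.98, 33),
                           [0.99, 0.995, 0.998]])
    vals = np.array([diff(x) for x in grid])
    ok = np.isfinite(vals)
    bracket = None
    for i in range(len(grid) - 1):
        if ok[i] and ok[i + 1] and vals[i] * vals[i + 1] < 0:
            bracket = (grid[i], grid[i + 1])
            break
    if bracket is None:
        raise RuntimeError(
            f"liquidus branches of {system.name} do not cross: "
            "monotonic system, no eutectic in (0, 1)")
    i = int(np.where(grid == bracket[0])[0][0])
    x_e = None
    for expand in range(3):
        lo = grid[max(i - expand, 0)]
        hi = grid[min(i + 1 + expand, len(grid) - 1)]
        t1 = t2 = None
        try:
            x_e = brentq(diff, lo, hi, xtol=xtol)
            break
        except ValueError:
            continue
    if x_e is None:
        # crossing sits within the root tolerance of a grid node
        x_e = float(grid[int(np.nanargmin(np.abs(vals)))])
    t_e = liquidus_temperature(system, 0, x_e, model)
    return EutecticPoint(temperature=t_e, composition=x_e)


def phase_diagram(system: BinarySystem, model: ActivityModel = "ideal",
                  grid: int = 101) -> PhaseDiagram:
    """Both liquidus branches on a composition grid plus the eutectic.

    The stable liquidus at a composition is the higher branch; points of
    a branch on the far side of the eutectic are metastable extensions
    and are flagged as such (where still solvable) or NaN.
    """
    eut = eutectic_point(system, model)
    xs = np.linspace(0.0, 1.0, grid)
    branches = []
    for solid in (0, 1):
        temps = np.full(grid, np.nan)
        t_prev = None
        failures = 0
        order = range(grid - 1, -1, -1) if solid == 0 else range(grid)
        for i in order:
            x_solid = xs[i] if solid == 0 else 1.0 - xs[i]
            if x_solid <= 0.0:
                continue
            temps[i] = _liquidus_or_nan(system, solid, x_solid, model,
                                        t_guess=t_prev)
            if np.isfinite(temps[i]):
                t_prev = temps[i]
                failures = 0
            else:
                # deep metastable extensions eventually stop being
                # solvable; give up on the branch after two misses
                failures += 1
                if failures >= 2:
                    break
        meta = (xs < eut.composition) if solid == 0 else (xs > eut.composition)
        branches.append(LiquidusCurve(compositions=xs, temperatures=temps,
                                      solid=solid, metastable=meta))
    return PhaseDiagram(branch_1=branches[0], branch_2=branches[1],
                        eutectic=eut)


def stable_liquidus(diagram: PhaseDiagram) -> np.ndarray:
    """Stable liquidus T_L(x) = max of the two branches, K."""
    return np.fmax(diagram.branch_1.temperatures,
                   diagram.branch_2.temperatures)


def liquidus_at(system: BinarySystem, x1: float,
                model: ActivityModel = "ideal") -> float:
    """Stable liquidus temperature (K) at a single composition x1."""
    t1 = _liquidus_or_nan(system, 0, x1, model) if x1 > 0 else np.nan
    t2 = _liquidus_or_nan(system, 1, 1.0 - x1, model) if x1 < 1 else np.nan
    t = np.nanmax([t1, t2])
    if not np.isfinite(t):
        raise RuntimeError(
            f"no liquidus branch solvable at x1={x1} for {system.name}")
    return float(t)


def deviation_statistics(calculated: Sequence[float],
                         experimental_x: Sequence[float],
                         experimental_t: Sequence[float]) -> DeviationReport:
    """Per-point dT = T_calc - T_exp and the average absolute deviation.

    ``calculated`` must be evaluated at exactly ``experimental_x``; all
    temperatures in K (or consistently in degC -- only differences and
    their absolute mean are reported).
    """
    calc = np.asarray(calculated, dtype=float)
    x = np.asarray(experimental_x, dtype=float)
    exp_t = np.asarray(experimental_t, dtype=float)
    if not (len(calc) == len(x) == len(exp_t)):
        raise ValueError(
            f"length mismatch: {len(calc)} calculated vs {len(x)} "
            f"compositions vs {len(exp_t)} experimental temperatures")
    return DeviationReport(compositions=x, calculated=calc,
                           experimental=exp_t,
                           per_point_deviation=calc - exp_t)
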