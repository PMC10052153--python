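"""Perturbed-chain SAFT equation of state for pure APIs and binary blends.

The residual Helmholtz energy is the sum of a hard-chain reference, a
dispersion perturbation and an association (hydrogen-bonding) contribution,

    a_res = a_hc + a_disp + a_assoc,

with the standard temperature-dependent segment diameter, the
Boublik-Mansoori hard-sphere mixture expression, the two power-series
dispersion integrals with the published universal constants
(:mod:`camphase.constants`), and mass-action association over
donor/acceptor site classes.  Cross association follows Wolbach-Sandler
type combining rules (arithmetic mean of the well depths; geometric mean
of the volumes corrected by the diameter ratio).

Everything downstream (compressibility, pressure, fugacity and activity
coefficients) is generated from ``a_res(T, rho, x)``.  Density and
composition derivatives are taken by complex-step differentiation, which
is exact to machine precision and therefore agrees with central finite
differences wherever the model is smooth; the site-fraction fixed point
iterates in complex arithmetic so the derivatives propagate through the
association term as well.

Units: temperature K, pressure Pa, molar density mol m^-3 on the public
surface.  Internally densities are segment-number densities in A^-3.
"""
from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .constants import A0, A1, A2, B0, B1, B2, ETA_MAX, KB, NAV
from .parameters import BinaryInteraction, PcSaftParameters

__all__ = [
    "PcSaftMixture", "ThermoState", "HelmholtzBreakdown",
    "cross_parameters", "ConvergenceError", "InvalidStateError",
    "NoDensityRootError",
]

_CSTEP = 1e-30          # relative complex-step size
_SITE_TOL = 1e-14       # site-fraction increment tolerance
_SITE_DAMPING = 0.5
_SITE_MAX_ITER = 500


class ConvergenceError(RuntimeError):
    """An inner iteration failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (last residual {residual:.3e})")
        self.residual = residual


class InvalidStateError(ValueError):
    """The requested thermodynamic state is unphysical."""


class NoDensityRootError(RuntimeError):
    """No density satisfies P(T, rho, x) = P in the physical packing range."""


def cross_parameters(p_i: PcSaftParameters, p_j: PcSaftParameters,
                     k_ij: float = 0.0) -> tuple[float, float]:
    """Cross segment diameter and dispersion energy for an (i, j) pair.

    sigma_ij is the arithmetic mean of the pure diameters and eps_ij the
    geometric mean of the pure dispersion energies corrected by (1 - k_ij).

    Returns
    -------
    (sigma_ij, eps_ij_k) : tuple of float
        Cross diameter in Angstrom and cross dispersion energy in K.
    """
    if k_ij > 1.0:
        raise ValueError("k_ij > 1 would give a negative cross dispersion energy")
    sigma_ij = 0.5 * (p_i.segment_diameter + p_j.segment_diameter)
    eps_ij = np.sqrt(p_i.dispersion_energy * p_j.dispersion_energy) * (1.0 - k_ij)
    return sigma_ij, eps_ij


@dataclass(frozen=True)
class HelmholtzBreakdown:
    """Reduced residual Helmholtz energy a_res and its three contributions."""

    hard_chain: float
    dispersion: float
    association: float

    @property
    def total(self) -> float:
        return self.hard_chain + self.dispersion + self.association


@dataclass(frozen=True)
class ThermoState:
    """A solved (T, P, x, rho) state point.

    ``molar_density`` is in mol m^-3 and ``compressibility`` is
    Z = P / (rho R T).
    """

    temperature: float
    pressure: float
    mole_fractions: np.ndarray
    molar_density: float
    compressibility: float


class PcSaftMixture:
    """PC-SAFT model for a fixed set of components.

    Parameters
    ----------
    components : sequence of PcSaftParameters
        One parameter block per component, in a fixed order.
    interaction : BinaryInteraction, optional
        Binary dispersion correction k_ij applied to every unlike pair
        (defaults to the purely predictive k_ij = 0).
    """

    def __init__(self, components: Sequence[PcSaftParameters],
                 interaction: BinaryInteraction | None = None):
        self.components = list(components)
        n = len(self.components)
        self.m = np.array([p.segment_number for p in components])
        self.sigma = np.array([p.segment_diameter for p in components])
        self.eps = np.array([p.dispersion_energy for p in components])
        self.eps_ab = np.array([p.association_energy for p in components])
        self.kappa_ab = np.array([p.association_volume for p in components])
        self.nd = np.array([p.donor_sites for p in components], dtype=float)
        self.na = np.array([p.acceptor_sites for p in components], dtype=float)
        k = (interaction or BinaryInteraction()).k_ij
        self.kij = np.full((n, n), k)
        np.fill_diagonal(self.kij, 0.0)

        self.sig_ij = 0.5 * np.add.outer(self.sigma, self.sigma)
        self.eps_ij = (np.sqrt(np.multiply.outer(self.eps, self.eps))
                       * (1.0 - self.kij))
        self._assoc_mask = (self.nd + self.na) > 0
        self._has_assoc = bool(np.any(self._assoc_mask
                                      & (self.eps_ab > 0)
                                      & (self.kappa_ab > 0)))
        # Wolbach-Sandler type cross association parameters
        self.eps_ab_ij = 0.5 * np.add.outer(self.eps_ab, self.eps_ab)
        self.kappa_ab_ij = (
            np.sqrt(np.multiply.outer(self.kappa_ab, self.kappa_ab))
            * (np.sqrt(np.multiply.outer(self.sigma, self.sigma))
               / self.sig_ij) ** 3)
        pair_ok = np.multiply.outer(self._assoc_mask, self._assoc_mask)
        self.kappa_ab_ij = np.where(pair_ok, self.kappa_ab_ij, 0.0)

    @property
    def n_components(self) -> int:
        return len(self.m)

    # ----- building blocks ------------------------------------------------

    def _prep(self, T, x):
        """Density-independent intermediates at (T, x); complex-safe."""
        x = np.asarray(x)
        d = self.sigma * (1.0 - 0.12 * np.exp(-3.0 * self.eps / T))
        zcoef = [np.pi / 6.0 * np.sum(x * self.m * d ** k) for k in range(4)]
        mbar = np.sum(x * self.m)
        xm2 = np.multiply.outer(x * self.m, x * self.m)
        s3 = self.sig_ij ** 3
        m2es3 = np.sum(xm2 * (self.eps_ij / T) * s3)
        m2e2s3 = np.sum(xm2 * (self.eps_ij / T) ** 2 * s3)
        f1 = (mbar - 1.0) / mbar
        f2 = f1 * (mbar - 2.0) / mbar
        ai = A0 + f1 * A1 + f2 * A2
        bi = B0 + f1 * B1 + f2 * B2
        dij = 0.5 * np.add.outer(d, d)
        ddij = np.multiply.outer(d, d) / np.add.outer(d, d)
        # association strength prefactor (everything except g_ij^hs)
        if self._has_assoc:
            delta0 = (self.kappa_ab_ij * s3
                      * (np.exp(self.eps_ab_ij / T) - 1.0))
        else:
            delta0 = None
        return SimpleNamespace(x=x, d=d, zcoef=zcoef, mbar=mbar,
                               m2es3=m2es3, m2e2s3=m2e2s3, ai=ai, bi=bi,
                               dij=dij, ddij=ddij, delta0=delta0)

    def _terms(self, prep, rho):
        """The three a_res contributions at segment density rho (A^-3).

        ``rho`` may be a scalar or an array; all expressions broadcast, so
        a density grid is evaluated in one pass.
        """
        rho = np.asarray(rho)
        scalar = rho.ndim == 0
        if scalar:
            rho = rho[None]
        z0 = rho * prep.zcoef[0]
        z1 = rho * prep.zcoef[1]
        z2 = rho * prep.zcoef[2]
        z3 = rho * prep.zcoef[3]
        if np.any(np.real(z3) >= ETA_MAX):
            raise InvalidStateError(
                f"packing fraction {np.max(np.real(z3)):.4f} beyond close "
                "packing")
        om = 1.0 - z3
        a_hs = (3.0 * z1 * z2 / om + z2 ** 3 / (z3 * om ** 2)
                + (z2 ** 3 / z3 ** 2 - z0) * np.log(om)) / z0
        dd = np.diag(prep.ddij)
        g_ii = (1.0 / om[..., None]
                + dd * 3.0 * z2[..., None] / om[..., None] ** 2
                + dd ** 2 * 2.0 * z2[..., None] ** 2 / om[..., None] ** 3)
        a_hc = (prep.mbar * a_hs
                - np.sum(prep.x * (self.m - 1.0) * np.log(g_ii), axis=-1))

        eta = z3
        powers = eta[..., None] ** np.arange(7)
        i1 = np.sum(prep.ai * powers, axis=-1)
        i2 = np.sum(prep.bi * powers, axis=-1)
        mbar = prep.mbar
        c1 = 1.0 / (1.0 + mbar * (8.0 * eta - 2.0 * eta ** 2) / om ** 4
                    + (1.0 - mbar)
                    * (20.0 * eta - 27.0 * eta ** 2
                       + 12.0 * eta ** 3 - 2.0 * eta ** 4)
                    / (om * (2.0 - eta)) ** 2)
        a_disp = (-2.0 * np.pi * rho * i1 * prep.m2es3
                  - np.pi * rho * mbar * c1 * i2 * prep.m2e2s3)

        if self._has_assoc:
            om2 = om[..., None, None]
            z2_2 = z2[..., None, None]
            g_ij = (1.0 / om2 + prep.ddij * 3.0 * z2_2 / om2 ** 2
                    + prep.ddij ** 2 * 2.0 * z2_2 ** 2 / om2 ** 3)
            delta = g_ij * prep.delta0
            xd, xa = self._site_fractions(prep.x, rho, delta)
            a_assoc = np.sum(prep.x * (
                self.nd * (np.log(xd) - 0.5 * xd)
                + self.na * (np.log(xa) - 0.5 * xa)
                + 0.5 * (self.nd + self.na)), axis=-1)
        else:
            a_assoc = 0.0 * a_hc
            xd = np.ones(rho.shape + self.nd.shape)
            xa = np.ones(rho.shape + self.na.shape)
        if scalar:
            return a_hc[0], a_disp[0], a_assoc[0], xd[0], xa[0]
        return a_hc, a_disp, a_assoc, xd, xa

    def _site_fractions(self, x, rho, delta):
        """Damped successive substitution for the nonbonded site fractions.

        ``delta`` has shape (..., n, n) with leading density dimensions;
        the fixed point is solved for every density point at once.
        """
        n = self.n_components
        rho = np.asarray(rho)
        dt = np.result_type(np.asarray(x).dtype, rho.dtype, delta.dtype,
                            float)
        shape = rho.shape + (n,)
        xd = np.full(shape, 0.2, dtype=dt)
        xa = np.full(shape, 0.2, dtype=dt)
        wa = np.asarray(x) * self.na
        wd = np.asarray(x) * self.nd
        rho_b = rho[..., None]
        res = np.inf
        for _ in range(_SITE_MAX_ITER):
            xd_new = 1.0 / (1.0 + rho_b * np.einsum(
                "...ij,...j->...i", delta, wa * xa))
            xa_new = 1.0 / (1.0 + rho_b * np.einsum(
                "...ji,...j->...i", delta, wd * xd))
            res = max(np.max(np.abs(xd_new - xd)),
                      np.max(np.abs(xa_new - xa)))
            xd = (1.0 - _SITE_DAMPING) * xd + _SITE_DAMPING * xd_new
            xa = (1.0 - _SITE_DAMPING) * xa + _SITE_DAMPING * xa_new
            if res < _SITE_TOL:
                return xd, xa
        raise ConvergenceError("association site fractions did not converge",
                               float(np.real(res)))

    # ----- public surface -------------------------------------------------

    def residual_helmholtz(self, T: float, molar_density: float,
                           x: Sequence[float]) -> HelmholtzBreakdown:
        """Reduced residual Helmholtz energy a_res/(RT) split into parts."""
        rho = molar_density * NAV * 1e-30
        prep = self._prep(T, np.asarray(x, dtype=float))
        a_hc, a_disp, a_assoc, _, _ = self._terms(prep, rho)
        return HelmholtzBreakdown(float(np.real(a_hc)),
                                  float(np.real(a_disp)),
                                  float(np.real(a_assoc)))

    def solve_site_fractions(self, T: float, molar_density: float,
                             x: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
        """Nonbonded donor and acceptor site fractions per component.

        Components without association sites report a fraction of 1.
        """
        if not self._has_assoc:
            n = self.n_components
            return np.ones(n), np.ones(n)
        rho = molar_density * NAV * 1e-30
        prep = self._prep(T, np.asarray(x, dtype=float))
        _, _, _, xd, xa = self._terms(prep, rho)
        return np.real(xd), np.real(xa)

    def _a_res(self, prep, rho):
        a_hc, a_disp, a_assoc, _, _ = self._terms(prep, rho)
        return a_hc + a_disp + a_assoc

    def _z_of(self, prep, rho):
        """Compressibility Z = 1 + rho d(a_res)/d(rho) via complex step."""
        h = _CSTEP * np.real(rho)
        da = np.imag(self._a_res(prep, rho + 1j * h)) / h
        return 1.0 + np.real(rho) * da

    def compressibility(self, T: float, molar_density: float,
                        x: Sequence[float]) -> float:
        rho = molar_density * NAV * 1e-30
        prep = self._prep(T, np.asarray(x, dtype=float))
        return float(self._z_of(prep, rho))

    def pressure(self, T: float, molar_density: float,
                 x: Sequence[float]) -> float:
        """Pressure in Pa from the EOS at (T, rho, x)."""
        rho = molar_density * NAV * 1e-30
        prep = self._prep(T, np.asarray(x, dtype=float))
        return self._z_of(prep, rho) * KB * T * rho * 1e30

    def _eta_to_rho(self, prep, eta):
        return eta / prep.zcoef[3]

    def solve_density(self, T: float, P: float, x: Sequence[float],
                      phase: str = "liquid") -> ThermoState:
        """Solve P(T, rho, x) = P for the density of the requested phase.

        The liquid root is the highest-packing solution, the vapor root the
        lowest.  ``phase='stable'`` picks, among all roots, the one with
        the lower residual Gibbs energy.
        """
        if T <= 0 or P <= 0:
            raise InvalidStateError("T and P must be positive")
        x = np.asarray(x, dtype=float)
        prep = self._prep(T, x)

        def p_err(eta):
            rho = self._eta_to_rho(prep, eta)
            return self._z_of(prep, rho) * KB * T * rho * 1e30 - P

        grid = np.concatenate([
            np.array([1e-10, 1e-7, 1e-5, 1e-3]),
            np.linspace(0.01, ETA_MAX - 1e-3, 56),
        ])
        vals = p_err(grid)  # vectorized over the whole packing grid
        roots = []
        for i in range(len(grid) - 1):
            if np.isfinite(vals[i]) and np.isfinite(vals[i + 1]) \
                    and vals[i] * vals[i + 1] < 0:
                eta = brentq(p_err, grid[i], grid[i + 1], xtol=1e-15,
                             rtol=8.9e-16)
                roots.append(eta)
        if not roots:
            raise NoDensityRootError(
                f"no density root at T={T:.2f} K, P={P:.0f} Pa, x={x}")
        def g_res(eta):
            rho = self._eta_to_rho(prep, eta)
            z = self._z_of(prep, rho)
            return (np.real(self._a_res(prep, rho)) + (z - 1.0)
                    - np.log(z))

        # vapor-like roots sit at low packing; several liquid-like roots
        # can coexist at low T in strongly associating systems (a known
        # artifact), so liquid-like candidates are ranked by residual
        # Gibbs energy
        liquid_like = [e for e in roots if e >= 0.15]
        vapor_like = [e for e in roots if e < 0.15]
        if phase == "liquid":
            eta = min(liquid_like or roots, key=g_res)
        elif phase == "vapor":
            eta = vapor_like[0] if vapor_like else min(roots, key=g_res)
        elif phase == "stable":
            eta = min(roots, key=g_res)
        else:
            raise ValueError(f"unknown phase {phase!r}")
        rho = self._eta_to_rho(prep, eta)
        z = self._z_of(prep, rho)
        return ThermoState(temperature=T, pressure=P, mole_fractions=x,
                           molar_density=rho * 1e30 / NAV,
                           compressibility=float(z))

    def ln_phi(self, state: ThermoState) -> np.ndarray:
        """Log fugacity coefficients ln phi_i at a solved state.

        ln phi_i = a_res + da/dx_i - sum_j x_j da/dx_j + (Z - 1) - ln Z,
        with the composition derivatives taken at constant (T, rho) in the
        unconstrained convention (the mole fractions are differentiated as
        independent variables).
        """
        z = state.compressibility
        if z <= 0:
            raise InvalidStateError(f"non-positive compressibility Z={z}")
        T = state.temperature
        x = state.mole_fractions
        rho = state.molar_density * NAV * 1e-30
        prep = self._prep(T, x)
        a = np.real(self._a_res(prep, rho))
        n = self.n_components
        dadx = np.empty(n)
        for i in range(n):
            xc = x.astype(complex).copy()
            xc[i] += 1j * _CSTEP
            dadx[i] = np.imag(self._a_res(self._prep(T, xc), rho)) / _CSTEP
        return a + dadx - np.sum(x * dadx) + (z - 1.0) - np.log(z)

    def fugacity_coefficients(self, T: float, P: float, x: Sequence[float],
                              phase: str = "liquid") -> np.ndarray:
        """Convenience wrapper: solve the density, then evaluate ln phi_i."""
        return self.ln_phi(self.solve_density(T, P, x, phase=phase))

    def _pure(self, i: int) -> "PcSaftMixture":
        return PcSaftMixture([self.components[i]])

    def ln_gamma(self, T: float, P: float, x: Sequence[float],
                 component: int | None = None):
        """Log activity coefficients in the liquid at (T, P, x).

        ln gamma_i = ln phi_i(mixture) - ln phi(pure liquid i).  With
        ``component`` given, only that component's value is returned
        (saves the other pure-reference density solve).
        """
        x = np.asarray(x, dtype=float)
        lp_mix = self.ln_phi(self.solve_density(T, P, x, phase="liquid"))
        idx = range(self.n_components) if component is None else [component]
        out = np.empty(len(lp_mix))
        out[:] = np.nan
        for i in idx:
            pure = self._pure(i)
            try:
                st0 = pure.solve_density(T, P, np.array([1.0]), phase="liquid")
            except NoDensityRootError as err:
                raise NoDensityRootError(
                    f"pure-liquid reference of component {i} has no "
                    f"density root at T={T:.2f} K") from err
            out[i] = lp_mix[i] - pure.ln_phi(st0)[0]
        return out[component] if component is not None else out

    def activity_coefficients(self, T: float, P: float,
                              x: Sequence[float]) -> np.ndarray:
        """Activity coefficients gamma_i of every component (liquid)."""
        return np.exp(self.ln_gamma(T, P, x))
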