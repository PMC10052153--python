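"""Seeded synthetic datasets with the structure of the DSC measurements.

Three generators mirror the three kinds of experimental input the
analyses consume: mixture glass transitions versus composition
(Gordon-Taylor/Kwei curves), liquidus temperatures versus composition
(solubility equation under a chosen activity model), and Tammann plots
(eutectic-peak enthalpy, two linear branches vanishing at the pure
components).  All randomness comes from ``numpy``'s PCG64 generator
seeded through the spec, so a dataset is reproducible byte for byte.

Default noise levels follow the stated measurement uncertainties of the
emulated experiments: 0.3 K for transition temperatures (liquidus and
Tg) and 3% relative for enthalpies.
"""
from __future__ import annotations

from typing import Any, Mapping

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import sle
from .tammann import TammannDataset
from .tg import TgDataset, gordon_taylor, kwei

__all__ = [
    "GeneratorSpec", "generate_tg_dataset", "generate_liquidus_dataset",
    "generate_tammann_dataset",
]

#: stated 0.95-confidence uncertainty of transition-temperature readings, K
TEMPERATURE_NOISE_SD = 0.3
#: relative uncertainty of enthalpy integrations
ENTHALPY_NOISE_REL = 0.03

RNG_ALGORITHM = "numpy.random.PCG64"


class GeneratorSpec(BaseModel):
    """Seed, noise level, size and generating truth for one dataset."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    #: None picks the generator's default (0.3 K for temperatures,
    #: 3% relative for enthalpies)
    noise_sd: float | None = Field(default=None, ge=0.0)
    n_points: int = Field(default=9, ge=1)
    truth: Mapping[str, Any] = Field(default_factory=dict)

    def metadata(self) -> dict:
        return {"seed": self.seed, "noise_sd": self.noise_sd,
                "n_points": self.n_points, "rng": RNG_ALGORITHM,
                "truth": {k: v for k, v in self.truth.items()
                          if not hasattr(v, "components")}}


def generate_tg_dataset(spec: GeneratorSpec,
                        x_range: tuple[float, float] = (0.0, 0.7)
                        ) -> TgDataset:
    """Mixture-Tg points on a uniform composition grid plus noise.

    ``truth`` must hold ``model`` ("gordon_taylor" or "kwei"), ``k``,
    ``Tg_1``, ``Tg_2`` in K and, for Kwei, ``q``.  The default grid stops
    at x_1 = 0.7: mixtures richer in a poor glass former than that cannot
    be quenched to a single glass, so no Tg reading exists there.
    """
    t = dict(spec.truth)
    model = t.get("model", "gordon_taylor")
    sd = TEMPERATURE_NOISE_SD if spec.noise_sd is None else spec.noise_sd
    x = np.linspace(x_range[0], x_range[1], spec.n_points)
    if model == "kwei":
        tg = kwei(x, t["Tg_1"], t["Tg_2"], t["k"], t["q"])
    else:
        tg = gordon_taylor(x, t["Tg_1"], t["Tg_2"], t["k"])
    rng = np.random.default_rng(spec.seed)
    tg = tg + sd * rng.standard_normal(len(x))
    return TgDataset(compositions=x, glass_transitions=tg)


def generate_liquidus_dataset(spec: GeneratorSpec,
                              compositions: np.ndarray | None = None):
    """Experimental-style (x1, T_L) table from a model liquidus plus noise.

    ``truth`` must hold ``system`` (a :class:`~camphase.sle.BinarySystem`)
    and may hold ``model`` ("ideal" default, or "pcsaft").  The stable
    liquidus is evaluated at the requested compositions (default: the
    0.1-spaced grid of the emulated measurements), Gaussian noise with
    ``noise_sd`` (K) is added, and no point is allowed below the eutectic
    temperature, where the liquidus ceases to exist.

    Returns
    -------
    (x, T_L, eutectic) : compositions, noisy liquidus temperatures in K,
        and the generating :class:`~camphase.sle.EutecticPoint`.
    """
    system = spec.truth["system"]
    model = spec.truth.get("model", "ideal")
    if compositions is None:
        compositions = np.round(np.linspace(0.1, 0.9, spec.n_points), 6)
    x = np.asarray(compositions, dtype=float)
    eut = sle.eutectic_point(system, model)
    sd = TEMPERATURE_NOISE_SD if spec.noise_sd is None else spec.noise_sd
    t_clean = np.array([sle.liquidus_at(system, xi, model) for xi in x])
    rng = np.random.default_rng(spec.seed)
    t_noisy = t_clean + sd * rng.standard_normal(len(x))
    return x, np.maximum(t_noisy, eut.temperature), eut


def generate_tammann_dataset(spec: GeneratorSpec,
                             compositions: np.ndarray | None = None
                             ) -> TammannDataset:
    """Triangular Tammann plot with apex at the true eutectic plus noise.

    ``truth``: ``x_E`` in (0, 1) and ``peak_enthalpy`` (J/mol, the
    enthalpy at the apex).  Branch values vanish at the pure components.
    Noise is relative (``noise_sd`` interpreted as a fraction of the
    apex enthalpy, default 3%).
    """
    x_e = float(spec.truth["x_E"])
    if not 0.0 < x_e < 1.0:
        raise ValueError("x_E must lie in (0, 1)")
    h_peak = float(spec.truth.get("peak_enthalpy", 100.0))
    if compositions is None:
        compositions = np.round(np.linspace(0.1, 0.9, spec.n_points), 6)
    x = np.asarray(compositions, dtype=float)
    h = np.where(x <= x_e, h_peak * x / x_e, h_peak * (1.0 - x) / (1.0 - x_e))
    noise_rel = ENTHALPY_NOISE_REL if spec.noise_sd is None else spec.noise_sd
    rng = np.random.default_rng(spec.seed)
    h = np.maximum(h + noise_rel * h_peak * rng.standard_normal(len(x)), 0.0)
    return TammannDataset(compositions=x, enthalpies=h)
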