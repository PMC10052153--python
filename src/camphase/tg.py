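"""Gordon-Taylor and Kwei modelling of mixture glass transitions.

The Gordon-Taylor equation interpolates the glass transition of a binary
amorphous mixture between the pure endpoints,

    Tg(x1) = (x1 Tg1 + k x2 Tg2) / (x1 + k x2),      x2 = 1 - x1,

with a single shape parameter k > 0.  The Kwei equation adds a quadratic
interaction term q x1 x2.  Compositions are mole fractions and the Tg
arithmetic is done in kelvin by default (the quotient structure makes the
fitted k depend on the temperature origin; a Celsius switch is provided
for sensitivity checks).

Fitting supports an arbitrary free/fixed parameter mask, which is how a
missing pure-component Tg (a poor glass former that cannot be vitrified
alone) is extrapolated from mixture data.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import T_CELSIUS

__all__ = [
    "TgDataset", "TgModelFit", "gordon_taylor", "kwei", "fit_tg_model",
    "pooled_pure_tg",
]

TgModelName = Literal["gordon_taylor", "kwei"]

_PARAM_ORDER = ("k", "q", "Tg_1", "Tg_2")
_BOUNDS = {"k": (1e-6, 10.0), "q": (-200.0, 200.0),
           "Tg_1": (50.0, 1000.0), "Tg_2": (50.0, 1000.0)}


@dataclass(frozen=True)
class TgDataset:
    """Measured mixture glass transitions versus composition.

    ``compositions`` are mole fractions of component 1; ``glass_transitions``
    are in K.
    """

    compositions: np.ndarray
    glass_transitions: np.ndarray
    component_1: str = "1"
    component_2: str = "2"

    def __post_init__(self):
        x = np.asarray(self.compositions, dtype=float)
        t = np.asarray(self.glass_transitions, dtype=float)
        if x.shape != t.shape:
            raise ValueError("compositions and Tg arrays differ in length")
        if np.any((x < 0) | (x > 1)):
            raise ValueError("compositions must lie in [0, 1]")
        object.__setattr__(self, "compositions", x)
        object.__setattr__(self, "glass_transitions", t)

    def __len__(self) -> int:
        return len(self.compositions)


@dataclass(frozen=True)
class TgModelFit:
    """Result of a Gordon-Taylor or Kwei least-squares fit."""

    model: TgModelName
    k: float
    q: float                      # 0 and unused for gordon_taylor
    Tg_1: float                   # K
    Tg_2: float                   # K
    free_parameters: tuple[str, ...]
    residual_sd: float            # K
    rss: float                    # K^2

    @property
    def estimated_pure_tg(self) -> float | None:
        """The fitted pure-component Tg, when one endpoint was free."""
        if "Tg_1" in self.free_parameters:
            return self.Tg_1
        if "Tg_2" in self.free_parameters:
            return self.Tg_2
        return None

    def predict(self, x1) -> np.ndarray:
        if self.model == "kwei":
            return kwei(x1, self.Tg_1, self.Tg_2, self.k, self.q)
        return gordon_taylor(x1, self.Tg_1, self.Tg_2, self.k)


def gordon_taylor(x_1, Tg_1: float, Tg_2: float, k: float):
    """Gordon-Taylor mixture Tg; inputs and output in consistent units."""
    if k <= 0:
        raise ValueError("k must be positive")
    x_1 = np.asarray(x_1, dtype=float)
    x_2 = 1.0 - x_1
    return (x_1 * Tg_1 + k * x_2 * Tg_2) / (x_1 + k * x_2)


def kwei(x_1, Tg_1: float, Tg_2: float, k: float, q: float):
    """Kwei mixture Tg: Gordon-Taylor plus the interaction term q x1 x2."""
    x_1 = np.asarray(x_1, dtype=float)
    return gordon_taylor(x_1, Tg_1, Tg_2, k) + q * x_1 * (1.0 - x_1)


def _model_tg(model: TgModelName, x, p: Mapping[str, float]):
    if model == "kwei":
        return kwei(x, p["Tg_1"], p["Tg_2"], p["k"], p["q"])
    return gordon_taylor(x, p["Tg_1"], p["Tg_2"], p["k"])


def fit_tg_model(data: TgDataset, model: TgModelName = "gordon_taylor",
                 free_parameters: Sequence[str] = ("k",),
                 initial: Mapping[str, float] | None = None,
                 celsius: bool = False) -> TgModelFit:
    """Least-squares fit of a mixture-Tg model with a free/fixed mask.

    Parameters
    ----------
    data : TgDataset
        Compositions (mole fraction of component 1) and Tg values in K.
    model : {"gordon_taylor", "kwei"}
    free_parameters : subset of {"k", "q", "Tg_1", "Tg_2"}
        Parameters optimised; the rest must be supplied in ``initial`` and
        are returned unchanged.  Fixed endpoint Tg values are mandatory.
    initial : mapping
        Starting values (and values for fixed parameters).  Defaults:
        k = 1, q = 0, endpoints from the data extremes.
    celsius : bool
        Evaluate the model quotient on the Celsius scale instead of
        kelvin (for probing the scale-dependence of k).  Input data stay
        in K either way.

    Notes
    -----
    The objective sum((Tg_model - Tg_obs)^2) is minimised with bounded
    least squares from a small deterministic multistart (k and q are the
    parameters at risk of local minima when an endpoint is also free).
    """
    free = tuple(free_parameters)
    if model == "gordon_taylor" and "q" in free:
        raise ValueError("q is not a Gordon-Taylor parameter")
    unknown = set(free) - set(_PARAM_ORDER)
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")
    n_free = len(free)
    if len(data) < n_free + 1:
        raise ValueError(
            f"{len(data)} points cannot determine {n_free} free parameters")

    x = data.compositions
    t_obs = data.glass_transitions
    params = {"k": 1.0, "q": 0.0,
              "Tg_1": float(t_obs[np.argmax(x)]),
              "Tg_2": float(t_obs[np.argmin(x)])}
    if initial:
        params.update(initial)
    for name in ("Tg_1", "Tg_2"):
        if name not in free and initial is not None and name not in initial \
                and not np.any(np.isclose(x, 1.0 if name == "Tg_1" else 0.0)):
            raise ValueError(
                f"fixed endpoint {name} must be given in `initial` when the "
                "data do not include that pure component")

    offset = T_CELSIUS if celsius else 0.0

    def residuals(theta):
        p = dict(params)
        p.update(zip(free, theta))
        pred = _model_tg(model, x, {**p,
                                    "Tg_1": p["Tg_1"] - offset,
                                    "Tg_2": p["Tg_2"] - offset}) + offset
        return pred - t_obs

    lo = np.array([_BOUNDS[n][0] for n in free])
    hi = np.array([_BOUNDS[n][1] for n in free])
    starts = [np.array([params[n] for n in free], dtype=float)]
    for k0 in (0.3, 0.7, 1.5, 3.0):
        s = starts[0].copy()
        if "k" in free:
            s[free.index("k")] = k0
        starts.append(s)

    best = None
    for s0 in starts:
        s0 = np.clip(s0, lo, hi)
        try:
            sol = least_squares(residuals, s0, bounds=(lo, hi),
                                method="trf", xtol=1e-14, ftol=1e-14,
                                gtol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("Tg model fit failed from every start point")

    fitted = dict(params)
    fitted.update(zip(free, best.x))
    res = residuals(best.x)
    dof = max(len(data) - n_free, 1)
    return TgModelFit(model=model, k=float(fitted["k"]),
                      q=float(fitted["q"]) if model == "kwei" else 0.0,
                      Tg_1=float(fitted["Tg_1"]), Tg_2=float(fitted["Tg_2"]),
                      free_parameters=free,
                      residual_sd=float(np.sqrt(np.sum(res ** 2) / dof)),
                      rss=float(np.sum(res ** 2)))


def pooled_pure_tg(estimates: Iterable[float]) -> tuple[float, float]:
    """Mean and standard deviation of the mean of pure-Tg estimates.

    Accepts either plain numbers or :class:`TgModelFit` objects with a
    fitted pure endpoint.
    """
    vals = []
    for e in estimates:
        if isinstance(e, TgModelFit):
            v = e.estimated_pure_tg
            if v is None:
                raise ValueError("fit has no estimated pure Tg")
            vals.append(v)
        else:
            vals.append(float(e))
    if len(vals) < 2:
        raise ValueError("need at least two estimates to pool")
    arr = np.array(vals)
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(len(arr)))
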