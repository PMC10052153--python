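"""Tammann-plot estimation of the eutectic composition.

In a DSC composition series the enthalpy of the eutectic melting peak
grows linearly with the amount of eutectic material, vanishing at both
pure components and peaking at the eutectic composition.  Fitting one
straight line to each side and intersecting them therefore locates x_E
without any liquidus modelling.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TammannDataset", "TammannEstimate", "tammann_eutectic"]


@dataclass(frozen=True)
class TammannDataset:
    """Eutectic-peak enthalpies versus composition.

    ``enthalpies`` may be molar (J/mol) or specific (J/g); the unit only
    scales the plot and is recorded for bookkeeping.
    """

    compositions: np.ndarray
    enthalpies: np.ndarray
    unit: str = "J/mol"

    def __post_init__(self):
        x = np.asarray(self.compositions, dtype=float)
        h = np.asarray(self.enthalpies, dtype=float)
        if x.shape != h.shape:
            raise ValueError("composition and enthalpy arrays differ in length")
        if np.any(h < 0):
            raise ValueError("eutectic-peak enthalpies must be non-negative")
        object.__setattr__(self, "compositions", x)
        object.__setattr__(self, "enthalpies", h)

    def mirrored(self) -> "TammannDataset":
        """The same data with the component labels swapped (x -> 1-x)."""
        return TammannDataset(1.0 - self.compositions, self.enthalpies,
                              self.unit)


@dataclass(frozen=True)
class TammannEstimate:
    composition: float            # x_E
    uncertainty: float            # 1-sigma, from the fit covariances
    ascending: tuple[float, float]    # (slope, intercept) left branch
    descending: tuple[float, float]   # (slope, intercept) right branch


def _line_fit(x, y, through: float | None):
    """LSQ line y = a x + b; ``through`` forces y(through) = 0.

    Returns (a, b, cov) with cov the 2x2 covariance of (a, b).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if through is None:
        if len(x) < 2:
            raise ValueError("need at least 2 points per branch")
        A = np.column_stack([x, np.ones_like(x)])
    else:
        if len(x) < 1:
            raise ValueError("need at least 1 point per branch")
        A = (x - through)[:, None]
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    dof = len(x) - A.shape[1]
    if dof > 0:
        s2 = float(np.sum((A @ coef - y) ** 2) / dof)
    else:
        s2 = 0.0
    cov_small = s2 * np.linalg.inv(A.T @ A)
    if through is None:
        return coef[0], coef[1], cov_small
    # y = a (x - through): slope a, intercept -a*through
    a = coef[0]
    var_a = cov_small[0, 0]
    cov = np.array([[var_a, -through * var_a],
                    [-through * var_a, through ** 2 * var_a]])
    return a, -a * through, cov


def tammann_eutectic(data: TammannDataset,
                     constrain_zero_at_pure: bool = False,
                     exclude_near_peak: int = 0) -> TammannEstimate:
    """Eutectic composition from the intersection of two Tammann branches.

    Parameters
    ----------
    data : TammannDataset
    constrain_zero_at_pure : bool
        Force the ascending line through (0, 0) and the descending line
        through (1, 0).
    exclude_near_peak : int
        Drop this many points adjacent to the empirical enthalpy maximum
        on each side (the eutectic and liquidus peaks overlap near x_E,
        making those integrations least reliable).  The apex point itself
        is always excluded from both branches.

    Returns
    -------
    TammannEstimate
        x_E with a 1-sigma uncertainty propagated from the two line-fit
        covariances.
    """
    order = np.argsort(data.compositions)
    x = data.compositions[order]
    h = data.enthalpies[order]
    i_max = int(np.argmax(h))
    lo = max(i_max - exclude_near_peak, 0)
    hi = min(i_max + exclude_near_peak, len(x) - 1)
    left = slice(0, lo)
    right = slice(hi + 1, len(x))
    if len(x[left]) == 0 or len(x[right]) == 0:
        raise ValueError(
            "all usable points lie on one side of the enthalpy maximum")

    a1, b1, cov1 = _line_fit(x[left], h[left],
                             0.0 if constrain_zero_at_pure else None)
    a2, b2, cov2 = _line_fit(x[right], h[right],
                             1.0 if constrain_zero_at_pure else None)
    if a1 == a2:
        raise ValueError("branches are parallel; no intersection")
    x_e = (b2 - b1) / (a1 - a2)
    if not 0.0 < x_e < 1.0:
        raise ValueError(f"branch intersection x={x_e:.3f} outside (0, 1)")

    # first-order propagation: x_E = (b2-b1)/(a1-a2)
    da = a1 - a2
    g1 = np.array([-x_e / da, -1.0 / da])      # d x_E/d(a1, b1)
    g2 = np.array([x_e / da, 1.0 / da])        # d x_E/d(a2, b2)
    var = float(g1 @ cov1 @ g1 + g2 @ cov2 @ g2)
    return TammannEstimate(composition=float(x_e),
                           uncertainty=float(np.sqrt(max(var, 0.0))),
                           ascending=(float(a1), float(b1)),
                           descending=(float(a2), float(b2)))
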