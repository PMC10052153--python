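"""Physical constants and the PC-SAFT universal dispersion constants.

The power-series coefficients ``A0..A2`` / ``B0..B2`` are the universal
model constants of the original perturbed-chain SAFT dispersion term
(first-order and second-order perturbation integrals).  They are model
constants, not fit parameters of this package.
"""
from __future__ import annotations

import numpy as np

#: Molar gas constant, J K^-1 mol^-1 (CODATA).
R = 8.31446

#: Boltzmann constant, J K^-1.
KB = 1.380649e-23

#: Avogadro constant, mol^-1.
NAV = 6.02214076e23

#: Offset between the Celsius and Kelvin scales.
T_CELSIUS = 273.15

#: Close packing limit of the reduced segment packing fraction.
ETA_MAX = 0.7405

# First-order dispersion integral coefficients a_0i, a_1i, a_2i.
A0 = np.array([0.9105631445, 0.6361281449, 2.6861347891, -26.547362491,
               97.759208784, -159.59154087, 91.297774084])
A1 = np.array([-0.3084016918, 0.1860531159, -2.5030047259, 21.419793629,
               -65.255885330, 83.318680481, -33.746922930])
A2 = np.array([-0.0906148351, 0.4527842806, 0.5962700728, -1.7241829131,
               -4.1302112531, 13.776631870, -8.6728470368])

# Second-order dispersion integral coefficients b_0i, b_1i, b_2i.
B0 = np.array([0.7240946941, 2.2382791861, -4.0025849485, -21.003576815,
               26.855641363, 206.55133841, -355.60235612])
B1 = np.array([-0.5755498075, 0.6995095521, 3.8925673390, -17.215471648,
               192.67226447, -161.82646165, -165.20769346])
B2 = np.array([0.0976883116, -0.2557574982, -9.1558561530, 20.642075974,
               -38.804430052, 93.626774077, -29.666905585])


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + T_CELSIUS


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - T_CELSIUS
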