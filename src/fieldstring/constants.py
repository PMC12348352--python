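"""Physical constants (CODATA 2018) and unit helpers.

All free energies are in kJ/mol, temperatures in K, angles in degrees at
public interfaces and radians inside the samplers.
"""

import numpy as np

#: Boltzmann constant, J/K
K_B = 1.380649e-23
#: Planck constant, J s
PLANCK_H = 6.62607015e-34
#: Speed of light, cm/s (for wavenumber conversions)
C_CM = 2.99792458e10
#: Molar gas constant, J/(mol K)
R_GAS = 8.314462618
#: Avogadro constant, 1/mol
N_A = 6.02214076e23

#: h*c/k_B in cm*K — converts a wavenumber times this, divided by T, into
#: a dimensionless vibrational temperature ratio.
HC_OVER_KB_CM_K = PLANCK_H * C_CM / K_B  # = 1.438777 cm K

DEG = np.pi / 180.0
RAD = 180.0 / np.pi


def rt_kj_mol(temperature: float) -> float:
    """Thermal energy RT in kJ/mol at the given temperature in K."""
    return R_GAS * temperature / 1000.0
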