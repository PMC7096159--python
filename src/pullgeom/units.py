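"""Unit constants and conversions used across the package.

Internal working units: force in pN, length in nm (Å where noted for
trajectories), time in s (ns for trajectories), energy in pN·nm, spring
constants in N/m. Simulation spring constants are commonly quoted in
kcal/(mol·Å²); :func:`spring_constant_to_si` converts them.
"""

from __future__ import annotations

from scipy import constants as _const

#: Thermal energy kB·T at 300 K, in pN·nm (1 kBT = 4.141947e-21 J).
KBT_300K_PN_NM: float = _const.Boltzmann * 300.0 * 1e21  # J -> pN·nm

#: One kcal/mol in joules.
KCAL_PER_MOL_J: float = 1000.0 * _const.calorie / _const.Avogadro

#: One kcal/(mol·Å) expressed in pN.
KCAL_PER_MOL_A_PN: float = KCAL_PER_MOL_J / 1e-10 * 1e12

#: kBT at 300 K in kcal/mol (for Langevin dynamics in simulation units).
KBT_300K_KCAL_MOL: float = _const.Boltzmann * 300.0 / KCAL_PER_MOL_J


def spring_constant_to_si(k_kcal_mol_A2: float) -> float:
    """Convert a spring constant from kcal/(mol·Å²) to N/m.

    1 kcal/(mol·Å²) = 4184 J / (6.022e23 · 1e-20 m²) = 0.6948 N/m, so the
    1.0 kcal/(mol·Å²) restraint standard in constant-velocity steered-MD
    corresponds to 0.69 N/m.
    """
    return k_kcal_mol_A2 * KCAL_PER_MOL_J / 1e-20


def spring_constant_from_si(k_N_m: float) -> float:
    """Convert a spring constant from N/m to kcal/(mol·Å²)."""
    return k_N_m * 1e-20 / KCAL_PER_MOL_J
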