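"""Physical constants and unit conversion helpers.

Convention used throughout the package: steering engines report work in
kJ/mol, free energies are reported in kcal/mol, and the toy simulator works
in reduced units where k_B*T = 1 ("kT"). The functions here are the single
place where the three meet.
"""

from __future__ import annotations

import numpy as np
from scipy import constants as _sc

#: kJ per kcal (thermochemical calorie), fixed by definition.
KJ_PER_KCAL = 4.184

#: Molar gas constant in kJ/(mol K).
GAS_CONSTANT_KJ = _sc.R / 1000.0

#: Units accepted for work curves.
WORK_UNITS = ("kJ/mol", "kcal/mol", "kT")


def kt_kj(temperature: float) -> float:
    """k_B*T in kJ/mol at `temperature` (K)."""
    if not temperature > 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return GAS_CONSTANT_KJ * temperature


def kt_kcal(temperature: float) -> float:
    """k_B*T in kcal/mol at `temperature` (K). About 0.592 kcal/mol at 298 K."""
    return kt_kj(temperature) / KJ_PER_KCAL


def to_kcal(work, units: str, temperature: float = 298.0):
    """Convert work values from `units` to kcal/mol.

    "kT" values are interpreted as multiples of k_B*T at `temperature`.
    """
    w = np.asarray(work, dtype=float)
    if units == "kcal/mol":
        return w
    if units == "kJ/mol":
        return w / KJ_PER_KCAL
    if units == "kT":
        return w * kt_kcal(temperature)
    raise ValueError(f"unknown work units {units!r}; expected one of {WORK_UNITS}")


def beta_kcal(temperature: float = 298.0) -> float:
    """Inverse temperature 1/(k_B*T) in (kcal/mol)^-1."""
    return 1.0 / kt_kcal(temperature)
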