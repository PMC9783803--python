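"""Unit conventions and physical constants.

All in-memory quantities use the package's internal unit system:
lengths in angstrom (Å), times in femtoseconds (fs), masses in unified
atomic mass units (amu) and energies in kcal/mol.  Conversions to and
from atomic units happen only at file boundaries (CPMD TRAJECTORY dialect)
and when quoting electronic-structure descriptors.

The derived mechanical energy unit amu·Å²·fs⁻² equals exactly
1 / KCAL_PER_MOL_TO_MECH kcal/mol (thermochemical calorie, 4.184 J).
"""

from __future__ import annotations

# -- file-boundary conversions (CPMD atomic units) ---------------------------
BOHR_TO_ANGSTROM = 0.52917721
AU_TIME_TO_FS = 0.02418884
#: atomic velocity unit (bohr per a.u. time) in Å/fs
AU_VELOCITY_TO_ANGSTROM_FS = BOHR_TO_ANGSTROM / AU_TIME_TO_FS

# -- thermodynamic / spectroscopic constants ---------------------------------
#: Boltzmann constant, kcal·mol⁻¹·K⁻¹
KB_KCAL = 0.0019872
#: hartree → kcal/mol
HARTREE_TO_KCAL = 627.5095
#: speed of light in cm/fs (wavenumber axis conversions)
C_CM_PER_FS = 2.99792458e-5

# -- mechanical unit bridge --------------------------------------------------
#: kcal/mol expressed in amu·Å²·fs⁻² (exact: 4184 J/mol over 1 g/mol scale)
KCAL_PER_MOL_TO_MECH = 4.184e-4
#: ħ in kcal·mol⁻¹·fs
HBAR_KCAL_FS = 1.054571817e-34 * 6.02214076e23 / 4184.0 * 1e15
#: ħ in mechanical units (amu·Å²·fs⁻¹)
HBAR_MECH = HBAR_KCAL_FS * KCAL_PER_MOL_TO_MECH
#: Boltzmann constant in mechanical units (amu·Å²·fs⁻²·K⁻¹)
KB_MECH = KB_KCAL * KCAL_PER_MOL_TO_MECH

#: standard atomic masses in amu for the elements the toy bridges emit
ATOMIC_MASSES = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403,
}


def atomic_mass(label: str) -> float:
    """Mass in amu for an element symbol (case-sensitive, e.g. ``"O"``)."""
    try:
        return ATOMIC_MASSES[label]
    except KeyError:
        raise KeyError(
            f"no tabulated mass for element {label!r}; known: "
            f"{sorted(ATOMIC_MASSES)}"
        ) from None


def wavenumber_to_angular_frequency(wavenumber_cm: float) -> float:
    """Convert a wavenumber in cm⁻¹ to angular frequency in rad/fs."""
    import math

    return 2.0 * math.pi * C_CM_PER_FS * wavenumber_cm


def angular_frequency_to_wavenumber(omega_rad_fs: float) -> float:
    """Convert angular frequency (rad/fs) to wavenumber (cm⁻¹)."""
    import math

    return omega_rad_fs / (2.0 * math.pi * C_CM_PER_FS)
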