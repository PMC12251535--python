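"""Physical constants and unit conversions.

Internal unit system everywhere in the package:

* length      Å
* time        fs
* mass        amu
* energy      amu·Å²/fs²   (1 amu·Å²/fs² = 10⁷/N_A J ≈ 1.6605×10⁻¹⁷ J)
* wavenumber  cm⁻¹ (spectral axes only)

All conversion to and from other unit systems happens at the I/O boundary.
"""

from __future__ import annotations

import numpy as np

#: Boltzmann constant in amu·Å²·fs⁻²·K⁻¹ (CODATA 2018).
KB = 8.31446261815324e-7

#: Speed of light in cm/fs (defined value).
C_CM_PER_FS = 2.99792458e-5

#: 1 kJ/mol expressed in amu·Å²/fs² (exact: 10³/N_A J ÷ 10⁷/N_A J).
KJ_PER_MOL = 1.0e-4

#: 1 kcal/mol in amu·Å²/fs².
KCAL_PER_MOL = 4.184e-4

#: Standard atomic weights (amu), IUPAC 2021 abridged values.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "He": 4.0026,
    "Li": 6.94, "Be": 9.0122, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95,
    "K": 39.098, "Ca": 40.078, "Ti": 47.867, "Cr": 51.996, "Mn": 54.938,
    "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38,
    "Se": 78.971, "Br": 79.904, "Kr": 83.798, "I": 126.90,
}


def wavenumber_to_frequency(nu_cm: float | np.ndarray) -> float | np.ndarray:
    """Convert wavenumber (cm⁻¹) to ordinary frequency (fs⁻¹): f = c·ν̃."""
    return np.asarray(nu_cm) * C_CM_PER_FS if np.ndim(nu_cm) else nu_cm * C_CM_PER_FS


def frequency_to_wavenumber(f_fs: float | np.ndarray) -> float | np.ndarray:
    """Convert ordinary frequency (fs⁻¹) to wavenumber (cm⁻¹): ν̃ = f/c."""
    return np.asarray(f_fs) / C_CM_PER_FS if np.ndim(f_fs) else f_fs / C_CM_PER_FS


def wavenumber_to_angular_frequency(nu_cm: float | np.ndarray):
    """Convert wavenumber (cm⁻¹) to angular frequency (rad/fs)."""
    return 2.0 * np.pi * C_CM_PER_FS * np.asarray(nu_cm)


def wavenumber_to_period(nu_cm: float | np.ndarray):
    """Convert wavenumber (cm⁻¹) to oscillation period (fs)."""
    return 1.0 / (C_CM_PER_FS * np.asarray(nu_cm))


def period_to_wavenumber(period_fs: float | np.ndarray):
    """Convert oscillation period (fs) to wavenumber (cm⁻¹)."""
    return 1.0 / (C_CM_PER_FS * np.asarray(period_fs))
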