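"""Physical constants and unit conversions.

Conventions used throughout the package: atomic positions and cell vectors
are stored in Angstrom, time steps in femtoseconds, wavenumbers in cm^-1.
Tensor labels keep the units they are trained in -- e*bohr for dipole
moments, bohr^3 for molecular polarizabilities, unitless for the electric
susceptibility -- and are never rescaled implicitly.
"""

#: 1 bohr in Angstrom (CODATA 2018).
BOHR_IN_ANGSTROM = 0.529177210903

#: 1 fs^-1 expressed in cm^-1: 1e15 / c with c in cm/s.
FS_INV_IN_CM = 33356.40952

#: Speed of light in Angstrom / fs.
SPEED_OF_LIGHT_ANG_FS = 2997.92458

#: Boltzmann constant in eV / K.
KB_EV = 8.617333262e-5


def angstrom_to_bohr(x):
    """Convert lengths from Angstrom to bohr."""
    return x / BOHR_IN_ANGSTROM


def bohr_to_angstrom(x):
    """Convert lengths from bohr to Angstrom."""
    return x * BOHR_IN_ANGSTROM


def wavenumber_to_freq_fs(nu_cm: float) -> float:
    """Convert a wavenumber in cm^-1 to an ordinary frequency in fs^-1."""
    return nu_cm / FS_INV_IN_CM


def freq_fs_to_wavenumber(f_fs: float) -> float:
    """Convert an ordinary frequency in fs^-1 to a wavenumber in cm^-1."""
    return f_fs * FS_INV_IN_CM
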