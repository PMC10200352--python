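"""Unit system and conversion constants.

Internal units throughout the package are Hartree (energy), Bohr (length),
atomic mass units (mass) and elementary charges (charge).  All file I/O uses
Å for coordinates and cm⁻¹ for frequencies.  Every conversion constant below
is derived at import time from CODATA values published via
:mod:`scipy.constants`; nothing is a transcribed literal, so the constants
cannot drift from the underlying standard.
"""

from __future__ import annotations

import math

import scipy.constants as _codata

# --- base CODATA quantities (SI) -------------------------------------------
BOHR_RADIUS_M: float = _codata.physical_constants["Bohr radius"][0]
HARTREE_J: float = _codata.physical_constants["Hartree energy"][0]
AMU_KG: float = _codata.physical_constants["atomic mass constant"][0]
ELEMENTARY_CHARGE_C: float = _codata.e
SPEED_OF_LIGHT_M_S: float = _codata.c
PLANCK_J_S: float = _codata.h
HBAR_J_S: float = _codata.hbar
AVOGADRO: float = _codata.N_A
EPSILON_0: float = _codata.epsilon_0
ELECTRON_MASS_KG: float = _codata.m_e

# --- length -----------------------------------------------------------------
BOHR_TO_ANGSTROM: float = BOHR_RADIUS_M * 1e10
ANGSTROM_TO_BOHR: float = 1.0 / BOHR_TO_ANGSTROM

# --- mass -------------------------------------------------------------------
#: amu expressed in electron masses (the atomic unit of mass)
AMU_TO_ME: float = AMU_KG / ELECTRON_MASS_KG

# --- Hessian eigenvalue -> wavenumber ---------------------------------------
# A mass-weighted Hessian eigenvalue λ in Hartree/(Bohr²·amu) corresponds to
# an angular frequency ω = sqrt(λ·E_h/(u·a0²)) in rad/s; the harmonic
# wavenumber is ω/(2πc), reported in cm⁻¹.
EIGENVALUE_TO_WAVENUMBER: float = math.sqrt(
    HARTREE_J / (AMU_KG * BOHR_RADIUS_M**2)
) / (2.0 * math.pi * SPEED_OF_LIGHT_M_S * 100.0)

# --- IR intensity -----------------------------------------------------------
# Conventional double-harmonic IR intensity (integrated molar napierian
# absorption coefficient), A = N_A·π/(3c²) · (1/4πε₀) · |∂μ/∂Q|², reported in
# km/mol.  |∂μ/∂Q|² is carried internally in e²/amu (e·Bohr per Bohr·√amu).
# The absolute experimental set-up prefactor of the absorption rate is
# deliberately folded into this single documented convention.
IR_KM_PER_MOL_PER_E2_AMU: float = (
    AVOGADRO
    * math.pi
    / (3.0 * SPEED_OF_LIGHT_M_S**2)
    * (1.0 / (4.0 * math.pi * EPSILON_0))
    * ELEMENTARY_CHARGE_C**2
    / AMU_KG
    / 1000.0
)

# --- Raman activity ---------------------------------------------------------
#: polarizability derivatives are carried in Bohr²/√amu; activities are
#: reported in the conventional Å⁴/amu.
BOHR4_PER_AMU_TO_ANG4_PER_AMU: float = BOHR_TO_ANGSTROM**4


def q01_squared_amu_bohr2(wavenumber_cm: float) -> float:
    """Squared 0→1 transition matrix element |⟨0|Q|1⟩|² = ħ/(2ω).

    For a harmonic oscillator of unit (mass-weighted) mass at harmonic
    wavenumber ``wavenumber_cm`` (cm⁻¹), returns the matrix element squared
    in amu·Bohr².
    """
    if wavenumber_cm <= 0.0:
        raise ValueError(f"wavenumber must be positive, got {wavenumber_cm}")
    omega_si = 2.0 * math.pi * SPEED_OF_LIGHT_M_S * 100.0 * wavenumber_cm
    q2_si = HBAR_J_S / (2.0 * omega_si)  # kg·m²
    return q2_si / (AMU_KG * BOHR_RADIUS_M**2)


def q01_squared_amu_ang2(wavenumber_cm: float) -> float:
    """As :func:`q01_squared_amu_bohr2` but in amu·Å²."""
    return q01_squared_amu_bohr2(wavenumber_cm) * BOHR_TO_ANGSTROM**2
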