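"""Per-mode IR intensities and (resonance) Raman activities.

In the double harmonic approximation the IR absorption strength of mode i is
proportional to |∂μ/∂Q_i|² and the Raman scattering factor is

    S_i = 45·ᾱ′² + 7·β′²,

built from the isotropic and anisotropic invariants of the polarizability
derivative tensor ∂α/∂Q_i.  The absolute radiation/set-up prefactor of the
absorption rate is folded into a single conventional constant so IR
intensities are reported in km/mol; Raman activities are reported in Å⁴/amu.
"Scaled" activities additionally multiply in the squared harmonic 0→1
transition matrix element |⟨0|Q|1⟩|² = ħ/(2ω).

Resonance Raman uses a complex polarizability derivative evaluated at the
incident frequency with an empirical damping (0.006 a.u. is the conventional
choice); the invariant formulas are identical with every squared term read as
a squared modulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import (
    BOHR4_PER_AMU_TO_ANG4_PER_AMU,
    IR_KM_PER_MOL_PER_E2_AMU,
    q01_squared_amu_ang2,
)
from .vibrations import ModeDerivatives, ModeSet

__all__ = [
    "SpectrumPeaks",
    "ir_intensity",
    "raman_invariants",
    "raman_activity",
    "resonance_raman_activity",
    "compute_peaks",
]

#: relative tolerance for the symmetry of polarizability derivative tensors
ALPHA_SYMMETRY_TOL = 1e-8


@dataclass
class SpectrumPeaks:
    """Per-mode spectral data.

    ``ir_raw`` is |∂μ/∂Q|² in e²/amu; ``ir_km_mol`` the same in km/mol.
    ``raman_unscaled`` is S in Å⁴/amu; ``raman_scaled`` multiplies in
    |⟨0|Q|1⟩|² (amu·Å²) and is NaN for modes with non-positive frequency,
    where the matrix element diverges.  ``resonance`` flags a complex
    evaluation at (``frequency``, ``damping``), both in Hartree.
    """

    frequencies: np.ndarray
    ir_raw: np.ndarray | None = None
    ir_km_mol: np.ndarray | None = None
    raman_unscaled: np.ndarray | None = None
    raman_scaled: np.ndarray | None = None
    resonance: bool = False
    frequency: float = 0.0
    damping: float = 0.0

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)


def ir_intensity(dmu_dQ: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Double-harmonic IR intensity per mode.

    ``dmu_dQ``: (n_modes, 3) dipole derivatives in e/√amu.  Returns
    (raw |∂μ/∂Q|² in e²/amu, intensity in km/mol).
    """
    dmu_dQ = np.asarray(dmu_dQ)
    if dmu_dQ.ndim == 1:
        dmu_dQ = dmu_dQ[None, :]
    if dmu_dQ.shape[-1] != 3:
        raise ValueError(f"dipole derivatives must be 3-vectors, got shape {dmu_dQ.shape}")
    raw = np.sum(np.abs(dmu_dQ) ** 2, axis=-1)
    return raw, raw * IR_KM_PER_MOL_PER_E2_AMU


def raman_invariants(dalpha_dQ: np.ndarray) -> tuple[float, float]:
    """Isotropic and anisotropic invariants (ᾱ′, β′²) of one mode's
    polarizability derivative tensor.

    ᾱ′ = (α′_xx + α′_yy + α′_zz)/3 and
    β′² = ½[(α′_xx−α′_yy)² + (α′_yy−α′_zz)² + (α′_zz−α′_xx)² +
            6(α′_xy² + α′_xz² + α′_yz²)].

    For complex tensors (resonance Raman) every squared term is a squared
    modulus, and the returned ᾱ′ is |ᾱ′|.  The tensor must be symmetric.
    """
    a = np.asarray(dalpha_dQ)
    if a.shape != (3, 3):
        raise ValueError(f"expected a 3x3 tensor, got shape {a.shape}")
    scale = max(1.0, float(np.max(np.abs(a))))
    asym = float(np.max(np.abs(a - a.T)))
    if asym > ALPHA_SYMMETRY_TOL * scale:
        raise ValueError(
            f"polarizability derivative tensor is asymmetric by {asym:.3e} "
            f"(tolerance {ALPHA_SYMMETRY_TOL:g} relative)"
        )
    mean = abs((a[0, 0] + a[1, 1] + a[2, 2]) / 3.0)
    beta2 = 0.5 * (
        abs(a[0, 0] - a[1, 1]) ** 2
        + abs(a[1, 1] - a[2, 2]) ** 2
        + abs(a[2, 2] - a[0, 0]) ** 2
        + 6.0 * (abs(a[0, 1]) ** 2 + abs(a[0, 2]) ** 2 + abs(a[1, 2]) ** 2)
    )
    return float(mean), float(beta2)


def raman_activity(
    invariants: tuple[float, float],
    mode_frequency_cm: float | None = None,
    scaled: bool = False,
) -> float:
    """Raman scattering factor S = 45·ᾱ′² + 7·β′² from the invariants.

    The result carries the squared units of the invariants (Å⁴/amu when the
    invariants are in Å²/√amu, the convention used by :func:`compute_peaks`).
    With ``scaled=True`` the activity is multiplied by |⟨0|Q|1⟩|² = ħ/(2ω)
    in amu·Å², which requires a positive mode frequency.
    """
    mean, beta2 = invariants
    s = 45.0 * mean**2 + 7.0 * beta2
    if scaled:
        if mode_frequency_cm is None or mode_frequency_cm <= 0:
            raise ValueError(
                "scaled Raman activity needs a positive mode frequency; "
                f"got {mode_frequency_cm}"
            )
        s *= q01_squared_amu_ang2(mode_frequency_cm)
    return s


def resonance_raman_activity(
    dalpha_dQ: np.ndarray,
    mode_frequency_cm: float | None = None,
    scaled: bool = False,
) -> float:
    """Raman scattering factor from a complex (damped, frequency-dependent)
    polarizability derivative: identical invariant formulas on the moduli.

    At ω = 0, Γ = 0 this reduces exactly to the static activity.
    """
    return raman_activity(raman_invariants(dalpha_dQ), mode_frequency_cm, scaled)


def compute_peaks(
    modeset: ModeSet,
    derivatives: ModeDerivatives,
    ir: bool = True,
    raman: bool = False,
    resonance: bool = False,
    frequency: float = 0.0,
    damping: float = 0.0,
) -> SpectrumPeaks:
    """Assemble a full per-mode peak table from projected derivatives.

    Modes with non-positive frequency get NaN scaled Raman activity (the
    harmonic matrix element is undefined there); all 3N modes are reported.
    """
    peaks = SpectrumPeaks(
        frequencies=modeset.frequencies.copy(),
        resonance=resonance,
        frequency=frequency,
        damping=damping,
    )
    if ir:
        if derivatives.dmu_dQ is None:
            raise ValueError("IR requested but no dipole derivatives available")
        peaks.ir_raw, peaks.ir_km_mol = ir_intensity(derivatives.dmu_dQ)
    if raman or resonance:
        if derivatives.dalpha_dQ is None:
            raise ValueError("Raman requested but no polarizability derivatives available")
        # convert Bohr²/√amu → Å²/√amu so activities come out in Å⁴/amu
        dalpha_ang = derivatives.dalpha_dQ * np.sqrt(BOHR4_PER_AMU_TO_ANG4_PER_AMU)
        unscaled = np.empty(modeset.n_modes)
        scaled = np.empty(modeset.n_modes)
        for i in range(modeset.n_modes):
            inv = raman_invariants(dalpha_ang[i])
            unscaled[i] = raman_activity(inv)
            f = modeset.frequencies[i]
            scaled[i] = raman_activity(inv, f, scaled=True) if f > 0 else np.nan
        peaks.raman_unscaled = unscaled
        peaks.raman_scaled = scaled
    return peaks
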