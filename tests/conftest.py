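"""Shared fixtures: analytic model systems with hand-checkable physics."""

import numpy as np
import pytest

from vibrid import (
    HarmonicTriatomic,
    MorseChargeFluxDiatomic,
    RegionMap,
    ShellModelIonic,
    Structure,
    compute_peaks,
    finite_difference_sweep,
    normal_modes,
    project_to_modes,
)
from vibrid.calculators import SpeciesParams

# Morse/charge-flux diatomic parameters (a.u.): k_eff = 2·D·a² = 0.34
MORSE = dict(D=0.17, a=1.0, r0=1.4, q0=0.5, q1=0.1, p0=2.0, p1=0.5, s0=1.0, s1=0.2)


@pytest.fixture
def morse_calc():
    return MorseChargeFluxDiatomic(**MORSE)


@pytest.fixture
def h2():
    """H₂-like diatomic at the Morse minimum, unit test masses 1 amu."""
    return Structure.from_arrays(
        ["H", "H"], [[0.0, 0.0, 0.0], [0.0, 0.0, MORSE["r0"]]], masses=[1.0, 1.0]
    )


@pytest.fixture
def rigid_diatomic():
    """Rigid-charge diatomic: q = 1 e constant, masses 1 amu (μ_red = 0.5)."""
    calc = MorseChargeFluxDiatomic(D=0.17, a=1.0, r0=1.4, q0=1.0, q1=0.0)
    struct = Structure.from_arrays(
        ["H", "H"], [[0.0, 0.0, 0.0], [0.0, 0.0, 1.4]], masses=[1.0, 1.0]
    )
    return calc, struct


@pytest.fixture
def aba():
    """Centrosymmetric linear A–B–A molecule (CO₂-like) with per-bond
    polarizability: realises the IR/Raman mutual-exclusion rule."""
    calc = HarmonicTriatomic(
        k_bond=0.6, r0=2.2, k_theta=0.12, q_center=1.0, p0=4.0, p1=0.8, s0=2.0, s1=0.15
    )
    struct = Structure.from_arrays(
        ["O", "C", "O"], [[0, 0, -2.2], [0, 0, 0], [0, 0, 2.2]]
    )
    return calc, struct


@pytest.fixture
def shell_atom_engine():
    """Single core–shell atom with q_s = 2 e, k = 4 Hartree/Bohr²:
    closed-form polarizability q_s²/k = 1 Bohr³."""
    engine = ShellModelIonic({"O": SpeciesParams(core_charge=0.0, shell_charge=2.0, spring=4.0)})
    struct = Structure.from_arrays(["O"], [[0.0, 0.0, 0.0]])
    return engine, struct


@pytest.fixture
def shell_pair_engine():
    """Two coupled net-charged core–shell ions with Buckingham repulsion."""
    engine = ShellModelIonic(
        {"O": SpeciesParams(core_charge=1.0, shell_charge=-2.0, spring=5.0)},
        buckingham={("O", "O"): (100.0, 0.5, 10.0)},
    )
    struct = Structure.from_arrays(["O", "O"], [[0.0, 0.0, 0.0], [0.0, 0.0, 4.0]])
    return engine, struct


def run_pipeline(
    calc,
    structure,
    region_map=None,
    step=0.01,
    raman=False,
    workgroups=1,
    project_tr=False,
    frequency=0.0,
    damping=0.0,
):
    """Sweep → modes → projections → peaks, returned as a 4-tuple."""
    bundle = finite_difference_sweep(
        calc,
        structure,
        region_map,
        step=step,
        workgroups=workgroups,
        want_polarizability=raman,
        frequency=frequency,
        damping=damping,
    )
    modeset = normal_modes(bundle, project_tr=project_tr)
    derivs = project_to_modes(bundle, modeset)
    peaks = compute_peaks(
        modeset, derivs, ir=True, raman=raman, resonance=frequency > 0,
        frequency=frequency, damping=damping,
    )
    return bundle, modeset, derivs, peaks
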