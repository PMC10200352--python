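"""Model calculators: energies, analytic gradients, dipoles, polarizabilities."""

import numpy as np
import pytest
from scipy.optimize import minimize

from vibrid import (
    CapabilityError,
    ConvergenceError,
    HarmonicTriatomic,
    MorseChargeFluxDiatomic,
    PropertyRequest,
    ShellModelIonic,
    Structure,
    finite_field_polarizability,
)
from vibrid.calculators import SpeciesParams, calculator_from_dict


def diatomic(r, masses=(1.0, 1.0)):
    return Structure.from_arrays(
        ["H", "H"], [[0.0, 0.0, 0.0], [0.0, 0.0, r]], masses=list(masses)
    )


def fd_gradient(calc, structure, external_charges=None, field=None, h=1e-6):
    """Central-difference energy gradient — the independent oracle."""
    req = PropertyRequest(external_field=field if field is not None else np.zeros(3))
    g = np.zeros((structure.n_atoms, 3))
    base = structure.positions
    for i in range(structure.n_atoms):
        for j in range(3):
            es = []
            for sign in (1.0, -1.0):
                pos = base.copy()
                pos[i, j] += sign * h
                es.append(
                    calc.evaluate(structure.with_positions(pos), external_charges, req).energy
                )
            g[i, j] = (es[0] - es[1]) / (2 * h)
    return g


class TestMorseDiatomic:
    def test_minimum(self, morse_calc, h2):
        b = morse_calc.evaluate(h2, None, PropertyRequest(gradient=True))
        assert b.energy == pytest.approx(0.0, abs=1e-14)
        assert np.linalg.norm(b.gradient) == pytest.approx(0.0, abs=1e-14)

    def test_dipole_arithmetic(self):
        calc = MorseChargeFluxDiatomic(D=0.1, a=1.0, r0=2.0, q0=0.5, q1=0.0)
        b = calc.evaluate(diatomic(2.0), None, PropertyRequest(dipole=True))
        assert np.linalg.norm(b.dipole) == pytest.approx(1.0, abs=1e-14)

    def test_external_charge_coulomb_oracle(self, morse_calc, h2):
        ext = [((1.0, 2.5, 0.3), 0.8)]
        iso = morse_calc.evaluate(h2).energy
        emb = morse_calc.evaluate(h2, ext).energy
        q = 0.5  # at r = r0 the flux term vanishes
        sites = h2.positions
        oracle = sum(
            qi * 0.8 / np.linalg.norm(s - np.array(ext[0][0]))
            for qi, s in zip([-q, q], sites)
        )
        assert emb - iso == pytest.approx(oracle, rel=1e-12)

    def test_capability_error_without_polarizability_terms(self):
        calc = MorseChargeFluxDiatomic(D=0.1, a=1.0, r0=1.4, q0=0.5)
        with pytest.raises(CapabilityError, match="polarizability"):
            calc.evaluate(diatomic(1.4), None, PropertyRequest(polarizability=True))

    def test_lorentzian_static_limit_is_exact(self, morse_calc, h2):
        calc = MorseChargeFluxDiatomic(**{**_params(morse_calc), "omega_e": 0.25})
        a_static = morse_calc.evaluate(h2, None, PropertyRequest(polarizability=True)).polarizability
        a_zero = calc.evaluate(
            h2, None, PropertyRequest(polarizability=True, frequency=0.0, damping=0.0)
        ).polarizability
        assert np.array_equal(a_static, a_zero)

    def test_frequency_request_without_resonance_fails(self, morse_calc, h2):
        with pytest.raises(CapabilityError, match="resonance"):
            morse_calc.evaluate(
                h2, None, PropertyRequest(polarizability=True, frequency=0.1)
            )


def _params(calc: MorseChargeFluxDiatomic) -> dict:
    return dict(
        D=calc.D, a=calc.a, r0=calc.r0, q0=calc.q0, q1=calc.q1,
        p0=calc.p0, p1=calc.p1, s0=calc.s0, s1=calc.s1,
    )


class TestAnalyticGradients:
    """Every model's analytic gradient matches the central-difference energy
    derivative, including charge-flux, external-charge and field terms."""

    def case_morse(self):
        calc = MorseChargeFluxDiatomic(D=0.17, a=1.1, r0=1.4, q0=0.5, q1=0.2)
        struct = diatomic(1.55)
        return calc, struct, [((0.9, 1.8, -0.4), 0.7)], np.array([1e-3, -2e-3, 5e-4])

    def case_triatomic(self):
        calc = HarmonicTriatomic(k_bond=0.6, r0=2.2, k_theta=0.12, q_center=1.0)
        struct = Structure.from_arrays(
            ["O", "C", "O"], [[0.1, -0.2, -2.3], [0.0, 0.05, 0.1], [-0.15, 0.0, 2.25]]
        )
        return calc, struct, [((3.0, 1.0, 0.0), 0.5)], np.array([2e-3, 0.0, -1e-3])

    def case_shell(self):
        calc = ShellModelIonic(
            {"O": SpeciesParams(core_charge=1.0, shell_charge=-2.0, spring=5.0)},
            buckingham={("O", "O"): (100.0, 0.5, 10.0)},
        )
        struct = Structure.from_arrays(["O", "O"], [[0.0, 0.0, 0.0], [0.3, 0.2, 3.8]])
        return calc, struct, [((5.0, 0.0, 1.0), 0.5)], np.array([1e-3, 1e-3, 0.0])

    @pytest.mark.parametrize("case", ["case_morse", "case_triatomic", "case_shell"])
    def test_gradient_matches_fd(self, case):
        calc, struct, ext, field = getattr(self, case)()
        req = PropertyRequest(gradient=True, external_field=field)
        analytic = calc.evaluate(struct, ext, req).gradient
        numeric = fd_gradient(calc, struct, ext, field)
        assert np.allclose(analytic, numeric, atol=5e-9)

    def test_translational_invariance(self):
        calc = MorseChargeFluxDiatomic(D=0.17, a=1.0, r0=1.4, q0=0.5, q1=0.1)
        struct = diatomic(1.5)
        ext = [((1.0, 2.0, 0.5), 0.6)]
        shift = np.array([3.7, -1.2, 0.4])
        e1 = calc.evaluate(struct, ext).energy
        struct2 = struct.with_positions(struct.positions + shift)
        ext2 = [(tuple(np.array(ext[0][0]) + shift), 0.6)]
        e2 = calc.evaluate(struct2, ext2).energy
        assert e2 == pytest.approx(e1, abs=1e-10)

    def test_ext_charge_gradient_matches_fd(self):
        calc = MorseChargeFluxDiatomic(D=0.17, a=1.0, r0=1.4, q0=0.5, q1=0.1)
        struct = diatomic(1.5)
        pos0 = np.array([0.9, 1.8, -0.4])
        analytic = calc.evaluate(struct, [(pos0, 0.7)]).ext_charge_gradients[0]
        h = 1e-6
        numeric = np.zeros(3)
        for j in range(3):
            es = []
            for sign in (1.0, -1.0):
                p = pos0.copy()
                p[j] += sign * h
                es.append(calc.evaluate(struct, [(p, 0.7)]).energy)
            numeric[j] = (es[0] - es[1]) / (2 * h)
        assert np.allclose(analytic, numeric, atol=1e-9)


class TestTriatomic:
    def test_neutral_symmetric_dipole_is_zero(self, aba):
        calc, struct = aba
        b = calc.evaluate(struct, None, PropertyRequest(dipole=True))
        assert np.linalg.norm(b.dipole) == pytest.approx(0.0, abs=1e-14)

    def test_equilibrium_is_stationary(self, aba):
        calc, struct = aba
        b = calc.evaluate(struct, None, PropertyRequest(gradient=True))
        assert b.energy == pytest.approx(0.0, abs=1e-14)
        assert np.linalg.norm(b.gradient) == pytest.approx(0.0, abs=1e-12)


class TestShellModel:
    def test_single_shell_atom_closed_form(self, shell_atom_engine):
        engine, struct = shell_atom_engine
        alpha = finite_field_polarizability(engine, struct)
        assert np.allclose(alpha, np.eye(3) * (2.0**2 / 4.0), atol=1e-9)

    def test_internal_polarizability_route_agrees(self, shell_atom_engine):
        engine, struct = shell_atom_engine
        b = engine.evaluate(struct, None, PropertyRequest(polarizability=True))
        assert np.allclose(b.polarizability.real, np.eye(3), atol=1e-9)
        assert np.allclose(b.polarizability.imag, 0.0)

    def test_rigid_point_charge_molecule_has_zero_polarizability(self):
        calc = HarmonicTriatomic(k_bond=0.6, r0=2.2, k_theta=0.12, q_center=1.0)
        struct = Structure.from_arrays(["O", "C", "O"], [[0, 0, -2.2], [0, 0, 0], [0, 0, 2.2]])
        alpha = finite_field_polarizability(calc, struct)
        assert np.allclose(alpha, 0.0, atol=1e-12)

    def test_coupled_shells_match_minimizer_oracle(self, shell_pair_engine):
        engine, struct = shell_pair_engine
        x = struct.positions
        h = 1e-3

        def total_energy(shell_flat, field):
            sh = shell_flat.reshape(2, 3)
            pos = np.vstack([x, sh])
            q = np.array([1.0, 1.0, -2.0, -2.0])
            e = 0.0
            g = np.zeros((4, 3))
            for i, j in [(0, 1), (0, 3), (1, 2), (2, 3)]:
                d = pos[i] - pos[j]
                r = np.linalg.norm(d)
                e += q[i] * q[j] / r
                f = -q[i] * q[j] * d / r**3
                g[i] += f
                g[j] -= f
            e += 0.5 * 5.0 * np.sum((sh - x) ** 2)
            g[2:] += 5.0 * (sh - x)
            d = sh[0] - sh[1]
            r = np.linalg.norm(d)
            e += 100.0 * np.exp(-r / 0.5) - 10.0 / r**6
            dedr = -100.0 / 0.5 * np.exp(-r / 0.5) + 60.0 / r**7
            g[2] += dedr * d / r
            g[3] -= dedr * d / r
            e -= q @ (pos @ field)
            g[2:] -= q[2:, None] * field[None, :]
            return e, g[2:].ravel()

        def oracle_dipole(field):
            res = minimize(
                total_energy, x.ravel() + 1e-3, args=(field,), method="BFGS",
                jac=True, options={"gtol": 1e-13},
            )
            sh = res.x.reshape(2, 3)
            return np.array([1.0, 1.0]) @ x + np.array([-2.0, -2.0]) @ sh

        alpha_oracle = np.zeros((3, 3))
        for j in range(3):
            fp, fm = np.zeros(3), np.zeros(3)
            fp[j], fm[j] = h, -h
            alpha_oracle[:, j] = (oracle_dipole(fp) - oracle_dipole(fm)) / (2 * h)
        alpha = finite_field_polarizability(engine, struct, field_step=h)
        assert np.allclose(alpha, 0.5 * (alpha_oracle + alpha_oracle.T), atol=1e-6)

    def test_relaxation_cycle_cap_raises(self, shell_pair_engine):
        engine, struct = shell_pair_engine
        with pytest.raises(ConvergenceError, match="cycles"):
            engine.relax_shells(struct, [((0.0, 0.0, 2.0), 3.0)], max_cycles=1)

    def test_polarizability_symmetric(self, shell_pair_engine):
        engine, struct = shell_pair_engine
        alpha = finite_field_polarizability(engine, struct, [((6.0, 1.0, 0.0), 0.4)])
        assert np.allclose(alpha, alpha.T, atol=1e-10)


class TestFactory:
    def test_roundtrip_types(self):
        morse = calculator_from_dict({"type": "morse_diatomic", "D": 0.1, "a": 1.0, "r0": 1.4})
        assert isinstance(morse, MorseChargeFluxDiatomic)
        shell = calculator_from_dict(
            {
                "type": "shell_ionic",
                "species": {"O": {"core_charge": -2.0, "shell_charge": 1.0, "spring": 3.0}},
                "buckingham": {"O-O": [100.0, 0.3, 5.0]},
            }
        )
        assert isinstance(shell, ShellModelIonic)
        assert shell.buckingham[("O", "O")] == (100.0, 0.3, 5.0)

    def test_unknown_type(self):
        with pytest.raises(ValueError, match="unknown calculator type"):
            calculator_from_dict({"type": "dft"})
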