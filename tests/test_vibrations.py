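"""Finite-difference sweeps, normal modes, projections, isotope restarts."""

import math

import numpy as np
import pytest

from vibrid import (
    EmbeddingOptions,
    MorseChargeFluxDiatomic,
    PropertyRequest,
    RegionMap,
    ShellModelIonic,
    Structure,
    compose_additive,
    finite_difference_sweep,
    load_bundle,
    normal_modes,
    project_to_modes,
    remass_restart,
    save_bundle,
)
from vibrid.calculators import Calculator, PropertyBundle, SpeciesParams
from vibrid.units import EIGENVALUE_TO_WAVENUMBER
from vibrid.vibrations import DerivativeBundle

from conftest import MORSE, run_pipeline


def make_bundle(hessian, masses=None, positions=None, **kwargs):
    """Hand-built DerivativeBundle for eigen-solver contract tests."""
    n3 = hessian.shape[0]
    n = n3 // 3
    masses = np.ones(n) if masses is None else np.asarray(masses, float)
    positions = (
        np.arange(3 * n, dtype=float).reshape(n, 3) if positions is None else positions
    )
    return DerivativeBundle(
        step=0.01,
        elements=["H"] * n,
        masses=masses,
        positions=positions,
        region_map=RegionMap.all_inner(n),
        hessian_raw=hessian,
        hessian=0.5 * (hessian + hessian.T),
        max_asymmetry=0.0,
        **kwargs,
    )


class TestSweep:
    def test_harmonic_diagonal_element(self, morse_calc, h2):
        bundle = finite_difference_sweep(morse_calc, h2, step=0.01)
        # zz element for atom 0 is d²E/dz0² = k = 2·D·a² + O(step²)
        k = morse_calc.harmonic_force_constant
        assert bundle.hessian[2, 2] == pytest.approx(k, rel=1e-3)

    def test_central_difference_is_second_order(self, morse_calc, h2):
        k = morse_calc.harmonic_force_constant
        errs = []
        for step in (0.02, 0.01):
            b = finite_difference_sweep(morse_calc, h2, step=step)
            errs.append(abs(b.hessian[2, 2] - k))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.15)

    def test_zero_charge_model_gives_zero_dipole_derivatives(self):
        calc = MorseChargeFluxDiatomic(D=0.17, a=1.0, r0=1.4)
        s = Structure.from_arrays(["H", "H"], [[0, 0, 0], [0, 0, 1.4]], masses=[1, 1])
        b = finite_difference_sweep(calc, s, step=0.01)
        assert np.all(b.dipole_derivatives == 0.0)

    def test_workgroup_count_does_not_change_a_single_bit(self, morse_calc, h2):
        bundles = [
            finite_difference_sweep(morse_calc, h2, step=0.01, workgroups=m,
                                    want_polarizability=True)
            for m in (1, 3)
        ]
        assert np.array_equal(bundles[0].hessian_raw, bundles[1].hessian_raw)
        assert np.array_equal(bundles[0].dipole_derivatives, bundles[1].dipole_derivatives)
        assert np.array_equal(
            bundles[0].polarizability_derivatives, bundles[1].polarizability_derivatives
        )

    def test_asymmetric_gradient_field_is_rejected(self):
        class BadCalculator(Calculator):
            capabilities = frozenset({"energy", "gradient", "dipole"})

            def _evaluate(self, structure, ext_pos, ext_q, request):
                # a non-symmetric linear force field: curl is nonzero, so the
                # finite-difference Hessian cannot be symmetric
                A = np.array([[0.0, 1.0], [0.0, 0.0]])
                x = structure.positions[:, 0]
                g = np.zeros((2, 3))
                g[:, 0] = A @ x
                return PropertyBundle(energy=0.0, gradient=g, dipole=np.zeros(3))

        s = Structure.from_arrays(["H", "H"], [[0, 0, 0], [0, 0, 1.4]], masses=[1, 1])
        with pytest.raises(RuntimeError, match="asymmetry"):
            finite_difference_sweep(BadCalculator(), s, step=0.01)

    def test_nonfinite_gradient_reports_displacement(self):
        class NaNCalculator(Calculator):
            capabilities = frozenset({"energy", "gradient", "dipole"})

            def _evaluate(self, structure, ext_pos, ext_q, request):
                return PropertyBundle(
                    energy=0.0, gradient=np.full((2, 3), np.nan), dipole=np.zeros(3)
                )

        s = Structure.from_arrays(["H", "H"], [[0, 0, 0], [0, 0, 1.4]], masses=[1, 1])
        with pytest.raises(RuntimeError, match="atom 0 axis x"):
            finite_difference_sweep(NaNCalculator(), s, step=0.01)


class TestNormalModes:
    def test_diatomic_stretch_closed_form(self, morse_calc, h2):
        bundle = finite_difference_sweep(morse_calc, h2, step=0.01)
        modes = normal_modes(bundle)
        k = morse_calc.harmonic_force_constant
        mu_red = 0.5
        expected = math.sqrt(k / mu_red) * EIGENVALUE_TO_WAVENUMBER
        assert modes.frequencies[-1] == pytest.approx(expected, rel=1e-3)

    def test_zero_hessian_gives_zero_frequencies(self):
        modes = normal_modes(make_bundle(np.zeros((6, 6))))
        assert np.all(modes.frequencies == 0.0)

    def test_negative_eigenvalue_reported_first_with_sign(self):
        h = np.diag([-0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        modes = normal_modes(make_bundle(h))
        assert modes.frequencies[0] < 0
        assert np.sum(modes.frequencies < 0) == 1
        assert np.all(np.diff(modes.frequencies) >= 0)

    def test_orthonormality_and_reconstruction(self, morse_calc, h2):
        bundle = finite_difference_sweep(morse_calc, h2, step=0.01)
        modes = normal_modes(bundle)
        L = modes.modes
        assert np.allclose(L.T @ L, np.eye(6), atol=1e-8)
        inv_sqrt_m = np.repeat(1.0 / np.sqrt(modes.masses), 3)
        fmat = bundle.hessian * np.outer(inv_sqrt_m, inv_sqrt_m)
        lam = np.sign(modes.frequencies) * (modes.frequencies / EIGENVALUE_TO_WAVENUMBER) ** 2
        assert np.allclose(L @ np.diag(lam) @ L.T, fmat, atol=1e-8)

    def test_nonfinite_hessian_rejected(self):
        h = np.zeros((6, 6))
        h[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            normal_modes(make_bundle(h))

    def test_free_linear_molecule_has_five_zero_modes(self, morse_calc, h2):
        bundle = finite_difference_sweep(morse_calc, h2, step=0.01)
        modes = normal_modes(bundle, project_tr=True)
        zero = np.abs(modes.frequencies) < 1.0
        assert int(zero.sum()) == 5

    def test_free_nonlinear_molecule_has_six_zero_modes(self):
        engine = ShellModelIonic(
            {"Na": SpeciesParams(core_charge=1.0), "Cl": SpeciesParams(core_charge=-1.0)},
            buckingham={("Na", "Cl"): (50.0, 0.8, 5.0), ("Na", "Na"): (80.0, 0.6, 2.0)},
        )
        s = Structure.from_arrays(
            ["Na", "Cl", "Na"], [[0.0, 0.0, 0.0], [4.0, 0.0, 0.0], [2.0, 3.5, 0.0]]
        )
        bundle = finite_difference_sweep(engine, s, step=0.01, want_dipole=False)
        modes = normal_modes(bundle, project_tr=True)
        zero = np.abs(modes.frequencies) < 1.0
        assert int(zero.sum()) == 6

    def test_embedded_fragment_tr_modes_become_vibrations(self):
        inner = MorseChargeFluxDiatomic(**MORSE)
        env = ShellModelIonic({"Na": SpeciesParams(core_charge=1.0)})
        struct = Structure.from_arrays(
            ["H", "H", "Na"],
            [[0, 0, 0], [0, 0, 1.4], [0.5, 2.5, 0.7]],
            masses=[1.0, 1.0, 22.99],
        )
        rm = RegionMap(inner=(0, 1), frozen_env=(2,), vib_active=(0, 1), n_atoms=3)
        comp = compose_additive(inner, env, rm, EmbeddingOptions())
        bundle = finite_difference_sweep(comp, struct, rm, step=0.01)
        modes = normal_modes(bundle, project_tr=False)
        assert modes.n_modes == 6  # all 3N modes kept
        assert np.all(np.abs(modes.frequencies) > 1.0)


class TestProjection:
    def test_rigid_charge_diatomic_closed_form(self, rigid_diatomic):
        calc, struct = rigid_diatomic
        _, modes, derivs, _ = run_pipeline(calc, struct)
        # stretch mode is the highest; |∂μ/∂Q| = q/√μ_red
        dmu = np.linalg.norm(derivs.dmu_dQ[-1])
        assert dmu == pytest.approx(1.0 / math.sqrt(0.5), rel=1e-6)

    def test_zero_cartesian_derivatives_project_to_zero(self):
        bundle = make_bundle(np.eye(6), dipole_derivatives=np.zeros((6, 3)))
        modes = normal_modes(bundle)
        derivs = project_to_modes(bundle, modes)
        assert np.all(derivs.dmu_dQ == 0.0)

    def test_against_displacement_along_mode_oracle(self, morse_calc, h2):
        bundle = finite_difference_sweep(morse_calc, h2, step=0.01)
        modes = normal_modes(bundle)
        derivs = project_to_modes(bundle, modes)
        i = 5  # stretch
        disp = modes.cartesian_displacements()[:, i].reshape(-1, 3)
        delta = 1e-4
        mus = []
        for sign in (1.0, -1.0):
            s = h2.with_positions(h2.positions + sign * delta * disp)
            mus.append(morse_calc.evaluate(s, None, PropertyRequest(dipole=True)).dipole)
        oracle = (mus[0] - mus[1]) / (2 * delta)
        assert np.allclose(derivs.dmu_dQ[i], oracle, atol=1e-6)

    def test_shape_mismatch_rejected(self, morse_calc, h2):
        bundle = finite_difference_sweep(morse_calc, h2, step=0.01)
        other = normal_modes(make_bundle(np.zeros((3, 3)), masses=[1.0]))
        with pytest.raises(ValueError, match="3N"):
            project_to_modes(bundle, other)


class TestRemassRestart:
    def test_doubling_masses_scales_frequencies(self, morse_calc, h2):
        bundle = finite_difference_sweep(morse_calc, h2, step=0.01)
        ref = normal_modes(bundle)
        calls_before = morse_calc.n_calls
        modes2, _ = remass_restart(bundle, 2.0 * bundle.masses)
        assert morse_calc.n_calls == calls_before  # pure restart
        # exact 1/√2 scaling for every mode above the numerical-zero floor;
        # numerically-zero modes stay numerically zero
        assert np.allclose(
            modes2.frequencies, ref.frequencies / math.sqrt(2.0), rtol=1e-10, atol=1e-4
        )

    def test_identical_masses_identical_modes(self, morse_calc, h2):
        bundle = finite_difference_sweep(morse_calc, h2, step=0.01)
        ref = normal_modes(bundle)
        modes2, _ = remass_restart(bundle, bundle.masses)
        assert np.array_equal(modes2.frequencies, ref.frequencies)
        assert np.array_equal(modes2.modes, ref.modes)

    def test_h_to_d_ir_scaling(self, rigid_diatomic):
        """H→D substitution: stretch IR raw intensity q²/μ_red scales by
        μ_red(H)/μ_red(D)."""
        calc, struct = rigid_diatomic
        bundle = finite_difference_sweep(calc, struct, step=0.01)
        modes_h = normal_modes(bundle)
        derivs_h = project_to_modes(bundle, modes_h)
        modes_d, derivs_d = remass_restart(bundle, 2.0 * bundle.masses)
        ir_h = np.sum(np.abs(derivs_h.dmu_dQ[-1]) ** 2)
        ir_d = np.sum(np.abs(derivs_d.dmu_dQ[-1]) ** 2)
        assert ir_h / ir_d == pytest.approx(2.0, rel=1e-8)
        assert ir_h == pytest.approx(1.0**2 / 0.5, rel=1e-6)

    def test_mass_count_mismatch(self, morse_calc, h2):
        bundle = finite_difference_sweep(morse_calc, h2, step=0.01)
        with pytest.raises(ValueError, match="masses"):
            remass_restart(bundle, [1.0, 2.0, 3.0])


class TestArchive:
    def test_roundtrip(self, morse_calc, h2, tmp_path):
        bundle = finite_difference_sweep(
            morse_calc, h2, step=0.01, want_polarizability=True
        )
        path = tmp_path / "restart.json"
        save_bundle(bundle, path)
        loaded = load_bundle(path)
        assert np.array_equal(loaded.hessian_raw, bundle.hessian_raw)
        assert np.array_equal(loaded.dipole_derivatives, bundle.dipole_derivatives)
        assert np.array_equal(
            loaded.polarizability_derivatives, bundle.polarizability_derivatives
        )
        assert loaded.region_map == bundle.region_map
        assert loaded.structure_hash == bundle.structure_hash

    def test_unknown_schema_version_rejected(self, morse_calc, h2, tmp_path):
        import json

        bundle = finite_difference_sweep(morse_calc, h2, step=0.01)
        path = tmp_path / "restart.json"
        save_bundle(bundle, path)
        doc = json.loads(path.read_text())
        doc["schema_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="schema version"):
            load_bundle(path)
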