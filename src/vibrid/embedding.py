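"""Additive QM/MM composition with electrostatic or polarizable embedding.

The composite calculator presents the standard calculator contract over the
*full* structure while internally splitting it by a :class:`~vibrid.molsys.RegionMap`:

* the inner (QM-like) region is evaluated by the inner calculator in the
  presence of the environment's point charges (cores and, for polarizable
  embedding, relaxed shells);
* the environment engine supplies the MM energy and, through its shells, the
  dielectric response; forces on environment atoms include the back-coupling
  from the inner region's charges;
* the total energy decomposes additively as
  E_total = E_QM + E_MM + E_QM-MM, checked to machine precision.

For polarizable embedding the two regions are iterated to mutual
self-consistency: the environment shells relax in the field of the inner
region's effective charges, the inner region is re-evaluated in the field of
the relaxed shells, and the cycle repeats until the inner dipole moment is
stationary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .calculators import (
    Calculator,
    ConvergenceError,
    PropertyBundle,
    PropertyRequest,
    ShellModelIonic,
    _coulomb_sites_vs_ext,
    _normalize_external_charges,
)
from .molsys import RegionMap, ShellSpec, Structure

__all__ = [
    "ConfigurationError",
    "EmbeddingOptions",
    "CompositeEnergy",
    "CompositeResult",
    "CompositeCalculator",
    "compose_additive",
    "relax_shells",
    "mutual_polarization",
]


class ConfigurationError(ValueError):
    """Inconsistent embedding configuration (e.g. polarizable scheme without
    shells in the environment)."""


@dataclass
class EmbeddingOptions:
    """Embedding scheme and convergence controls.

    ``shell_tolerance`` is the largest per-cycle shell displacement (Bohr)
    accepted as converged; ``dipole_tolerance`` the largest change of the
    inner dipole (e·Bohr) between outer mutual-polarization iterations.
    """

    scheme: str = "electrostatic"
    shell_tolerance: float = 1e-7
    dipole_tolerance: float = 1e-8
    max_outer_iterations: int = 200

    def __post_init__(self) -> None:
        if self.scheme not in ("electrostatic", "polarizable"):
            raise ConfigurationError(
                f"scheme must be 'electrostatic' or 'polarizable', got {self.scheme!r}"
            )
        if self.shell_tolerance <= 0 or self.dipole_tolerance <= 0:
            raise ConfigurationError("tolerances must be positive")
        if self.max_outer_iterations < 1:
            raise ConfigurationError("max_outer_iterations must be >= 1")


@dataclass
class CompositeEnergy:
    """Additive QM/MM energy decomposition (Hartree)."""

    total: float
    qm: float
    mm: float
    coupling: float

    def __post_init__(self) -> None:
        if abs(self.total - (self.qm + self.mm + self.coupling)) > 1e-12 * max(
            1.0, abs(self.total)
        ):
            raise ValueError("energy decomposition does not sum to the total")


@dataclass
class CompositeResult:
    """Self-consistent composite evaluation: property bundle, energy
    decomposition, outer-iteration count, the trace of inner-dipole residuals
    and the final environment shell positions (n_env_atoms, 3)."""

    bundle: PropertyBundle
    energy: CompositeEnergy
    n_outer: int
    dipole_residuals: list[float] = field(default_factory=list)
    env_shell_positions: np.ndarray | None = None


class CompositeCalculator(Calculator):
    """Additive composition of an inner calculator and an environment engine."""

    def __init__(
        self,
        inner: Calculator,
        env_engine: Calculator,
        region_map: RegionMap,
        options: EmbeddingOptions | None = None,
    ) -> None:
        super().__init__()
        self.inner = inner
        self.env = env_engine
        self.region_map = region_map
        self.options = options or EmbeddingOptions()
        if self.options.scheme == "polarizable" and not isinstance(
            env_engine, ShellModelIonic
        ):
            raise ConfigurationError(
                "polarizable embedding needs a shell-model environment engine"
            )
        if isinstance(env_engine, ShellModelIonic):
            env_engine.shell_tolerance = min(
                env_engine.shell_tolerance, self.options.shell_tolerance
            )

    @property
    def capabilities(self) -> frozenset[str]:
        caps = {"energy"}
        if "gradient" in self.inner.capabilities and "gradient" in self.env.capabilities:
            caps.add("gradient")
        if "dipole" in self.inner.capabilities:
            caps.add("dipole")
        if "polarizability" in self.inner.capabilities:
            caps.add("polarizability")
        return frozenset(caps)

    # -- internals ------------------------------------------------------------
    def _split(self, structure: Structure):
        inner_struct = structure.subset(self.region_map.inner)
        env_idx = self.region_map.environment
        env_struct = structure.subset(env_idx) if env_idx else None
        return inner_struct, env_struct, env_idx

    @staticmethod
    def _concat_charges(*site_sets):
        pos = np.vstack([p for p, _ in site_sets if len(p)]) if any(
            len(p) for p, _ in site_sets
        ) else np.zeros((0, 3))
        q = np.concatenate([c for _, c in site_sets]) if site_sets else np.zeros(0)
        return pos, q

    def _evaluate(self, structure, ext_pos, ext_q, request):
        return self.evaluate_detailed(structure, (ext_pos, ext_q), request).bundle

    def evaluate_detailed(
        self,
        structure: Structure,
        external_charges: Sequence | None = None,
        request: PropertyRequest | None = None,
    ) -> CompositeResult:
        """Full self-consistent evaluation with energy decomposition.

        External charges passed to the composite are seen by both regions and
        contribute to the coupling/MM terms; their own interaction energy
        with each region is counted exactly once.
        """
        request = request or PropertyRequest()
        ext_pos, ext_q = _normalize_external_charges(external_charges)
        inner_struct, env_struct, env_idx = self._split(structure)
        polar = self.options.scheme == "polarizable"
        if polar:
            if env_struct is None or not (
                isinstance(self.env, ShellModelIonic) and self.env.has_shells(env_struct)
            ):
                raise ConfigurationError(
                    "polarizable embedding requested but the environment has no shells"
                )

        inner_req = PropertyRequest(
            energy=True,
            gradient=request.gradient,
            dipole=True,
            polarizability=request.polarizability,
            frequency=request.frequency,
            damping=request.damping,
            external_field=request.external_field,
            relax_shells=request.relax_shells,
        )
        env_req = PropertyRequest(
            energy=True,
            gradient=request.gradient,
            dipole=False,
            external_field=request.external_field,
            relax_shells=polar and request.relax_shells,
        )

        if env_struct is None:
            inner_bundle = self.inner.evaluate(inner_struct, (ext_pos, ext_q), inner_req)
            e_qm = (
                inner_bundle.energy
                if len(ext_q) == 0
                else self.inner.evaluate(inner_struct, None, PropertyRequest()).energy
            )
            energy = CompositeEnergy(
                total=e_qm + (inner_bundle.energy - e_qm),
                qm=e_qm,
                mm=0.0,
                coupling=inner_bundle.energy - e_qm,
            )
            return CompositeResult(inner_bundle, energy, 1, [], None)

        # -- initial environment charge representation ------------------------
        env_sites = self.env.charge_sites(
            env_struct,
            None,
            PropertyRequest(relax_shells=False),
        )
        if polar:
            # honour any stored initial shell positions
            init_pos = []
            init_q = []
            core_q, shell_q, _ = self.env._resolve(env_struct)
            x_env = env_struct.positions
            for i in range(env_struct.n_atoms):
                if core_q[i] != 0.0:
                    init_pos.append(x_env[i])
                    init_q.append(core_q[i])
            for i in range(env_struct.n_atoms):
                if shell_q[i] != 0.0:
                    atom = env_struct.atoms[i]
                    sp = (
                        atom.shell.position
                        if atom.shell is not None and atom.shell.position is not None
                        else x_env[i]
                    )
                    init_pos.append(sp)
                    init_q.append(shell_q[i])
            env_sites = (np.asarray(init_pos).reshape(-1, 3), np.asarray(init_q))

        # -- outer mutual-polarization loop -----------------------------------
        ext_for_inner = self._concat_charges(env_sites, (ext_pos, ext_q))
        inner_bundle = self.inner.evaluate(inner_struct, ext_for_inner, inner_req)
        mu_prev = inner_bundle.dipole.copy()
        inner_sites = self.inner.charge_sites(inner_struct, ext_for_inner, inner_req)
        residuals: list[float] = []
        env_bundle = None
        n_outer = 0
        max_outer = self.options.max_outer_iterations if polar else 1
        while True:
            n_outer += 1
            ext_for_env = self._concat_charges(inner_sites, (ext_pos, ext_q))
            env_bundle = self.env.evaluate(env_struct, ext_for_env, env_req)
            env_sites = self.env.charge_sites(env_struct, ext_for_env, env_req)
            ext_for_inner = self._concat_charges(env_sites, (ext_pos, ext_q))
            inner_bundle = self.inner.evaluate(inner_struct, ext_for_inner, inner_req)
            inner_sites = self.inner.charge_sites(inner_struct, ext_for_inner, inner_req)
            residual = float(np.linalg.norm(inner_bundle.dipole - mu_prev))
            residuals.append(residual)
            mu_prev = inner_bundle.dipole.copy()
            if not polar or residual < self.options.dipole_tolerance:
                break
            if n_outer >= max_outer:
                raise ConvergenceError(
                    "mutual polarization did not converge in "
                    f"{max_outer} outer iterations; dipole residual trace: "
                    + ", ".join(f"{r:.3e}" for r in residuals[-10:])
                )

        # -- assemble ----------------------------------------------------------
        e_qm = self.inner.evaluate(inner_struct, None, PropertyRequest()).energy
        e_cross, _, _ = _coulomb_sites_vs_ext(
            inner_sites[0], inner_sites[1], env_sites[0], env_sites[1]
        )
        e_mm = env_bundle.energy - e_cross
        e_coupling = inner_bundle.energy - e_qm
        energy = CompositeEnergy(
            total=e_qm + e_mm + e_coupling, qm=e_qm, mm=e_mm, coupling=e_coupling
        )

        n_env_sites = len(env_sites[1])
        n_inner_sites = len(inner_sites[1])
        grad = None
        if request.gradient:
            grad = np.zeros((structure.n_atoms, 3))
            grad[list(self.region_map.inner)] = inner_bundle.gradient
            grad[list(env_idx)] = env_bundle.gradient
        ext_grad = np.zeros_like(ext_pos)
        if len(ext_q):
            ext_grad = (
                inner_bundle.ext_charge_gradients[n_env_sites:]
                + env_bundle.ext_charge_gradients[n_inner_sites:]
            )
        dipole = None
        if request.dipole:
            dipole = inner_bundle.dipole + env_sites[1] @ env_sites[0]

        bundle = PropertyBundle(
            energy=energy.total,
            gradient=grad,
            dipole=dipole,
            polarizability=inner_bundle.polarizability if request.polarizability else None,
            ext_charge_gradients=ext_grad,
        )
        shell_positions = None
        if polar:
            ext_for_env = self._concat_charges(inner_sites, (ext_pos, ext_q))
            shell_positions = self.env.relax_shells(
                env_struct, ext_for_env, request.external_field
            )
        return CompositeResult(bundle, energy, n_outer, residuals, shell_positions)

    def converged_structure(self, structure: Structure) -> Structure:
        """Copy of ``structure`` with environment shells placed at their
        mutually-polarized positions (useful to warm-start a re-run)."""
        result = self.evaluate_detailed(structure, None, PropertyRequest(dipole=True))
        if result.env_shell_positions is None:
            return structure
        new = structure.with_positions(structure.positions)
        env_struct = structure.subset(self.region_map.environment)
        _, shell_q, spring = self.env._resolve(env_struct)
        for local_i, global_i in enumerate(self.region_map.environment):
            if shell_q[local_i] == 0.0:
                continue
            new.atoms[global_i].shell = ShellSpec(
                shell_q[local_i],
                spring[local_i],
                result.env_shell_positions[local_i],
            )
        return new


def compose_additive(
    inner_calc: Calculator,
    env_engine: Calculator,
    region_map: RegionMap,
    options: EmbeddingOptions | None = None,
) -> CompositeCalculator:
    """Compose an inner calculator and an environment engine into one
    additive QM/MM calculator (E_total = E_QM + E_MM + E_QM-MM)."""
    return CompositeCalculator(inner_calc, env_engine, region_map, options)


def relax_shells(
    env_engine: ShellModelIonic,
    structure: Structure,
    external_charges: Sequence | None = None,
    external_field: np.ndarray | None = None,
    tolerance: float | None = None,
    max_cycles: int | None = None,
) -> tuple[np.ndarray, float]:
    """Relax environment shells in a fixed external field/charge distribution.

    Returns (shell positions (n_atoms, 3), relaxed MM energy including the
    external interaction).
    """
    positions = env_engine.relax_shells(
        structure, external_charges, external_field, tolerance, max_cycles
    )
    from .calculators import _normalize_external_charges as _norm

    ext_pos, ext_q = _norm(external_charges)
    F = np.zeros(3) if external_field is None else np.asarray(external_field, float)
    core_q, shell_q, spring = env_engine._resolve(structure)
    energy, _, _, _ = env_engine._energy_forces(
        structure, structure.positions, positions, core_q, shell_q, spring,
        ext_pos, ext_q, F,
    )
    return positions, energy


def mutual_polarization(
    composite: CompositeCalculator,
    structure: Structure,
    request: PropertyRequest | None = None,
) -> CompositeResult:
    """Iterate inner evaluation and shell relaxation to self-consistency.

    For an electrostatic composite this is a single pass; for a polarizable
    one the loop runs until the inner dipole is stationary to the configured
    tolerance.
    """
    return composite.evaluate_detailed(structure, None, request)
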