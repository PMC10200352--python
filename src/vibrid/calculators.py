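"""Property calculators: the provider contract and bundled analytic models.

A calculator is a pure function of (structure, external charges, request):
it never stores geometry, which is what makes task-farmed finite differences
deterministic.  Every calculator advertises its capabilities so downstream
consumers can fail fast instead of receiving silent zeros.

The bundled models are analytic stand-ins for electronic-structure and
forcefield drivers:

* :class:`MorseChargeFluxDiatomic` — Morse bond with a bond-length-dependent
  charge (charge flux), a bond-polarizability model and an optional
  damped-Lorentzian electronic resonance for resonance-Raman work.
* :class:`HarmonicTriatomic` — centrosymmetric linear A–B–A molecule with
  harmonic bonds and bend, fixed point charges and per-bond polarizability;
  its symmetric/asymmetric stretches realise the IR/Raman mutual-exclusion
  rule exactly.
* :class:`ShellModelIonic` — core–shell polarizable ionic engine with
  Buckingham short-range repulsion-dispersion, used as the MM environment
  engine for polarizable embedding.

All quantities are in atomic-style internal units: Hartree, Bohr, amu, e.
Internal point charges of the molecular models exist for dipole moments and
embedding coupling; their mutual interaction is considered folded into the
model force constants.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .molsys import Structure

__all__ = [
    "CapabilityError",
    "ConvergenceError",
    "PropertyRequest",
    "PropertyBundle",
    "Calculator",
    "MorseChargeFluxDiatomic",
    "HarmonicTriatomic",
    "ShellModelIonic",
    "finite_field_polarizability",
    "calculator_from_dict",
    "load_calculator",
]

#: default field step (a.u.) for operational finite-field polarizabilities
DEFAULT_FIELD_STEP = 1e-3


class CapabilityError(RuntimeError):
    """A property was requested that the calculator cannot provide."""


class ConvergenceError(RuntimeError):
    """An iterative sub-solver (shell relaxation) failed to converge."""


@dataclass
class PropertyRequest:
    """What to compute in one single-point evaluation.

    ``frequency`` is the radiation frequency ω in Hartree (0 = static);
    ``damping`` the empirical excited-state damping Γ in Hartree (0.006 a.u.
    is the conventional choice for resonance Raman).  ``external_field`` is a
    uniform electric field in a.u. applied to the calculator's own charge
    sites (a probe used for finite-field polarizabilities; external point
    charges are not coupled to it).  ``relax_shells=False`` pins shells to
    their cores (rigid-ion limit) in shell-model engines.
    """

    energy: bool = True
    gradient: bool = False
    dipole: bool = False
    polarizability: bool = False
    frequency: float = 0.0
    damping: float = 0.0
    external_field: np.ndarray = field(default_factory=lambda: np.zeros(3))
    relax_shells: bool = True

    def __post_init__(self) -> None:
        if self.frequency < 0 or self.damping < 0:
            raise ValueError("frequency and damping must be non-negative")
        self.external_field = np.asarray(self.external_field, dtype=float)

    @property
    def wanted(self) -> set[str]:
        out = set()
        for name in ("energy", "gradient", "dipole", "polarizability"):
            if getattr(self, name):
                out.add(name)
        return out


@dataclass
class PropertyBundle:
    """Results of one single-point evaluation.

    ``gradient`` is (n_atoms, 3) in Hartree/Bohr; ``dipole`` (3,) in e·Bohr;
    ``polarizability`` (3, 3) complex in Bohr³; ``ext_charge_gradients``
    (n_ext, 3) — the energy derivative with respect to each external point
    charge position (the back-coupling force channel of electrostatic
    embedding).
    """

    energy: float | None = None
    gradient: np.ndarray | None = None
    dipole: np.ndarray | None = None
    polarizability: np.ndarray | None = None
    ext_charge_gradients: np.ndarray | None = None


def _normalize_external_charges(
    external_charges: Sequence | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize to (positions (k,3) Bohr, charges (k,) e)."""
    if external_charges is None or len(external_charges) == 0:
        return np.zeros((0, 3)), np.zeros(0)
    if isinstance(external_charges, tuple) and len(external_charges) == 2:
        pos, q = external_charges
        return np.asarray(pos, float).reshape(-1, 3), np.asarray(q, float).ravel()
    pos = np.array([np.asarray(p, float) for p, _ in external_charges])
    q = np.array([float(c) for _, c in external_charges])
    return pos.reshape(-1, 3), q


def _coulomb_sites_vs_ext(
    site_pos: np.ndarray,
    site_q: np.ndarray,
    ext_pos: np.ndarray,
    ext_q: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Coulomb energy between two distinct site sets, with gradients.

    Returns (energy, dE/d(site_pos), dE/d(ext_pos)).
    """
    if len(site_q) == 0 or len(ext_q) == 0:
        return 0.0, np.zeros_like(site_pos), np.zeros_like(ext_pos)
    diff = site_pos[:, None, :] - ext_pos[None, :, :]  # (n, k, 3)
    r = np.linalg.norm(diff, axis=2)
    if np.any(r < 1e-12):
        raise ValueError("coincident charge sites in Coulomb evaluation")
    qq = site_q[:, None] * ext_q[None, :]
    energy = float(np.sum(qq / r))
    # dE/d(site) = -q_s q_e (site-ext)/r^3 summed over ext
    g = -qq[:, :, None] * diff / (r**3)[:, :, None]
    grad_sites = g.sum(axis=1)
    grad_ext = -g.sum(axis=0)
    return energy, grad_sites, grad_ext


def _coulomb_internal(
    pos: np.ndarray, q: np.ndarray, pairs: np.ndarray
) -> tuple[float, np.ndarray]:
    """Coulomb energy over explicit site pairs, with site gradients."""
    grad = np.zeros_like(pos)
    if len(pairs) == 0:
        return 0.0, grad
    i, j = pairs[:, 0], pairs[:, 1]
    d = pos[i] - pos[j]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-12):
        raise ValueError("coincident charge sites in Coulomb evaluation")
    qq = q[i] * q[j]
    energy = float(np.sum(qq / r))
    f = -(qq / r**3)[:, None] * d  # dE/d(pos_i)
    np.add.at(grad, i, f)
    np.add.at(grad, j, -f)
    return energy, grad


def _lorentzian_response_factor(
    omega_e: float | None, frequency: float, damping: float
) -> complex:
    """Damped-Lorentzian frequency dependence α(ω)/α(0) = ω_e²/(ω_e²-ω²-iΓω).

    Static models (``omega_e`` is None) only support ω = 0.
    """
    if frequency == 0.0:
        return 1.0 + 0.0j
    if omega_e is None:
        raise CapabilityError(
            "frequency-dependent polarizability requested from a model with "
            "no electronic resonance (omega_e)"
        )
    denom = omega_e**2 - frequency**2 - 1j * damping * frequency
    if denom == 0:
        raise ZeroDivisionError(
            "undamped evaluation exactly on resonance; set a nonzero damping"
        )
    return omega_e**2 / denom


class Calculator(abc.ABC):
    """Base class for property providers.

    Subclasses implement :meth:`_evaluate`; the public :meth:`evaluate` does
    capability checking and call counting.  ``n_calls`` counts single-point
    evaluations and is the hook used to assert that isotope restarts trigger
    no new calculations.
    """

    def __init__(self) -> None:
        self.n_calls = 0

    @property
    @abc.abstractmethod
    def capabilities(self) -> frozenset[str]:
        """Subset of {'energy', 'gradient', 'dipole', 'polarizability'}."""

    def evaluate(
        self,
        structure: Structure,
        external_charges: Sequence | None = None,
        request: PropertyRequest | None = None,
    ) -> PropertyBundle:
        request = request or PropertyRequest()
        missing = request.wanted - self.capabilities
        if missing:
            raise CapabilityError(
                f"{type(self).__name__} cannot provide {sorted(missing)}; "
                f"capabilities are {sorted(self.capabilities)}"
            )
        ext_pos, ext_q = _normalize_external_charges(external_charges)
        self.n_calls += 1
        return self._evaluate(structure, ext_pos, ext_q, request)

    @abc.abstractmethod
    def _evaluate(
        self,
        structure: Structure,
        ext_pos: np.ndarray,
        ext_q: np.ndarray,
        request: PropertyRequest,
    ) -> PropertyBundle:
        ...

    def charge_sites(
        self,
        structure: Structure,
        external_charges: Sequence | None = None,
        request: PropertyRequest | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Effective point-charge representation (positions, charges).

        This is how a region is seen by the other side of an embedding
        boundary.  The default raises; models with a charge representation
        override it.
        """
        raise CapabilityError(
            f"{type(self).__name__} has no point-charge representation"
        )


# ---------------------------------------------------------------------------
# diatomic Morse / charge-flux model
# ---------------------------------------------------------------------------

class MorseChargeFluxDiatomic(Calculator):
    """Morse diatomic with charge flux, bond polarizability and optional
    electronic resonance.

    Potential: E(r) = D·(1 − exp(−a·(r − r0)))².
    Charges: ∓q(r) on atoms 0/1 with q(r) = q0 + q1·(r − r0), so the dipole
    is μ = q(r)·(x₁ − x₀) (magnitude q·r along the bond).
    Polarizability: axial bond model, α = α_⊥(r)·I + (α_∥(r) − α_⊥(r))·r̂r̂ᵀ
    with α_∥ = p0 + p1·(r − r0) and α_⊥ = s0 + s1·(r − r0).
    With ``omega_e`` set, α(ω) = α_static·ω_e²/(ω_e² − ω² − iΓω).
    """

    def __init__(
        self,
        D: float,
        a: float,
        r0: float,
        q0: float = 0.0,
        q1: float = 0.0,
        p0: float = 0.0,
        p1: float = 0.0,
        s0: float = 0.0,
        s1: float = 0.0,
        omega_e: float | None = None,
    ) -> None:
        super().__init__()
        if D <= 0 or a <= 0 or r0 <= 0:
            raise ValueError("Morse parameters D, a, r0 must be positive")
        self.D, self.a, self.r0 = D, a, r0
        self.q0, self.q1 = q0, q1
        self.p0, self.p1, self.s0, self.s1 = p0, p1, s0, s1
        self.omega_e = omega_e

    @property
    def harmonic_force_constant(self) -> float:
        """d²E/dr² at the minimum: k = 2·D·a²."""
        return 2.0 * self.D * self.a**2

    @property
    def capabilities(self) -> frozenset[str]:
        caps = {"energy", "gradient", "dipole"}
        if any((self.p0, self.p1, self.s0, self.s1)):
            caps.add("polarizability")
        return frozenset(caps)

    def _geometry(self, structure: Structure):
        if structure.n_atoms != 2:
            raise ValueError("MorseChargeFluxDiatomic requires exactly 2 atoms")
        x0, x1 = structure.positions
        d = x1 - x0
        r = float(np.linalg.norm(d))
        if r < 1e-12:
            raise ValueError("coincident atoms")
        return x0, x1, d, r, d / r

    def charge_sites(self, structure, external_charges=None, request=None):
        x0, x1, d, r, rhat = self._geometry(structure)
        q = self.q0 + self.q1 * (r - self.r0)
        return np.array([x0, x1]), np.array([-q, q])

    def _evaluate(self, structure, ext_pos, ext_q, request):
        x0, x1, d, r, rhat = self._geometry(structure)
        D, a, r0 = self.D, self.a, self.r0
        e = np.exp(-a * (r - r0))
        energy = D * (1.0 - e) ** 2
        dEdr = 2.0 * D * a * e * (1.0 - e)
        grad = np.zeros((2, 3))
        grad[0] = -dEdr * rhat
        grad[1] = dEdr * rhat

        q = self.q0 + self.q1 * (r - self.r0)
        charges = np.array([-q, q])
        site_pos = np.array([x0, x1])
        mu = q * d
        ext_grad = np.zeros_like(ext_pos)

        if len(ext_q):
            e_ext, g_sites, ext_grad = _coulomb_sites_vs_ext(
                site_pos, charges, ext_pos, ext_q
            )
            energy += e_ext
            grad += g_sites
            # charge-flux contribution: q depends on r
            diff = site_pos[:, None, :] - ext_pos[None, :, :]
            rr = np.linalg.norm(diff, axis=2)
            phi = (ext_q[None, :] / rr).sum(axis=1)  # potential at each atom
            flux = self.q1 * (phi[1] - phi[0])
            grad[0] += flux * (-rhat)
            grad[1] += flux * rhat

        F = request.external_field
        if np.any(F):
            dF = float(d @ F)
            energy += -q * dF
            grad[0] += self.q1 * rhat * dF + q * F
            grad[1] += -self.q1 * rhat * dF - q * F

        bundle = PropertyBundle(
            energy=energy,
            gradient=grad if request.gradient else None,
            dipole=mu if request.dipole else None,
            ext_charge_gradients=ext_grad,
        )
        if request.polarizability:
            par = self.p0 + self.p1 * (r - self.r0)
            perp = self.s0 + self.s1 * (r - self.r0)
            alpha = perp * np.eye(3) + (par - perp) * np.outer(rhat, rhat)
            factor = _lorentzian_response_factor(
                self.omega_e, request.frequency, request.damping
            )
            bundle.polarizability = alpha.astype(complex) * factor
        return bundle


# ---------------------------------------------------------------------------
# centrosymmetric linear triatomic
# ---------------------------------------------------------------------------

class HarmonicTriatomic(Calculator):
    """Linear centrosymmetric A–B–A molecule (atom order A, B, A).

    E = ½k_b[(r₀₁ − r0)² + (r₁₂ − r0)²] + k_θ·(1 + cos θ), which is smooth in
    Cartesians through the linear equilibrium.  Fixed charges q_center on B
    and −q_center/2 on each A (neutral).  Per-bond axial polarizability as in
    the diatomic model; the two bond contributions add, which makes the
    symmetric stretch Raman-active/IR-silent and the asymmetric stretch
    IR-active/Raman-silent.
    """

    def __init__(
        self,
        k_bond: float,
        r0: float,
        k_theta: float,
        q_center: float = 0.0,
        p0: float = 0.0,
        p1: float = 0.0,
        s0: float = 0.0,
        s1: float = 0.0,
        omega_e: float | None = None,
    ) -> None:
        super().__init__()
        if k_bond <= 0 or k_theta <= 0 or r0 <= 0:
            raise ValueError("force constants and r0 must be positive")
        self.k_bond, self.r0, self.k_theta = k_bond, r0, k_theta
        self.q_center = q_center
        self.p0, self.p1, self.s0, self.s1 = p0, p1, s0, s1
        self.omega_e = omega_e

    @property
    def capabilities(self) -> frozenset[str]:
        caps = {"energy", "gradient", "dipole"}
        if any((self.p0, self.p1, self.s0, self.s1)):
            caps.add("polarizability")
        return frozenset(caps)

    def _charges(self) -> np.ndarray:
        return np.array([-self.q_center / 2.0, self.q_center, -self.q_center / 2.0])

    def charge_sites(self, structure, external_charges=None, request=None):
        if structure.n_atoms != 3:
            raise ValueError("HarmonicTriatomic requires exactly 3 atoms")
        return structure.positions, self._charges()

    def _evaluate(self, structure, ext_pos, ext_q, request):
        if structure.n_atoms != 3:
            raise ValueError("HarmonicTriatomic requires exactly 3 atoms")
        x = structure.positions
        grad = np.zeros((3, 3))

        energy = 0.0
        for (i, j) in ((0, 1), (1, 2)):
            d = x[j] - x[i]
            r = float(np.linalg.norm(d))
            rhat = d / r
            energy += 0.5 * self.k_bond * (r - self.r0) ** 2
            f = self.k_bond * (r - self.r0) * rhat
            grad[i] -= f
            grad[j] += f

        u = x[0] - x[1]
        v = x[2] - x[1]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        cos_t = float(u @ v) / (nu * nv)
        energy += self.k_theta * (1.0 + cos_t)
        dcos_du = v / (nu * nv) - cos_t * u / nu**2
        dcos_dv = u / (nu * nv) - cos_t * v / nv**2
        grad[0] += self.k_theta * dcos_du
        grad[2] += self.k_theta * dcos_dv
        grad[1] -= self.k_theta * (dcos_du + dcos_dv)

        charges = self._charges()
        mu = charges @ x
        ext_grad = np.zeros_like(ext_pos)
        if len(ext_q):
            e_ext, g_sites, ext_grad = _coulomb_sites_vs_ext(x, charges, ext_pos, ext_q)
            energy += e_ext
            grad += g_sites
        F = request.external_field
        if np.any(F):
            energy += -float(mu @ F)
            grad -= charges[:, None] * F[None, :]

        bundle = PropertyBundle(
            energy=energy,
            gradient=grad if request.gradient else None,
            dipole=mu if request.dipole else None,
            ext_charge_gradients=ext_grad,
        )
        if request.polarizability:
            alpha = np.zeros((3, 3))
            for (i, j) in ((0, 1), (1, 2)):
                d = x[j] - x[i]
                r = float(np.linalg.norm(d))
                rhat = d / r
                par = self.p0 + self.p1 * (r - self.r0)
                perp = self.s0 + self.s1 * (r - self.r0)
                alpha += perp * np.eye(3) + (par - perp) * np.outer(rhat, rhat)
            factor = _lorentzian_response_factor(
                self.omega_e, request.frequency, request.damping
            )
            bundle.polarizability = alpha.astype(complex) * factor
        return bundle


# ---------------------------------------------------------------------------
# shell-model ionic engine
# ---------------------------------------------------------------------------

@dataclass
class SpeciesParams:
    """Per-element shell-model parameters: core charge (e), shell charge (e)
    and shell spring constant (Hartree/Bohr²).  ``shell_charge=0`` means a
    rigid ion."""

    core_charge: float
    shell_charge: float = 0.0
    spring: float | None = None

    def __post_init__(self) -> None:
        if self.shell_charge != 0.0 and (self.spring is None or self.spring <= 0):
            raise ValueError("a shelled species needs a positive spring constant")


class ShellModelIonic(Calculator):
    """Core–shell polarizable ionic engine with Buckingham short-range terms.

    Each atom carries a core charge and optionally a massless shell bound by
    a harmonic spring; the isolated-ion polarizability is q_shell²/spring.
    Coulomb interactions act between all charge sites of *different* atoms;
    the core–shell pair of one atom interacts only through its spring.
    Buckingham A·exp(−r/ρ) − C/r⁶ acts between the electron-cloud sites
    (shell if present, else core).

    Shell positions are relaxed by damped fixed-point iteration
    s ← x + F_non-spring(s)/k until the largest per-cycle displacement drops
    below ``shell_tolerance`` (equivalently: residual shell force below
    k·tolerance).  Gradients on cores are evaluated at the relaxed shells,
    which is exact for the minimized energy.  The polarizability is defined
    operationally as the finite-field dipole response after shell relaxation.
    """

    def __init__(
        self,
        species: dict[str, SpeciesParams | dict],
        buckingham: dict[tuple[str, str], tuple[float, float, float]] | None = None,
        shell_tolerance: float = 1e-9,
        max_shell_cycles: int = 2000,
        mixing: float = 1.0,
        field_step: float = DEFAULT_FIELD_STEP,
    ) -> None:
        super().__init__()
        self.species = {
            el: (sp if isinstance(sp, SpeciesParams) else SpeciesParams(**sp))
            for el, sp in species.items()
        }
        self.buckingham = {}
        for key, val in (buckingham or {}).items():
            a, b = key
            self.buckingham[tuple(sorted((a, b)))] = tuple(float(x) for x in val)
        if shell_tolerance <= 0:
            raise ValueError("shell_tolerance must be positive")
        self.shell_tolerance = shell_tolerance
        self.max_shell_cycles = max_shell_cycles
        self.mixing = mixing
        self.field_step = field_step

    @property
    def capabilities(self) -> frozenset[str]:
        return frozenset({"energy", "gradient", "dipole", "polarizability"})

    # -- per-structure parameter resolution ----------------------------------
    def _resolve(self, structure: Structure):
        """Resolve per-atom (core charge, shell charge, spring); explicit
        Atom.charge / Atom.shell entries override the species table."""
        core_q = np.zeros(structure.n_atoms)
        shell_q = np.zeros(structure.n_atoms)
        spring = np.zeros(structure.n_atoms)
        for i, atom in enumerate(structure.atoms):
            sp = self.species.get(atom.element)
            if atom.charge is not None:
                core_q[i] = atom.charge
            elif sp is not None:
                core_q[i] = sp.core_charge
            else:
                raise ValueError(
                    f"no charge for atom {i} ({atom.element}): not in species table "
                    "and no explicit charge"
                )
            if atom.shell is not None:
                shell_q[i] = atom.shell.charge
                spring[i] = atom.shell.spring
            elif sp is not None and sp.shell_charge != 0.0:
                shell_q[i] = sp.shell_charge
                spring[i] = sp.spring
        return core_q, shell_q, spring

    def has_shells(self, structure: Structure) -> bool:
        _, shell_q, _ = self._resolve(structure)
        return bool(np.any(shell_q != 0.0))

    def _buck_params(self, structure: Structure):
        n = structure.n_atoms
        pairs, params = [], []
        els = structure.elements
        for i in range(n):
            for j in range(i + 1, n):
                key = tuple(sorted((els[i], els[j])))
                if key in self.buckingham:
                    pairs.append((i, j))
                    params.append(self.buckingham[key])
        return pairs, params

    # -- energy/forces at given shell positions ------------------------------
    def _site_arrays(self, x, s, core_q, shell_q):
        """All charge sites: cores first, then the shelled atoms' shells."""
        shelled = np.nonzero(shell_q != 0.0)[0]
        pos = np.vstack([x, s[shelled]]) if len(shelled) else x.copy()
        q = np.concatenate([core_q, shell_q[shelled]])
        owner = np.concatenate([np.arange(len(x)), shelled])
        return pos, q, owner, shelled

    def _energy_forces(
        self, structure, x, s, core_q, shell_q, spring, ext_pos, ext_q, F
    ):
        """Total energy and per-site forces at shell configuration ``s``.

        Returns (energy, grad_cores, grad_shells, ext_grad) where the core
        gradient holds everything that moves with the atom position x (spring
        end, core Coulomb/field, Buckingham on unshelled atoms) and the shell
        gradient everything acting on s.
        """
        n = structure.n_atoms
        shelled_mask = shell_q != 0.0
        grad_x = np.zeros((n, 3))
        grad_s = np.zeros((n, 3))
        ext_grad = np.zeros_like(ext_pos)
        energy = 0.0

        # springs
        disp = s - x
        energy += 0.5 * float(np.sum(spring[shelled_mask] * np.sum(disp[shelled_mask] ** 2, axis=1)))
        spring_f = spring[:, None] * disp
        grad_s[shelled_mask] += spring_f[shelled_mask]
        grad_x[shelled_mask] -= spring_f[shelled_mask]

        pos, q, owner, shelled = self._site_arrays(x, s, core_q, shell_q)
        is_shell_site = np.zeros(len(q), dtype=bool)
        is_shell_site[n:] = True

        # internal Coulomb between sites of different atoms
        pairs = [
            (a, b)
            for a in range(len(q))
            for b in range(a + 1, len(q))
            if owner[a] != owner[b] and q[a] != 0.0 and q[b] != 0.0
        ]
        e_c, g_sites = _coulomb_internal(pos, q, np.array(pairs).reshape(-1, 2))
        energy += e_c

        # Buckingham between cloud sites (shell if present else core)
        buck_pairs, buck_params = self._buck_params(structure)
        cloud = np.where(shelled_mask[:, None], s, x)
        for (i, j), (A, rho, C) in zip(buck_pairs, buck_params):
            d = cloud[i] - cloud[j]
            r = float(np.linalg.norm(d))
            energy += A * np.exp(-r / rho) - C / r**6
            dEdr = -A / rho * np.exp(-r / rho) + 6.0 * C / r**7
            f = dEdr * d / r
            for k, sgn in ((i, 1.0), (j, -1.0)):
                if shelled_mask[k]:
                    grad_s[k] += sgn * f
                else:
                    grad_x[k] += sgn * f

        # external charges and uniform field act on every site
        if len(ext_q):
            e_ext, g_ext_sites, ext_grad = _coulomb_sites_vs_ext(pos, q, ext_pos, ext_q)
            energy += e_ext
            g_sites = g_sites + g_ext_sites
        if np.any(F):
            energy += -float((q[:, None] * pos).sum(axis=0) @ F)
            g_sites = g_sites - q[:, None] * F[None, :]

        # scatter site gradients to core/shell holders
        grad_x += np.where(is_shell_site[:n, None], 0.0, g_sites[:n])
        if len(shelled):
            for site_idx, atom_idx in zip(range(n, len(q)), shelled):
                grad_s[atom_idx] += g_sites[site_idx]
        return energy, grad_x, grad_s, ext_grad

    def relax_shells(
        self,
        structure: Structure,
        external_charges: Sequence | None = None,
        external_field: np.ndarray | None = None,
        tolerance: float | None = None,
        max_cycles: int | None = None,
    ) -> np.ndarray:
        """Relax shell positions; returns (n_atoms, 3) shell coordinates
        (equal to core positions for unshelled atoms).

        Raises :class:`ConvergenceError` with the worst residual when the
        cycle cap is reached.
        """
        ext_pos, ext_q = _normalize_external_charges(external_charges)
        F = np.zeros(3) if external_field is None else np.asarray(external_field, float)
        tol = tolerance if tolerance is not None else self.shell_tolerance
        max_cycles = max_cycles if max_cycles is not None else self.max_shell_cycles
        x = structure.positions
        core_q, shell_q, spring = self._resolve(structure)
        shelled = shell_q != 0.0
        s = x.copy()
        for i, atom in enumerate(structure.atoms):
            if atom.shell is not None and atom.shell.position is not None:
                s[i] = atom.shell.position
        if not np.any(shelled):
            return s
        last_delta = np.inf
        for _ in range(max_cycles):
            _, _, grad_s, _ = self._energy_forces(
                structure, x, s, core_q, shell_q, spring, ext_pos, ext_q, F
            )
            # remove the spring term to get the non-spring force on shells
            f_nonspring = -(grad_s - spring[:, None] * (s - x))
            target = x + np.where(
                shelled[:, None], f_nonspring / np.where(shelled, spring, 1.0)[:, None], 0.0
            )
            new_s = s + self.mixing * (target - s)
            new_s[~shelled] = x[~shelled]
            last_delta = float(np.max(np.linalg.norm(new_s - s, axis=1)))
            s = new_s
            if last_delta < tol:
                return s
        raise ConvergenceError(
            f"shell relaxation did not converge in {max_cycles} cycles; "
            f"worst per-cycle displacement {last_delta:.3e} Bohr (tol {tol:.1e})"
        )

    def _evaluate(self, structure, ext_pos, ext_q, request):
        x = structure.positions
        core_q, shell_q, spring = self._resolve(structure)
        F = request.external_field
        if request.relax_shells:
            s = self.relax_shells(structure, (ext_pos, ext_q), F)
        else:
            s = x.copy()
        energy, grad_x, grad_s, ext_grad = self._energy_forces(
            structure, x, s, core_q, shell_q, spring, ext_pos, ext_q, F
        )
        grad = grad_x
        if not request.relax_shells:
            # rigid shells ride on the cores: their site forces move the atom
            grad = grad_x + grad_s
        mu = (core_q[:, None] * x).sum(axis=0) + (shell_q[:, None] * s).sum(axis=0)
        bundle = PropertyBundle(
            energy=energy,
            gradient=grad if request.gradient else None,
            dipole=mu if request.dipole else None,
            ext_charge_gradients=ext_grad,
        )
        if request.polarizability:
            if request.frequency != 0.0:
                raise CapabilityError(
                    "ShellModelIonic has no electronic resonance model; only "
                    "static polarizability is available"
                )
            alpha = np.zeros((3, 3))
            h = self.field_step
            for j in range(3):
                mus = []
                for sign in (1.0, -1.0):
                    Fj = F.copy()
                    Fj[j] += sign * h
                    sj = (
                        self.relax_shells(structure, (ext_pos, ext_q), Fj)
                        if request.relax_shells
                        else x.copy()
                    )
                    mus.append(
                        (core_q[:, None] * x).sum(axis=0)
                        + (shell_q[:, None] * sj).sum(axis=0)
                    )
                alpha[:, j] = (mus[0] - mus[1]) / (2.0 * h)
            bundle.polarizability = (0.5 * (alpha + alpha.T)).astype(complex)
        return bundle

    def charge_sites(self, structure, external_charges=None, request=None):
        x = structure.positions
        core_q, shell_q, spring = self._resolve(structure)
        relax = request.relax_shells if request is not None else True
        F = request.external_field if request is not None else None
        if relax and np.any(shell_q != 0.0):
            s = self.relax_shells(structure, external_charges, F)
        else:
            s = x.copy()
        pos, q, _, _ = self._site_arrays(x, s, core_q, shell_q)
        keep = q != 0.0
        return pos[keep], q[keep]


# ---------------------------------------------------------------------------
# finite-field polarizability (oracle-grade operation)
# ---------------------------------------------------------------------------

def finite_field_polarizability(
    calculator: Calculator,
    structure: Structure,
    external_charges: Sequence | None = None,
    field_step: float = DEFAULT_FIELD_STEP,
) -> np.ndarray:
    """Static polarizability as the central-difference dipole response to a
    uniform field, α_ij = ∂μ_i/∂F_j (Bohr³); symmetric to O(step²).

    Works for any calculator with dipole capability, including shell-model
    engines (shells re-relax at every field value).
    """
    if "dipole" not in calculator.capabilities:
        raise CapabilityError("finite-field polarizability needs dipole capability")
    alpha = np.zeros((3, 3))
    for j in range(3):
        mus = []
        for sign in (1.0, -1.0):
            F = np.zeros(3)
            F[j] = sign * field_step
            req = PropertyRequest(dipole=True, external_field=F)
            mus.append(calculator.evaluate(structure, external_charges, req).dipole)
        alpha[:, j] = (mus[0] - mus[1]) / (2.0 * field_step)
    return 0.5 * (alpha + alpha.T)


# ---------------------------------------------------------------------------
# parameter-file factory
# ---------------------------------------------------------------------------

_MODEL_TYPES = {
    "morse_diatomic": MorseChargeFluxDiatomic,
    "harmonic_triatomic": HarmonicTriatomic,
}


def calculator_from_dict(spec: dict) -> Calculator:
    """Build a calculator from a flat key–value mapping.

    Schema: a ``type`` key selecting ``morse_diatomic``,
    ``harmonic_triatomic`` or ``shell_ionic``; remaining keys are the model's
    constructor parameters.  For ``shell_ionic``, ``species`` maps element →
    {core_charge, shell_charge, spring} and ``buckingham`` maps "El1-El2" →
    [A, rho, C].
    """
    spec = dict(spec)
    try:
        kind = spec.pop("type")
    except KeyError:
        raise ValueError("calculator spec needs a 'type' key") from None
    if kind in _MODEL_TYPES:
        return _MODEL_TYPES[kind](**spec)
    if kind == "shell_ionic":
        buck = {}
        for key, val in (spec.pop("buckingham", None) or {}).items():
            pair = tuple(key.split("-")) if isinstance(key, str) else tuple(key)
            if len(pair) != 2:
                raise ValueError(f"bad buckingham pair key {key!r}")
            buck[pair] = tuple(val)
        return ShellModelIonic(spec.pop("species"), buck, **spec)
    raise ValueError(f"unknown calculator type {kind!r}")


def load_calculator(path: str | Path) -> Calculator:
    """Load a calculator from a YAML parameter file (see
    :func:`calculator_from_dict` for the schema)."""
    import yaml

    with open(path) as fh:
        return calculator_from_dict(yaml.safe_load(fh))
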