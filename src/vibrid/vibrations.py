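"""Finite-difference derivative sweeps, normal modes and isotope restarts.

The partial Hessian and the dipole/polarizability derivatives are evaluated
over the 3N Cartesian coordinates of the vibrationally active atoms with
two-point central differences.  Displacements are applied in plain Cartesian
coordinates and mass weighting is applied analytically afterwards, so one
stored sweep can be re-used for isotope studies by amending atomic masses —
no new single-point calculations are needed.

The 3N displaced-geometry pairs are distributed over M work groups
(task farming).  Results are keyed by coordinate index and aggregated in
fixed coordinate order, so the assembled derivatives are bit-for-bit
independent of the number of work groups and of completion order.
"""

from __future__ import annotations

import hashlib
import json
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg

from .calculators import Calculator, PropertyRequest
from .molsys import RegionMap, Structure
from .units import EIGENVALUE_TO_WAVENUMBER

__all__ = [
    "DerivativeBundle",
    "ModeSet",
    "ModeDerivatives",
    "finite_difference_sweep",
    "normal_modes",
    "project_to_modes",
    "remass_restart",
    "save_bundle",
    "load_bundle",
]

ARCHIVE_SCHEMA_VERSION = 1

#: modes with |frequency| below this (cm⁻¹) are reported as zero-frequency;
#: nothing is dropped — all 3N modes are always kept.
ZERO_FREQ_THRESHOLD_CM = 1.0

#: Hessian asymmetry above this (Hartree/Bohr²) signals a bad calculator.
MAX_HESSIAN_ASYMMETRY = 1e-4


@dataclass
class DerivativeBundle:
    """Cartesian second derivatives of the energy and first derivatives of
    dipole/polarizability over the vibrationally active atoms.

    ``hessian`` is the symmetrized matrix used downstream; ``hessian_raw``
    keeps the as-computed matrix with its recorded ``max_asymmetry``.
    """

    step: float
    elements: list[str]
    masses: np.ndarray
    positions: np.ndarray
    region_map: RegionMap
    hessian_raw: np.ndarray
    hessian: np.ndarray
    max_asymmetry: float
    dipole_derivatives: np.ndarray | None = None
    polarizability_derivatives: np.ndarray | None = None
    frequency: float = 0.0
    damping: float = 0.0
    structure_hash: str = ""
    provenance: list[dict] = field(default_factory=list)
    schema_version: int = ARCHIVE_SCHEMA_VERSION

    @property
    def n_active(self) -> int:
        return len(self.masses)

    def __post_init__(self) -> None:
        n3 = 3 * self.n_active
        if self.hessian.shape != (n3, n3):
            raise ValueError(f"hessian shape {self.hessian.shape} != {(n3, n3)}")
        if self.dipole_derivatives is not None and self.dipole_derivatives.shape != (n3, 3):
            raise ValueError("dipole derivative shape mismatch")
        if (
            self.polarizability_derivatives is not None
            and self.polarizability_derivatives.shape != (n3, 3, 3)
        ):
            raise ValueError("polarizability derivative shape mismatch")


@dataclass
class ModeSet:
    """Normal modes of the mass-weighted Hessian.

    ``frequencies`` are in cm⁻¹, signed (negative encodes an imaginary
    frequency), ascending with negatives first.  ``modes`` columns are
    orthonormal in the mass-weighted metric.
    """

    frequencies: np.ndarray
    modes: np.ndarray
    masses: np.ndarray

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)

    def cartesian_displacements(self) -> np.ndarray:
        """(3N, n_modes) Cartesian displacement patterns (un-mass-weighted
        mode vectors), the shape viewers expect."""
        inv_sqrt_m = np.repeat(1.0 / np.sqrt(self.masses), 3)
        return inv_sqrt_m[:, None] * self.modes


@dataclass
class ModeDerivatives:
    """Per-mode property derivatives: ∂μ/∂Q_i (e/√amu) and ∂α/∂Q_i
    (Bohr²/√amu, complex)."""

    dmu_dQ: np.ndarray | None
    dalpha_dQ: np.ndarray | None


def _structure_hash(structure: Structure) -> str:
    h = hashlib.sha256()
    h.update(",".join(structure.elements).encode())
    h.update(np.ascontiguousarray(structure.positions).tobytes())
    return h.hexdigest()


def finite_difference_sweep(
    calculator: Calculator,
    structure: Structure,
    region_map: RegionMap | None = None,
    step: float = 0.01,
    workgroups: int = 1,
    want_dipole: bool = True,
    want_polarizability: bool = False,
    frequency: float = 0.0,
    damping: float = 0.0,
) -> DerivativeBundle:
    """Central-difference sweep over the 3N vibrationally active coordinates.

    Each coordinate is displaced by ±``step`` (Bohr) and the calculator is
    evaluated at the displaced geometry (the embedding scheme, including any
    shell relaxation, runs at every displaced geometry).  6N single points in
    total, distributed over ``workgroups`` work groups.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if workgroups < 1:
        raise ValueError("workgroups must be >= 1")
    region_map = region_map or RegionMap.all_inner(structure.n_atoms)
    if "gradient" not in calculator.capabilities:
        raise ValueError("the calculator must provide gradients")
    vib_atoms = list(region_map.vib_active)
    n = len(vib_atoms)
    n3 = 3 * n
    request = PropertyRequest(
        energy=True,
        gradient=True,
        dipole=want_dipole,
        polarizability=want_polarizability,
        frequency=frequency,
        damping=damping,
    )

    base_positions = structure.positions

    def run_single_point(task_id: int):
        coord, pm = divmod(task_id, 2)
        sign = 1.0 if pm == 0 else -1.0
        atom = vib_atoms[coord // 3]
        axis = coord % 3
        pos = base_positions.copy()
        pos[atom, axis] += sign * step
        label = f"atom {atom} axis {'xyz'[axis]} {'+' if sign > 0 else '-'}{step:g} Bohr"
        try:
            bundle = calculator.evaluate(structure.with_positions(pos), None, request)
        except Exception as exc:
            raise RuntimeError(f"single-point failure at displacement [{label}]") from exc
        if not np.all(np.isfinite(bundle.gradient)):
            raise RuntimeError(f"non-finite gradient at displacement [{label}]")
        return task_id, label, bundle

    task_ids = list(range(2 * n3))
    results: dict[int, tuple[str, object]] = {}

    def run_group(ids: list[int]) -> list:
        return [run_single_point(t) for t in ids]

    groups = [task_ids[g::workgroups] for g in range(workgroups)]
    with ThreadPoolExecutor(max_workers=workgroups) as pool:
        for chunk in pool.map(run_group, groups):
            for task_id, label, bundle in chunk:
                results[task_id] = (label, bundle)

    hessian = np.empty((n3, n3))
    dmu = np.empty((n3, 3)) if want_dipole else None
    dalpha = np.empty((n3, 3, 3), dtype=complex) if want_polarizability else None
    provenance = []
    for coord in range(n3):
        lab_p, bp = results[2 * coord]
        lab_m, bm = results[2 * coord + 1]
        gp = bp.gradient[vib_atoms].ravel()
        gm = bm.gradient[vib_atoms].ravel()
        hessian[:, coord] = (gp - gm) / (2.0 * step)
        if want_dipole:
            dmu[coord] = (bp.dipole - bm.dipole) / (2.0 * step)
        if want_polarizability:
            dalpha[coord] = (bp.polarizability - bm.polarizability) / (2.0 * step)
        provenance.append(
            {"coord": coord, "labels": [lab_p, lab_m],
             "energies": [bp.energy, bm.energy]}
        )

    max_asym = float(np.max(np.abs(hessian - hessian.T))) if n3 else 0.0
    if max_asym > MAX_HESSIAN_ASYMMETRY:
        raise RuntimeError(
            f"Hessian asymmetry {max_asym:.3e} Hartree/Bohr² exceeds "
            f"{MAX_HESSIAN_ASYMMETRY:g}; the calculator gradients are inconsistent"
        )
    sym = 0.5 * (hessian + hessian.T)

    vib_struct = structure.subset(vib_atoms)
    return DerivativeBundle(
        step=step,
        elements=vib_struct.elements,
        masses=vib_struct.masses,
        positions=vib_struct.positions,
        region_map=region_map,
        hessian_raw=hessian,
        hessian=sym,
        max_asymmetry=max_asym,
        dipole_derivatives=dmu,
        polarizability_derivatives=dalpha,
        frequency=frequency,
        damping=damping,
        structure_hash=_structure_hash(structure),
        provenance=provenance,
    )


def _tr_basis(positions: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Orthonormal basis of mass-weighted rigid translations and rotations.

    Returns (3N, k) with k = 6 for a nonlinear, 5 for a linear arrangement
    (3 for a single atom).
    """
    n = len(masses)
    sqrt_m = np.sqrt(masses)
    com = (masses[:, None] * positions).sum(axis=0) / masses.sum()
    rel = positions - com
    vecs = []
    for a in range(3):
        v = np.zeros((n, 3))
        v[:, a] = sqrt_m
        vecs.append(v.ravel())
    for a in range(3):
        e = np.zeros(3)
        e[a] = 1.0
        v = sqrt_m[:, None] * np.cross(e, rel)
        vecs.append(v.ravel())
    basis = np.array(vecs).T  # (3N, 6)
    u, sv, _ = np.linalg.svd(basis, full_matrices=False)
    keep = sv > 1e-8 * sv[0]
    return u[:, keep]


def _fix_mode_signs(modes: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude component positive (ties broken
    by lowest index, which is what argmax returns)."""
    out = modes.copy()
    for i in range(out.shape[1]):
        k = int(np.argmax(np.abs(out[:, i])))
        if out[k, i] < 0:
            out[:, i] = -out[:, i]
    return out


def normal_modes(
    bundle: DerivativeBundle,
    masses: Sequence[float] | None = None,
    project_tr: bool = False,
) -> ModeSet:
    """Eigendecomposition of the mass-weighted (symmetrized) Hessian.

    Eigenvalue λ maps to a signed frequency sign(λ)·√|λ| in cm⁻¹; negative
    frequencies encode imaginary modes and come first.  With ``project_tr``
    the rigid translations/rotations are projected out before diagonalization
    (free-molecule mode); the default keeps them, because for an embedded
    fragment the nominally translational and rotational motions are genuine
    vibrations.  All 3N modes are returned in every case.
    """
    masses = np.asarray(masses if masses is not None else bundle.masses, dtype=float)
    if masses.shape != (bundle.n_active,):
        raise ValueError(
            f"expected {bundle.n_active} masses, got shape {masses.shape}"
        )
    if not np.all(np.isfinite(bundle.hessian)):
        raise ValueError("Hessian contains non-finite entries")
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(masses), 3)
    fmat = bundle.hessian * np.outer(inv_sqrt_m, inv_sqrt_m)
    if project_tr:
        d = _tr_basis(bundle.positions, masses)
        p = np.eye(fmat.shape[0]) - d @ d.T
        fmat = p @ fmat @ p
        fmat = 0.5 * (fmat + fmat.T)
    evals, evecs = scipy.linalg.eigh(fmat)
    freqs = np.sign(evals) * np.sqrt(np.abs(evals)) * EIGENVALUE_TO_WAVENUMBER
    order = np.argsort(freqs, kind="stable")
    return ModeSet(
        frequencies=freqs[order],
        modes=_fix_mode_signs(evecs[:, order]),
        masses=masses,
    )


def project_to_modes(bundle: DerivativeBundle, modeset: ModeSet) -> ModeDerivatives:
    """Chain-rule projection of Cartesian property derivatives onto normal
    modes: ∂μ/∂Q_i = Σ_k (∂μ/∂x_k)·(1/√m_k)·L_ki, and likewise for α."""
    n3 = 3 * bundle.n_active
    if modeset.modes.shape != (n3, n3):
        raise ValueError(
            f"mode matrix shape {modeset.modes.shape} does not match 3N = {n3}"
        )
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(modeset.masses), 3)
    weighted = modeset.modes * inv_sqrt_m[:, None]  # (3N coords, 3N modes)
    dmu = None
    if bundle.dipole_derivatives is not None:
        dmu = weighted.T @ bundle.dipole_derivatives  # (modes, 3)
    dalpha = None
    if bundle.polarizability_derivatives is not None:
        flat = bundle.polarizability_derivatives.reshape(n3, 9)
        dalpha = (weighted.T @ flat).reshape(n3, 3, 3)
    return ModeDerivatives(dmu_dQ=dmu, dalpha_dQ=dalpha)


def remass_restart(
    bundle: DerivativeBundle,
    new_masses: Sequence[float],
    project_tr: bool = False,
) -> tuple[ModeSet, ModeDerivatives]:
    """Recompute modes and mode derivatives with amended atomic masses.

    Because the stored derivatives are plain Cartesian, an isotope study is a
    pure restart: zero new calculator calls.
    """
    modeset = normal_modes(bundle, new_masses, project_tr=project_tr)
    return modeset, project_to_modes(bundle, modeset)


# ---------------------------------------------------------------------------
# restart archive (versioned JSON)
# ---------------------------------------------------------------------------

def save_bundle(bundle: DerivativeBundle, path: str | Path) -> None:
    """Serialize a DerivativeBundle to the versioned JSON restart archive."""
    rm = bundle.region_map
    doc = {
        "schema_version": bundle.schema_version,
        "step": bundle.step,
        "elements": bundle.elements,
        "masses": bundle.masses.tolist(),
        "positions": bundle.positions.tolist(),
        "region_map": {
            "inner": list(rm.inner),
            "active_env": list(rm.active_env),
            "frozen_env": list(rm.frozen_env),
            "vib_active": list(rm.vib_active),
            "n_atoms": rm.n_atoms,
        },
        "hessian_raw": bundle.hessian_raw.tolist(),
        "max_asymmetry": bundle.max_asymmetry,
        "dipole_derivatives": (
            None if bundle.dipole_derivatives is None else bundle.dipole_derivatives.tolist()
        ),
        "polarizability_derivatives_re": (
            None
            if bundle.polarizability_derivatives is None
            else bundle.polarizability_derivatives.real.tolist()
        ),
        "polarizability_derivatives_im": (
            None
            if bundle.polarizability_derivatives is None
            else bundle.polarizability_derivatives.imag.tolist()
        ),
        "frequency": bundle.frequency,
        "damping": bundle.damping,
        "structure_hash": bundle.structure_hash,
        "provenance": bundle.provenance,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def load_bundle(path: str | Path) -> DerivativeBundle:
    """Load a DerivativeBundle from a restart archive."""
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != ARCHIVE_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported restart archive schema version {version!r} "
            f"(this build reads version {ARCHIVE_SCHEMA_VERSION})"
        )
    rm = doc["region_map"]
    region_map = RegionMap(
        inner=tuple(rm["inner"]),
        active_env=tuple(rm["active_env"]),
        frozen_env=tuple(rm["frozen_env"]),
        vib_active=tuple(rm["vib_active"]),
        n_atoms=rm["n_atoms"],
    )
    raw = np.array(doc["hessian_raw"])
    dmu = doc["dipole_derivatives"]
    re = doc["polarizability_derivatives_re"]
    im = doc["polarizability_derivatives_im"]
    return DerivativeBundle(
        step=doc["step"],
        elements=list(doc["elements"]),
        masses=np.array(doc["masses"]),
        positions=np.array(doc["positions"]),
        region_map=region_map,
        hessian_raw=raw,
        hessian=0.5 * (raw + raw.T),
        max_asymmetry=doc["max_asymmetry"],
        dipole_derivatives=None if dmu is None else np.array(dmu),
        polarizability_derivatives=(
            None if re is None else np.array(re) + 1j * np.array(im)
        ),
        frequency=doc["frequency"],
        damping=doc["damping"],
        structure_hash=doc["structure_hash"],
        provenance=doc["provenance"],
    )
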