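"""Core chemical data model: atoms, structures, regions, masses, XYZ I/O.

Positions are stored internally in Bohr; XYZ files are read and written in Å.
Atom order in a :class:`Structure` is stable and serves as the index space
for all derivative bookkeeping (region maps, Hessian rows, restart archives).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM

__all__ = [
    "ATOMIC_WEIGHTS",
    "Atom",
    "ShellSpec",
    "Structure",
    "RegionMap",
    "UnknownElementError",
    "XYZParseError",
    "atomic_mass",
    "mass_weight",
    "read_xyz",
    "write_xyz",
]

# IUPAC standard atomic weights (conventional values, amu).
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.002602, "Li": 6.94, "Be": 9.0121831, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998403162, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815384, "Si": 28.085,
    "P": 30.973761998, "S": 32.06, "Cl": 35.45, "Ar": 39.95, "K": 39.0983,
    "Ca": 40.078, "Sc": 44.955907, "Ti": 47.867, "V": 50.9415, "Cr": 51.9961,
    "Mn": 54.938043, "Fe": 55.845, "Co": 58.933194, "Ni": 58.6934,
    "Cu": 63.546, "Zn": 65.38, "Ga": 69.723, "Ge": 72.630, "As": 74.921595,
    "Se": 78.971, "Br": 79.904, "Kr": 83.798, "Rb": 85.4678, "Sr": 87.62,
    "Y": 88.905838, "Zr": 91.222, "Nb": 92.90637, "Mo": 95.95, "Ru": 101.07,
    "Rh": 102.90549, "Pd": 106.42, "Ag": 107.8682, "Cd": 112.414,
    "In": 114.818, "Sn": 118.710, "Sb": 121.760, "Te": 127.60,
    "I": 126.90447, "Xe": 131.293, "Cs": 132.90545196, "Ba": 137.327,
    "W": 183.84, "Re": 186.207, "Os": 190.23, "Ir": 192.217, "Pt": 195.084,
    "Au": 196.966570, "Hg": 200.592, "Tl": 204.38, "Pb": 207.2,
    "Bi": 208.98040, "U": 238.02891,
}


class UnknownElementError(KeyError):
    """Raised for an element symbol with no tabulated atomic weight."""


class XYZParseError(ValueError):
    """Raised for malformed XYZ files; the message carries the line number."""


def atomic_mass(element: str, override: float | None = None) -> float:
    """Standard atomic weight of ``element`` in amu, or ``override`` if given.

    The override supports isotopic substitution (e.g. 2.014 amu for
    deuterium) without touching the element symbol.
    """
    if override is not None:
        if override <= 0:
            raise ValueError(f"mass override must be positive, got {override}")
        return float(override)
    try:
        return ATOMIC_WEIGHTS[element]
    except KeyError:
        raise UnknownElementError(
            f"no tabulated atomic weight for element symbol {element!r}; "
            "supply a mass override"
        ) from None


@dataclass
class ShellSpec:
    """Massless charged shell harmonically bound to its core.

    ``charge`` in e, ``spring`` in Hartree/Bohr² (must be positive),
    ``position`` in Bohr (defaults to the core position when relaxed from
    scratch).  The isolated-atom polarizability of a core–shell pair is
    charge²/spring.
    """

    charge: float
    spring: float
    position: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.spring > 0:
            raise ValueError(f"shell spring constant must be > 0, got {self.spring}")
        if self.position is not None:
            self.position = np.asarray(self.position, dtype=float)


@dataclass
class Atom:
    """One atom: element symbol, mass (amu), position (Bohr), optional
    point charge (e) and optional polarizable shell."""

    element: str
    mass: float
    position: np.ndarray
    charge: float | None = None
    shell: ShellSpec | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {self.position.shape}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position components must be finite")
        if not self.mass > 0:
            raise ValueError(f"mass must be positive, got {self.mass}")


class Structure:
    """Ordered list of atoms plus a free-text comment.

    The atom order is the single source of truth for indexing throughout the
    package.
    """

    def __init__(self, atoms: Sequence[Atom], comment: str = "") -> None:
        atoms = list(atoms)
        if len(atoms) < 1:
            raise ValueError("a Structure needs at least one atom")
        self.atoms: list[Atom] = atoms
        self.comment = comment

    # -- array views ---------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(n_atoms, 3) array in Bohr (a copy)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def charges(self) -> np.ndarray:
        """Per-atom point charge, zero where unset."""
        return np.array(
            [0.0 if a.charge is None else a.charge for a in self.atoms], dtype=float
        )

    def with_positions(self, positions: np.ndarray) -> "Structure":
        """Copy of the structure with new positions (Bohr); shells move
        rigidly with their cores, preserving any stored offset."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (self.n_atoms, 3):
            raise ValueError(
                f"expected positions of shape {(self.n_atoms, 3)}, got {positions.shape}"
            )
        new_atoms = []
        for atom, pos in zip(self.atoms, positions):
            shell = atom.shell
            if shell is not None:
                offset = (
                    shell.position - atom.position if shell.position is not None else None
                )
                shell = ShellSpec(
                    shell.charge,
                    shell.spring,
                    None if offset is None else pos + offset,
                )
            new_atoms.append(replace(atom, position=pos.copy(), shell=shell))
        return Structure(new_atoms, self.comment)

    def with_masses(self, masses: Sequence[float]) -> "Structure":
        masses = np.asarray(masses, dtype=float)
        if masses.shape != (self.n_atoms,):
            raise ValueError(f"expected {self.n_atoms} masses, got {masses.shape}")
        return Structure(
            [replace(a, mass=float(m)) for a, m in zip(self.atoms, masses)],
            self.comment,
        )

    def subset(self, indices: Iterable[int]) -> "Structure":
        idx = list(indices)
        return Structure([self.atoms[i] for i in idx], self.comment)

    @classmethod
    def from_arrays(
        cls,
        elements: Sequence[str],
        positions_bohr: np.ndarray,
        charges: Sequence[float] | None = None,
        masses: Sequence[float] | None = None,
        comment: str = "",
    ) -> "Structure":
        positions_bohr = np.asarray(positions_bohr, dtype=float)
        atoms = []
        for i, el in enumerate(elements):
            atoms.append(
                Atom(
                    element=el,
                    mass=atomic_mass(el) if masses is None else float(masses[i]),
                    position=positions_bohr[i],
                    charge=None if charges is None else float(charges[i]),
                )
            )
        return cls(atoms, comment)


@dataclass(frozen=True)
class RegionMap:
    """Partition of atoms into inner (QM-like), active environment and frozen
    environment, plus the vibrationally active subset.

    ``inner``, ``active_env`` and ``frozen_env`` must be disjoint and cover
    all atoms; ``vib_active`` must lie inside inner ∪ active_env.  The
    vibrationally active atoms define the 3N-dimensional space of the partial
    Hessian: nominal translations/rotations of an embedded fragment are
    genuine vibrations and are never dropped.
    """

    inner: tuple[int, ...]
    active_env: tuple[int, ...] = ()
    frozen_env: tuple[int, ...] = ()
    vib_active: tuple[int, ...] = ()
    n_atoms: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "inner", tuple(sorted(self.inner)))
        object.__setattr__(self, "active_env", tuple(sorted(self.active_env)))
        object.__setattr__(self, "frozen_env", tuple(sorted(self.frozen_env)))
        vib = tuple(sorted(self.vib_active)) or self.inner
        object.__setattr__(self, "vib_active", vib)
        inner, aenv, fenv = set(self.inner), set(self.active_env), set(self.frozen_env)
        if inner & aenv or inner & fenv or aenv & fenv:
            raise ValueError("inner/active_env/frozen_env must be disjoint")
        union = inner | aenv | fenv
        if self.n_atoms is not None and union != set(range(self.n_atoms)):
            raise ValueError(
                f"regions must cover all {self.n_atoms} atoms exactly; got {sorted(union)}"
            )
        if not set(vib) <= (inner | aenv):
            raise ValueError("vib_active must be a subset of inner ∪ active_env")
        if len(vib) < 1:
            raise ValueError("vib_active must contain at least one atom")

    @property
    def environment(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.active_env) | set(self.frozen_env)))

    @classmethod
    def all_inner(cls, n_atoms: int) -> "RegionMap":
        idx = tuple(range(n_atoms))
        return cls(inner=idx, vib_active=idx, n_atoms=n_atoms)


def mass_weight(
    vector: np.ndarray,
    masses: np.ndarray,
    kind: str = "displacement",
    inverse: bool = False,
) -> np.ndarray:
    """Mass-weight a 3N Cartesian vector.

    ``kind='displacement'`` multiplies each component by √m (x → √m·x), the
    transform that takes Cartesian displacements into mass-weighted
    coordinates; ``kind='gradient'`` divides by √m, the covariant transform
    for gradients.  ``inverse=True`` undoes the respective transform.
    """
    vector = np.asarray(vector, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if vector.shape[0] != 3 * masses.shape[0]:
        raise ValueError(
            f"vector length {vector.shape[0]} does not match 3 x {masses.shape[0]} masses"
        )
    sqrt_m = np.repeat(np.sqrt(masses), 3)
    if kind == "displacement":
        factor = sqrt_m
    elif kind == "gradient":
        factor = 1.0 / sqrt_m
    else:
        raise ValueError(f"kind must be 'displacement' or 'gradient', got {kind!r}")
    if inverse:
        factor = 1.0 / factor
    return vector * factor.reshape((-1,) + (1,) * (vector.ndim - 1))


# --- XYZ I/O -----------------------------------------------------------------

def read_xyz(path: str | Path) -> Structure:
    """Read a standard XYZ file (count line, comment line, ``El x y z`` in Å).

    Coordinates are converted to Bohr; masses come from the standard atomic
    weight table.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file (line 1)")
    try:
        count = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(
            f"{path}: line 1: expected an atom count, got {lines[0]!r}"
        ) from None
    comment = lines[1] if len(lines) > 1 else ""
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != count:
        raise XYZParseError(
            f"{path}: header declares {count} atoms but {len(body)} atom lines found"
        )
    atoms = []
    for i, line in enumerate(body):
        parts = line.split()
        lineno = i + 3
        if len(parts) < 4:
            raise XYZParseError(f"{path}: line {lineno}: expected 'El x y z', got {line!r}")
        el = parts[0]
        try:
            xyz = np.array([float(p) for p in parts[1:4]])
        except ValueError:
            raise XYZParseError(
                f"{path}: line {lineno}: could not parse coordinates from {line!r}"
            ) from None
        atoms.append(Atom(element=el, mass=atomic_mass(el), position=xyz * ANGSTROM_TO_BOHR))
    return Structure(atoms, comment=comment)


def write_xyz(structure: Structure, path: str | Path) -> None:
    """Write the structure as a standard XYZ file (Å)."""
    path = Path(path)
    lines = [str(structure.n_atoms), structure.comment]
    for atom in structure.atoms:
        x, y, z = atom.position * BOHR_TO_ANGSTROM
        lines.append(f"{atom.element:<4s} {x: .12f} {y: .12f} {z: .12f}")
    path.write_text("\n".join(lines) + "\n")
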