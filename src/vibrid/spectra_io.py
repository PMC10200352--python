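"""Spectrum synthesis, standard-format writers and the task pipeline.

Stick spectra are broadened with an area-normalized Lorentzian of full width
at half maximum γ (default 20 cm⁻¹):

    I(ν) = Σ_i I_i · (1/π) · (γ/2) / ((ν − ν_i)² + (γ/2)²)

so a unit-intensity peak has height 2/(πγ) at its centre and the integrated
band area equals the stick intensity.  All writers use fixed-precision
formatting, making repeated runs byte-identical.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .calculators import Calculator, calculator_from_dict, load_calculator
from .intensities import SpectrumPeaks, compute_peaks
from .molsys import RegionMap, Structure, read_xyz
from .vibrations import (
    DerivativeBundle,
    finite_difference_sweep,
    load_bundle,
    normal_modes,
    project_to_modes,
    save_bundle,
)

__all__ = [
    "BroadenedSpectrum",
    "broaden_lorentzian",
    "write_peaks_table",
    "read_peaks_table",
    "write_spectrum_csv",
    "write_molden",
    "read_molden_frequencies",
    "run_task",
    "restart_task",
]

logger = logging.getLogger("vibrid")

_FLOAT_FMT = "{:.12e}"


@dataclass
class BroadenedSpectrum:
    """Uniform wavenumber grid (cm⁻¹) with broadened intensity and the FWHM
    bandwidth γ (cm⁻¹) used."""

    grid: np.ndarray
    intensity: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        if len(self.grid) and np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")


def lorentzian_profile(
    grid: np.ndarray,
    centers: np.ndarray,
    intensities: np.ndarray,
    fwhm: float,
) -> np.ndarray:
    """Sum of area-normalized Lorentzians on ``grid``."""
    half = fwhm / 2.0
    out = np.zeros_like(grid, dtype=float)
    for nu0, strength in zip(centers, intensities):
        out += strength * (half / np.pi) / ((grid - nu0) ** 2 + half**2)
    return out


def _resolve_grid(grid_spec) -> np.ndarray:
    if isinstance(grid_spec, dict):
        lo, hi = float(grid_spec["min"]), float(grid_spec["max"])
        n = int(grid_spec.get("points", 2001))
    else:
        lo, hi, n = float(grid_spec[0]), float(grid_spec[1]), int(grid_spec[2])
    if hi <= lo or n < 2:
        raise ValueError(f"bad grid specification {grid_spec!r}")
    return np.linspace(lo, hi, n)


def broaden_lorentzian(
    peaks: SpectrumPeaks,
    bandwidth: float = 20.0,
    grid=(0.0, 4000.0, 2001),
    quantity: str = "ir",
) -> BroadenedSpectrum:
    """Broaden one intensity column of a peak table.

    ``quantity`` selects 'ir' (km/mol), 'raman_unscaled' or 'raman_scaled'.
    Peaks with undefined (NaN) intensity are skipped.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid_arr = _resolve_grid(grid)
    column = {
        "ir": peaks.ir_km_mol,
        "raman_unscaled": peaks.raman_unscaled,
        "raman_scaled": peaks.raman_scaled,
    }.get(quantity)
    if quantity not in ("ir", "raman_unscaled", "raman_scaled"):
        raise ValueError(f"unknown quantity {quantity!r}")
    if column is None or peaks.n_modes == 0:
        warnings.warn(f"no peaks available for quantity {quantity!r}; empty spectrum")
        return BroadenedSpectrum(grid_arr, np.zeros_like(grid_arr), bandwidth)
    keep = np.isfinite(column)
    intensity = lorentzian_profile(
        grid_arr, peaks.frequencies[keep], column[keep], bandwidth
    )
    return BroadenedSpectrum(grid_arr, intensity, bandwidth)


# ---------------------------------------------------------------------------
# tabular writers
# ---------------------------------------------------------------------------

_PEAK_COLUMNS = [
    "mode",
    "frequency_cm-1",
    "ir_km_mol",
    "raman_unscaled_A4_amu",
    "raman_scaled",
]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and np.isnan(value):
        return "nan"
    return _FLOAT_FMT.format(value)


def write_peaks_table(peaks: SpectrumPeaks, path: str | Path) -> None:
    """Write the per-mode peak table as CSV with fixed precision.

    Columns without computed data are left empty; negative (imaginary)
    frequencies keep their sign.
    """
    lines = [",".join(_PEAK_COLUMNS)]
    for i in range(peaks.n_modes):
        row = [
            str(i),
            _FLOAT_FMT.format(peaks.frequencies[i]),
            _fmt(None if peaks.ir_km_mol is None else float(peaks.ir_km_mol[i])),
            _fmt(None if peaks.raman_unscaled is None else float(peaks.raman_unscaled[i])),
            _fmt(None if peaks.raman_scaled is None else float(peaks.raman_scaled[i])),
        ]
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_peaks_table(path: str | Path) -> SpectrumPeaks:
    """Read back a peak table written by :func:`write_peaks_table`."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split(",")
    if header != _PEAK_COLUMNS:
        raise ValueError(f"unexpected peak table header {header}")
    rows = [ln.split(",") for ln in lines[1:] if ln]
    freqs = np.array([float(r[1]) for r in rows]) if rows else np.zeros(0)

    def column(k: int):
        vals = [r[k] for r in rows]
        if all(v == "" for v in vals):
            return None
        return np.array([np.nan if v in ("", "nan") else float(v) for v in vals])

    return SpectrumPeaks(
        frequencies=freqs,
        ir_km_mol=column(2),
        raman_unscaled=column(3),
        raman_scaled=column(4),
    )


def write_spectrum_csv(spectrum: BroadenedSpectrum, path: str | Path) -> None:
    """Write a broadened spectrum as a two-column CSV."""
    lines = ["wavenumber_cm-1,intensity"]
    for nu, inten in zip(spectrum.grid, spectrum.intensity):
        lines.append(f"{_FLOAT_FMT.format(nu)},{_FLOAT_FMT.format(inten)}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Molden frequency file
# ---------------------------------------------------------------------------

def write_molden(
    structure: Structure,
    modeset,
    peaks: SpectrumPeaks,
    path: str | Path,
    region_map: RegionMap | None = None,
) -> None:
    """Write a Molden frequency file ([FREQ]/[FR-COORD]/[FR-NORM-COORD]/[INT]).

    Coordinates are in Bohr.  Frozen/environment atoms are included as static
    coordinates with zero displacement in every mode.
    """
    region_map = region_map or RegionMap.all_inner(structure.n_atoms)
    vib_atoms = list(region_map.vib_active)
    n_modes = modeset.n_modes
    if n_modes != 3 * len(vib_atoms):
        raise ValueError(
            f"mode count {n_modes} inconsistent with {len(vib_atoms)} active atoms"
        )
    disp = modeset.cartesian_displacements()  # (3N, modes)
    lines = ["[Molden Format]", "[FREQ]"]
    for f in modeset.frequencies:
        lines.append(f"{f:12.6f}")
    lines.append("[FR-COORD]")
    for atom in structure.atoms:
        x, y, z = atom.position
        lines.append(f"{atom.element:<4s} {x: 14.8f} {y: 14.8f} {z: 14.8f}")
    lines.append("[FR-NORM-COORD]")
    for m in range(n_modes):
        lines.append(f"vibration {m + 1:5d}")
        col = disp[:, m].reshape(-1, 3)
        for i in range(structure.n_atoms):
            if i in vib_atoms:
                dx, dy, dz = col[vib_atoms.index(i)]
            else:
                dx = dy = dz = 0.0
            lines.append(f" {dx: 14.8f} {dy: 14.8f} {dz: 14.8f}")
    lines.append("[INT]")
    inten = peaks.ir_km_mol if peaks.ir_km_mol is not None else np.zeros(n_modes)
    for v in inten:
        lines.append(f"{v:14.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_molden_frequencies(path: str | Path) -> np.ndarray:
    """Parse the [FREQ] section back out of a Molden frequency file."""
    freqs = []
    in_freq = False
    for line in Path(path).read_text().splitlines():
        tag = line.strip().lower()
        if tag.startswith("["):
            in_freq = tag == "[freq]"
            continue
        if in_freq and line.strip():
            freqs.append(float(line.strip()))
    return np.array(freqs)


# ---------------------------------------------------------------------------
# task pipeline
# ---------------------------------------------------------------------------

def _build_calculator(cfg: dict, base_dir: Path) -> Calculator:
    if "calculator_file" in cfg:
        return load_calculator(base_dir / cfg["calculator_file"])
    return calculator_from_dict(cfg["calculator"])


def _build_region_map(cfg: dict, n_atoms: int) -> RegionMap:
    region = cfg.get("region")
    if region is None:
        return RegionMap.all_inner(n_atoms)
    return RegionMap(
        inner=tuple(region.get("inner", ())),
        active_env=tuple(region.get("active_env", ())),
        frozen_env=tuple(region.get("frozen_env", ())),
        vib_active=tuple(region.get("vib_active", ())),
        n_atoms=n_atoms,
    )


def _stage(name: str):
    """Decorator-ish context: re-raise with the pipeline stage label."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_task(config: str | Path | dict, output_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline described by a YAML config.

    Stages: structure/calculator setup → finite-difference sweep → normal
    modes → intensities → broadening → writers.  Outputs (peaks table,
    broadened spectra, Molden file, restart archive, JSON run summary) are
    computed fully in memory before anything is written, so a stage failure
    leaves no partial files.  Returns a dict of output paths plus the
    in-memory results.
    """
    if isinstance(config, (str, Path)):
        base_dir = Path(config).parent
        cfg = yaml.safe_load(Path(config).read_text())
    else:
        base_dir = Path(".")
        cfg = dict(config)

    task = dict(cfg.get("task", {}))
    ir = bool(task.get("ir", True))
    raman = bool(task.get("raman", False))
    resonance = bool(task.get("resonance_raman", False))
    frequency = float(task.get("frequency", 0.0)) if resonance else 0.0
    damping = float(task.get("damping", 0.006)) if resonance else 0.0
    step = float(task.get("step", 0.01))
    workgroups = int(task.get("workgroups", 1))
    project_tr = bool(task.get("project_tr", False))
    bandwidth = float(task.get("bandwidth", 20.0))
    grid = task.get("grid", {"min": 0.0, "max": 4000.0, "points": 2001})

    with _stage("setup"):
        structure = (
            cfg["structure"]
            if isinstance(cfg.get("structure"), Structure)
            else read_xyz(base_dir / cfg["structure"])
        )
        for idx, mass in (cfg.get("masses") or {}).items():
            structure.atoms[int(idx)].mass = float(mass)
        region_map = _build_region_map(cfg, structure.n_atoms)
        calculator = _build_calculator(cfg, base_dir)
        env_cfg = cfg.get("environment")
        detail = None
        if env_cfg is not None:
            engine = (
                load_calculator(base_dir / env_cfg["engine_file"])
                if "engine_file" in env_cfg
                else calculator_from_dict(env_cfg["engine"])
            )
            options = EmbeddingOptions(
                scheme=env_cfg.get("scheme", "electrostatic"),
                shell_tolerance=float(env_cfg.get("shell_tolerance", 1e-7)),
                dipole_tolerance=float(env_cfg.get("dipole_tolerance", 1e-8)),
                max_outer_iterations=int(env_cfg.get("max_outer_iterations", 200)),
            )
            calculator = compose_additive(calculator, engine, region_map, options)
            detail = calculator.evaluate_detailed(structure)

    with _stage("finite-difference sweep"):
        bundle = finite_difference_sweep(
            calculator,
            structure,
            region_map,
            step=step,
            workgroups=workgroups,
            want_dipole=ir,
            want_polarizability=raman or resonance,
            frequency=frequency,
            damping=damping,
        )

    with _stage("normal modes"):
        modeset = normal_modes(bundle, project_tr=project_tr)
        derivs = project_to_modes(bundle, modeset)

    with _stage("intensities"):
        peaks = compute_peaks(
            modeset,
            derivs,
            ir=ir,
            raman=raman or resonance,
            resonance=resonance,
            frequency=frequency,
            damping=damping,
        )

    with _stage("broadening"):
        spectra = {}
        if ir:
            spectra["ir"] = broaden_lorentzian(peaks, bandwidth, grid, "ir")
        if raman or resonance:
            spectra["raman"] = broaden_lorentzian(peaks, bandwidth, grid, "raman_unscaled")

    outdir = Path(output_dir or cfg.get("output_dir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    with _stage("write outputs"):
        paths["peaks"] = outdir / "peaks.csv"
        write_peaks_table(peaks, paths["peaks"])
        for name, spectrum in spectra.items():
            paths[f"spectrum_{name}"] = outdir / f"spectrum_{name}.csv"
            write_spectrum_csv(spectrum, paths[f"spectrum_{name}"])
        paths["molden"] = outdir / "modes.molden"
        write_molden(structure, modeset, peaks, paths["molden"], region_map)
        paths["restart"] = outdir / "restart.json"
        save_bundle(bundle, paths["restart"])
        summary = {
            "ir": ir,
            "raman": raman,
            "resonance_raman": resonance,
            "frequency_hartree": frequency,
            "damping_hartree": damping,
            "step_bohr": step,
            "workgroups": workgroups,
            "project_tr": project_tr,
            "bandwidth_cm-1": bandwidth,
            "n_modes": int(modeset.n_modes),
            "max_hessian_asymmetry": bundle.max_asymmetry,
            "calculator_calls": calculator.n_calls,
        }
        if detail is not None:
            summary["embedding"] = {
                "scheme": calculator.options.scheme,
                "outer_iterations": detail.n_outer,
                "shell_tolerance": calculator.options.shell_tolerance,
                "dipole_tolerance": calculator.options.dipole_tolerance,
                "energy_total": detail.energy.total,
                "energy_qm": detail.energy.qm,
                "energy_mm": detail.energy.mm,
                "energy_coupling": detail.energy.coupling,
            }
        paths["summary"] = outdir / "summary.json"
        paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "bundle": bundle,
        "modeset": modeset,
        "peaks": peaks,
        "spectra": spectra,
    }


def restart_task(
    archive: str | Path,
    masses: dict | None = None,
    output_dir: str | Path = ".",
    project_tr: bool = False,
    bandwidth: float = 20.0,
    grid=(0.0, 4000.0, 2001),
) -> dict:
    """Isotope restart: reload a derivative archive, amend masses, recompute
    modes and intensities with zero new single-point calculations.

    ``masses`` maps either element symbols or active-atom indices (as int or
    str) to new masses in amu.
    """
    bundle: DerivativeBundle = load_bundle(archive)
    new_masses = bundle.masses.copy()
    for key, value in (masses or {}).items():
        if isinstance(key, str) and not key.isdigit():
            hits = [i for i, el in enumerate(bundle.elements) if el == key]
            if not hits:
                raise ValueError(f"element {key!r} not among active atoms")
            new_masses[hits] = float(value)
        else:
            new_masses[int(key)] = float(value)

    modeset = normal_modes(bundle, new_masses, project_tr=project_tr)
    derivs = project_to_modes(bundle, modeset)
    ir = bundle.dipole_derivatives is not None
    raman = bundle.polarizability_derivatives is not None
    peaks = compute_peaks(
        modeset,
        derivs,
        ir=ir,
        raman=raman,
        resonance=raman and bundle.frequency > 0,
        frequency=bundle.frequency,
        damping=bundle.damping,
    )
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"peaks": outdir / "peaks.csv"}
    write_peaks_table(peaks, paths["peaks"])
    if ir:
        paths["spectrum_ir"] = outdir / "spectrum_ir.csv"
        write_spectrum_csv(broaden_lorentzian(peaks, bandwidth, grid, "ir"), paths["spectrum_ir"])
    if raman:
        paths["spectrum_raman"] = outdir / "spectrum_raman.csv"
        write_spectrum_csv(
            broaden_lorentzian(peaks, bandwidth, grid, "raman_unscaled"),
            paths["spectrum_raman"],
        )
    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "modeset": modeset,
        "peaks": peaks,
    }
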