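# Methods

This note documents the models, numerical procedures, defaults and design
choices behind `vibrid`, and what the bundled analytic fixtures do and do not
establish about real embedded systems.

## Energy model and embedding

The total energy of an embedded system is additive,
`E_total = E_QM + E_MM + E_QM–MM`, and the decomposition is constructed so the
identity holds to machine precision: `E_QM` is the inner region evaluated in
isolation, `E_QM–MM` is the change of the inner energy when the environment's
charge sites are present as external point charges, and `E_MM` is the
environment engine's energy with the cross Coulomb term (computed once by
direct summation between the two regions' charge sites) subtracted, so no
interaction is counted twice.

*Electrostatic embedding.*  The environment is a set of fixed point charges;
the inner calculator sees them as external charges and returns gradients on
them (`ext_charge_gradients`), which is the back-coupling force channel onto
environment atoms.

*Polarizable embedding.*  Environment atoms carry core–shell pairs: a
massless shell of charge `q_s` bound to its core by a spring `k`
(Hartree/Bohr²), isolated-ion polarizability `q_s²/k` Bohr³.  Mutual
polarization alternates (i) relaxation of the environment shells in the field
of the inner region's effective point charges and (ii) re-evaluation of the
inner region in the field of cores + relaxed shells, until the inner dipole
changes by less than `dipole_tolerance` (default 1e-8 e·Bohr) between outer
cycles, capped at `max_outer_iterations` (default 200, with the dipole
residual trace reported on failure).  The inner region is represented to the
shells by its point charges — a deliberate model-level simplification of a
self-consistent charge density.  Convergence is measured on the inner dipole
because it is the quantity the spectroscopic derivatives consume.  Re-running
from a converged state (shell positions stored on the atoms) converges in one
outer iteration.

*Shell relaxation.*  Shells are relaxed by damped fixed-point iteration
`s ← x + F_non-spring(s)/k` until the largest per-cycle displacement is below
`shell_tolerance` (default 1e-7 Bohr at the embedding level; equivalently a
residual shell force below `k·tol`).  For a quadratic environment energy this
converges geometrically to the unique minimum; one solver covers the
quadratic and anharmonic (Buckingham) cases alike, which keeps the rigid and
relaxed code paths identical.  Gradients on cores are evaluated at the relaxed
shells; since the shells minimize the energy, this is exact for the relaxed
surface (envelope theorem).  Shell-engine polarizability is defined
operationally as the finite-field dipole response after shell relaxation
(central differences, default field step 1e-3 a.u.).

*Composite properties.*  The composite dipole is the inner (self-consistent)
dipole plus Σ z_i R_i over environment charge sites, so IR intensities include
the environment's dielectric response.  The composite polarizability is the
inner-region tensor; the environment's electronic response enters the Raman
derivatives adiabatically, through the re-relaxation of the self-consistent
state at every displaced geometry, not as an additive environment tensor.

## Derivatives, modes, intensities

*Finite differences.*  The partial Hessian and the dipole/polarizability
derivatives are two-point central differences over the 3N Cartesian
coordinates of the vibrationally active atoms (default step 0.01 Bohr,
configurable).  Displacements are applied in plain Cartesian coordinates and
mass weighting is applied analytically afterwards, so one stored sweep serves
isotope restarts; a mass-weighted displacement store would forbid them.  The
raw Hessian is kept beside its symmetrized (H+Hᵀ)/2 copy; the maximum
asymmetry is recorded and an error is raised above 1e-4 Hartree/Bohr²
(inconsistent calculator gradients).  The embedding scheme — including shell
relaxation and mutual polarization — runs at every displaced geometry.

*Task farming.*  The 6N single points are distributed round-robin over M work
groups executed concurrently; results are keyed by coordinate index and
aggregated in a fixed order, so the assembled `DerivativeBundle` and all
downstream files are byte-identical for any M.  A failed single point aborts
the sweep with the displacement label (atom, axis, sign, step).

*Normal modes.*  Eigendecomposition of the mass-weighted Hessian; eigenvalue
λ (Hartree/(Bohr²·amu)) maps to sign(λ)·√|λ| in cm⁻¹ via a conversion
constant derived from CODATA values at import time (as are all unit
conversions — Bohr↔Å, the km/mol IR factor, ħ/(2ω)).  Frequencies are sorted
ascending with negatives (imaginary modes) first.  Mode signs are fixed by
making the largest-magnitude component positive, ties broken by lowest index,
so spectra files are reproducible.  All 3N modes are always kept; 1 cm⁻¹ is a
reporting threshold for "numerically zero", never a dropping criterion.  With
`project_tr=true` rigid translations/rotations (5 for linear arrangements, 6
otherwise, detected by singular-value rank of the TR basis) are projected out
before diagonalization — appropriate for free molecules only; the default
`false` matches embedded fragments, whose nominal TR motions are genuine
vibrations.

*Projection and intensities.*  Cartesian property derivatives are chain-ruled
onto modes, ∂μ/∂Q_i = Σ_k (∂μ/∂x_k)(1/√m_k)L_ki (likewise ∂α/∂Q_i).  IR:
raw |∂μ/∂Q|² in e²/amu and km/mol via the conventional double-harmonic
constant; the absolute radiation/set-up prefactor of the absorption rate is
deliberately folded into that constant — relative intensities are the
contract.  Raman: S = 45ᾱ′² + 7β′² from the invariants of ∂α/∂Q, reported
unscaled (Å⁴/amu) and scaled by |⟨0|Q|1⟩|² = ħ/(2ω) in amu·Å² (scaled values
therefore carry Å⁶; modes with non-positive frequency get NaN scaled
activity since the matrix element diverges).  For complex tensors (resonance)
every squared term in the invariants is a squared modulus — the natural
extension of the static formulas to a damped response; this interpretation is
a documented choice.  Depolarization ratios are not computed.

*Resonance Raman.*  The bundled frequency dependence is a damped Lorentzian,
α(ω) = α_static·ω_e²/(ω_e² − ω² − iΓω), an artifact stand-in for a TDDFT
response function: exact at ω = 0, modulus enhancement ω_e/Γ on resonance.
Γ defaults to 0.006 a.u., the conventional empirical damping.

## Broadening and outputs

Stick spectra are broadened with an *area-normalized* Lorentzian
(I(ν) = Σ I_i(γ/2π)/((ν−ν_i)² + (γ/2)²); height 2I/(πγ) at the centre) —
normalization is a documented convention, tested via the closed-form height
and the quadrature sum rule.  Default FWHM 20 cm⁻¹, per-run configurable
(10 cm⁻¹ is typical for congested resonance-Raman regions).  Writers use
fixed-precision formatting, so repeated runs are byte-identical.  Outputs:
peaks CSV (mode, frequency, IR km/mol, Raman unscaled/scaled), spectrum CSVs,
a Molden frequency file ([FREQ]/[FR-COORD]/[FR-NORM-COORD]/[INT], Bohr,
frozen atoms included with zero displacements), a versioned JSON restart
archive, and a JSON run summary (tolerances, iteration counts, step,
bandwidth, flags).  The pipeline computes everything in memory before writing,
so a stage failure (re-raised with its stage label) leaves no partial files.

### Config schema (YAML)

```yaml
structure: mol.xyz                # Å; count + comment + "El x y z"
calculator: {type: morse_diatomic, D: 0.17, a: 1.0, r0: 1.4, q0: 0.5, q1: 0.1,
             p0: 2.0, p1: 0.5, s0: 1.0, s1: 0.2, omega_e: 0.25}
# or calculator_file: params.yml  (same flat key-value schema)
environment:                      # optional; enables embedding
  engine: {type: shell_ionic,
           species: {O: {core_charge: -2.0, shell_charge: 0.8, spring: 2.0}},
           buckingham: {O-O: [100.0, 0.5, 10.0]}}
  scheme: polarizable             # or electrostatic
  shell_tolerance: 1.0e-7         # Bohr
  dipole_tolerance: 1.0e-8        # e·Bohr
region: {inner: [0, 1], frozen_env: [2], vib_active: [0, 1]}
masses: {0: 2.014}                # per-atom overrides, amu (isotopes)
task: {ir: true, raman: true, resonance_raman: false,
       frequency: 0.0, damping: 0.006,        # Hartree
       step: 0.01, workgroups: 4, project_tr: false,
       bandwidth: 20.0, grid: {min: 0.0, max: 4000.0, points: 2001}}
output_dir: out
```

Calculator types: `morse_diatomic` (Morse bond, charge flux
q(r) = q0 + q1·(r−r0) with dipole q(r)·r·r̂, axial bond polarizability
α_∥/α_⊥ linear in r, optional ω_e resonance), `harmonic_triatomic`
(centrosymmetric linear A–B–A: harmonic bonds, k_θ(1+cos θ) bend smooth
through linearity, fixed charges, per-bond polarizability), `shell_ionic`
(core–shell Coulomb + Buckingham engine; per-element species table, explicit
`Atom.charge`/`Atom.shell` entries override it).  Model point charges exist
for dipoles and embedding coupling; their internal interaction is considered
folded into the model force constants.

## What the fixtures do and do not establish

The analytic models make every stage falsifiable against closed forms:
√(k/μ) frequencies, q²/μ IR intensities, hand-evaluated Raman invariants,
q_s²/k polarizabilities, (ω_e/Γ)² resonance enhancement, exact selection
rules on the centrosymmetric fixture, and a brute-force minimizer for the
mutual-polarization fixed point.  They share the symmetries and the additive
structure of real QM/MM systems, but not their scale or their physics beyond
that: no self-consistent electron density (inner charges respond to geometry,
not to the environment field, except for shell-model inner regions), no link
atoms or covalent boundary cuts, finite clusters only (no Ewald periodicity),
harmonic PES only.  Passing tests therefore validate the spectroscopy
machinery — derivatives, modes, intensities, embedding bookkeeping,
determinism, restarts — not any electronic-structure accuracy.

## Numerical choices and limitations

- Internal units Hartree/Bohr/amu/e; I/O in Å and cm⁻¹; all conversion
  constants derived from CODATA at import time and pinned in tests against
  independently known values.
- Central differences are second order: observed error ratios ≈4 on step
  halving (asserted in tests).  Rotational invariance of frequencies and
  intensities is exact for the models and is verified at a small step
  (3e-5 Bohr) where the orientation-dependent O(h²) truncation term is
  negligible.
- Degenerate eigenpairs (e.g. bends of a linear molecule) are individually
  basis-dependent; invariant comparisons use sums over degenerate subspaces.
- The fixed-point shell relaxer assumes spring-dominated coupling; for
  pathologically soft springs next to strong fields it can diverge and then
  reports the worst residual rather than a silent wrong answer.
- Anharmonicity (overtones, VSCF), Boltzmann/temperature factors, absolute
  Raman cross sections and Gaussian/Voigt lineshapes are out of scope.
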