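# aggrex

Geometry, exciton, and embedded-cluster tools for studying excited states
of molecular aggregates and crystals.

Photochemistry in molecular crystals is local — an excitation lives on one
molecule or a handful of neighbors — but it is shaped by the aggregate:
packing constrains the nuclear relaxation, neighboring molecules mix with
the excitation to form Frenkel or charge-transfer excitons, and the
long-range Coulomb field of the lattice shifts the excited-state energetics.
`aggrex` provides the scaffolding to study all three effects from nothing
more than a unit cell geometry, lattice vectors, and the output of whatever
quantum-chemistry program the user prefers, exchanged through neutral
JSON/text files and an abstract calculator contract.

## What it computes

**Geometry.** From a unit cell: supercells, reconstruction of molecules
split by periodic boundaries, and spherical clusters of whole molecules.
Packing tightness is quantified by grid-based Voronoi volumes under a
vdW-scaled metric (a point belongs to the molecule of its "nearest" atom,
nearness measured as |p − r_a| / r_vdW(a)), summarized by the volumetric
index Vi = V_V / V_vdW.  Dimers are enumerated, deduplicated by their
sorted intermolecular-distance fingerprint (RMSD < 1e−4 Å by default), and
characterized by principal-axes angles (α, β, γ) and the slip angle.

**Excitons.** Mulliken fragment densities ρ_A(k) = Σ_{μ∈A,ν} c_μk c_νk S_μν
feed the classification indices

    ΣP_A = Σ_{i→j} σ_ij C²(ρ_A(j) + ρ_A(i)) ∈ [0, 2] e⁻
    ΔP_A = Σ_{i→j} σ_ij C²(ρ_A(j) − ρ_A(i)) ∈ [−1, 1] e⁻

which separate LOC(A)/LOC(B) Frenkel excitons, CT(A→B)/CT(B→A) states, and
DELOC excitations (0.5 e⁻ threshold).  Exciton couplings J are available via
the Kasha point-dipole approximation, atomic transition charges, the
half-gap of a resonant dimer, and N-state diabatization: from adiabatic
energies and state properties (TDMs or ATCs) against isolated-monomer
references, the SVD-optimal orthogonal map C = (UVᵀ)ᵀ builds
H_D = C diag(E) Cᵀ whose off-diagonals are the couplings.

**Embedded clusters.** Subtractive ONIOM QM:QM′,

    E(1∪2) = E_high^EE(1) + E_low(1∪2) − E_low^EE(1),

with electrostatic embedding from Region-2 charges (OEC), from a finite
point-charge array fitted to the Ewald lattice potential under exact
zero-charge and zero-dipole constraints (OEEC), or from self-consistently
equilibrated charges (SC-OEEC, ground or excited state).  BFGS minimization
on ground/excited surfaces and minimal-energy conical intersection search
by the gap-penalty function F = Ē + σΔE²/(ΔE + α) complete the toolkit.

## Worked example

```
$ python examples/ewald_fit.py
Ewald potential at a cation site: -1.747565 a.u. (the rocksalt Madelung constant, -1.747565)
fitted array: 1000 charges, total +3.55e-15 e, |dipole| 5.62e-15
worst potential residual at the 8 inner sites: 1.04e-14 a.u.
```

The Ewald sum on an 8-site rocksalt cell with unit nearest-neighbor spacing
reproduces the Madelung constant −1.747565; the fitted 1000-charge array is
strictly neutral and dipole-free yet matches the infinite lattice's
potential at the central sites to machine precision — exactly the property
an embedded-cluster calculation needs.

```
$ python examples/meci_search.py
MECI located at (u, v) = (-0.00000, -0.00000) Bohr
mean energy 0.000000 Hartree, S1-S0 gap 9.34e-07 Hartree
18 energy evaluations
```

On the analytic two-state conical model the penalty optimizer walks from
(0.8, 0.5) Bohr to the true intersection at the origin and closes the gap
below 10⁻⁶ Hartree without nonadiabatic coupling vectors.

The other scripts under `examples/` show cluster generation, packing
volumes, dimer surveys, exciton classification, and the four coupling
schemes, each printing the quantities it computes.  A `aggrex` command-line
tool wraps the same library for shell use (`aggrex uc-tools`,
`aggrex dimer-tools`, `aggrex volumetrics`, `aggrex exciton-classification`,
`aggrex coupling`, `aggrex assign-charges`, `aggrex prep`, `aggrex run`,
`aggrex fixtures`).

## Scope

External program adapters (Gaussian/Molcas/Turbomole/DFTB+ drivers and
binary checkpoint parsing) are intentionally out of scope: quantum
calculations enter through the JSON exchange files and the calculator
contract.  CIF parsing, space-group expansion, RESP charge generation,
exact transition-density Coulomb couplings, and polarizable-continuum
corrections are likewise not provided.
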