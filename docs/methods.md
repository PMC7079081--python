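# Methods

This note documents the models implemented in `aggrex`, the defaults and
numerical choices behind them, what the synthetic fixtures do and do not
emulate, and the package's known limitations.

## Geometry containers and bonding

All in-memory coordinates are Angstrom; charges are elementary charges;
electrostatics and couplings are Hartree atomic units, converted at the
boundaries (1 Bohr = 0.529177210903 Å, 1 Hartree = 27.211386 eV).  Cube
files are written in Bohr per the format convention.

Two atoms are bonded when a distance falls below a threshold.  Three modes
exist: nucleus–nucleus (`center`), distance minus both covalent radii
(`covalent`), and the analogue with vdW radii (`vdw`).  The default is
covalent-edge with a 0.4 Å slack, with radii from embedded Cordero
(covalent) and Bondi/Alvarez (vdW) tables; the slack value is a package
default chosen so standard organic bond lengths register while
next-nearest contacts do not.  Molecules are the connected components of
the bond graph (scipy csgraph).

Molecule completion across periodic boundaries grows each molecule
breadth-first from a seed atom, shifting each newly attached atom by the
lattice vector that minimizes the bond image; a reconstructed bond longer
than half the shortest cell height aborts with an ambiguity error, since
the minimum image is then not unique in any meaningful sense.  Completed
molecules are folded so their fractional centroid lies in [0, 1).

Cluster extraction includes a molecule when *any* atom falls within the
requested radius of the origin and then keeps the molecule whole — the
standard embedded-cluster convention, since truncating molecules at the
sphere would create dangling bonds.  A `strict_all_atoms` flag implements
the literal all-atoms-inside reading.  Duplicate periodic images are
removed at a 1e−6 Å per-atom tolerance.

## Voronoi volumes

Volumes are measured by voxel counting on a rectangular grid covering the
cluster plus its largest vdW radius plus 2 Å padding, at 0.2 Å default
spacing.  A voxel belongs to the atom minimizing |p − r_a| / r_vdW(a); the
division by the vdW radius is the natural scale-free choice that hands
oxygen more space than hydrogen.  Ties go to the lowest atom index, making
the assignment deterministic; bare point charges (empty element) never own
voxels.  Because every molecule of a cluster is measured on the same grid,
per-molecule Voronoi volumes partition the grid volume exactly — a voxel
accounting identity the tests assert literally.  The Voronoi cell of a
molecule on the cluster surface is box-truncated; results carry an
`interior` flag (false when the molecule's region touches the grid
boundary).  Expected discretization error is one voxel layer over the
dividing surface: ~1% for a single vdW sphere at 0.2 Å spacing, confirmed
against the analytic sphere and two-sphere lens formulas.

## Dimer analysis

The dimer fingerprint is the sorted vector of all intermolecular atom-pair
distances — invariant under rigid motions and reflections — and two dimers
are equivalent when fingerprints of equal length agree to RMSD < 1e−4 Å.
Deduplication is a greedy first-representative pass; for crystal-derived
clusters the RMSD gap between equivalent and inequivalent pairs is many
orders of magnitude, so the result is order-independent in practice (and
tested against an all-pairs transitive-closure oracle).

Principal axes: atoms (minus any ignored elements) are centered and the
smallest right singular vector of the coordinate matrix taken as the plane
normal; atoms are projected onto that plane.  The two longest projected
interatomic segments form a quadrilateral ABCD with AC the longest diagonal
and the A/B/C/D labeling chosen so AB is the longest side (ties broken by
lexicographic atom index, keeping the axes deterministic).  The principal
axis runs between the midpoints of DA and BC, the secondary between those
of CD and AB.  The two are made exactly perpendicular by symmetric
orthogonalization — both rotated by equal and opposite half-angles within
their common plane, implemented through the bisector frame — and the
tertiary axis is their cross product, giving a right-handed orthonormal
triad.  When one atom belongs to both longest segments, B and C coincide;
the degenerate quadrilateral still yields valid midpoints.  A long-axis
mode instead takes the single longest distance as the principal axis with
the in-plane perpendicular as secondary.

Inter-axis angles α, β, γ are reported unsigned in [0, 180°] (not folded to
[0, 90°], so antiparallel arrangements remain distinguishable).  The slip
angle is the smallest acute angle between the centroid–centroid axis and
either monomer's tertiary axis: 0° for cofacial stacking, 90° for a fully
slipped pair.  Archetype labels use documented heuristic thresholds —
face-to-face when the planes are near-parallel (γ folded below 30°) with
slip < 30°, parallel-displaced for the same γ with larger slip,
edge-to-face for γ within 60–120°, otherwise "other" — all configurable,
since no universal boundaries exist.

## Exciton indices and couplings

Mulliken fragment densities require each MO normalized against the AO
overlap (checked at 1e−8).  The excitation amplitudes must satisfy
Σ σ_ij C² = 1 with σ_ij = +1 for excitations (i < j) and −1 for
de-excitations; because quantum-chemistry programs differ in closed-shell
amplitude conventions, a `renormalize` flag rescales instead of raising
(tolerance 1e−6).  Within these preconditions the bounds 0 ≤ ΣP ≤ 2 and
−1 ≤ ΔP ≤ 1 are convexity consequences and are swept stochastically in the
tests.  Classification tests charge-transfer conditions before localization
ones; with the default 0.5 e⁻ threshold the regions are mutually exclusive
except at pathological corners, where CT wins.

Couplings: the point-dipole interaction is evaluated with scalar products,
J = (μ_i·μ_j)/R³ − 3(μ_i·R)(R·μ_j)/R⁵ — the standard Kasha form.  The
atomic-transition-charge coupling is the bare Coulomb double sum over the
two monomers' atoms (positions converted to Bohr); in the far field it
reproduces the point-dipole result, a multipole-limit identity the tests
verify quantitatively.  The half-gap estimate |J| = (E₂ − E₁)/2 is exposed
as a pure function of two energies; it is exact only for monomers in
perfect resonance, and no attempt is made to restrict where the energies
come from.  Diabatization uses real orthogonal algebra throughout (state
properties are real, so conjugations become transposes): the property
overlap M between adiabatic and isolated-monomer reference properties is
decomposed as M = UΣVᵀ and C = (UVᵀ)ᵀ is the orthogonal Procrustes
solution mapping adiabatic to diabatic states; H_D = C diag(E) Cᵀ.  The
construction is invariant to global sign flips of any property (phases are
absorbed by the SVD) and fails loudly when M is rank-deficient, which
signals a property unable to distinguish the states.  Any N ≥ 2 is
supported, e.g. trimer Hamiltonians whose three off-diagonals are the
pairwise couplings in the presence of the third monomer.

## Ewald embedding

The lattice potential is split into a real-space erfc sum and a reciprocal
sum over G ≠ 0; for a neutral cell the result is independent of the
screening constant γ.  Defaults: γ = 5.6/h_min (h_min the shortest cell
height in Bohr), real-space cutoff h_min — erfc(5.6) ≈ 2e−15, so one cell
of images suffices — and a reciprocal cutoff where the Gaussian factor
reaches 1e−4 × the 1e−6 a.u. target accuracy.  At an atomic site the
divergent self term is replaced by −2γq_i/√π.  The implementation recovers
the rocksalt and CsCl Madelung constants to better than 1e−5 against
shell-summed direct oracles, and γ-invariance holds to 1e−6.

Charge fitting distributes point charges on the atomic sites of a centered
supercell sized to cover roughly the requested count.  Charges within the
fixed zone — a sphere of the inner region's bounding radius + 2 Å by
default — keep their nominal values; the rest solve a linear least-squares
problem matching the Ewald potential at the inner region's atomic sites,
with Σq = 0 and Σ q·r = 0 imposed exactly via a KKT system solved by
`lstsq` (rank-robust).  Fractional charges are allowed throughout.  With
more free charges than check sites the fit is exact to machine precision on
the toys; the meaningful guarantees, asserted in tests, are constraint
satisfaction and that the fit never worsens the worst residual.

Bond-order matrices are all-pairs shortest paths in bonds on the detected
bond graph (BFS via scipy); this is the unique fixed point of iteratively
extending first-neighbor connections through shared atoms.  An atom's
identity is its element plus the multiset of (element, bond distance)
pairs over its molecule; charges are redistributed onto a target by
averaging reference charges over equal identities, which conserves
per-molecule totals by construction.  Identity matching is exact, so the
reference must contain every target atom's connectivity environment.

The self-consistent loop alternates embedding construction, population
analysis at the requested state, fingerprint redistribution into the cell,
and refitting, with linear mixing (default 1.0, i.e. undamped) and a
1e−4 e per-atom convergence tolerance — both package defaults, exposed as
parameters.  Iterations count population analyses; non-convergence raises
an error carrying the full charge-change trace.  The default embedding
builder is the Ewald fit; a pluggable builder supports cheap models.

## ONIOM and surface optimization

The subtractive energy and gradient are composed literally; with
electrostatic embedding the point-charge array enters only the two
Region-1 terms (for a fixed Region 2 it would add a constant to the
full-system term).  Low-level terms are evaluated in the ground state;
excited states live in the high-level Region-1 term.  Regions must be
disjoint sets of whole molecules — no link atoms are supported, and
crossing covalent bonds is the user's error to avoid.  With identical
high/low calculators and embeddings the composition collapses to the
full-system energy at machine precision, which the tests assert, and all
gradients are validated by central finite differences at 1e−6.

Optimization is BFGS (scipy) over Region-1 coordinates only, converged
when every gradient component is below 3e−4 Hartree/Bohr.  State ordering
at each geometry is by energy with no diabatic tracking — adequate for
minima away from crossings, and irrelevant for the penalty-function MECI
search, which minimizes F = Ē + σΔE²/(ΔE + α).  F is C¹ through the
intersection seam (ΔE² smooths the |ΔE| cusp), so BFGS applies.  Defaults
σ = 3.5 and α = 0.02 Hartree follow common penalty-method practice; σ is
fixed during a search, with an optional stepping schedule (×2 per pass)
when the gap stagnates above tolerance.  Success additionally requires the
final gap below `gap_tol` (1e−3 Hartree default).

## Synthetic fixtures: what they do and do not show

The toy crystals (rocksalt, CsCl, a tilted-diatomic herringbone cell, a
planar quadrilateral molecule) provide exact analytic targets: Madelung
constants, symmetry-related dimer populations, known axes.  The random
wavefunction generator uses an identity AO overlap and orthogonal MO
coefficients by default so every Mulliken quantity is hand-checkable;
non-orthogonal overlaps are exercised separately in unit tests.  Mock
calculators (harmonic wells with Coulomb embedding response, a quartic
double well, a two-state linear vibronic cone) are pure and carry exact
analytic gradients.

Passing tests on these fixtures demonstrates the correctness of the
geometry algebra, the index and coupling formulas, the Ewald and fitting
machinery, and the optimization logic.  They do not demonstrate chemical
accuracy on real crystals: real wavefunctions have non-orthogonal AO bases
and thousands of amplitudes, real monomers are not rigid diatomics, and
real excited-state surfaces are not harmonic.  Quantities that depend on
external electronic-structure input (absolute coupling magnitudes for a
given crystal, MECI energetics of a real chromophore) are exactly as good
as the calculator supplied.

Problem sizes used by the test suite and the acceptance script — 8-site
cells, ~1000-charge arrays, 10³–10⁴ wavefunction samples, 0.2–0.3 Å grids —
were chosen as the smallest sizes at which every analytic target is met at
its stated tolerance.

## Known limitations

- No link atoms: ONIOM regions must be whole molecules.
- Minimum-image completion fails (by design, loudly) for molecules longer
  than half the cell.
- Grid-based volumes carry O(one voxel layer) discretization error and
  box-truncation for surface molecules; no exact tessellation is provided.
- The half-gap coupling is biased off resonance; diabatization requires a
  property that actually distinguishes the states.
- Charge fitting assumes the inner region sits near the array center; a
  strongly off-center region degrades the fixed/fitted zone split.
- The SC loop with undamped mixing can oscillate for strongly responsive
  populations; the `mixing` parameter is the remedy.
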