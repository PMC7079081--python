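"""Deterministic synthetic inputs: toy crystals, wavefunctions, mock PESs.

Every other part of the package operates on crystal structures,
excited-state wavefunction data, or an external quantum calculator.  This
module generates all three synthetically so the whole toolkit runs with no
external data or programs: ionic toy cells with known Madelung constants,
a herringbone diatomic crystal for dimer statistics, random normalized
single-excitation wavefunctions for the exciton indices, and analytic
model potential-energy surfaces (quadratic bowls, double wells, a
two-state linear vibronic cone) wrapped in the calculator contract with
exact gradients.

All generators are seed-deterministic and all mock calculators are pure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ANGSTROM_IN_BOHR
from .exciton import WavefunctionData
from .oniom_optim import CalcResult, Calculator
from .structures import AtomSite, BondingScheme, Structure

__all__ = [
    "ToyCrystalSpec",
    "MockPES",
    "make_toy_crystal",
    "make_methanol",
    "make_water",
    "random_cis_wavefunction",
    "make_mock_calculator",
    "QuadraticCalculator",
    "DoubleWellCalculator",
    "TwoStateConicalCalculator",
    "FixedPopulationCalculator",
    "LinearPopulationCalculator",
]


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass
class ToyCrystalSpec:
    """Recipe for a synthetic unit cell.

    Motifs: ``rocksalt`` (8-site conventional NaCl cell, charges +-q),
    ``cscl`` (2-site cell), ``herringbone-diatomic`` (two symmetry-related
    tilted diatomic molecules per cell), ``planar-quad`` (one rectangular
    4-atom molecule in a roomy cell).  ``jitter`` adds seeded Gaussian noise
    to the positions (Angstrom).
    """

    motif: str = "rocksalt"
    a: float = 4.0
    b: float | None = None
    c: float | None = None
    charge: float = 1.0
    tilt_deg: float = 30.0
    bond_length: float = 1.1
    jitter: float = 0.0
    seed: int = 0


def make_toy_crystal(spec: ToyCrystalSpec) -> Structure:
    """Build the unit cell described by the recipe (charge-neutral throughout)."""
    a = spec.a
    b = spec.b if spec.b is not None else a
    c = spec.c if spec.c is not None else a
    if min(a, b, c) <= 0:
        raise ValueError("lattice constants must be positive")
    lattice = np.diag([a, b, c])
    if spec.motif == "rocksalt":
        cat = [(0, 0, 0), (0, .5, .5), (.5, 0, .5), (.5, .5, 0)]
        ani = [(.5, 0, 0), (0, .5, 0), (0, 0, .5), (.5, .5, .5)]
        atoms = [AtomSite("Na", np.array(f) @ lattice, spec.charge) for f in cat]
        atoms += [AtomSite("Cl", np.array(f) @ lattice, -spec.charge) for f in ani]
        bonding = BondingScheme("center", 0.1)
    elif spec.motif == "cscl":
        atoms = [AtomSite("Cs", np.zeros(3), spec.charge),
                 AtomSite("Cl", np.array([.5, .5, .5]) @ lattice, -spec.charge)]
        bonding = BondingScheme("center", 0.1)
    elif spec.motif == "herringbone-diatomic":
        half = spec.bond_length / 2.0
        out_atoms = []
        for center_frac, sign in (((0.25, 0.25, 0.5), 1.0), ((0.75, 0.75, 0.5), -1.0)):
            theta = np.radians(sign * spec.tilt_deg)
            axis = np.array([np.cos(theta), np.sin(theta), 0.0])
            center = np.array(center_frac) @ lattice
            out_atoms.append(AtomSite("N", center + half * axis))
            out_atoms.append(AtomSite("N", center - half * axis))
        atoms = out_atoms
        bonding = BondingScheme("covalent", 0.4)
    elif spec.motif == "planar-quad":
        # connected rectangular molecule, 1.8 x 1.4 A C4 ring analogue
        center = np.array([a, b, c]) / 2.0
        corners = np.array([[-0.9, -0.7, 0], [0.9, -0.7, 0],
                            [0.9, 0.7, 0], [-0.9, 0.7, 0]])
        atoms = [AtomSite("C", center + p) for p in corners]
        bonding = BondingScheme("covalent", 0.4)
    else:
        raise ValueError(f"unknown toy crystal motif {spec.motif!r}")
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        for at in atoms:
            at.position = at.position + rng.normal(0.0, spec.jitter, 3)
    return Structure(atoms, lattice, bonding, comment=f"toy {spec.motif}")


def make_methanol() -> Structure:
    """A methanol molecule at a standard gas-phase-like geometry."""
    coords = [
        ("C", (-0.046, 0.662, 0.000)),
        ("O", (-0.046, -0.758, 0.000)),
        ("H", (-1.086, 0.976, 0.000)),
        ("H", (0.437, 1.072, 0.890)),
        ("H", (0.437, 1.072, -0.890)),
        ("H", (0.860, -1.055, 0.000)),
    ]
    return Structure([AtomSite(e, p) for e, p in coords], comment="methanol")


def make_water() -> Structure:
    coords = [
        ("O", (0.000, 0.000, 0.117)),
        ("H", (0.000, 0.757, -0.469)),
        ("H", (0.000, -0.757, -0.469)),
    ]
    return Structure([AtomSite(e, p) for e, p in coords], comment="water")


# ---------------------------------------------------------------------------
# Wavefunctions
# ---------------------------------------------------------------------------

def random_cis_wavefunction(n_occ_A: int, n_vir_A: int, n_occ_B: int,
                            n_vir_B: int, seed: int = 0,
                            localized: bool = False,
                            single_excitation: tuple | None = None
                            ) -> WavefunctionData:
    """A random normalized single-excitation wavefunction on two fragments.

    The AO overlap is the identity and the MO coefficients form a random
    orthogonal matrix, so every MO is normalized.  MO columns are ordered
    [A-occupied, B-occupied, A-virtual, B-virtual]; with ``localized=True``
    the orthogonal mixing is block-diagonal per fragment, so each MO lives
    entirely on one fragment.  One excited state is generated with random
    amplitudes over all occupied -> virtual pairs, normalized to
    sum sigma C^2 = 1; ``single_excitation=(i, j)`` instead puts all weight
    on one pair.
    """
    for n in (n_occ_A, n_vir_A, n_occ_B, n_vir_B):
        if n <= 0:
            raise ValueError("orbital counts must be positive")
    rng = np.random.default_rng(seed)
    n_a = n_occ_A + n_vir_A
    n_b = n_occ_B + n_vir_B
    n = n_a + n_b
    n_occ = n_occ_A + n_occ_B

    def ortho(k, r):
        q, _ = np.linalg.qr(r.normal(size=(k, k)))
        return q

    if localized:
        qa = ortho(n_a, rng)
        qb = ortho(n_b, rng)
        coeff = np.zeros((n, n))
        # rows: A AOs then B AOs; columns ordered occ-A, occ-B, vir-A, vir-B
        coeff[:n_a, :n_occ_A] = qa[:, :n_occ_A]
        coeff[n_a:, n_occ_A:n_occ] = qb[:, :n_occ_B]
        coeff[:n_a, n_occ:n_occ + n_vir_A] = qa[:, n_occ_A:]
        coeff[n_a:, n_occ + n_vir_A:] = qb[:, n_occ_B:]
    else:
        coeff = ortho(n, rng)
    fragment_of_ao = np.array(["A"] * n_a + ["B"] * n_b)

    if single_excitation is not None:
        i, j = single_excitation
        amps = [(int(i), int(j), 1.0)]
    else:
        pairs = [(i, j) for i in range(n_occ) for j in range(n_occ, n)]
        w = rng.normal(size=len(pairs))
        w /= np.linalg.norm(w)
        amps = [(i, j, float(c)) for (i, j), c in zip(pairs, w)]
    return WavefunctionData(coeff, np.eye(n), fragment_of_ao, [amps], n_occ)


# ---------------------------------------------------------------------------
# Mock calculators
# ---------------------------------------------------------------------------

def _coulomb_with_embedding(geometry: Structure, embedding, atom_charges):
    """Interaction energy/gradient of fixed atomic charges with embedding charges."""
    n = len(geometry)
    if embedding is None or atom_charges is None or len(embedding) == 0:
        return 0.0, np.zeros((n, 3))
    r_a = geometry.positions * ANGSTROM_IN_BOHR
    r_p = embedding.positions * ANGSTROM_IN_BOHR
    qa = np.asarray(atom_charges, dtype=float)[:n]
    qp = embedding.charges
    diff = r_a[:, None, :] - r_p[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    if dist.min() < 1e-10:
        raise ValueError("embedding charge coincides with an atom")
    energy = float(np.sum(np.outer(qa, qp) / dist))
    grad = -(qa[:, None, None] * qp[None, :, None] * diff
             / dist[:, :, None] ** 3).sum(axis=1)
    return energy, grad


class QuadraticCalculator(Calculator):
    """Isotropic harmonic bowl around reference positions.

    E = 1/2 k sum_a |r_a - c_a|^2 (coordinates in Bohr) + optional Coulomb
    interaction of fixed per-atom charges with the embedding array.  The
    per-atom charges double as the population analysis.
    """

    def __init__(self, centers, k: float = 1.0, e0: float = 0.0,
                 atom_charges=None):
        self.centers = np.asarray(centers, dtype=float).reshape(-1, 3)
        self.k = float(k)
        self.e0 = float(e0)
        self.atom_charges = (None if atom_charges is None
                             else np.asarray(atom_charges, dtype=float))
        caps = {"energy", "gradient"}
        if atom_charges is not None:
            caps.add("population")
        self.capabilities = frozenset(caps)

    def evaluate(self, geometry, embedding, state=0):
        if state > 0:
            raise ValueError("quadratic mock has no excited states")
        n = len(geometry)
        disp = (geometry.positions - self.centers[:n]) * ANGSTROM_IN_BOHR
        energy = self.e0 + 0.5 * self.k * float(np.sum(disp * disp))
        grad = self.k * disp
        e_c, g_c = _coulomb_with_embedding(geometry, embedding, self.atom_charges)
        pops = None if self.atom_charges is None else self.atom_charges[:n].copy()
        return CalcResult(energy + e_c, grad + g_c, pops)


class DoubleWellCalculator(Calculator):
    """Quartic double well along x of the first atom, harmonic elsewhere.

    E = a (u^2 - u0^2)^2 + 1/2 k |rest|^2 with u the first atom's x in Bohr;
    minima at u = +-u0.
    """

    capabilities = frozenset({"energy", "gradient"})

    def __init__(self, a: float = 1.0, u0: float = 1.0, k: float = 1.0):
        self.a, self.u0, self.k = float(a), float(u0), float(k)

    def evaluate(self, geometry, embedding, state=0):
        if state > 0:
            raise ValueError("double-well mock has no excited states")
        r = geometry.positions * ANGSTROM_IN_BOHR
        u = r[0, 0]
        rest = r.copy()
        rest[0, 0] = 0.0
        energy = self.a * (u * u - self.u0 ** 2) ** 2 + 0.5 * self.k * float(np.sum(rest * rest))
        grad = self.k * rest
        grad[0, 0] = 4.0 * self.a * u * (u * u - self.u0 ** 2)
        return CalcResult(energy, grad)


class TwoStateConicalCalculator(Calculator):
    """Two-state linear vibronic model with a conical intersection.

    In the (u, v) = first atom's (x, y) Bohr coordinates,
    H = [[kappa u, c v], [c v, -kappa u]] + 1/2 omega (u^2 + v^2) I,
    giving E_± = 1/2 omega (u^2+v^2) ± sqrt(kappa^2 u^2 + c^2 v^2) with a
    degeneracy (conical intersection) at the origin.  State 0 is the lower
    surface.  The population analysis returns the (constant) mock charges.
    """

    def __init__(self, kappa: float = 0.5, c: float = 0.3, omega: float = 1.0,
                 atom_charges=None):
        self.kappa, self.c, self.omega = float(kappa), float(c), float(omega)
        self.atom_charges = (None if atom_charges is None
                             else np.asarray(atom_charges, dtype=float))
        caps = {"energy", "gradient", "excited_states"}
        if atom_charges is not None:
            caps.add("population")
        self.capabilities = frozenset(caps)

    def evaluate(self, geometry, embedding, state=0):
        if state > 1:
            raise ValueError("two-state mock provides states 0 and 1 only")
        r = geometry.positions * ANGSTROM_IN_BOHR
        u, v = r[0, 0], r[0, 1]
        root = np.sqrt(self.kappa ** 2 * u * u + self.c ** 2 * v * v)
        sign = -1.0 if state == 0 else 1.0
        energy = 0.5 * self.omega * float(np.sum(r * r)) + sign * root
        grad = self.omega * r
        if root > 1e-14:
            grad[0, 0] += sign * self.kappa ** 2 * u / root
            grad[0, 1] += sign * self.c ** 2 * v / root
        pops = None if self.atom_charges is None else self.atom_charges.copy()
        return CalcResult(energy, grad, pops)


class FixedPopulationCalculator(Calculator):
    """Returns constant population charges; zero energy surface."""

    capabilities = frozenset({"energy", "gradient", "population", "excited_states"})

    def __init__(self, charges):
        self.pop = np.asarray(charges, dtype=float)

    def evaluate(self, geometry, embedding, state=0):
        return CalcResult(0.0, np.zeros((len(geometry), 3)), self.pop.copy())


class LinearPopulationCalculator(Calculator):
    """Population analysis responding linearly to the current charges.

    Returns q_new = a * q_geometry + b; the self-consistent loop on this
    mock has the closed-form fixed point q* = b / (1 - a).
    """

    capabilities = frozenset({"energy", "gradient", "population", "excited_states"})

    def __init__(self, a: float = 0.5, b: float = 0.1):
        self.a, self.b = float(a), float(b)

    def evaluate(self, geometry, embedding, state=0):
        pops = self.a * geometry.charges + self.b
        return CalcResult(0.0, np.zeros((len(geometry), 3)), pops)


@dataclass
class MockPES:
    """Named analytic model surface with parameters."""

    form: str = "quadratic"
    params: dict = field(default_factory=dict)


def make_mock_calculator(pes: MockPES) -> Calculator:
    """Instantiate the calculator for an analytic model surface."""
    if pes.form == "quadratic":
        params = dict(pes.params)
        if "centers" not in params:
            params["centers"] = np.zeros((1, 3))
        return QuadraticCalculator(**params)
    if pes.form == "double-well":
        return DoubleWellCalculator(**pes.params)
    if pes.form == "two-state-conical":
        return TwoStateConicalCalculator(**pes.params)
    raise ValueError(f"unknown mock PES form {pes.form!r}")
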