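import numpy as np
import pytest

from aggrex.data import BOHR_IN_ANGSTROM
from aggrex.ewald_embedding import (ConvergenceError, EwaldParams,
                                    PointChargeArray, assign_charges,
                                    bond_order_matrix,
                                    ewald_potential, fit_ewald_charges,
                                    molecule_fingerprints, sc_embedding_loop)
from aggrex.fixtures import (FixedPopulationCalculator,
                             LinearPopulationCalculator, ToyCrystalSpec,
                             make_methanol, make_toy_crystal)
from aggrex.structures import AtomSite, BondingScheme, Structure


def evjen_direct_sum(n=16):
    """Direct Madelung sum for rocksalt (nn distance 1) over an expanding
    cube with Evjen fractional boundary weights — an independent oracle."""
    total = 0.0
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            for k in range(-n, n + 1):
                if i == j == k == 0:
                    continue
                w = 1.0
                for c in (i, j, k):
                    if abs(c) == n:
                        w *= 0.5
                total += w * (-1.0) ** (i + j + k) / np.sqrt(i * i + j * j + k * k)
    return total


# ---------------------------------------------------------------------------
# Ewald potential
# ---------------------------------------------------------------------------

def test_madelung_constant_against_direct_sum_oracle(rocksalt_bohr):
    v = ewald_potential(rocksalt_bohr, rocksalt_bohr.positions[0])
    assert v == pytest.approx(evjen_direct_sum(16), abs=1e-5)


def test_potential_is_gamma_invariant(rocksalt_bohr):
    hmin_bohr = 2.0
    v1 = ewald_potential(rocksalt_bohr, rocksalt_bohr.positions[0],
                         EwaldParams(gamma=5.6 / hmin_bohr))
    v2 = ewald_potential(rocksalt_bohr, rocksalt_bohr.positions[0],
                         EwaldParams(gamma=2 * 5.6 / hmin_bohr))
    assert v1 == pytest.approx(v2, abs=1e-6)


def test_potential_linear_in_charges(rocksalt_bohr):
    p = np.array([0.3, 0.1, 0.2])  # off-site probe, Angstrom
    v1 = ewald_potential(rocksalt_bohr, p)
    scaled = rocksalt_bohr.copy()
    scaled.charges = scaled.charges * 0.25
    assert ewald_potential(scaled, p) == pytest.approx(0.25 * v1, abs=1e-10)


def test_cscl_madelung_constant():
    cell = make_toy_crystal(ToyCrystalSpec("cscl", a=2 * BOHR_IN_ANGSTROM))
    d_nn = np.sqrt(3.0)  # Bohr
    v = ewald_potential(cell, cell.positions[0])
    assert v * d_nn == pytest.approx(-1.762675, abs=1e-5)


def test_non_neutral_cell_rejected(rocksalt_bohr):
    bad = rocksalt_bohr.copy()
    bad.atoms[0].charge = 2.0
    with pytest.raises(ValueError, match="neutral"):
        ewald_potential(bad, np.zeros(3))


# ---------------------------------------------------------------------------
# charge fitting
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted_rocksalt():
    cell = make_toy_crystal(ToyCrystalSpec("rocksalt", a=2 * BOHR_IN_ANGSTROM))
    inner = cell.subset(range(len(cell)))
    array = fit_ewald_charges(cell, inner, n_charges=1000)
    return cell, inner, array


def test_fit_satisfies_total_charge_and_dipole_constraints(fitted_rocksalt):
    _, _, array = fitted_rocksalt
    assert abs(array.charges.sum()) < 1e-10
    dipole = array.charges @ array.positions
    assert np.abs(dipole).max() < 1e-8


def test_fit_never_worsens_the_potential_residual(fitted_rocksalt):
    cell, inner, array = fitted_rocksalt
    sites = inner.positions
    v_ref = np.atleast_1d(ewald_potential(cell, sites))
    nominal = PointChargeArray(array.positions,
                               np.tile(cell.charges, len(array) // len(cell)))
    before = np.abs(nominal.potential(sites) - v_ref).max()
    after = np.abs(array.potential(sites) - v_ref).max()
    assert after <= before + 1e-12


def test_fit_reproduces_ewald_potential_at_inner_sites(fitted_rocksalt):
    cell, inner, array = fitted_rocksalt
    sites = inner.positions
    v_ref = np.atleast_1d(ewald_potential(cell, sites))
    v_fit = np.atleast_1d(array.potential(sites))
    assert np.abs(v_fit - v_ref).max() < 1e-3


def test_fit_residual_decreases_with_more_charges():
    cell = make_toy_crystal(ToyCrystalSpec("rocksalt", a=2 * BOHR_IN_ANGSTROM))
    inner = cell.subset(range(len(cell)))
    sites = inner.positions
    v_ref = np.atleast_1d(ewald_potential(cell, sites))
    residuals = []
    for n in (216, 1000):
        arr = fit_ewald_charges(cell, inner, n_charges=n, r_fix=1.3)
        residuals.append(np.abs(np.atleast_1d(arr.potential(sites)) - v_ref).max())
    # least squares with a superset of free charges cannot do worse
    # (beyond numerical noise; here both fits are essentially exact)
    assert residuals[1] <= residuals[0] + 1e-12


# ---------------------------------------------------------------------------
# bond orders and fingerprints
# ---------------------------------------------------------------------------

def test_methanol_bond_distances(methanol):
    bom = bond_order_matrix(methanol)
    # atoms: C, O, H(methyl) x3, H(hydroxyl)
    assert bom.B[2, 5] == 3  # methyl H to hydroxyl H: three bonds
    assert bom.B[1, 2] == 2  # O to methyl H
    assert bom.B[0, 5] == 2  # C to hydroxyl H


def test_water_hh_distance(water):
    bom = bond_order_matrix(water)
    assert bom.B[1, 2] == 2


def test_linear_chain_end_to_end():
    n = 7
    chain = Structure([AtomSite("C", (1.4 * i, 0, 0)) for i in range(n)],
                      bonding=BondingScheme("center", 1.5))
    bom = bond_order_matrix(chain)
    assert bom.B[0, n - 1] == n - 1


def test_bond_orders_match_networkx_bfs_oracle():
    networkx = pytest.importorskip("networkx")
    rng = np.random.default_rng(0)
    for _ in range(30):
        # grow a random connected molecule by attaching each new atom near
        # a previously placed one
        pts = [np.zeros(3)]
        for _ in range(rng.integers(3, 10)):
            base = pts[rng.integers(len(pts))]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pts.append(base + direction * 1.45)
        mol = Structure([AtomSite("C", p) for p in pts],
                        bonding=BondingScheme("center", 1.6))
        try:
            bom = bond_order_matrix(mol)
        except ValueError:
            continue  # rare geometric fragmentation; not the property at stake
        g = networkx.Graph()
        g.add_nodes_from(range(len(mol)))
        pos = mol.positions
        for i in range(len(mol)):
            for j in range(i + 1, len(mol)):
                if np.linalg.norm(pos[i] - pos[j]) < 1.6:
                    g.add_edge(i, j)
        lengths = dict(networkx.all_pairs_shortest_path_length(g))
        for i in range(len(mol)):
            for j in range(len(mol)):
                assert bom.B[i, j] == lengths[i][j]


def test_disconnected_molecule_rejected():
    two = Structure([AtomSite("H", (0, 0, 0)), AtomSite("H", (9, 0, 0))],
                    bonding=BondingScheme("center", 1.0))
    with pytest.raises(ValueError, match="fragments"):
        bond_order_matrix(two)


def test_methanol_fingerprints(methanol):
    fps = molecule_fingerprints(methanol)
    methyl = fps[2]
    assert methyl.element == "H"
    assert dict(methyl.shells) == {("C", 1): 1, ("O", 2): 1, ("H", 2): 2, ("H", 3): 1}
    assert fps[2] == fps[3] == fps[4]  # the three methyl hydrogens
    assert fps[5] != fps[2]  # hydroxyl H differs


def test_assign_charges_averages_equivalent_atoms(methanol):
    ref = methanol.copy()
    ref.charges = [0.2, -0.5, 0.03, 0.04, 0.05, 0.18]
    target = methanol.copy()
    out = assign_charges(ref, target)
    assert out.atoms[2].charge == pytest.approx(0.04)
    assert out.atoms[3].charge == pytest.approx(0.04)
    assert out.total_charge() == pytest.approx(ref.total_charge(), abs=1e-10)


def test_assign_charges_onto_cluster_conserves_per_molecule(methanol):
    ref = methanol.copy()
    ref.charges = [0.21, -0.52, 0.03, 0.04, 0.05, 0.19]
    k = 3
    atoms = []
    for m in range(k):
        atoms.extend(methanol.translated([5.0 * m, 0, 0]).atoms)
    cluster = Structure(atoms, bonding=methanol.bonding)
    out = assign_charges(ref, cluster)
    assert out.total_charge() == pytest.approx(k * ref.total_charge(), abs=1e-9)


def test_assign_charges_follows_atoms_not_indices(methanol):
    ref = methanol.copy()
    ref.charges = [0.2, -0.5, 0.03, 0.04, 0.05, 0.18]
    rng = np.random.default_rng(4)
    perm = rng.permutation(6)
    target = Structure([methanol.atoms[p].copy() for p in perm],
                       bonding=methanol.bonding)
    out = assign_charges(ref, target)
    expected = {"C": 0.2, "O": -0.5}
    for atom in out:
        if atom.element in expected:
            assert atom.charge == pytest.approx(expected[atom.element])


def test_assign_charges_unmatched_fingerprint_errors(methanol, water):
    with pytest.raises(ValueError, match="no matching"):
        assign_charges(methanol, water)


# ---------------------------------------------------------------------------
# self-consistent embedding
# ---------------------------------------------------------------------------

def methanol_cell():
    cell = make_methanol()
    cell.positions = cell.positions + 5.0
    cell.lattice = np.diag([10.0, 10.0, 10.0])
    return cell


def direct_embedding(cell, region):
    return PointChargeArray.from_structure(cell)


def test_fixed_point_mock_converges_immediately():
    cell = methanol_cell()
    fixed = np.array([0.2, -0.5, 0.05, 0.05, 0.05, 0.15])
    cell.charges = fixed
    calc = FixedPopulationCalculator(fixed)
    res = sc_embedding_loop(calc, cell, range(6), tol=1e-6,
                            embed_builder=direct_embedding)
    assert res.iterations == 1
    assert res.trace[0] == pytest.approx(0.0)


def test_linear_response_reaches_analytic_fixed_point():
    cell = methanol_cell()
    calc = LinearPopulationCalculator(a=0.5, b=0.1)
    res = sc_embedding_loop(calc, cell, range(6), tol=1e-8, max_iter=60,
                            embed_builder=direct_embedding)
    # q* = b / (1 - a) = 0.2 for every atom
    final = np.unique(np.round(res.array.charges, 6))
    assert final == pytest.approx([0.2], abs=1e-5)


def test_tighter_tolerance_never_reduces_iterations():
    iters = []
    for tol in (1e-2, 1e-4, 1e-6):
        cell = methanol_cell()
        calc = LinearPopulationCalculator(a=0.5, b=0.1)
        res = sc_embedding_loop(calc, cell, range(6), tol=tol, max_iter=80,
                                embed_builder=direct_embedding)
        iters.append(res.iterations)
    assert iters == sorted(iters)


def test_non_convergence_carries_trace():
    cell = methanol_cell()
    calc = LinearPopulationCalculator(a=1.0, b=0.1)  # diverging update
    with pytest.raises(ConvergenceError) as err:
        sc_embedding_loop(calc, cell, range(6), tol=1e-8, max_iter=5,
                          embed_builder=direct_embedding)
    assert len(err.value.trace) == 5


def test_damping_still_converges_to_the_fixed_point():
    cell = methanol_cell()
    calc = LinearPopulationCalculator(a=0.5, b=0.1)
    res = sc_embedding_loop(calc, cell, range(6), tol=1e-8, max_iter=200,
                            mixing=0.5, embed_builder=direct_embedding)
    assert np.allclose(res.array.charges, 0.2, atol=1e-5)
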