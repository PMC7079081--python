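import numpy as np
import pytest

from aggrex.data import ANGSTROM_IN_BOHR, BOHR_IN_ANGSTROM
from aggrex.ewald_embedding import PointChargeArray
from aggrex.fixtures import (DoubleWellCalculator, QuadraticCalculator,
                             TwoStateConicalCalculator)
from aggrex.oniom_optim import (ConvergenceWarningError, OniomSystem,
                                PenaltyParams, oniom_ee_energy, oniom_energy,
                                oniom_gradient, optimize_meci,
                                optimize_minimum, penalty_function)
from aggrex.structures import AtomSite, Structure


def point_structure(positions, charges=None):
    pos = np.atleast_2d(positions)
    atoms = [AtomSite("C", p) for p in pos]
    s = Structure(atoms)
    if charges is not None:
        s.charges = charges
    return s


def embedded_system(n1=1, n2=1, q1=0.3, q2=-0.3, k_high=2.0, k_low=1.0):
    """Two 'molecules': Region 1 atom(s) at the origin, Region 2 displaced.

    High and low calculators are harmonic with charge-embedding interaction.
    """
    n = n1 + n2
    centers = np.zeros((n, 3))
    centers[n1:] = [4.0, 0, 0]
    charges = np.array([q1] * n1 + [q2] * n2)
    high = QuadraticCalculator(centers, k=k_high, atom_charges=charges)
    low = QuadraticCalculator(centers, k=k_low, atom_charges=charges)
    geometry = point_structure(centers + 0.1, charges)
    system = OniomSystem(tuple(range(n1)), tuple(range(n1, n)), high, low,
                         "electrostatic")
    return system, geometry


# ---------------------------------------------------------------------------
# energy composition
# ---------------------------------------------------------------------------

def test_subtractive_energy_arithmetic():
    assert oniom_energy(-2.0, -5.0, -1.5) == pytest.approx(-5.5)
    # high == low collapses to the full-system low energy
    assert oniom_energy(-1.5, -5.0, -1.5) == pytest.approx(-5.0)
    assert oniom_energy(-2.0 + 1.0, -5.0, -1.5) == pytest.approx(-5.5 + 1.0)


def test_electrostatic_embedding_matches_hand_composition():
    system, geometry = embedded_system()
    sub1 = geometry.subset(system.region1)
    full = geometry.subset(system.region1 + system.region2)
    emb = system.embedding_array(geometry)
    e_expected = (system.high_calc.evaluate(sub1, emb, 0).energy
                  + system.low_calc.evaluate(full, None, 0).energy
                  - system.low_calc.evaluate(sub1, emb, 0).energy)
    assert oniom_ee_energy(system, geometry, 0) == pytest.approx(e_expected, abs=1e-14)


def test_zero_embedding_charges_reduce_to_mechanical():
    system, geometry = embedded_system(q1=0.0, q2=0.0)
    mech = OniomSystem(system.region1, system.region2, system.high_calc,
                       system.low_calc, "mechanical")
    assert oniom_ee_energy(system, geometry, 0) == pytest.approx(
        oniom_ee_energy(mech, geometry, 0), abs=1e-14)


def test_identical_levels_collapse_to_full_system_energy():
    n1, n2 = 1, 2
    centers = np.zeros((3, 3))
    centers[1:] = [[4.0, 0, 0], [0, 4.0, 0]]
    calc = QuadraticCalculator(centers, k=1.3)
    geometry = point_structure(centers + 0.2)
    system = OniomSystem((0,), (1, 2), calc, calc, "mechanical")
    e_oniom = oniom_ee_energy(system, geometry, 0)
    e_full = calc.evaluate(geometry, None, 0).energy
    assert e_oniom == pytest.approx(e_full, abs=1e-14)


def test_excited_state_requires_capability():
    system, geometry = embedded_system()
    with pytest.raises(ValueError, match="excited"):
        oniom_ee_energy(system, geometry, 1)


def test_regions_must_be_disjoint():
    calc = QuadraticCalculator(np.zeros((2, 3)))
    with pytest.raises(ValueError, match="disjoint"):
        OniomSystem((0, 1), (1,), calc, calc)


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def finite_difference_gradient(system, geometry, state=0, h=1e-5):
    """Central differences of the ONIOM energy, converted to Hartree/Bohr."""
    x0 = geometry.positions[list(system.region1)].ravel()
    g = np.zeros_like(x0)
    for i in range(x0.size):
        for sgn in (+1, -1):
            x = x0.copy()
            x[i] += sgn * h
            geo = geometry.copy()
            pos = geo.positions
            pos[list(system.region1)] = x.reshape(-1, 3)
            geo.positions = pos
            g[i] += sgn * oniom_ee_energy(system, geo, state)
    return (g / (2 * h)).reshape(-1, 3) / ANGSTROM_IN_BOHR


def test_gradient_matches_finite_differences():
    system, geometry = embedded_system(n1=2, n2=2)
    g = oniom_gradient(system, geometry, 0)
    g_fd = finite_difference_gradient(system, geometry)
    np.testing.assert_allclose(g, g_fd, atol=1e-6)


def test_gradient_for_identical_levels_is_full_low_gradient():
    centers = np.zeros((2, 3))
    centers[1] = [4.0, 0, 0]
    calc = QuadraticCalculator(centers, k=0.8)
    geometry = point_structure(centers + 0.3)
    system = OniomSystem((0,), (1,), calc, calc, "mechanical")
    g = oniom_gradient(system, geometry, 0)
    g_full = calc.evaluate(geometry, None, 0).gradient[:1]
    np.testing.assert_allclose(g, g_full, atol=1e-14)


def test_mechanical_gradient_translation_invariant_mock():
    """A pair-potential-like mock built from two quadratic wells whose
    difference depends on relative geometry only."""
    system, geometry = embedded_system(q1=0.0, q2=0.0)
    g1 = oniom_gradient(system, geometry, 0)
    g2 = oniom_gradient(system, geometry.translated([0.5, -0.25, 1.0]), 0)
    # harmonic wells are not translation invariant, but the FD consistency
    # must hold at any reference point
    np.testing.assert_allclose(
        g2, finite_difference_gradient(system, geometry.translated([0.5, -0.25, 1.0])),
        atol=1e-6)
    assert g1.shape == g2.shape == (1, 3)


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------

def test_quadratic_bowl_minimum_recovered():
    center = np.array([[0.3, -0.2, 0.5]])
    calc = QuadraticCalculator(center, k=2.0)
    system = OniomSystem.single_region(calc, 1)
    geometry = point_structure([[1.0, 1.0, 1.0]])
    res = optimize_minimum(system, geometry, tol=1e-8)
    np.testing.assert_allclose(res.geometry.positions, center, atol=1e-6)
    assert res.converged
    assert res.energy == pytest.approx(0.0, abs=1e-10)


def test_trace_of_accepted_steps_is_non_increasing():
    calc = QuadraticCalculator(np.zeros((1, 3)), k=1.0)
    system = OniomSystem.single_region(calc, 1)
    res = optimize_minimum(system, point_structure([[2.0, -1.0, 0.7]]), tol=1e-7)
    energies = res.trace
    # line-search trial points may rise; the running best must not
    best = np.minimum.accumulate(energies)
    assert best[-1] <= best[0]
    assert res.energy == pytest.approx(best[-1], abs=1e-12)


def test_double_well_converges_to_starting_basin():
    calc = DoubleWellCalculator(a=1.0, u0=1.0, k=1.0)
    system = OniomSystem.single_region(calc, 1)
    for start, expected in ((0.4, 1.0), (-0.4, -1.0)):
        geometry = point_structure([[start * BOHR_IN_ANGSTROM, 0, 0]])
        res = optimize_minimum(system, geometry, tol=1e-8)
        u = res.geometry.positions[0, 0] * ANGSTROM_IN_BOHR
        assert u == pytest.approx(expected, abs=1e-5)


def test_region2_frozen_during_optimization():
    system, geometry = embedded_system(n1=1, n2=2)
    before = geometry.positions[list(system.region2)].copy()
    res = optimize_minimum(system, geometry, tol=1e-6)
    np.testing.assert_array_equal(res.geometry.positions[list(system.region2)], before)


# ---------------------------------------------------------------------------
# penalty function and MECI search
# ---------------------------------------------------------------------------

def test_penalty_function_values():
    p = PenaltyParams(sigma=3.5, alpha=0.02)
    assert penalty_function(1.0, 1.0, p) == pytest.approx(1.0)
    assert penalty_function(0.0, 1.0, p) == pytest.approx(0.5 + 3.5 / 1.02)
    with pytest.warns(UserWarning):
        val = penalty_function(1.0, 0.0, p)
    assert val == pytest.approx(0.5 + 3.5 / 1.02)


def test_penalty_increases_with_gap_at_fixed_mean():
    p = PenaltyParams()
    gaps = np.linspace(0, 0.5, 20)
    vals = [penalty_function(-g / 2, g / 2, p) for g in gaps]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def grid_meci_oracle(calc, gap_tol, extent=1.5, step=0.01):
    """Dense grid search of the minimal mean energy subject to a closed gap."""
    us = np.arange(-extent, extent + step, step)
    best = (np.inf, None)
    for u in us:
        for v in us:
            geometry = point_structure([[u * BOHR_IN_ANGSTROM,
                                         v * BOHR_IN_ANGSTROM, 0.0]])
            e0 = calc.evaluate(geometry, None, 0).energy
            e1 = calc.evaluate(geometry, None, 1).energy
            if e1 - e0 < gap_tol:
                mean = 0.5 * (e0 + e1)
                if mean < best[0]:
                    best = (mean, (u, v))
    return best


def test_meci_matches_grid_oracle():
    calc = TwoStateConicalCalculator(kappa=0.5, c=0.3, omega=1.0)
    system = OniomSystem.single_region(calc, 1)
    start = point_structure([[0.8 * BOHR_IN_ANGSTROM, 0.5 * BOHR_IN_ANGSTROM, 0]])
    res = optimize_meci(system, start, gap_tol=1e-3)
    assert res.gap < 1e-3
    oracle_mean, oracle_uv = grid_meci_oracle(calc, gap_tol=1e-3, step=0.01)
    assert res.energy == pytest.approx(oracle_mean, abs=0.01)
    u, v = res.geometry.positions[0, :2] * ANGSTROM_IN_BOHR
    assert np.hypot(u - oracle_uv[0], v - oracle_uv[1]) < 0.02


def test_conical_seam_limit_reduces_to_mean_energy_minimization():
    """With zero interstate coupling along v = 0 the penalty adds nothing on
    the seam and the optimizer minimizes the mean surface."""
    calc = TwoStateConicalCalculator(kappa=0.5, c=0.3, omega=1.0)
    system = OniomSystem.single_region(calc, 1)
    start = point_structure([[0, 0, 0]])  # exactly at the conical point
    e0 = calc.evaluate(start, None, 0).energy
    e1 = calc.evaluate(start, None, 1).energy
    assert e1 - e0 == pytest.approx(0.0, abs=1e-14)
    res = optimize_meci(system, start, gap_tol=1e-3)
    assert res.energy == pytest.approx(0.0, abs=1e-8)


def test_increasing_sigma_never_raises_the_final_gap():
    calc = TwoStateConicalCalculator(kappa=0.5, c=0.3, omega=1.0)
    system = OniomSystem.single_region(calc, 1)
    start = point_structure([[0.8 * BOHR_IN_ANGSTROM, 0.5 * BOHR_IN_ANGSTROM, 0]])
    gaps = []
    for sigma in (1.0, 4.0, 16.0):
        res = optimize_meci(system, start, PenaltyParams(sigma=sigma, alpha=0.02),
                            gap_tol=1e-2)
        gaps.append(res.gap)
    assert all(b <= a * 1.05 + 1e-10 for a, b in zip(gaps, gaps[1:]))


def test_meci_failure_suggests_sigma_increase():
    # a tiny sigma cannot close the gap from a skewed model
    calc = TwoStateConicalCalculator(kappa=0.5, c=0.3, omega=1.0)
    system = OniomSystem.single_region(calc, 1)
    start = point_structure([[0.8 * BOHR_IN_ANGSTROM, 0.5 * BOHR_IN_ANGSTROM, 0]])
    with pytest.raises(ConvergenceWarningError, match="sigma"):
        optimize_meci(system, start, PenaltyParams(sigma=1e-4, alpha=0.02),
                      gap_tol=1e-9)


def test_ewald_mode_requires_prepared_array():
    calc = QuadraticCalculator(np.zeros((2, 3)))
    with pytest.raises(ValueError, match="point-charge array"):
        OniomSystem((0,), (1,), calc, calc, "ewald")
    arr = PointChargeArray([[10.0, 0, 0]], [0.1])
    system = OniomSystem((0,), (1,), calc, calc, "ewald", arr)
    assert system.embedding_array(point_structure(np.zeros((2, 3)))) is arr
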