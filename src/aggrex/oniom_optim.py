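"""Subtractive ONIOM QM:QM' energies, gradients, and surface optimization.

The two-level subtractive hybrid energy is

    E_high:low(1 u 2) = E_high(1) + E_low(1 u 2) - E_low(1),

where Region 1 holds the molecules involved in the excitation and Region 2
a cluster of molecules encasing them.  With electrostatic embedding the two
Region-1 terms are evaluated in a point-charge potential (Region-2 atomic
charges, an Ewald-fitted array, or a self-consistently equilibrated array);
the full-system low-level term is left unembedded, since with a fixed
Region 2 the array only adds a constant.

All electronic-structure work goes through the abstract
:class:`Calculator` contract, so any energy/gradient/population provider —
including the analytic mock potentials used for testing — can stand behind
the ONIOM composition.  Geometry optimization (BFGS) acts on Region-1
coordinates only; Region 2 and the embedding charges stay frozen.

Minimal-energy conical intersections are located without nonadiabatic
coupling vectors by minimizing the gap-penalized average energy

    F = (E1 + E0)/2 + sigma * dE^2 / (dE + alpha),    dE = E1 - E0,

whose smooth penalty drives the gap to zero while descending the mean
surface.  Energies are Hartree, gradients Hartree/Bohr, geometries
Angstrom.
"""

from __future__ import annotations

import warnings
from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .data import BOHR_IN_ANGSTROM
from .ewald_embedding import PointChargeArray
from .structures import Structure

__all__ = [
    "Calculator",
    "CalcResult",
    "OniomSystem",
    "PenaltyParams",
    "PESResult",
    "oniom_energy",
    "oniom_ee_energy",
    "oniom_gradient",
    "optimize_minimum",
    "penalty_function",
    "optimize_meci",
]

EMBEDDING_MODES = ("mechanical", "electrostatic", "ewald", "sc-ewald-s0", "sc-ewald-s1")


@dataclass
class CalcResult:
    """One calculator evaluation: energy (Hartree), gradient (Hartree/Bohr,
    per atom), and optionally per-atom population charges (e)."""

    energy: float
    gradient: np.ndarray | None = None
    populations: np.ndarray | None = None


class Calculator(ABC):
    """The pluggable energy/gradient/population provider.

    ``capabilities`` is a set drawn from {"energy", "gradient",
    "excited_states", "population"}.  ``evaluate`` must be pure: repeated
    evaluation at identical inputs returns identical results.
    """

    capabilities: frozenset = frozenset({"energy"})

    @abstractmethod
    def evaluate(self, geometry: Structure, embedding: PointChargeArray | None,
                 state: int) -> CalcResult:
        """Energy (and gradient/populations) of a geometry in an embedding."""


@dataclass
class OniomSystem:
    """A two-region ONIOM setup over one geometry.

    ``region1`` and ``region2`` are disjoint tuples of atom indices;
    ``embedding_mode`` is one of ``mechanical``, ``electrostatic`` (OEC:
    Region-2 atomic charges), ``ewald`` (OEEC: a fitted array in
    ``charges_r2``), or ``sc-ewald-s0`` / ``sc-ewald-s1`` (SC-OEEC: the
    self-consistent loop's output in ``charges_r2``).
    """

    region1: tuple
    region2: tuple
    high_calc: Calculator
    low_calc: Calculator
    embedding_mode: str = "mechanical"
    charges_r2: PointChargeArray | None = None

    def __post_init__(self) -> None:
        self.region1 = tuple(self.region1)
        self.region2 = tuple(self.region2)
        if set(self.region1) & set(self.region2):
            raise ValueError("ONIOM regions must be disjoint")
        if self.embedding_mode not in EMBEDDING_MODES:
            raise ValueError(f"embedding mode must be one of {EMBEDDING_MODES}")
        if self.embedding_mode in ("ewald", "sc-ewald-s0", "sc-ewald-s1") \
                and self.charges_r2 is None:
            raise ValueError(f"{self.embedding_mode} embedding needs a prepared "
                             "point-charge array in charges_r2")

    @classmethod
    def single_region(cls, calc: Calculator, n_atoms: int) -> "OniomSystem":
        """Degenerate system treating all atoms at one level (no environment)."""
        return cls(tuple(range(n_atoms)), (), calc, calc, "mechanical")

    def embedding_array(self, geometry: Structure) -> PointChargeArray | None:
        if self.embedding_mode == "mechanical":
            return None
        if self.embedding_mode == "electrostatic":
            if not self.region2:
                return None
            sub = geometry.subset(self.region2)
            return PointChargeArray.from_structure(sub)
        return self.charges_r2


def oniom_energy(E_high_1: float, E_low_12: float, E_low_1: float) -> float:
    """Subtractive two-level combination E_high(1) + E_low(1 u 2) - E_low(1)."""
    return E_high_1 + E_low_12 - E_low_1


def _check_excited(calc: Calculator, state: int) -> None:
    if state > 0 and "excited_states" not in calc.capabilities:
        raise ValueError("calculator does not provide excited states")


def _regions(system: OniomSystem, geometry: Structure):
    sub1 = geometry.subset(system.region1)
    full = geometry.subset(system.region1 + system.region2)
    return sub1, full


def oniom_ee_energy(system: OniomSystem, geometry: Structure, state: int = 0) -> float:
    """ONIOM energy with the selected embedding, high level at ``state``.

    The point-charge array enters only the two Region-1 terms; the
    full-system low-level term and both low-level terms run in the ground
    state.
    """
    _check_excited(system.high_calc, state)
    sub1, full = _regions(system, geometry)
    emb = system.embedding_array(geometry)
    e_high = system.high_calc.evaluate(sub1, emb, state).energy
    e_low_full = system.low_calc.evaluate(full, None, 0).energy
    e_low_1 = system.low_calc.evaluate(sub1, emb, 0).energy
    return oniom_energy(e_high, e_low_full, e_low_1)


def oniom_gradient(system: OniomSystem, geometry: Structure, state: int = 0) -> np.ndarray:
    """ONIOM gradient on Region-1 atoms (Hartree/Bohr, shape (n1, 3)).

    Region 2 and the embedding charges are frozen, so only the Region-1
    rows of the full-system low-level gradient contribute.
    """
    _check_excited(system.high_calc, state)
    for calc in (system.high_calc, system.low_calc):
        if "gradient" not in calc.capabilities:
            raise ValueError("calculator does not provide gradients")
    sub1, full = _regions(system, geometry)
    emb = system.embedding_array(geometry)
    n1 = len(system.region1)
    g_high = np.asarray(system.high_calc.evaluate(sub1, emb, state).gradient)
    g_low_full = np.asarray(system.low_calc.evaluate(full, None, 0).gradient)[:n1]
    g_low_1 = np.asarray(system.low_calc.evaluate(sub1, emb, 0).gradient)
    return g_high + g_low_full - g_low_1


@dataclass
class PESResult:
    """Outcome of a surface optimization."""

    geometry: Structure
    energy: float
    trace: list = field(default_factory=list)
    converged: bool = False
    gap: float | None = None


def _with_region1(geometry: Structure, system: OniomSystem, x: np.ndarray) -> Structure:
    geo = geometry.copy()
    pos = geo.positions
    pos[list(system.region1)] = x.reshape(-1, 3)
    geo.positions = pos
    return geo


def optimize_minimum(system: OniomSystem, geometry: Structure, state: int = 0,
                     tol: float = 3e-4, max_steps: int = 300) -> PESResult:
    """Quasi-Newton (BFGS) minimization over Region-1 coordinates.

    Converged when every gradient component is below ``tol`` Hartree/Bohr
    (default 3e-4).  Region-2 coordinates are never touched.
    """
    x0 = geometry.positions[list(system.region1)].ravel()
    trace: list[float] = []

    def fun(x):
        geo = _with_region1(geometry, system, x)
        e = oniom_ee_energy(system, geo, state)
        # gradient wrt Angstrom displacements for scipy, converted back below
        g = oniom_gradient(system, geo, state).ravel() / BOHR_IN_ANGSTROM
        trace.append(e)
        return e, g

    res = minimize(fun, x0, jac=True, method="BFGS",
                   options={"gtol": tol / BOHR_IN_ANGSTROM, "maxiter": max_steps})
    geo = _with_region1(geometry, system, res.x)
    grad = oniom_gradient(system, geo, state)
    converged = bool(np.abs(grad).max() < tol)
    if not converged:
        raise ConvergenceWarningError(
            f"minimization did not reach |g| < {tol} in {max_steps} steps", trace)
    return PESResult(geo, float(res.fun), trace, converged)


class ConvergenceWarningError(RuntimeError):
    """Optimization failure carrying the energy trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


def penalty_function(E0: float, E1: float, p: "PenaltyParams") -> float:
    """Gap-penalized average energy F = (E1+E0)/2 + sigma dE^2/(dE+alpha)."""
    if E1 < E0:
        warnings.warn("states out of order; reordering E0 <= E1")
        E0, E1 = E1, E0
    de = E1 - E0
    return 0.5 * (E0 + E1) + p.sigma * de * de / (de + p.alpha)


@dataclass
class PenaltyParams:
    """Penalty-function parameters.

    ``sigma`` is the dimensionless penalty multiplier; ``alpha`` (Hartree)
    smooths the penalty near degeneracy and must stay much smaller than
    typical gaps.
    """

    sigma: float = 3.5
    alpha: float = 0.02

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.alpha <= 0:
            raise ValueError("sigma and alpha must be positive")


def optimize_meci(system: OniomSystem, geometry: Structure,
                  p: PenaltyParams | None = None, gap_tol: float = 1e-3,
                  tol: float = 3e-4, max_steps: int = 300,
                  sigma_steps: int = 0, sigma_factor: float = 2.0) -> PESResult:
    """Minimal-energy conical intersection search by penalty minimization.

    Minimizes F over Region-1 coordinates with BFGS using analytic
    gradients of the penalty function.  Success requires the final
    S1-S0 gap below ``gap_tol`` Hartree; if the gap stagnates above it,
    ``sigma_steps`` additional passes with ``sigma`` scaled by
    ``sigma_factor`` are attempted before raising.
    """
    p = p or PenaltyParams()
    _check_excited(system.high_calc, 1)
    x = geometry.positions[list(system.region1)].ravel()
    trace: list[tuple[float, float]] = []

    def fg(xvec, sigma):
        geo = _with_region1(geometry, system, xvec)
        e0 = oniom_ee_energy(system, geo, 0)
        e1 = oniom_ee_energy(system, geo, 1)
        g0 = oniom_gradient(system, geo, 0).ravel()
        g1 = oniom_gradient(system, geo, 1).ravel()
        de = e1 - e0
        f = 0.5 * (e0 + e1) + sigma * de * de / (de + p.alpha)
        dpen = (de * de + 2.0 * p.alpha * de) / (de + p.alpha) ** 2
        g = 0.5 * (g0 + g1) + sigma * dpen * (g1 - g0)
        trace.append((0.5 * (e0 + e1), de))
        return f, g / BOHR_IN_ANGSTROM

    sigma = p.sigma
    for attempt in range(sigma_steps + 1):
        res = minimize(fg, x, args=(sigma,), jac=True, method="BFGS",
                       options={"gtol": tol / BOHR_IN_ANGSTROM, "maxiter": max_steps})
        x = res.x
        geo = _with_region1(geometry, system, x)
        e0 = oniom_ee_energy(system, geo, 0)
        e1 = oniom_ee_energy(system, geo, 1)
        gap = e1 - e0
        if gap < gap_tol:
            return PESResult(geo, 0.5 * (e0 + e1), trace, True, gap)
        sigma *= sigma_factor
    raise ConvergenceWarningError(
        f"MECI search stagnated with gap {gap:.3e} Hartree above tolerance "
        f"{gap_tol:.1e}; consider increasing sigma (sigma-stepping available)",
        trace)
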