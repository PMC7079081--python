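"""Ewald lattice potentials, point-charge fitting, and charge redistribution.

The electrostatic (Madelung) potential of a neutral periodic charge
distribution is conditionally convergent when summed directly; the Ewald
decomposition splits it into a rapidly convergent real-space sum of
screened (erfc) charges and a reciprocal-space sum over nonzero lattice
vectors G:

    V(r) = sum_{L,s} q_s erfc(g |r - L - R_s|) / |r - L - R_s|
         + (4 pi / v_c) sum_{G != 0} exp(-G^2 / 4 g^2) / G^2
                        sum_s q_s cos(G . (r - R_s)),

with g the Ewald screening constant and v_c the cell volume.  At an atomic
site r = R_i the divergent L = 0, s = i real-space term is replaced by the
self correction -2 g q_i / sqrt(pi).  For a neutral cell the result is
independent of g.

On top of the potential this module provides the Klintenberg-Derenzo-style
constrained least-squares fit of a finite point-charge array to the Ewald
potential at the atomic sites of a central region (total charge and dipole
of the array constrained to zero), shortest-path bond-order matrices and
connectivity fingerprints for redistributing population-analysis charges
onto equivalent atoms, and the self-consistent embedding loop that
equilibrates embedding charges against a quantum calculator's population
analysis.

All electrostatics are in Hartree atomic units internally; structure
coordinates enter in Angstrom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.special import erfc

from .data import ANGSTROM_IN_BOHR
from .structures import Structure, detect_bonds, segment_molecules

__all__ = [
    "EwaldParams",
    "PointChargeArray",
    "BondOrderMatrix",
    "AtomFingerprint",
    "ConvergenceError",
    "ewald_potential",
    "fit_ewald_charges",
    "bond_order_matrix",
    "atom_fingerprint",
    "molecule_fingerprints",
    "assign_charges",
    "sc_embedding_loop",
    "SCEmbeddingResult",
]


class ConvergenceError(RuntimeError):
    """Raised when an iterative procedure fails to converge.

    Carries the per-iteration trace in the ``trace`` attribute.
    """

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class EwaldParams:
    """Parameters of the Ewald evaluation (atomic units).

    Any field left ``None`` is resolved against the cell: the screening
    constant defaults to 5.6 / h_min with h_min the shortest cell height in
    Bohr (making erfc negligible beyond one cell), the real-space cutoff to
    h_min, and the reciprocal cutoff to the G magnitude at which the
    Gaussian factor reaches the target accuracy.
    """

    gamma: float | None = None
    real_cutoff: float | None = None
    recip_cutoff: float | None = None
    target_accuracy: float = 1e-6

    def resolved(self, lattice_bohr: np.ndarray) -> "EwaldParams":
        vol = abs(np.linalg.det(lattice_bohr))
        heights = np.empty(3)
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            heights[i] = vol / np.linalg.norm(np.cross(lattice_bohr[j], lattice_bohr[k]))
        hmin = heights.min()
        gamma = self.gamma if self.gamma is not None else 5.6 / hmin
        if gamma <= 0:
            raise ValueError("Ewald gamma must be positive")
        real_cutoff = self.real_cutoff if self.real_cutoff is not None else hmin
        acc = min(self.target_accuracy, 1e-6)
        recip_cutoff = (self.recip_cutoff if self.recip_cutoff is not None
                        else 2.0 * gamma * np.sqrt(-np.log(acc * 1e-4)))
        if real_cutoff <= 0 or recip_cutoff <= 0:
            raise ValueError("Ewald cutoffs must be positive")
        return EwaldParams(gamma, real_cutoff, recip_cutoff, self.target_accuracy)


@dataclass
class PointChargeArray:
    """Positions (Angstrom), charges (e), and a fixed/fitted zone label each."""

    positions: np.ndarray
    charges: np.ndarray
    zone: np.ndarray = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float).ravel()
        if self.positions.shape[0] != self.charges.shape[0]:
            raise ValueError("positions and charges must have equal length")
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.charges))):
            raise ValueError("point charges must be finite")
        if self.zone is None:
            self.zone = np.full(len(self.charges), "fixed", dtype=object)
        else:
            self.zone = np.asarray(self.zone, dtype=object).ravel()
            if self.zone.shape[0] != self.charges.shape[0]:
                raise ValueError("zone labels must cover every charge")

    def __len__(self) -> int:
        return len(self.charges)

    def potential(self, points) -> np.ndarray:
        """Bare Coulomb potential of the array at the given points (Angstrom in, a.u. out)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) * ANGSTROM_IN_BOHR
        pos = self.positions * ANGSTROM_IN_BOHR
        dist = np.linalg.norm(pts[:, None, :] - pos[None, :, :], axis=-1)
        dist[dist < 1e-10] = np.inf  # a site does not see its own charge
        v = (self.charges[None, :] / dist).sum(axis=1)
        return v if v.size > 1 else float(v[0])

    @classmethod
    def from_structure(cls, struct: Structure, zone: str = "fixed") -> "PointChargeArray":
        return cls(struct.positions, struct.charges,
                   np.full(len(struct), zone, dtype=object))


# ---------------------------------------------------------------------------
# Ewald potential
# ---------------------------------------------------------------------------

def _check_neutral(cell: Structure) -> None:
    q = cell.total_charge()
    if abs(q) > 1e-8:
        raise ValueError(f"Ewald sum requires a neutral cell; total charge = {q:.6g} e")


def ewald_potential(cell: Structure, points, params: EwaldParams | None = None) -> np.ndarray:
    """Ewald lattice potential at one or more points (a.u.).

    ``cell`` must carry a lattice and per-atom charges summing to zero;
    ``points`` are Cartesian positions in Angstrom, a single 3-vector or an
    (N, 3) array.  When a point coincides with a lattice site (within 1e-8
    Bohr) the divergent self term is replaced by -2 gamma q_i / sqrt(pi).
    """
    if cell.lattice is None:
        raise ValueError("Ewald potential requires a lattice")
    _check_neutral(cell)
    lat = cell.lattice * ANGSTROM_IN_BOHR
    sites = cell.positions * ANGSTROM_IN_BOHR
    charges = cell.charges
    pts = np.atleast_2d(np.asarray(points, dtype=float)) * ANGSTROM_IN_BOHR
    single = np.asarray(points).ndim == 1
    p = (params or EwaldParams()).resolved(lat)

    vol = abs(np.linalg.det(lat))
    heights = np.empty(3)
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        heights[i] = vol / np.linalg.norm(np.cross(lat[j], lat[k]))

    # real-space images covering the cutoff sphere around any point
    span = np.linalg.norm(sites, axis=1).max() + np.linalg.norm(pts, axis=1).max()
    nmax = np.ceil((p.real_cutoff + span) / heights).astype(int) + 1
    shifts = np.array([m @ lat for m in
                       itertools.product(*(range(-n, n + 1) for n in nmax))])
    images = sites[None, :, :] + shifts[:, None, :]  # (n_img, n_sites, 3)
    images = images.reshape(-1, 3)
    img_q = np.tile(charges, len(shifts))

    out = np.empty(len(pts))
    for ip, r in enumerate(pts):
        d = np.linalg.norm(images - r, axis=1)
        near = d < 1e-8
        mask = (d <= p.real_cutoff) & ~near
        real = float(np.sum(img_q[mask] * erfc(p.gamma * d[mask]) / d[mask]))
        # self-term replacement at coincident sites
        real += float(np.sum(-2.0 * p.gamma * img_q[near] / np.sqrt(np.pi)))
        out[ip] = real

    # reciprocal-space sum over G != 0
    recip = 2.0 * np.pi * np.linalg.inv(lat).T
    gmax_n = np.ceil(p.recip_cutoff / np.linalg.norm(recip, axis=1)).astype(int) + 1
    gvecs = []
    for m in itertools.product(*(range(-n, n + 1) for n in gmax_n)):
        if m == (0, 0, 0):
            continue
        g = np.array(m, dtype=float) @ recip
        if np.linalg.norm(g) <= p.recip_cutoff:
            gvecs.append(g)
    gvecs = np.array(gvecs)
    g2 = np.einsum("ij,ij->i", gvecs, gvecs)
    damp = np.exp(-g2 / (4.0 * p.gamma ** 2)) / g2
    # structure factor sum_s q_s e^{-i G.R_s}; potential term uses the real part
    phase_sites = gvecs @ sites.T  # (n_G, n_sites)
    sf = (charges[None, :] * np.exp(-1j * phase_sites)).sum(axis=1)
    phase_pts = gvecs @ pts.T  # (n_G, n_pts)
    rec_part = (4.0 * np.pi / vol) * np.real(
        (damp[:, None] * sf[:, None] * np.exp(1j * phase_pts)).sum(axis=0))
    out += rec_part
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# Constrained point-charge fitting
# ---------------------------------------------------------------------------

def fit_ewald_charges(cell: Structure, inner_region: Structure,
                      n_charges: int = 1000, check_sites=None,
                      r_fix: float | None = None,
                      params: EwaldParams | None = None) -> PointChargeArray:
    """Fit a finite charge array to reproduce the Ewald potential.

    A centered supercell of point charges at the crystal's atomic sites is
    generated, covering roughly ``n_charges`` sites.  Charges within the
    fixed zone (a sphere of radius ``r_fix`` around the inner region,
    default bounding-sphere radius + 2 Angstrom) keep their nominal values;
    the remaining outer charges are adjusted by linear least squares so the
    array reproduces the Ewald potential at the inner region's atomic sites,
    under the exact linear constraints sum q = 0 and sum q r = 0 (total
    charge and dipole of the whole array), imposed via Lagrange multipliers.
    """
    if cell.lattice is None:
        raise ValueError("charge fitting requires a lattice")
    _check_neutral(cell)
    natoms = len(cell)
    k = 1
    while (2 * k + 1) ** 3 * natoms < n_charges:
        k += 1
    positions = []
    charges = []
    for img in itertools.product(range(-k, k + 1), repeat=3):
        shift = np.array(img, dtype=float) @ cell.lattice
        positions.append(cell.positions + shift)
        charges.append(cell.charges)
    positions = np.vstack(positions)
    charges = np.concatenate(charges)

    inner_pos = inner_region.positions
    inner_center = inner_pos.mean(axis=0)
    if r_fix is None:
        r_fix = np.linalg.norm(inner_pos - inner_center, axis=1).max() + 2.0
    dist_center = np.linalg.norm(positions - inner_center, axis=1)
    fixed = dist_center <= r_fix
    fitted = ~fixed
    nfit = int(fitted.sum())
    if nfit < 4:
        raise ValueError("too few fitted charges to satisfy the constraints; "
                         "increase n_charges or reduce r_fix")

    sites = np.asarray(check_sites, dtype=float) if check_sites is not None else inner_pos
    sites = np.atleast_2d(sites)
    v_target = np.atleast_1d(ewald_potential(cell, sites, params))

    pts_b = sites * ANGSTROM_IN_BOHR
    pos_b = positions * ANGSTROM_IN_BOHR
    dist = np.linalg.norm(pts_b[:, None, :] - pos_b[None, :, :], axis=-1)
    dist[dist < 1e-10] = np.inf
    inv_d = 1.0 / dist
    a_fit = inv_d[:, fitted]
    b = v_target - inv_d[:, fixed] @ charges[fixed]

    # constraints: total charge and dipole of the full array are zero
    cons = np.vstack([np.ones(nfit), pos_b[fitted].T])  # (4, nfit)
    rhs = -np.concatenate([[charges[fixed].sum()],
                           charges[fixed] @ pos_b[fixed]])

    ata = a_fit.T @ a_fit
    kkt = np.block([[2.0 * ata, cons.T],
                    [cons, np.zeros((4, 4))]])
    vec = np.concatenate([2.0 * a_fit.T @ b, rhs])
    sol, *_ = np.linalg.lstsq(kkt, vec, rcond=None)
    q_fit = sol[:nfit]

    out_q = charges.copy()
    out_q[fitted] = q_fit
    zone = np.where(fixed, "fixed", "fitted").astype(object)
    return PointChargeArray(positions, out_q, zone)


# ---------------------------------------------------------------------------
# Bond orders and fingerprints
# ---------------------------------------------------------------------------

@dataclass
class BondOrderMatrix:
    """Shortest-path bond counts between every atom pair of one molecule."""

    B: np.ndarray
    elements: list

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=int)
        if np.any(np.diag(self.B) != 0):
            raise ValueError("bond-order diagonal must be zero")


@dataclass(frozen=True)
class AtomFingerprint:
    """An atom's element plus the multiset of (element, bond distance) shells."""

    element: str
    shells: frozenset  # of ((element, nbonds), count) items


def bond_order_matrix(mol: Structure) -> BondOrderMatrix:
    """All-pairs shortest path in bonds on the detected bond graph.

    This is the fixed point of iteratively extending first-neighbor
    connections through shared atoms.  The input must be a single connected
    molecule.
    """
    adj = detect_bonds(mol)
    n = len(mol)
    mat = np.zeros((n, n), dtype=bool)
    for i, nbrs in enumerate(adj):
        for j in nbrs:
            mat[i, j] = True
    ncomp, labels = connected_components(csr_matrix(mat), directed=False)
    if ncomp > 1:
        frags = [tuple(np.nonzero(labels == c)[0].tolist()) for c in range(ncomp)]
        raise ValueError(f"molecule is disconnected; fragments: {frags}")
    d = shortest_path(csr_matrix(mat.astype(float)), method="D", unweighted=True)
    return BondOrderMatrix(d.astype(int), list(mol.elements))


def atom_fingerprint(bom: BondOrderMatrix, i: int) -> AtomFingerprint:
    """Connectivity identity of atom i: own element + per-shell element counts."""
    counts: dict[tuple, int] = {}
    for j, elem in enumerate(bom.elements):
        if j == i:
            continue
        key = (elem, int(bom.B[i, j]))
        counts[key] = counts.get(key, 0) + 1
    return AtomFingerprint(bom.elements[i], frozenset(counts.items()))


def molecule_fingerprints(mol: Structure) -> list[AtomFingerprint]:
    bom = bond_order_matrix(mol)
    return [atom_fingerprint(bom, i) for i in range(len(mol))]


def assign_charges(reference: Structure, target: Structure) -> Structure:
    """Redistribute reference partial charges onto a target by atom identity.

    Every atom of every reference molecule is fingerprinted; atoms sharing a
    fingerprint (e.g. the three hydrogens of a methyl group) contribute the
    average of their charges.  Each target atom then receives the charge of
    its fingerprint.  Raises if a target atom's identity does not occur in
    the reference.
    """
    charge_lists: dict[AtomFingerprint, list] = {}
    for mol_idx in segment_molecules(reference):
        sub = reference.subset(mol_idx)
        for local, fp in enumerate(molecule_fingerprints(sub)):
            charge_lists.setdefault(fp, []).append(sub.atoms[local].charge)
    means = {fp: float(np.mean(vals)) for fp, vals in charge_lists.items()}

    out = target.copy()
    for mol_idx in segment_molecules(out):
        sub = out.subset(mol_idx)
        for local, fp in enumerate(molecule_fingerprints(sub)):
            if fp not in means:
                atom_global = mol_idx[local]
                raise ValueError(
                    f"target atom {atom_global} ({fp.element}) has no matching "
                    "identity in the reference")
            out.atoms[mol_idx[local]].charge = means[fp]
    return out


# ---------------------------------------------------------------------------
# Self-consistent embedding
# ---------------------------------------------------------------------------

@dataclass
class SCEmbeddingResult:
    """Converged embedding array, iteration count, and charge-change trace."""

    array: PointChargeArray
    iterations: int
    trace: list = field(default_factory=list)


def sc_embedding_loop(calc, cell: Structure, region1, state: int = 0,
                      tol: float = 1e-4, max_iter: int = 50,
                      mixing: float = 1.0, embed_builder=None,
                      fit_kwargs: dict | None = None) -> SCEmbeddingResult:
    """Self-consistently equilibrate embedding charges with a calculator.

    Each cycle embeds Region 1 in a point-charge array built from the
    current cell charges, runs the calculator's population analysis at the
    requested state, redistributes the resulting fractional charges onto the
    whole unit cell by connectivity fingerprints, and rebuilds the array.
    Convergence when the largest per-atom charge change of the population
    analysis falls below ``tol`` (e); ``mixing`` < 1 applies linear damping
    to the charge updates.

    ``embed_builder(cell, region1_struct)`` may replace the default Ewald
    fit (useful for cheap models and testing).
    """
    if "population" not in getattr(calc, "capabilities", {"population"}):
        raise ValueError("calculator does not provide population analysis")
    work = cell.copy()
    region1 = tuple(region1)
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        sub = work.subset(region1)
        if embed_builder is not None:
            emb = embed_builder(work, sub)
        else:
            emb = fit_ewald_charges(work, sub, **(fit_kwargs or {}))
        res = calc.evaluate(sub, emb, state)
        pops = np.asarray(res.populations, dtype=float)
        if pops.shape != (len(region1),):
            raise ValueError("population analysis size does not match Region 1")
        old = sub.charges
        change = float(np.abs(pops - old).max())
        trace.append(change)
        if change < tol:
            return SCEmbeddingResult(emb, it, trace)
        mixed = old + mixing * (pops - old)
        sub.charges = mixed
        work = assign_charges(sub, work)
    raise ConvergenceError(
        f"self-consistent embedding did not converge in {max_iter} iterations "
        f"(last change {trace[-1]:.3e} e)", trace=trace)
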