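"""Exciton classification and coupling evaluation for molecular dimers.

Classification follows the Mulliken fragment-density scheme: for each
molecular orbital k the density resident on fragment A is

    rho_A(k) = sum_{mu in A, nu} c_mu(k) c_nu(k) S_mu,nu ,

and a single excitation I with amplitudes C_{i->j} yields two indices

    SumP_A  = sum_{i->j} sigma_ij C^2 (rho_A(j) + rho_A(i))   in [0, 2] e-,
    DeltaP_A = sum_{i->j} sigma_ij C^2 (rho_A(j) - rho_A(i))  in [-1, 1] e-,

with sigma_ij = +1 for i < j (excitation) and -1 for i > j (de-excitation).
SumP near 2 (0) marks a transition confined to monomer A (B); DeltaP near
-1 (+1) marks net charge transfer A->B (B->A); otherwise the excitation is
delocalized.  An excitation closer than 0.5 e- to an extreme value is
classified as the corresponding exciton type by default.

Couplings are available at four levels: the Kasha point-dipole
approximation, the atomic-transition-charge Coulomb sum, the half-gap of a
resonant dimer, and N-state diabatization of adiabatic state properties
against isolated-monomer references (the off-diagonal elements of the
resulting diabatic Hamiltonian are the exciton couplings J_ij).
All coupling routines work in Hartree atomic units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .data import ANGSTROM_IN_BOHR

__all__ = [
    "WavefunctionData",
    "ExcitonIndices",
    "StateProperty",
    "DiabaticHamiltonian",
    "mulliken_fragment_density",
    "exciton_indices",
    "classify_exciton",
    "coupling_pda",
    "coupling_atc",
    "coupling_half_gap",
    "diabatize",
    "wavefunction_to_json",
    "wavefunction_from_json",
    "read_tdm_table",
]


@dataclass
class WavefunctionData:
    """Program-agnostic single-excitation (CIS/TDDFT-like) wavefunction data.

    ``mo_coefficients`` has AO rows and MO columns; ``fragment_of_ao`` maps
    each AO to fragment label "A" or "B"; ``amplitudes`` holds, per excited
    state, a list of ``(i, j, C)`` with i an occupied and j a virtual MO
    index (0-based, global) and C the amplitude.  ``n_occ`` is the number of
    occupied MOs.
    """

    mo_coefficients: np.ndarray
    ao_overlap: np.ndarray
    fragment_of_ao: np.ndarray
    amplitudes: list
    n_occ: int

    def __post_init__(self) -> None:
        self.mo_coefficients = np.asarray(self.mo_coefficients, dtype=float)
        self.ao_overlap = np.asarray(self.ao_overlap, dtype=float)
        self.fragment_of_ao = np.asarray(self.fragment_of_ao)
        s = self.ao_overlap
        if s.shape[0] != s.shape[1] or not np.allclose(s, s.T, atol=1e-10):
            raise ValueError("AO overlap must be square and symmetric")
        if self.mo_coefficients.shape[0] != s.shape[0]:
            raise ValueError("MO coefficient rows must match AO count")
        if self.fragment_of_ao.shape[0] != s.shape[0]:
            raise ValueError("fragment map must cover every AO")

    @property
    def n_states(self) -> int:
        return len(self.amplitudes)


@dataclass
class ExcitonIndices:
    """The two classification indices (e-) and the resulting label."""

    sumP: float
    deltaP: float
    label: str


@dataclass
class StateProperty:
    """An excited-state property used for diabatization.

    ``kind`` is ``"TDM"`` (3-vector, a.u.) or ``"ATC"`` (per-atom transition
    charges, e).
    """

    kind: str
    value: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("TDM", "ATC"):
            raise ValueError("property kind must be 'TDM' or 'ATC'")
        self.value = np.asarray(self.value, dtype=float).ravel()
        if self.kind == "TDM" and self.value.shape != (3,):
            raise ValueError("a TDM is a 3-vector")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("state property must be finite")


@dataclass
class DiabaticHamiltonian:
    """Symmetric N x N diabatic Hamiltonian; off-diagonals are couplings."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("diabatic Hamiltonian must be square")
        if np.abs(m - m.T).max() > 1e-10:
            raise ValueError("diabatic Hamiltonian must be symmetric")
        self.matrix = m

    @property
    def couplings(self) -> np.ndarray:
        """Lower-triangular off-diagonal elements J_ij, row-major order."""
        n = self.matrix.shape[0]
        return np.array([self.matrix[i, j] for i in range(n) for j in range(i)])

    @property
    def energies(self) -> np.ndarray:
        return np.diag(self.matrix)


# ---------------------------------------------------------------------------
# Mulliken fragment densities and classification indices
# ---------------------------------------------------------------------------

def mulliken_fragment_density(w: WavefunctionData, fragment: str, k: int) -> float:
    """Mulliken density of MO k resident on the given fragment (e-).

    Requires the MO to be normalized against the AO overlap; the densities
    on the two fragments of a dimer then sum to one.
    """
    c = w.mo_coefficients[:, k]
    sc = w.ao_overlap @ c
    norm = float(c @ sc)
    if abs(norm - 1.0) > 1e-8:
        raise ValueError(f"MO {k} is not normalized: <k|S|k> = {norm:.10f}")
    mask = w.fragment_of_ao == fragment
    return float(c[mask] @ sc[mask])


def _sigma(i: int, j: int) -> float:
    return 1.0 if i < j else -1.0


def exciton_indices(w: WavefunctionData, state: int, fragment: str = "A",
                    renormalize: bool = False) -> ExcitonIndices:
    """SumP and DeltaP indices of one excited state for one fragment.

    The amplitudes must satisfy sum sigma C^2 = 1; ``renormalize=True``
    rescales them instead of raising.
    """
    amps = [(int(i), int(j), float(c)) for i, j, c in w.amplitudes[state]]
    ssum = sum(_sigma(i, j) * c * c for i, j, c in amps)
    if renormalize:
        if abs(ssum) < 1e-14:
            raise ValueError("cannot renormalize: sum sigma C^2 is zero")
        scale = 1.0 / np.sqrt(abs(ssum))
        amps = [(i, j, c * scale) for i, j, c in amps]
        ssum = sum(_sigma(i, j) * c * c for i, j, c in amps)
    if abs(ssum - 1.0) > 1e-6:
        raise ValueError(f"amplitudes not normalized: sum sigma C^2 = {ssum:.8f}")
    rho: dict[int, float] = {}

    def rho_of(k: int) -> float:
        if k not in rho:
            rho[k] = mulliken_fragment_density(w, fragment, k)
        return rho[k]

    sumP = sum(_sigma(i, j) * c * c * (rho_of(j) + rho_of(i)) for i, j, c in amps)
    deltaP = sum(_sigma(i, j) * c * c * (rho_of(j) - rho_of(i)) for i, j, c in amps)
    label = classify_exciton(sumP, deltaP)
    return ExcitonIndices(float(sumP), float(deltaP), label)


def classify_exciton(sumP: float, deltaP: float, threshold: float = 0.5) -> str:
    """Label an excitation from its indices.

    Charge-transfer tests take precedence over localization tests; with the
    default 0.5 e- threshold the regions are mutually exclusive except at
    pathological corners, where CT wins.
    """
    if not (-1e-9 <= sumP <= 2 + 1e-9) or not (-1 - 1e-9 <= deltaP <= 1 + 1e-9):
        raise ValueError(f"indices out of bounds: sumP={sumP}, deltaP={deltaP}")
    if abs(deltaP - (-1.0)) < threshold:
        return "CT(A->B)"
    if abs(deltaP - 1.0) < threshold:
        return "CT(B->A)"
    if abs(sumP - 2.0) < threshold:
        return "LOC(A)"
    if abs(sumP - 0.0) < threshold:
        return "LOC(B)"
    return "DELOC"


# ---------------------------------------------------------------------------
# Couplings
# ---------------------------------------------------------------------------

def coupling_pda(mu_i, mu_j, R_i, R_j) -> float:
    """Kasha point-dipole exciton coupling, Hartree.

    J = (mu_i . mu_j) / R^3 - 3 (mu_i . R)(R . mu_j) / R^5 with
    R = R_j - R_i.  Dipoles in a.u., centroid positions in Bohr.
    """
    mu_i = np.asarray(mu_i, dtype=float).reshape(3)
    mu_j = np.asarray(mu_j, dtype=float).reshape(3)
    rij = np.asarray(R_j, dtype=float).reshape(3) - np.asarray(R_i, dtype=float).reshape(3)
    r = np.linalg.norm(rij)
    if r < 1e-12:
        raise ValueError("coincident monomer centroids")
    return float(mu_i @ mu_j / r ** 3 - 3.0 * (mu_i @ rij) * (rij @ mu_j) / r ** 5)


def coupling_atc(q_i, pos_i, q_j, pos_j, positions_in_angstrom: bool = False) -> float:
    """Atomic-transition-charge Coulomb coupling, Hartree.

    J = sum_a sum_b q_a q_b / |R_a - R_b| over the two monomers' atoms.
    Positions in Bohr by default; set ``positions_in_angstrom`` to convert.
    """
    q_i = np.asarray(q_i, dtype=float).ravel()
    q_j = np.asarray(q_j, dtype=float).ravel()
    pos_i = np.asarray(pos_i, dtype=float).reshape(len(q_i), 3)
    pos_j = np.asarray(pos_j, dtype=float).reshape(len(q_j), 3)
    if positions_in_angstrom:
        pos_i = pos_i * ANGSTROM_IN_BOHR
        pos_j = pos_j * ANGSTROM_IN_BOHR
    diff = pos_i[:, None, :] - pos_j[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    if dist.min() < 1e-10:
        raise ValueError("coincident atoms between the two monomers")
    return float(np.sum(np.outer(q_i, q_j) / dist))


def coupling_half_gap(E1: float, E2: float) -> float:
    """|J| as half the S1-S2 splitting of a (resonant) dimer."""
    if E2 < E1:
        raise ValueError("states must be ordered: E2 >= E1")
    return 0.5 * (E2 - E1)


def diabatize(E_adiabatic, props_adiabatic, props_reference) -> DiabaticHamiltonian:
    """Diabatic Hamiltonian from adiabatic energies and state properties.

    Builds the overlap matrix M_kl between the adiabatic properties and the
    isolated-monomer reference properties (plain inner products), takes its
    SVD M = U Sigma V^T, forms the optimal orthogonal adiabatic-to-diabatic
    map C = (U V^T)^T, and returns H_D = C diag(E) C^T.  The eigenvalues of
    H_D equal the input adiabatic energies (orthogonal similarity) and the
    off-diagonal elements are the exciton couplings.

    Works for any N >= 2 (e.g. trimer Hamiltonians).  The reference
    properties must be evaluated on monomers retaining their aggregate
    orientation.
    """
    energies = np.asarray(E_adiabatic, dtype=float).ravel()
    n = energies.size
    if n < 2:
        raise ValueError("diabatization needs at least two states")
    if len(props_adiabatic) != n or len(props_reference) != n:
        raise ValueError("need one property per state on both sides")
    kinds = {p.kind for p in list(props_adiabatic) + list(props_reference)}
    if len(kinds) != 1:
        raise ValueError("adiabatic and reference property kinds must match")
    M = np.array([[float(pa.value @ pr.value) for pr in props_reference]
                  for pa in props_adiabatic])
    u, sig, vt = np.linalg.svd(M)
    if sig.min() < 1e-12 * max(sig.max(), 1e-300):
        raise ValueError("property overlap matrix is rank deficient; "
                         "choose a different excited-state property")
    cmat = (u @ vt).T
    h = cmat @ np.diag(energies) @ cmat.T
    h = 0.5 * (h + h.T)
    return DiabaticHamiltonian(h)


# ---------------------------------------------------------------------------
# Exchange formats
# ---------------------------------------------------------------------------

def wavefunction_to_json(w: WavefunctionData, path) -> None:
    """Write wavefunction data to the neutral JSON exchange format."""
    payload = {
        "mo_coefficients": w.mo_coefficients.tolist(),
        "ao_overlap": w.ao_overlap.tolist(),
        "fragment_of_ao": [str(x) for x in w.fragment_of_ao],
        "n_occ": int(w.n_occ),
        "amplitudes": [[[int(i), int(j), float(c)] for i, j, c in state]
                       for state in w.amplitudes],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def wavefunction_from_json(path) -> WavefunctionData:
    with open(path) as fh:
        payload = json.load(fh)
    return WavefunctionData(
        np.array(payload["mo_coefficients"], dtype=float),
        np.array(payload["ao_overlap"], dtype=float),
        np.array(payload["fragment_of_ao"]),
        [[(int(i), int(j), float(c)) for i, j, c in state]
         for state in payload["amplitudes"]],
        int(payload["n_occ"]),
    )


def read_tdm_table(path) -> tuple[np.ndarray, list]:
    """Parse a plain-text excited-state table: ``state  E  mu_x mu_y mu_z``.

    Energies in the file's units (returned unchanged), TDM components in
    a.u.  Lines starting with ``#`` are comments.  Returns (energies,
    [StateProperty("TDM", mu), ...]) ordered by state index.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ValueError(f"malformed TDM table line: {line!r}")
            rows.append((int(fields[0]), float(fields[1]),
                         np.array([float(x) for x in fields[2:5]])))
    rows.sort(key=lambda r: r[0])
    energies = np.array([r[1] for r in rows])
    props = [StateProperty("TDM", r[2]) for r in rows]
    return energies, props
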