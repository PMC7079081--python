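"""Dimer extraction, fingerprint deduplication, and arrangement descriptors.

In a crystal the unit-cell symmetry produces groups of dimers identical up
to a rotation or reflection.  Sorting all intermolecular atom-pair distances
yields a rigid-motion-invariant fingerprint of the dimer geometry; two
dimers are equivalent when their sorted fingerprints agree to an RMSD below
a threshold (1e-4 Angstrom by default).

Each monomer's shape is summarized by an orthonormal right-handed triad of
principal (a), secondary (b), and tertiary (c) axes derived from a
least-squares plane fit and the two longest in-plane interatomic segments.
The angles (alpha, beta, gamma) between like axes of the two monomers, plus
the slip angle between the centroid-centroid axis and the tertiary axes,
classify the pair into archetypes such as face-to-face or edge-to-face.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structures import Structure, centroid, segment_molecules

__all__ = [
    "DimerRecord",
    "PrincipalAxes",
    "enumerate_dimers",
    "deduplicate_dimers",
    "fingerprint_rmsd",
    "principal_axes",
    "dimer_angles",
    "slip_angle",
    "classify_dimer",
    "characterize_dimers",
    "ClassificationThresholds",
]

DEFAULT_RMSD_TOL = 1e-4  # Angstrom


@dataclass
class PrincipalAxes:
    """Orthonormal right-handed molecular axes (a, b, c = a x b)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            setattr(self, name, v / np.linalg.norm(v))
        if max(abs(self.a @ self.b), abs(self.a @ self.c), abs(self.b @ self.c)) > 1e-8:
            raise ValueError("axes must be pairwise orthogonal")
        if np.linalg.norm(np.cross(self.a, self.b) - self.c) > 1e-8:
            raise ValueError("axes must be right-handed (c = a x b)")


@dataclass
class DimerRecord:
    """A pair of molecules in a cluster with its geometric descriptors.

    Angle fields are filled by :func:`characterize_dimers`; they are left
    ``None`` for monomers too small for an axes fit (e.g. diatomics).
    """

    mol_a: tuple
    mol_b: tuple
    centroid_a: np.ndarray
    centroid_b: np.ndarray
    centroid_distance: float
    fingerprint: np.ndarray
    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    slip: float | None = None
    archetype: str | None = None


def enumerate_dimers(cluster: Structure, metric: str = "centroid",
                     threshold: float = 10.0) -> list[DimerRecord]:
    """All unordered molecule pairs whose distance is below the threshold.

    ``metric`` selects the intermolecular distance definition:
    ``"centroid"`` (centroid-to-centroid), ``"atom-pair"`` (nearest
    intermolecular atom pair), or ``"vdw-adjusted"`` (nearest pair distance
    minus both atoms' vdW radii).
    """
    if metric not in ("centroid", "atom-pair", "vdw-adjusted"):
        raise ValueError(f"unknown dimer metric {metric!r}")
    mols = segment_molecules(cluster)
    if len(mols) < 2:
        raise ValueError("cluster must contain at least two molecules")
    pos = cluster.positions
    vdw = np.array([a.vdw_radius if a.element else 0.0 for a in cluster])
    records = []
    for ma, mb in itertools.combinations(mols, 2):
        ca, cb = centroid(cluster, ma), centroid(cluster, mb)
        dists = cdist(pos[list(ma)], pos[list(mb)])
        if metric == "centroid":
            d = float(np.linalg.norm(cb - ca))
        elif metric == "atom-pair":
            d = float(dists.min())
        else:
            adjusted = dists - vdw[list(ma)][:, None] - vdw[list(mb)][None, :]
            d = float(adjusted.min())
        if d < threshold:
            records.append(DimerRecord(ma, mb, ca, cb,
                                       float(np.linalg.norm(cb - ca)),
                                       np.sort(dists, axis=None)))
    return records


def fingerprint_rmsd(f1: np.ndarray, f2: np.ndarray) -> float:
    """RMSD of two sorted distance fingerprints (infinite if lengths differ)."""
    if f1.shape != f2.shape:
        return float("inf")
    return float(np.sqrt(np.mean((f1 - f2) ** 2)))


def deduplicate_dimers(dimers: list[DimerRecord],
                       rmsd_tol: float = DEFAULT_RMSD_TOL) -> list[DimerRecord]:
    """Keep one representative per group of symmetry-equivalent dimers.

    Greedy first-representative pass: a dimer is a duplicate when some kept
    dimer has a fingerprint of the same length within ``rmsd_tol`` RMSD.
    """
    unique: list[DimerRecord] = []
    for rec in dimers:
        if not any(fingerprint_rmsd(rec.fingerprint, kept.fingerprint) < rmsd_tol
                   for kept in unique):
            unique.append(rec)
    return unique


# ---------------------------------------------------------------------------
# Principal axes
# ---------------------------------------------------------------------------

def _ordered_pairs_by_distance(points: np.ndarray) -> list[tuple[int, int, float]]:
    """(i, j, distance) for i<j, sorted by decreasing distance, ties by (i, j)."""
    n = len(points)
    pairs = [(i, j, float(np.linalg.norm(points[j] - points[i])))
             for i in range(n) for j in range(i + 1, n)]
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    return pairs


def principal_axes(mol: Structure, ignore_elements=frozenset(),
                   long_axis_mode: bool = False) -> PrincipalAxes:
    """Characteristic axes of a (roughly planar) molecule.

    The atoms are projected onto their least-squares plane (smallest
    singular direction of the centered coordinates is the normal).  The two
    longest projected interatomic segments form a quadrilateral ABCD with
    AC > BD as diagonals and AB the longest side; the principal axis a runs
    from the midpoint of DA to the midpoint of BC and the secondary axis b
    from the midpoint of CD to that of AB.  Both are rotated symmetrically
    in their common plane (equal and opposite half-angles) until exactly
    perpendicular, and c = a x b completes the right-handed triad.

    When one atom belongs to both longest segments, B and C coincide and the
    (degenerate) quadrilateral is still valid.  With ``long_axis_mode`` the
    principal axis is simply the unit vector of the single longest
    interatomic distance and b is the in-plane perpendicular.

    ``ignore_elements`` removes extraneous atoms (e.g. hydrogens) from the
    analysis before fitting.
    """
    ignore = {e.capitalize() for e in ignore_elements}
    pts = np.array([a.position for a in mol if a.element.capitalize() not in ignore])
    if len(pts) < 3:
        raise ValueError("principal axes need at least 3 non-ignored atoms")
    center = pts.mean(axis=0)
    centered = pts - center
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-10 * max(svals[0], 1e-300):
        raise ValueError("atoms are collinear; principal axes are undefined")
    normal = vt[2]
    proj = centered - np.outer(centered @ normal, normal)

    pairs = _ordered_pairs_by_distance(proj)
    i1, j1, _ = pairs[0]  # longest: diagonal AC
    i2 = j2 = None
    for i, j, _ in pairs[1:]:
        if (i, j) != (i1, j1):
            i2, j2 = i, j
            break
    if i2 is None:
        raise ValueError("not enough distinct interatomic segments")

    if long_axis_mode:
        a_vec = proj[j1] - proj[i1]
        a_vec = a_vec / np.linalg.norm(a_vec)
        b_vec = np.cross(normal, a_vec)
        b_vec = b_vec / np.linalg.norm(b_vec)
        return PrincipalAxes(a_vec, b_vec, np.cross(a_vec, b_vec))

    shared = {i1, j1} & {i2, j2}
    if shared:
        s = shared.pop()
        A = proj[j1] if i1 == s else proj[i1]
        D = proj[j2] if i2 == s else proj[i2]
        B = C = proj[s]
    else:
        # choose the labeling (A in segment 1 endpoints, B in segment 2
        # endpoints) that makes AB the longest side; ties resolved by the
        # lexicographically smallest index pair for determinism
        best = None
        for ai, ci in ((i1, j1), (j1, i1)):
            for bi, di in ((i2, j2), (j2, i2)):
                side = float(np.linalg.norm(proj[bi] - proj[ai]))
                key = (-side, ai, bi)
                if best is None or key < best[0]:
                    best = (key, ai, bi, ci, di)
        _, ai, bi, ci, di = best
        A, B, C, D = proj[ai], proj[bi], proj[ci], proj[di]

    H = (A + B) / 2
    G = (B + C) / 2
    F = (C + D) / 2
    E = (D + A) / 2
    a_raw = G - E
    b_raw = H - F
    na, nb = np.linalg.norm(a_raw), np.linalg.norm(b_raw)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("degenerate quadrilateral: zero-length axis")
    u, v = a_raw / na, b_raw / nb
    # symmetric orthogonalization: equal-angle rotation of u and v within
    # their common plane onto the bisector frame
    s = u + v
    d = u - v
    s /= np.linalg.norm(s)
    d /= np.linalg.norm(d)
    a_vec = (s + d) / np.sqrt(2.0)
    b_vec = (s - d) / np.sqrt(2.0)
    return PrincipalAxes(a_vec, b_vec, np.cross(a_vec, b_vec))


# ---------------------------------------------------------------------------
# Pair descriptors
# ---------------------------------------------------------------------------

def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    cosv = float(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
    return float(np.degrees(np.arccos(cosv)))


def dimer_angles(ax1: PrincipalAxes, ax2: PrincipalAxes) -> tuple[float, float, float]:
    """Angles (degrees, in [0, 180]) between like axes of two monomers."""
    return (_angle_deg(ax1.a, ax2.a), _angle_deg(ax1.b, ax2.b), _angle_deg(ax1.c, ax2.c))


def slip_angle(centroid_1, centroid_2, ax1: PrincipalAxes,
               ax2: PrincipalAxes) -> float:
    """Smallest angle between the centroid-centroid axis and either tertiary axis.

    Degrees in [0, 90]; small values indicate cofacial stacking with large
    pi-pi overlap, values near 90 a fully slipped arrangement.
    """
    r = np.asarray(centroid_2, dtype=float) - np.asarray(centroid_1, dtype=float)
    norm = np.linalg.norm(r)
    if norm < 1e-12:
        raise ValueError("coincident centroids: slip angle undefined")
    r = r / norm
    angles = []
    for c in (ax1.c, ax2.c):
        ang = _angle_deg(r, c)
        angles.append(min(ang, 180.0 - ang))
    return float(min(angles))


@dataclass
class ClassificationThresholds:
    """Heuristic archetype boundaries (degrees); configurable."""

    gamma_parallel: float = 30.0
    slip_split: float = 30.0
    gamma_edge_lo: float = 60.0
    gamma_edge_hi: float = 120.0


def classify_dimer(angles, slip: float,
                   thresholds: ClassificationThresholds | None = None) -> str:
    """Archetype label from inter-axis angles and the slip angle.

    face-to-face: near-parallel molecular planes (gamma below the parallel
    threshold) with small slip; parallel-displaced: parallel planes, large
    slip; edge-to-face: gamma near 90 degrees; everything else: other.
    """
    th = thresholds or ClassificationThresholds()
    gamma = angles[2]
    gamma_fold = min(gamma, 180.0 - gamma)
    if gamma_fold < th.gamma_parallel:
        return "face-to-face" if slip < th.slip_split else "parallel-displaced"
    if th.gamma_edge_lo <= gamma <= th.gamma_edge_hi:
        return "edge-to-face"
    return "other"


def characterize_dimers(cluster: Structure, dimers: list[DimerRecord],
                        ignore_elements=frozenset(), long_axis_mode: bool = False,
                        thresholds: ClassificationThresholds | None = None
                        ) -> list[DimerRecord]:
    """Fill angle, slip, and archetype fields of dimer records in place.

    Monomers with fewer than three usable atoms are left uncharacterized
    (fields stay ``None``).
    """
    axes_cache: dict[tuple, PrincipalAxes | None] = {}

    def axes_of(mol):
        if mol not in axes_cache:
            try:
                axes_cache[mol] = principal_axes(cluster.subset(mol),
                                                 ignore_elements, long_axis_mode)
            except ValueError:
                axes_cache[mol] = None
        return axes_cache[mol]

    for rec in dimers:
        ax1, ax2 = axes_of(rec.mol_a), axes_of(rec.mol_b)
        if ax1 is None or ax2 is None:
            continue
        rec.alpha, rec.beta, rec.gamma = dimer_angles(ax1, ax2)
        rec.slip = slip_angle(rec.centroid_a, rec.centroid_b, ax1, ax2)
        rec.archetype = classify_dimer((rec.alpha, rec.beta, rec.gamma),
                                       rec.slip, thresholds)
    return dimers
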