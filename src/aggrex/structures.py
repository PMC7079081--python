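"""Core geometry containers for molecular aggregates and crystals.

The two central objects are :class:`AtomSite` — an element-labelled point in
Cartesian space carrying a partial charge and radii — and :class:`Structure`,
an ordered collection of sites with optional lattice vectors and a bonding
scheme.  On top of these, this module provides bond detection, segmentation
of an aggregate into covalently bonded molecules, supercell generation,
reconstruction of molecules split across periodic boundaries, spherical
cluster extraction from crystal data, and plain-text file I/O (XYZ, lattice
vector files, per-atom charge tables).

Coordinates are Angstrom everywhere in memory; charges are in units of the
elementary charge e.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .data import COVALENT_RADII, VDW_RADII

__all__ = [
    "ParseError",
    "AtomSite",
    "BondingScheme",
    "Structure",
    "read_xyz",
    "write_xyz",
    "read_lattice",
    "write_lattice",
    "read_charge_file",
    "write_charge_file",
    "detect_bonds",
    "segment_molecules",
    "make_supercell",
    "complete_molecules",
    "build_cluster",
    "centroid",
]

# A molecule is represented as a sorted tuple of atom indices into its parent
# Structure; functions producing them guarantee connectivity of the induced
# bond graph.
MoleculeIndexSet = tuple


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


@dataclass
class AtomSite:
    """A point in Cartesian space with physical properties attached.

    Parameters
    ----------
    element:
        Chemical symbol.  May be empty for a bare point charge, in which
        case no radii are attached.
    position:
        Cartesian position, Angstrom.
    charge:
        Partial charge, e.
    cov_radius, vdw_radius:
        Covalent / van der Waals radii in Angstrom.  Looked up from the
        built-in tables when the element is set and no value is given.
    """

    element: str = ""
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    charge: float = 0.0
    cov_radius: float | None = None
    vdw_radius: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")
        self.element = self.element.strip()
        if self.element:
            key = self.element.capitalize()
            if self.cov_radius is None:
                if key not in COVALENT_RADII:
                    raise ValueError(f"no covalent radius known for element {self.element!r}")
                self.cov_radius = COVALENT_RADII[key]
            if self.vdw_radius is None:
                if key not in VDW_RADII:
                    raise ValueError(f"no vdW radius known for element {self.element!r}")
                self.vdw_radius = VDW_RADII[key]
            if self.cov_radius <= 0 or self.vdw_radius <= 0:
                raise ValueError("radii must be positive for a labelled atom")

    def copy(self) -> "AtomSite":
        return AtomSite(self.element, self.position.copy(), self.charge,
                        self.cov_radius, self.vdw_radius)


@dataclass
class BondingScheme:
    """Definition of a bond between two sites.

    ``mode`` selects what the threshold applies to:

    - ``"center"``   — nucleus-to-nucleus distance below ``threshold``;
    - ``"covalent"`` — distance minus both covalent radii below ``threshold``
      (i.e. a slack on the touching covalent spheres);
    - ``"vdw"``      — the same with van der Waals radii.
    """

    mode: str = "covalent"
    threshold: float = 0.4

    _MODES = ("center", "covalent", "vdw")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"bonding mode must be one of {self._MODES}, got {self.mode!r}")
        if self.threshold <= 0:
            raise ValueError("bonding threshold must be positive")

    def cutoffs(self, atoms: list[AtomSite]) -> np.ndarray:
        """Pairwise distance cutoffs (N, N) under this scheme."""
        n = len(atoms)
        if self.mode == "center":
            return np.full((n, n), self.threshold)
        attr = "cov_radius" if self.mode == "covalent" else "vdw_radius"
        radii = np.array([getattr(a, attr) if a.element else 0.0 for a in atoms])
        return radii[:, None] + radii[None, :] + self.threshold


class Structure:
    """An ordered collection of :class:`AtomSite` objects.

    Optionally carries 3x3 lattice vectors (row vectors, Angstrom) and a
    :class:`BondingScheme`.  Behaves like a list of atoms for indexing and
    iteration.  Atom order is stable under every operation and file
    round-trip in this module.
    """

    def __init__(self, atoms=None, lattice=None, bonding=None, comment=""):
        self.atoms: list[AtomSite] = list(atoms) if atoms else []
        self.lattice = lattice
        self.bonding = bonding if bonding is not None else BondingScheme()
        self.comment = comment

    @property
    def lattice(self) -> np.ndarray | None:
        return self._lattice

    @lattice.setter
    def lattice(self, value) -> None:
        if value is None:
            self._lattice = None
            return
        mat = np.asarray(value, dtype=float)
        if mat.shape != (3, 3):
            raise ValueError("lattice must be a 3x3 matrix of row vectors")
        if abs(np.linalg.det(mat)) < 1e-12:
            raise ValueError("lattice matrix is singular")
        self._lattice = mat

    # list-like access ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def __getitem__(self, idx):
        return self.atoms[idx]

    def append(self, atom: AtomSite) -> None:
        self.atoms.append(atom)

    # bulk views ---------------------------------------------------------
    @property
    def positions(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    @positions.setter
    def positions(self, value) -> None:
        pos = np.asarray(value, dtype=float).reshape(len(self.atoms), 3)
        for a, p in zip(self.atoms, pos):
            a.position = p.copy()

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @charges.setter
    def charges(self, value) -> None:
        vals = np.asarray(value, dtype=float).reshape(len(self.atoms))
        for a, q in zip(self.atoms, vals):
            a.charge = float(q)

    def total_charge(self) -> float:
        return float(self.charges.sum()) if self.atoms else 0.0

    # construction helpers ----------------------------------------------
    def copy(self) -> "Structure":
        return Structure([a.copy() for a in self.atoms],
                         None if self.lattice is None else self.lattice.copy(),
                         BondingScheme(self.bonding.mode, self.bonding.threshold),
                         self.comment)

    def subset(self, indices) -> "Structure":
        """A new lattice-free Structure holding copies of the given atoms."""
        return Structure([self.atoms[i].copy() for i in indices],
                         None,
                         BondingScheme(self.bonding.mode, self.bonding.threshold),
                         self.comment)

    def translated(self, shift) -> "Structure":
        out = self.copy()
        shift = np.asarray(shift, dtype=float).reshape(3)
        for a in out.atoms:
            a.position = a.position + shift
        return out

    def cell_heights(self) -> np.ndarray:
        """Perpendicular heights of the cell along the three lattice directions."""
        if self.lattice is None:
            raise ValueError("structure has no lattice")
        vol = abs(np.linalg.det(self.lattice))
        heights = np.empty(3)
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            heights[i] = vol / np.linalg.norm(np.cross(self.lattice[j], self.lattice[k]))
        return heights

    def fractional(self) -> np.ndarray:
        if self.lattice is None:
            raise ValueError("structure has no lattice")
        return self.positions @ np.linalg.inv(self.lattice)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_xyz(path) -> Structure:
    """Read a standard XYZ file: count line, comment line, element x y z."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: line 1: malformed atom count {lines[0]!r}") from None
    comment = lines[1] if len(lines) > 1 else ""
    atoms = []
    for ln in range(2, 2 + count):
        if ln >= len(lines) or not lines[ln].split():
            raise ParseError(f"{path}: line {ln + 1}: expected {count} atom records, "
                             f"found {len(atoms)}")
        fields = lines[ln].split()
        if len(fields) < 4:
            raise ParseError(f"{path}: line {ln + 1}: expected 'element x y z'")
        try:
            pos = [float(x) for x in fields[1:4]]
        except ValueError:
            raise ParseError(f"{path}: line {ln + 1}: non-numeric coordinate") from None
        atoms.append(AtomSite(fields[0], pos))
    return Structure(atoms, comment=comment)


def write_xyz(struct: Structure, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(struct)}\n{struct.comment}\n")
        for a in struct:
            x, y, z = a.position
            fh.write(f"{a.element:<4s} {x:16.6f} {y:16.6f} {z:16.6f}\n")


def read_lattice(path) -> np.ndarray:
    """Read three lattice row vectors from a 3-line, 3-column text file (Angstrom)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.split():
                rows.append([float(x) for x in line.split()])
    mat = np.array(rows, dtype=float)
    if mat.shape != (3, 3):
        raise ParseError(f"{path}: expected 3 lines of 3 floats, got shape {mat.shape}")
    return mat


def write_lattice(lattice, path) -> None:
    np.savetxt(path, np.asarray(lattice, dtype=float), fmt="%16.10f")


def read_charge_file(path) -> Structure:
    """XYZ with a fifth per-atom column holding the partial charge (e)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: line 1: malformed atom count") from None
    comment = lines[1] if len(lines) > 1 else ""
    atoms = []
    for ln in range(2, 2 + count):
        if ln >= len(lines):
            raise ParseError(f"{path}: line {ln + 1}: truncated file")
        fields = lines[ln].split()
        if len(fields) < 5:
            raise ParseError(f"{path}: line {ln + 1}: expected 'element x y z q'")
        atoms.append(AtomSite(fields[0], [float(x) for x in fields[1:4]],
                              charge=float(fields[4])))
    return Structure(atoms, comment=comment)


def write_charge_file(struct: Structure, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(struct)}\n{struct.comment}\n")
        for a in struct:
            x, y, z = a.position
            fh.write(f"{a.element:<4s} {x:16.6f} {y:16.6f} {z:16.6f} {a.charge:14.8f}\n")


# ---------------------------------------------------------------------------
# Bonding and segmentation
# ---------------------------------------------------------------------------

def _adjacency_matrix(struct: Structure, periodic: bool = False) -> np.ndarray:
    """Boolean bond matrix under the structure's bonding scheme.

    With ``periodic=True`` distances are evaluated under the minimum-image
    convention (requires a lattice).
    """
    n = len(struct)
    if n == 0:
        return np.zeros((0, 0), dtype=bool)
    pos = struct.positions
    if periodic:
        if struct.lattice is None:
            raise ValueError("periodic bond detection requires a lattice")
        frac = struct.fractional()
        diff = frac[:, None, :] - frac[None, :, :]
        diff -= np.round(diff)
        cart = diff @ struct.lattice
        dist = np.linalg.norm(cart, axis=-1)
    else:
        dist = cdist(pos, pos)
    cut = struct.bonding.cutoffs(struct.atoms)
    adj = dist < cut
    np.fill_diagonal(adj, False)
    return adj


def detect_bonds(struct: Structure, periodic: bool = False) -> list[set]:
    """Symmetric adjacency list of bonded atom indices."""
    adj = _adjacency_matrix(struct, periodic=periodic)
    return [set(np.nonzero(row)[0].tolist()) for row in adj]


def segment_molecules(struct: Structure, periodic: bool = False) -> list[MoleculeIndexSet]:
    """Partition the atoms into covalently bonded molecules.

    Returns the connected components of the bond graph as sorted tuples of
    atom indices; every atom appears in exactly one component.
    """
    n = len(struct)
    if n == 0:
        return []
    adj = _adjacency_matrix(struct, periodic=periodic)
    ncomp, labels = connected_components(csr_matrix(adj), directed=False)
    comps: list[list[int]] = [[] for _ in range(ncomp)]
    for idx, lab in enumerate(labels):
        comps[lab].append(idx)
    # deterministic order: by smallest member index
    comps.sort(key=lambda c: c[0])
    return [tuple(c) for c in comps]


def centroid(struct: Structure, mol: MoleculeIndexSet) -> np.ndarray:
    """Unweighted mean position of the molecule's atoms."""
    if len(mol) == 0:
        raise ValueError("cannot take the centroid of an empty molecule")
    return struct.positions[list(mol)].mean(axis=0)


# ---------------------------------------------------------------------------
# Periodic operations
# ---------------------------------------------------------------------------

def make_supercell(struct: Structure, na: int, nb: int, nc: int) -> Structure:
    """Replicate the unit cell na x nb x nc times.

    Image order is lexicographic in (ia, ib, ic); within each image the
    original atom order is preserved.  The lattice rows are scaled
    accordingly and charges carried over.
    """
    if struct.lattice is None:
        raise ValueError("supercell generation requires a lattice")
    if min(na, nb, nc) < 1:
        raise ValueError("supercell multipliers must be >= 1")
    out = Structure(lattice=struct.lattice * np.array([[na], [nb], [nc]]),
                    bonding=BondingScheme(struct.bonding.mode, struct.bonding.threshold),
                    comment=struct.comment)
    for ia, ib, ic in itertools.product(range(na), range(nb), range(nc)):
        shift = np.array([ia, ib, ic], dtype=float) @ struct.lattice
        for a in struct:
            img = a.copy()
            img.position = a.position + shift
            out.append(img)
    return out


def complete_molecules(struct: Structure) -> Structure:
    """Reconstruct molecules split across periodic boundaries.

    Atoms are translated by whole lattice vectors (minimum-image growth from
    a seed atom) until every molecule's bond graph is connected without
    periodic images; each molecule is then folded so that its fractional
    centroid lies in [0, 1).

    Raises
    ------
    ValueError
        If a reconstructed bond exceeds half the shortest cell height, which
        makes the minimum-image completion ambiguous.
    """
    if struct.lattice is None:
        raise ValueError("molecule completion requires a lattice")
    out = struct.copy()
    n = len(out)
    if n == 0:
        return out
    lat = out.lattice
    inv = np.linalg.inv(lat)
    frac = out.positions @ inv
    adj = _adjacency_matrix(out, periodic=True)
    half_height = out.cell_heights().min() / 2.0

    mols = segment_molecules(out, periodic=True)
    new_frac = frac.copy()
    for mol in mols:
        seed = mol[0]
        placed = {seed}
        queue = [seed]
        while queue:
            i = queue.pop(0)
            for j in np.nonzero(adj[i])[0]:
                if j in placed:
                    continue
                shift = np.round(new_frac[j] - new_frac[i])
                new_frac[j] = new_frac[j] - shift
                bond = np.linalg.norm((new_frac[j] - new_frac[i]) @ lat)
                if bond > half_height:
                    raise ValueError(
                        "ambiguous molecule completion: bond of "
                        f"{bond:.3f} A exceeds half the shortest cell height "
                        f"({half_height:.3f} A)")
                placed.add(int(j))
                queue.append(int(j))
        cen = new_frac[list(mol)].mean(axis=0)
        new_frac[list(mol)] -= np.floor(cen)
    out.positions = new_frac @ lat
    return out


def build_cluster(struct: Structure, radius: float,
                  strict_all_atoms: bool = False) -> Structure:
    """Extract a finite cluster of whole molecules around the origin.

    Enough periodic images are generated to cover a sphere of the given
    radius.  By default a molecule is included when *any* of its atoms lies
    within ``radius`` of the origin and is then kept whole (the embedded-
    cluster convention); ``strict_all_atoms=True`` requires all atoms within
    the radius.  Duplicate images (identical up to 1e-6 Angstrom) are kept
    once.  The returned structure has no lattice.
    """
    if radius <= 0:
        raise ValueError("cluster radius must be positive")
    cell = complete_molecules(struct)
    lat = cell.lattice
    mols = segment_molecules(cell)
    mol_pos = [cell.positions[list(m)] for m in mols]
    span = max(np.linalg.norm(p - p.mean(axis=0), axis=1).max() if len(p) > 1 else 0.0
               for p in mol_pos)
    heights = cell.cell_heights()
    nimg = np.ceil((radius + span) / heights).astype(int) + 1

    out = Structure(bonding=BondingScheme(cell.bonding.mode, cell.bonding.threshold),
                    comment=f"cluster r={radius} A")
    seen: set = set()
    for img in itertools.product(*(range(-k, k + 1) for k in nimg)):
        shift = np.array(img, dtype=float) @ lat
        for m, pos in zip(mols, mol_pos):
            moved = pos + shift
            dist = np.linalg.norm(moved, axis=1)
            ok = dist.max() <= radius if strict_all_atoms else dist.min() <= radius
            if not ok:
                continue
            key = (len(m), tuple(np.round(moved / 1e-6).astype(np.int64).ravel()))
            if key in seen:
                continue
            seen.add(key)
            for idx, p in zip(m, moved):
                a = cell.atoms[idx].copy()
                a.position = p
                out.append(a)
    return out
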