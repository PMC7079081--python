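"""Grid-based Voronoi and van der Waals volumes for molecules in aggregate.

A voxel belongs to the Voronoi volume of a molecule when the atom it is
nearest to — under a distance metric scaled by each atom's vdW radius,
``d(p, a) = |p - r_a| / r_vdw(a)`` — belongs to that molecule.  The scaled
metric assigns more space to large atoms (oxygen) than to small ones
(hydrogen).  The Voronoi volume V_V is compared with the volume of the
union of the molecule's vdW spheres (intersections counted once), V_vdW,
through the volumetric packing index Vi = V_V / V_vdW: a normalized
indication of how tightly the environment packs around the molecule.

All volumes are obtained by voxel counting on a common bounding grid built
from the whole cluster, so per-molecule Voronoi volumes partition the grid
volume exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .grids import VolumetricGrid
from .structures import Structure

__all__ = [
    "VoronoiResult",
    "voronoi_volume",
    "vdw_volume",
    "volumetric_index",
    "voxel_owners",
]

DEFAULT_SPACING = 0.2  # Angstrom
DEFAULT_PADDING = 2.0  # Angstrom beyond the largest vdW sphere


@dataclass
class VoronoiResult:
    """Volumes (cubic Angstrom) and occupancy grids for one molecule."""

    V_V: float
    V_vdW: float
    V_union: float
    Vi: float
    interior: bool
    grids: dict


def _grid_geometry(cluster: Structure, spacing: float, padding: float):
    pos = cluster.positions
    radii = np.array([a.vdw_radius if a.element else 0.0 for a in cluster])
    pad = radii.max() + padding
    lo = pos.min(axis=0) - pad
    hi = pos.max(axis=0) + pad
    counts = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    return lo, counts


def _volume_atoms(cluster: Structure):
    """Indices, positions, and vdW radii of labelled atoms (bare charges excluded)."""
    idx = [i for i, a in enumerate(cluster) if a.element]
    if not idx:
        raise ValueError("cluster has no labelled atoms")
    pos = cluster.positions[idx]
    radii = np.array([cluster.atoms[i].vdw_radius for i in idx])
    return np.array(idx), pos, radii


def voxel_owners(cluster: Structure, spacing: float = DEFAULT_SPACING,
                 padding: float = DEFAULT_PADDING) -> tuple[np.ndarray, np.ndarray]:
    """Assign every voxel of the cluster bounding grid to its nearest atom.

    Nearness uses the vdW-scaled metric; equidistant voxels go to the lowest
    atom index, which keeps the assignment deterministic.  Returns the owner
    array (atom indices into the cluster, shape = grid counts) and the grid
    origin.  Bare point charges never own voxels.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    idx, apos, radii = _volume_atoms(cluster)
    origin, counts = _grid_geometry(cluster, spacing, padding)
    ys = origin[1] + (np.arange(counts[1]) + 0.5) * spacing
    zs = origin[2] + (np.arange(counts[2]) + 0.5) * spacing
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    owners = np.empty(tuple(counts), dtype=np.int32)
    for ix in range(counts[0]):
        x = origin[0] + (ix + 0.5) * spacing
        pts = np.column_stack([np.full(yy.size, x), yy.ravel(), zz.ravel()])
        scaled = cdist(pts, apos) / radii[None, :]
        owners[ix] = idx[np.argmin(scaled, axis=1)].reshape(counts[1], counts[2])
    return owners, origin


def voronoi_volume(cluster: Structure, target, spacing: float = DEFAULT_SPACING,
                   padding: float = DEFAULT_PADDING,
                   keep_grids: bool = True) -> VoronoiResult:
    """Voronoi, vdW-union, and combined volumes of one molecule in a cluster.

    ``target`` is a molecule index set (atom indices into ``cluster``).  The
    grid is built from the whole cluster, so calling this for every molecule
    of the same cluster partitions the total grid volume.  A molecule whose
    Voronoi region touches the grid boundary is box-truncated; the result
    then carries ``interior=False``.
    """
    target = tuple(target)
    if len(target) == 0:
        raise ValueError("target molecule is empty")
    if max(target) >= len(cluster) or min(target) < 0:
        raise ValueError("target indices outside the cluster")
    owners, origin = voxel_owners(cluster, spacing, padding)
    counts = owners.shape
    target_set = set(target)
    in_voro = np.isin(owners, list(target_set))

    # vdW occupancy of the target atoms only
    tpos = cluster.positions[list(target)]
    tradii = np.array([cluster.atoms[i].vdw_radius if cluster.atoms[i].element else 0.0
                       for i in target])
    labelled = tradii > 0
    ys = origin[1] + (np.arange(counts[1]) + 0.5) * spacing
    zs = origin[2] + (np.arange(counts[2]) + 0.5) * spacing
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    in_vdw = np.zeros(counts, dtype=bool)
    if labelled.any():
        p = tpos[labelled]
        r = tradii[labelled]
        for ix in range(counts[0]):
            x = origin[0] + (ix + 0.5) * spacing
            pts = np.column_stack([np.full(yy.size, x), yy.ravel(), zz.ravel()])
            inside = (cdist(pts, p) < r[None, :]).any(axis=1)
            in_vdw[ix] = inside.reshape(counts[1], counts[2])

    vox = spacing ** 3
    union = in_voro | in_vdw
    boundary = np.zeros(counts, dtype=bool)
    boundary[0], boundary[-1] = True, True
    boundary[:, 0], boundary[:, -1] = True, True
    boundary[:, :, 0], boundary[:, :, -1] = True, True
    interior = not bool((in_voro & boundary).any())

    V_V = float(in_voro.sum() * vox)
    V_vdW = float(in_vdw.sum() * vox)
    V_union = float(union.sum() * vox)
    grids = {}
    if keep_grids:
        axes = np.eye(3) * spacing
        grids = {
            "voro": VolumetricGrid(origin, axes, counts, in_voro.astype(float)),
            "vdw": VolumetricGrid(origin, axes, counts, in_vdw.astype(float)),
            "union": VolumetricGrid(origin, axes, counts, union.astype(float)),
        }
    vi = V_V / V_vdW if V_vdW > 0 else float("nan")
    return VoronoiResult(V_V, V_vdW, V_union, vi, interior, grids)


def vdw_volume(mol: Structure, spacing: float = DEFAULT_SPACING,
               padding: float = DEFAULT_PADDING) -> float:
    """Volume of the union of the molecule's vdW spheres, cubic Angstrom.

    Grid-occupancy measure: intersections are naturally counted once.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    _, pos, radii = _volume_atoms(mol)
    pad = radii.max() + padding
    lo = pos.min(axis=0) - pad
    hi = pos.max(axis=0) + pad
    counts = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    ys = lo[1] + (np.arange(counts[1]) + 0.5) * spacing
    zs = lo[2] + (np.arange(counts[2]) + 0.5) * spacing
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    inside_count = 0
    for ix in range(counts[0]):
        x = lo[0] + (ix + 0.5) * spacing
        pts = np.column_stack([np.full(yy.size, x), yy.ravel(), zz.ravel()])
        inside_count += int((cdist(pts, pos) < radii[None, :]).any(axis=1).sum())
    return inside_count * spacing ** 3


def volumetric_index(V_V: float, V_vdW: float) -> float:
    """Packing index Vi = V_V / V_vdW (dimensionless)."""
    if V_vdW <= 0:
        raise ValueError("vdW volume must be positive")
    return V_V / V_vdW
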