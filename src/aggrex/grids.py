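"""Volumetric grids and Gaussian cube file I/O.

Grids are stored in Angstrom in memory; cube files are written in Bohr as
the format convention requires, with voxel values in z-fastest order, six
per line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ANGSTROM_IN_BOHR, ATOMIC_NUMBERS, BOHR_IN_ANGSTROM, SYMBOL_OF_NUMBER
from .structures import AtomSite, Structure

__all__ = ["VolumetricGrid", "write_cube", "read_cube"]


@dataclass
class VolumetricGrid:
    """A scalar field sampled on a parallelepiped voxel grid.

    ``origin`` is the corner of the first voxel, ``axes`` holds the three
    voxel edge vectors as rows (Angstrom), ``counts`` the voxel counts and
    ``values`` the scalars with shape ``counts``.
    """

    origin: np.ndarray
    axes: np.ndarray
    counts: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.counts = tuple(int(c) for c in self.counts)
        if min(self.counts) < 1:
            raise ValueError("voxel counts must be positive")
        if self.voxel_volume <= 0:
            raise ValueError("voxel volume must be positive")
        self.values = np.asarray(self.values, dtype=float).reshape(self.counts)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cubic Angstrom."""
        return float(abs(np.linalg.det(self.axes)))

    def integrate(self) -> float:
        """Sum of values times the voxel volume."""
        return float(self.values.sum() * self.voxel_volume)


def write_cube(grid: VolumetricGrid, struct: Structure, path) -> None:
    """Write a Gaussian cube file (lengths converted to Bohr)."""
    if grid.values.shape != grid.counts:
        raise ValueError("grid values do not match the voxel counts")
    with open(path, "w") as fh:
        fh.write("aggrex volumetric data\n")
        fh.write(f"{struct.comment or 'cube'}\n")
        ox, oy, oz = grid.origin * ANGSTROM_IN_BOHR
        fh.write(f"{len(struct):5d} {ox:12.6f} {oy:12.6f} {oz:12.6f}\n")
        for count, axis in zip(grid.counts, grid.axes):
            ax = axis * ANGSTROM_IN_BOHR
            fh.write(f"{count:5d} {ax[0]:12.6f} {ax[1]:12.6f} {ax[2]:12.6f}\n")
        for a in struct:
            z = ATOMIC_NUMBERS.get(a.element.capitalize(), 0)
            x, y, zz = a.position * ANGSTROM_IN_BOHR
            fh.write(f"{z:5d} {float(z):12.6f} {x:12.6f} {y:12.6f} {zz:12.6f}\n")
        flat = grid.values.reshape(-1)  # z fastest for C-ordered (nx, ny, nz)
        for start in range(0, flat.size, 6):
            chunk = flat[start:start + 6]
            fh.write("".join(f"{v:13.5E}" for v in chunk) + "\n")


def read_cube(path) -> tuple[VolumetricGrid, Structure]:
    """Read a Gaussian cube file back into Angstrom units."""
    with open(path) as fh:
        lines = fh.read().split("\n")
    natoms_fields = lines[2].split()
    natoms = int(natoms_fields[0])
    origin = np.array([float(x) for x in natoms_fields[1:4]]) * BOHR_IN_ANGSTROM
    counts = []
    axes = []
    for i in range(3):
        fields = lines[3 + i].split()
        counts.append(int(fields[0]))
        axes.append([float(x) * BOHR_IN_ANGSTROM for x in fields[1:4]])
    atoms = []
    for i in range(natoms):
        fields = lines[6 + i].split()
        z = int(fields[0])
        pos = np.array([float(x) for x in fields[2:5]]) * BOHR_IN_ANGSTROM
        atoms.append(AtomSite(SYMBOL_OF_NUMBER.get(z, ""), pos))
    values = np.array(" ".join(lines[6 + natoms:]).split(), dtype=float)
    grid = VolumetricGrid(origin, axes, counts, values.reshape(counts))
    return grid, Structure(atoms)
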