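"""From a unit cell to a finite cluster of whole molecules.

Builds a toy herringbone crystal of diatomics, replicates it as a
supercell, and extracts a spherical cluster around the origin.
"""

from aggrex.fixtures import ToyCrystalSpec, make_toy_crystal
from aggrex.structures import build_cluster, make_supercell, segment_molecules

cell = make_toy_crystal(ToyCrystalSpec("herringbone-diatomic", a=4.0, b=4.0, c=6.0))
print(f"unit cell: {len(cell)} atoms, "
      f"{len(segment_molecules(cell, periodic=True))} molecules")

sup = make_supercell(cell, 2, 2, 2)
print(f"2x2x2 supercell: {len(sup)} atoms")

cluster = build_cluster(cell, radius=8.0)
mols = segment_molecules(cluster)
print(f"cluster within 8 A of the origin: {len(cluster)} atoms in "
      f"{len(mols)} whole molecules")
# Every molecule is kept whole: each diatomic keeps its 1.1 A bond even when
# its lattice image straddled the cell boundary.
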