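"""Voronoi packing volumes and the volumetric index.

Two methanol molecules 4 A apart: each molecule's Voronoi volume (space
closer to it than to its neighbor, under the vdW-scaled metric) is compared
with its own vdW union volume through Vi = V_V / V_vdW.  Vi near 1 means
tight packing; large Vi means the molecule has room around it.
"""

from aggrex.fixtures import make_methanol
from aggrex.structures import Structure
from aggrex.volumetrics import voronoi_volume

methanol = make_methanol()
cluster = Structure([a.copy() for a in methanol]
                    + [a.copy() for a in methanol.translated([4.0, 0, 0])],
                    bonding=methanol.bonding)

for name, mol in (("left", range(6)), ("right", range(6, 12))):
    res = voronoi_volume(cluster, tuple(mol), spacing=0.3, keep_grids=False)
    print(f"{name} molecule: V_V = {res.V_V:7.1f} A^3, "
          f"V_vdW = {res.V_vdW:5.1f} A^3, Vi = {res.Vi:.2f}"
          + ("" if res.interior else "  (touches the box: surface molecule)"))
# Both molecules sit on the cluster surface, so their Voronoi volumes are
# box-truncated; in a real crystal cluster interior molecules have Vi ~ 1-2.
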