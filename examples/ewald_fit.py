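"""Madelung potential of a rocksalt toy and a fitted finite charge array.

The Ewald sum gives the exact lattice potential; a finite neutral,
dipole-free array of ~1000 point charges is then fitted to reproduce it at
the central sites, which is what embeds a quantum region in the crystal's
electrostatics.
"""

import numpy as np

from aggrex.data import BOHR_IN_ANGSTROM
from aggrex.ewald_embedding import ewald_potential, fit_ewald_charges
from aggrex.fixtures import ToyCrystalSpec, make_toy_crystal

cell = make_toy_crystal(ToyCrystalSpec("rocksalt", a=2 * BOHR_IN_ANGSTROM))
site = cell.positions[0]
v = ewald_potential(cell, site)
print(f"Ewald potential at a cation site: {v:.6f} a.u. "
      "(the rocksalt Madelung constant, -1.747565)")

inner = cell.subset(range(len(cell)))
array = fit_ewald_charges(cell, inner, n_charges=1000)
sites = inner.positions
resid = np.abs(np.atleast_1d(array.potential(sites))
               - np.atleast_1d(ewald_potential(cell, sites))).max()
print(f"fitted array: {len(array)} charges, total {array.charges.sum():+.2e} e, "
      f"|dipole| {np.linalg.norm(array.charges @ array.positions):.2e}")
print(f"worst potential residual at the 8 inner sites: {resid:.2e} a.u.")
# The array reproduces the infinite crystal's potential inside the cluster
# while remaining strictly neutral and dipole-free.
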