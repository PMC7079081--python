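"""Classifying excitations on a two-fragment model.

SumP measures how much of the transition density lives on fragment A
(0 to 2 e-); DeltaP measures net charge transferred (-1 to +1 e-).
Three constructed wavefunctions hit the three regimes.
"""

from aggrex.exciton import exciton_indices
from aggrex.fixtures import random_cis_wavefunction

cases = [
    ("A-localized occ -> A-localized vir", dict(single_excitation=(0, 4))),
    ("A-localized occ -> B-localized vir", dict(single_excitation=(0, 6))),
    ("random delocalized amplitudes", {}),
]
for label, kwargs in cases:
    w = random_cis_wavefunction(2, 2, 2, 2, seed=0,
                                localized="single_excitation" in kwargs, **kwargs)
    idx = exciton_indices(w, state=0, fragment="A")
    print(f"{label:38s} SumP = {idx.sumP:6.3f} e-, DeltaP = {idx.deltaP:6.3f} e-"
          f"  ->  {idx.label}")
# The first is a Frenkel exciton confined to A, the second a full A->B
# charge transfer; the random case usually lands in DELOC territory.
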