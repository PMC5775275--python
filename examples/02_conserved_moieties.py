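"""Conservation-law analysis of the reaction network.

Computes the left null space of the stoichiometry matrix — every vector v
with v·S = 0 defines a weighted concentration sum that stays constant along
any trajectory.  The aspartate pool (Asp + intermediate + Asn) and the total
enzyme pool are the two laws that explain why the products plateau: once the
free aspartate is consumed, asparagine production must stop.
"""

import numpy as np

from asnkin import build_asn_network, conserved_moieties, stoichiometry_matrix

net = build_asn_network()
S = stoichiometry_matrix(net)
C = conserved_moieties(net)
dyn = net.dynamic_species

print(f"stoichiometry matrix: {S.shape[0]} dynamic species x {S.shape[1]} reactions")
print(f"{C.shape[0]} independent conservation laws:\n")
for law in C:
    terms = " + ".join(
        (f"{w}*{s}" if abs(w) != 1 else s) if w > 0 else f"({w}*{s})"
        for w, s in zip(law, dyn) if w != 0
    )
    print(f"  {terms} = constant")
assert (C @ S == 0).all()
print("\nall laws annihilate the stoichiometry matrix (v . S = 0)")
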