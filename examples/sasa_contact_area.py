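"""Shrake-Rupley SASA and the SASA-difference contact area on a toy dimer.

The contact area between groups A and B is (SASA_A + SASA_B − SASA_AB)/2:
half the surface buried when the two are brought together.
"""

import math

from memtether.structio import Atom, AtomIndexSet, Structure
from memtether.surface import contact_area, sasa

atoms = [
    Atom(i + 1, "C", "C", "UNK", i + 1, "A", pos)
    for i, pos in enumerate(
        [(0.0, 0, 0), (1.8, 0, 0), (0.9, 1.6, 0),   # group A: small trimer
         (0.9, -3.2, 0), (2.7, -3.2, 0)]            # group B: dimer below
    )
]
s = Structure(atoms)
group_a = AtomIndexSet((0, 1, 2), "A")
group_b = AtomIndexSet((3, 4), "B")

iso = 4 * math.pi * (1.70 + 1.4) ** 2
print(f"isolated carbon SASA (probe 1.4 A): {iso:.2f} A^2 analytic")
print(f"computed single-atom SASA:          "
      f"{sasa(s, s.coords, AtomIndexSet((0,), 'one')).total:.2f} A^2")

sa = sasa(s, s.coords, group_a).total
sb = sasa(s, s.coords, group_b).total
area = contact_area(s, s.coords, group_a, group_b)
print(f"SASA(A) = {sa:.1f} A^2, SASA(B) = {sb:.1f} A^2")
print(f"contact area A-B = {area:.1f} A^2 "
      "(one face of the buried interface)")
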