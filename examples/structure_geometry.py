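"""Geometric readouts on a structure: termini distance, burial, hydrophobic runs.

Builds a tiny synthetic two-chain model: chain A is a straight C-alpha trace
whose first and last residues are 128 A apart (the extended-conformation
regime); chain B packs against residue 5 of chain A and buries it.  A
sequence scan then locates a stretch of eight consecutive hydrophobic
residues of the kind that marks a hydrophobic binding interface.
"""

import numpy as np
import biotite.structure as struc

from neuroquant.structure import (
    StructureModel,
    fibonacci_sphere,
    find_hydrophobic_runs,
    residue_burial,
    termini_distance,
)

# chain A: 9 CA atoms along z, 16 A apart -> termini 128 A = 12.8 nm
n_a = 9
coords_a = np.column_stack([np.zeros(n_a), np.zeros(n_a), np.arange(n_a) * 16.0])
# chain B: a shell of atoms caging residue 5 of chain A
cage = fibonacci_sphere(40) * 4.0 + coords_a[4]

coords = np.vstack([coords_a, cage])
arr = struc.AtomArray(len(coords))
arr.coord = coords
arr.element = np.array(["C"] * len(coords))
arr.chain_id = np.array(["A"] * n_a + ["B"] * 40)
arr.res_id = np.concatenate([np.arange(1, n_a + 1), np.arange(1, 41)])
arr.res_name = np.array(["ALA"] * len(coords))
arr.atom_name = np.array(["CA"] * len(coords))
model = StructureModel(arr, coords)

print(f"chain A termini distance: {termini_distance(model, 'A'):.2f} nm "
      "(too far for Förster transfer at R0 = 5 nm)")

burial = residue_burial(model, "A", 5, partner_chains=["B"])
print(f"residue A/5 SASA alone {burial['sasa_alone']:.1f} A^2, "
      f"in complex {burial['sasa_complex']:.1f} A^2 "
      f"(relative accessibility {burial['relative_complex']:.3f}: "
      "occluded by the partner chain)")

seq = "MKTSS" + "QQRKN" * 3 + "AVLILMVI" + "SSRKQ" * 2
runs = find_hydrophobic_runs(seq, min_len=8)
for r in runs:
    print(f"hydrophobic run {r.residues} at positions {r.start}-{r.end} "
          f"(length {r.length}): candidate binding interface")
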