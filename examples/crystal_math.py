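"""Crystal-cell arithmetic and packing expansion.

Evaluates the triclinic cell volume and the Matthews/solvent relation for
the deposited spin-labelled azurin crystal form (P1, four molecules per
asymmetric unit), then demonstrates lattice-translation packing expansion
on a small synthetic cell.
"""

import numpy as np

from spinlabel import CrystalCell, cell_volume, expand_packing, matthews_solvent
from spinlabel.structure import Atom, Chain, Residue, StructureModel

cell = CrystalCell(37.0, 53.7, 73.2, 74.4, 89.3, 83.4)
print(f"triclinic cell volume     : {cell_volume(cell):10.0f} A^3")
print(f"solvent content (Vm=2.41) : {matthews_solvent(2.41):10.1f} %")

# one atom in a 10 A cubic P1 cell: neighbours within 12 A are exactly the
# six face-adjacent lattice images
atom = Atom("C1", "C", np.zeros(3))
model = StructureModel([Chain("A", [Residue(1, "UNK", [atom])])],
                       CrystalCell(10, 10, 10, 90, 90, 90),
                       [(np.eye(3), np.zeros(3))])
out = expand_packing(model, "A", 12.0)
print(f"packing images within 12 A: {len(out.chains) - 1:10d}")
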