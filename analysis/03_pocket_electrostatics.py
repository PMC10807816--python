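#!/usr/bin/env python
"""Electrostatic potential and bond-projected field in the pseudo-pocket.

Treats every charged atom outside the pseudo-ligand as the environment,
maps the Coulomb potential on a grid spanning the ligand, and projects the
environment field onto each consecutive ligand C–C bond — the synthetic
analogue of asking how the binding pocket polarizes bonds along a
chromophore's polyene chain.

Writes results/pocket_potential.dx and results/bond_fields.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from prshift import PointChargeSet, bond_projected_field, potential_grid, read_structure
from prshift.electrostatics import labels_for_residues, write_dx

ROOT = Path(__file__).resolve().parents[1] / "results"
structure = read_structure(ROOT / "inputs" / "helix.pdb", ROOT / "inputs" / "helix_charges.tsv")
ligand = next(r for r in structure.residues if r.is_ligand)
charges = PointChargeSet.from_structure(structure)
ligand_labels = labels_for_residues(structure, [ligand.index])

# potential on a grid spanning the ligand, environment charges only
lig_xyz = ligand.coords_array()
lo, hi = lig_xyz.min(axis=0) - 2.0, lig_xyz.max(axis=0) + 2.0
spacing = 1.0
vals, axes = potential_grid(charges, (lo, hi), spacing, exclusion=ligand_labels)
write_dx(vals, lo, spacing, ROOT / "pocket_potential.dx")
finite = vals[np.isfinite(vals)]
print(f"potential grid {vals.shape}, {finite.size} unmasked nodes, "
      f"range [{finite.min():+.2f}, {finite.max():+.2f}] V -> pocket_potential.dx")

# field projected on each consecutive ligand C-C bond
carbons = [a.name for a in ligand.atoms if a.element == "C"]
rows = []
for a, b in zip(carbons, carbons[1:]):
    res = bond_projected_field(
        structure, (ligand.index, a), (ligand.index, b), charges, exclusion=ligand_labels
    )
    rows.append(
        {
            "bond": f"{a}-{b}",
            "projected_MV_per_cm": res.projected_magnitude,
            "magnitude_MV_per_cm": res.magnitude,
            "potential_V": res.potential,
        }
    )
df = pd.DataFrame(rows)
df.to_csv(ROOT / "bond_fields.tsv", sep="\t", index=False)
print(df.to_string(index=False, float_format=lambda v: f"{v:+.3f}"))
print("bond-projected environment fields -> bond_fields.tsv")
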