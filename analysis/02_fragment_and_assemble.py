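#!/usr/bin/env python
"""Fragment the synthetic structure and assemble its shift table.

Reads the structure written by 01_simulate_inputs.py, builds one
core+buffer fragment per residue (the chromophore pseudo-residue included),
caps severed bonds, embeds the remaining atoms as point charges, and
assembles the per-protein shift table from core-only mock-engine tensors.
Confirms the assembly equals a whole-system evaluation, the bookkeeping
guarantee the fragment scheme rests on.

Writes results/fragments/fragments.json and results/shifts_assembled.tsv.
"""

import json
from pathlib import Path

import numpy as np

from prshift import (
    FragmentationParams,
    MockShieldingEngine,
    assemble_shifts,
    fragment_all,
    read_structure,
    whole_system_shifts,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
structure = read_structure(ROOT / "inputs" / "helix.pdb", ROOT / "inputs" / "helix_charges.tsv")
# re-declare the chromophore-anchor link lost in plain PDB (no CONECT emitted)
structure.links.append(((21, "C1"), (10, "CB")))

params = FragmentationParams()
fragments = fragment_all(structure, params, include_ligands=True)

sizes = [len(f.buffer_indices) for f in fragments]
caps = [len(f.caps) for f in fragments]
print(f"{len(fragments)} fragments; buffer sizes {min(sizes)}-{max(sizes)} "
      f"(median {int(np.median(sizes))}), {min(caps)}-{max(caps)} caps each")

frag_dir = ROOT / "fragments"
frag_dir.mkdir(parents=True, exist_ok=True)
(frag_dir / "fragments.json").write_text(
    json.dumps([f.to_dict() for f in fragments], indent=1)
)

engine = MockShieldingEngine(locality_radius=3.0)
assembled = assemble_shifts(fragments, engine)
assembled.write(ROOT / "shifts_assembled.tsv")

whole = whole_system_shifts(structure, engine)
max_err = max(abs(assembled[k].iso - whole[k].iso) for k in assembled.keys())
print(f"assembled {len(assembled)} sites -> shifts_assembled.tsv")
print(f"assembly vs whole-system max |error| = {max_err:.2e} ppm "
      "(core-only extraction is exact at this locality radius)")
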