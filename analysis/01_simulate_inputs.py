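#!/usr/bin/env python
"""Generate the synthetic study inputs every later stage consumes.

Writes, under results/inputs/:
  * a 20-residue helical structure with a pseudo-ligand chain (PDB) and its
    per-atom charge table (TSV),
  * a 400-sequence two-group family alignment with the diagnostic Leu/Gln
    column at position 105 and a planted covarying pair (aligned FASTA),
    plus the ground-truth group labels and per-column targets,
  * paired green/blue shift tables whose per-residue difference magnitude
    follows the family conservation profile (TSV), with the true deltas.
"""

import json
from pathlib import Path

from prshift import (
    SyntheticSpec,
    delta_shifts,
    entropy_conservation,
    make_msa,
    make_shift_pair,
    make_structure,
    write_structure,
)
from prshift.structure import write_charge_table

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)

# --- structure -------------------------------------------------------------
spec = SyntheticSpec(seed=SEED, n_residues=20, with_ligand=True)
structure = make_structure(spec)
write_structure(structure, OUT / "helix.pdb")
write_charge_table(structure, OUT / "helix_charges.tsv")
print(f"structure: {len(structure)} residues, {structure.n_atoms} atoms, "
      f"net charge {structure.total_charge():+.3f} e -> helix.pdb")

# --- family alignment ------------------------------------------------------
mspec = SyntheticSpec(
    seed=SEED,
    n_sequences=400,
    alignment_length=120,
    diagnostic_position=105,
    covarying_pairs=[(40, 80, 1.0)],
)
msa, labels, column_truth = make_msa(mspec)
msa.write_fasta(OUT / "family.fasta")
(OUT / "family_labels.json").write_text(json.dumps(labels, indent=0))
column_truth.to_csv(OUT / "family_column_truth.tsv", sep="\t")
n_green = sum(v == "green" for v in labels.values())
print(f"alignment: {msa.n_sequences} sequences x {msa.n_columns} columns, "
      f"{n_green} green / {msa.n_sequences - n_green} blue, "
      f"diagnostic column at position {mspec.diagnostic_position} -> family.fasta")

# --- paired shift tables ---------------------------------------------------
bits = entropy_conservation(msa)["conservation"]
conservation = {
    r.index: float(bits.iloc[r.index - 1]) for r in structure.residues if not r.is_ligand
}
green, blue, truth = make_shift_pair(structure, spec, conservation)
green.write(OUT / "shifts_green.tsv")
blue.write(OUT / "shifts_blue.tsv")
truth.to_csv(OUT / "shift_truth.tsv", sep="\t")
n_delta = sum(r.delta_iso != 0 for r in delta_shifts(green, blue))
print(f"shift tables: {len(green)} sites each, {n_delta} perturbed CA sites "
      f"(sigma = {spec.shift_noise_sigma} ppm, slope = {spec.effect_slope} ppm/bit) "
      "-> shifts_green.tsv / shifts_blue.tsv")
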