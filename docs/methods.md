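# Methods

`prshift` re-implements, at desk scale, the computational machinery used to
dissect the green/blue color switch in proteorhodopsins: per-residue
fragmentation with electrostatic embedding for chemical-shift prediction,
chemical-shift-anisotropy (CSA) bookkeeping, point-charge electrostatics in
the chromophore pocket, shift-guided ranking of candidate structural models,
and the sequence-family conservation and covariation analysis that connects
shift perturbations to evolutionary conservation.  No quantum chemistry is
performed: the quantum shielding engine is an interchangeable contract, and a
deterministic local mock engine makes every stage testable end to end.

## Fragmentation model

Each residue in turn is a *core* region.  Its *buffer* is the union of four
criteria:

1. sequence neighbours within ±`seq_window` positions on the same chain
   (default 2, clipped at termini);
2. non-neighbouring residues with any atom closer than `r_any` = 4.0 Å to
   any core atom;
3. non-neighbouring residues with a hydrogen closer than `r_hh` = 3.0 Å to a
   core hydrogen;
4. non-neighbouring residues with an aromatic-ring heavy atom closer than
   `r_arom` = 5.0 Å to any core atom.

Core plus buffer form the quantum region; the rest of the structure enters
as fixed point charges at atom positions (electrostatic embedding).  Charges
are consumed, never derived: they come from a user-supplied per-atom table
(e.g. a force-field or polarized charge model).  Covalent bonds crossing the
boundary — peptide C–N bonds and explicitly declared links such as a
chromophore–lysine bond — are capped by hydrogens placed on the severed bond
line, 1.09 Å from the retained atom, and the replaced atom's point charge is
deleted so it is not double counted.  Whether boundary charges should
instead be redistributed is genuinely open; the delete-replaced-atom-only
choice is recorded in the fragment serialization metadata.  Criterion (2)
counts all atoms, hydrogens included (a `mode` parameter exposes heavy-only
behaviour); note that under the defaults criterion (3) is then subsumed by
criterion (2) and only becomes active when `r_any` is reduced.

Ring-atom sets default to the Phe/Tyr (6 carbons), Trp (9 heavy atoms, both
rings) and His (5 atoms) PDB names and are overridable per call, e.g. to
declare a ligand's ring.  Alternate conformations reduce to the
highest-occupancy conformer.  Hydrogen-free structures are allowed;
criterion (3) simply never fires.  A ligand such as the
retinal–Schiff-base–Cε unit is one pseudo-residue that may itself serve as a
core (`include_ligands=True`); it has no sequence neighbours, so only the
distance criteria recruit its buffer.

Neighbour searches use a KD-tree, but every tree hit is confirmed with the
same strict `<` comparison the exhaustive scan uses, so the accelerated and
exhaustive paths agree exactly, not just approximately.  Buffers are
monotone in all three radii by construction.

## Shifts, referencing and CSA conventions

Engines return one 3×3 shielding tensor σ per quantum-region atom.  When
the protein-wide table is assembled, only tensors of atoms in the fragment's
*core* are retained; buffer-atom tensors are discarded.  Shieldings become
shifts via δ = σ_ref − σ with per-nucleus reference shieldings; the shipped
defaults are placeholders on a plausible scale and must be calibrated before
any absolute comparison with experiment.  CSA principal values are the
eigenvalues of the symmetrized shift tensor ordered δ11 ≥ δ22 ≥ δ33
(largest = least shielded).  Published tables rarely state an ordering
convention, so this one is fixed here and written into outputs.  Shift
differences Δδ are blue − green on the key intersection of two tables;
missing keys are dropped with a warning, never imputed, because experimental
NMR tables are sparse.

### The mock shielding engine

The test double is deterministic and strictly local: the tensor of a target
atom is a per-element baseline plus, for every source within radius R,

    S_src · (1 − r/R)² · (α·I + β·(3ûûᵀ − I)),

with û the unit displacement, α = 2.0 ppm, β = 0.6 ppm, and S_src an
element term plus 0.8·q for quantum atoms or 0.8·q alone for embedding
charges.  The weight is identically zero at and beyond R — compact support
by construction, not numerically small.  Because any atom within the buffer
cutoffs of a core atom is guaranteed to be inside the quantum region, a
per-fragment evaluation reproduces a whole-system evaluation exactly for
R ≤ min(r_any, r_hh); this assembly–oracle equivalence is the central
property the fragmentation tests assert (at 1e-10 ppm).  Cap hydrogens
receive tensors but are not contribution sources: a cap can legitimately sit
within R of a core atom, and including it would (correctly for physics,
fatally for the bookkeeping check) make fragment and whole-system
evaluations incomparable.  The engine is a bookkeeping oracle, not a physics
surrogate.

## Electrostatics

Bare vacuum Coulomb sums over point charges, k = 14.39964 V·Å·e⁻¹, no
dielectric screening — matching how an embedding charge field is analysed.
Potentials are in volts, fields in MV/cm (1 V/Å = 100 MV/cm).  The
bond-projected field evaluates the environment field at the geometric bond
midpoint and projects it on the a→b unit vector; the two bond atoms' own
charges are always excluded, and any further exclusion (whole chromophore,
Schiff base, ...) is an explicit label set, since which charges to exclude
when quoting a "local field on the chromophore" is a reporting choice, not
physics.  Grids mask nodes within 1 Å of a charge and export as OpenDX
scalar fields.  Numerical consistency E = −∇V is asserted at 1% with
central differences at 0.05 Å spacing.

## Model scoring

Candidates are scored by RMSD between predicted (fragment → assemble) and
experimental shifts on the key intersection; CSA principal values enter as
sorted triples (no tensor-orientation matching, since orientations are not
published).  Nuclei are scored separately and pooled after multiplying each
residual by |γ(nucleus)|/|γ(¹³C)|, which places ¹H/¹⁵N residuals on a
carbon-equivalent frequency scale; RMSD rather than MAE because it is the
conventional agreement metric and monotone for ranking.  Pairings of
(green, blue) models are scored on predicted versus experimental shift
*differences*, with a sign-agreement fraction reported alongside (undefined,
reported as None, when no site has a non-zero difference on both sides).
Ranking is ascending with lexicographic id tie-breaks, hence deterministic
and independent of input order.  Candidate generation is deliberately out of
scope: the expert edits that produce candidates (side-chain flips, water
placement, template swaps) are inputs.

## Family analysis

Sequences are classified by the residue at a diagnostic reference position
(default 105, Leu → green, Gln → blue; anything else, including gaps, is
unclassified).  Position numbering anchors to a designated reference
sequence through the alignment column map.  The cross-group scatter reports,
per position, each group's modal residue, its within-group frequency, and
that residue type's frequency in the other group; ties break alphabetically
for determinism.  Fully conserved positions land at (1.0, 1.0) and a perfect
diagnostic column at (1.0, 0.0).  Gaps are excluded from column counts by
default (configurable to a 21st state); whether the original analysis
gap-normalized is unknown, so both policies are supported.

Entropy conservation is log₂20 − H per column in bits — a deliberately
simple stand-in for phylogeny-aware conservation scores, which require tree
inference that is out of scope.  Covariation is pairwise mutual information
in bits with the average-product correction
APCᵢⱼ = MIᵢⱼ − MI̅ᵢ·MI̅ⱼ/MI̅ subtracted, the standard light-weight
coevolution detector; it likewise stands in for heavier published tools.
Both are computed on gap-filtered integer-encoded columns; constant columns
have MI 0 by convention.

¹⁵N shift differences are multiplied by |γ(¹⁵N)|/|γ(¹³C)| = 0.40317 (from
γ(¹³C) = 6.728284, γ(¹⁵N) = −2.71262 ×10⁷ rad s⁻¹ T⁻¹) to place them on the
carbon scale; the factor is < 1, i.e. nitrogen shifts are shrunk, and the
direction is part of the API contract.  The shift–conservation association
is Spearman's ρ of |scaled Δδ| against conservation, with a p-value from
10⁴ seeded label permutations using the unbiased (1 + exceedances)/(1 + N)
estimator, one-sided "greater" by default since the scientific question is
whether larger perturbations concentrate at more conserved sites.

## Synthetic data: what it emulates, and what it does not

Generators are fully deterministic under a seed (integer-derived child
streams, no iteration-order dependence) and always emit their ground truth.

* **Structures**: ideal α-helix (rise 1.5 Å, 100°/residue, radius 2.3 Å,
  Cα–Cα ≈ 3.8 Å) with N/CA/C/O backbone, HA/CB/HB pseudo-atoms, named
  aromatic rings on Phe/Tyr/Trp/His, optional pseudo-ligand chain threading
  the axis with a declared covalent link, Gaussian coordinate jitter
  (0.05 Å) and random per-atom charges shifted to an exact declared net
  charge.  This exercises every fragmentation criterion and the embedding
  bookkeeping; it is not rhodopsin physics.
* **Alignments**: two groups in the family's observed ≈24:76 proportion
  (default 400 sequences × 120 columns), columns sampled independently at
  planted conservation targets (default U[0.25, 0.95]), a diagnostic column
  fully determined by group, and covarying pairs where one column follows a
  bijective recoding of another with given coupling.  Sequences are
  exchangeable — no phylogeny, no indel process — so tests say nothing about
  phylogenetic confounding, which is precisely why the entropy/MI scores are
  documented as stand-ins.
* **Shift pairs**: green = assembled mock shifts; blue perturbs one site per
  residue (CA) by slope × conservation with a random sign plus Gaussian
  noise.  Signs are random because the relationship being emulated is
  between perturbation *magnitude* and conservation.  Study conditions:
  σ = 0.2 ppm noise, slope 0.5 ppm per conservation *bit*, 40 sites — the
  slope acts on the package's own conservation measure (bits, range 0–4.32).

Passing tests therefore demonstrate correctness of the bookkeeping,
statistics and recovery behaviour under these idealized conditions, not
accuracy on real proteorhodopsin data, which additionally requires a real
shielding engine, curated charges and a real alignment.

## Validation studies and problem sizes

`prshift.studies` bundles the seeded end-to-end studies (the acceptance
script and `tests/test_acceptance.py` wrap them): 100 structures of 10–40
residues for the fragmentation/assembly oracle; 100 repetitions of 5-way
model ranking on 15-residue helices with 0.3 Å decoy jitter at 0.2 ppm
experimental noise; 100 alignments of 500 sequences × 50 columns for
covariation recovery; 100 null and 100 effect seeds at 40 sites and 10⁴
permutations for calibration and power.  These sizes were chosen so the full
battery completes in a couple of minutes while leaving the binomial margins
(e.g. ≥95/100) meaningful.

## Known limitations

* No real shielding engine is shipped; reference shieldings are
  uncalibrated placeholders until one is attached.
* Haeberlen/Mehring-style CSA reduced parameters are not emitted, only
  ordered principal values.
* mmCIF, bond-order perception and protonation prediction are out of scope;
  protonation states are an input embodied in the structure and charges.
* The electrostatics is bare Coulomb: no solvent screening, induced
  polarization, or Poisson–Boltzmann treatment.
* The conservation and covariation scores ignore phylogenetic structure and
  sequence weighting.
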