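"""Seeded generators for structures, alignments and shift tables.

These emulate the statistical structure the analysis assumes — small helical
proteins with optional pseudo-ligand, a two-group sequence family with a
planted diagnostic column, planted per-column conservation and covarying
column pairs, and paired green/blue shift tables whose difference magnitude
grows with conservation — so every downstream stage has a recovery target
without any external data.  Ground truth is returned alongside the data.

All randomness is derived from ``spec.seed`` via per-purpose child streams,
so the same spec reproduces byte-identical outputs regardless of call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .conservation import AMINO_ACIDS, MSA
from .fragmentation import FragmentationParams, fragment_all
from .shifts import MockShieldingEngine, ShiftTable, assemble_shifts
from .structure import AROMATIC_RING_ATOMS, Atom, Residue, Structure

__all__ = [
    "SyntheticSpec",
    "make_structure",
    "make_msa",
    "make_shift_pair",
    "perturb_structure",
]

# helix geometry: 1.5 Å rise and 100° turn per residue, 2.3 Å backbone radius
_HELIX_RISE = 1.5
_HELIX_TURN = math.radians(100.0)
_HELIX_RADIUS = 2.3

_RESIDUE_POOL = (
    "ALA", "LEU", "SER", "VAL", "THR", "GLY", "GLN", "ASN",
    "PHE", "TYR", "TRP", "HIS",
)

# stream tags so structure/MSA/shift draws are independent of call order
_TAG_STRUCTURE, _TAG_MSA, _TAG_SHIFTS = 11, 23, 37


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic generators.

    Family-level defaults mirror the analysed protein family at desk scale:
    400 aligned sequences of which ~24% are green (matching the published
    686:2154 group proportions), a 120-column alignment with the diagnostic
    Leu/Gln column at reference position 105, and per-column conservation
    targets drawn uniformly from [0.25, 0.95] unless planted explicitly.
    Shift-effect defaults (noise σ = 0.2 ppm, 0.5 ppm per conservation unit)
    are the conditions under which recovery is assessed.
    """

    seed: int = 0
    # structure
    n_residues: int = 20
    with_ligand: bool = False
    ligand_length: int = 8
    net_charge: float = 0.0
    coord_jitter: float = 0.05  # Å
    # alignment
    n_sequences: int = 400
    green_fraction: float = 686 / 2840
    alignment_length: int = 120
    conservation_levels: np.ndarray | None = None
    diagnostic_position: int = 105
    diagnostic_residues: tuple[str, str] = ("L", "Q")  # (green, blue)
    covarying_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    # shift pairs
    shift_noise_sigma: float = 0.2  # ppm
    effect_slope: float = 0.5  # ppm per conservation unit
    locality_radius: float = 3.0  # Å, mock engine

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, tag])


def _ring_positions(center: np.ndarray, normal: np.ndarray, n: int, radius: float) -> np.ndarray:
    """n points on a circle around ``center`` perpendicular to ``normal``."""
    normal = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, normal)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    angles = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return center + radius * (
        np.outer(np.cos(angles), e1) + np.outer(np.sin(angles), e2)
    )


def make_structure(spec: SyntheticSpec) -> Structure:
    """An ideal α-helix with pseudo side chains and synthetic charges.

    Backbone N/CA/C/O per residue plus HA, CB and HB pseudo-atoms; aromatic
    residues get a named ring (so the aromatic buffer criterion is
    exercised).  Optionally a pseudo-ligand chain threads along the helix
    axis, covalently linked to a mid-chain CB.  Per-atom charges are drawn
    at random and shifted to sum exactly to ``net_charge``.
    """
    if spec.n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = spec.rng(_TAG_STRUCTURE)
    n = spec.n_residues

    ca = np.array(
        [
            [
                _HELIX_RADIUS * math.cos(i * _HELIX_TURN),
                _HELIX_RADIUS * math.sin(i * _HELIX_TURN),
                _HELIX_RISE * i,
            ]
            for i in range(n + 1)  # one extra for direction extrapolation
        ]
    )
    axis_dirs = ca[1:] - ca[:-1]
    axis_dirs /= np.linalg.norm(axis_dirs, axis=1)[:, None]

    residues: list[Residue] = []
    serial = 0
    for i in range(n):
        name = str(rng.choice(_RESIDUE_POOL))
        u_next = axis_dirs[i]
        u_prev = axis_dirs[i - 1] if i > 0 else axis_dirs[0]
        radial = ca[i].copy()
        radial[2] = 0.0
        radial /= np.linalg.norm(radial)

        coords: dict[str, np.ndarray] = {
            "N": ca[i] - 1.2 * u_prev,
            "CA": ca[i],
            "C": ca[i] + 1.2 * u_next,
            "O": ca[i] + 1.2 * u_next + 1.0 * radial,
            "HA": ca[i] + 1.05 * np.array([0.0, 0.0, 1.0]) * 0.4 + 0.9 * radial,
            "CB": ca[i] + 1.5 * radial,
        }
        coords["HB"] = coords["CB"] + np.array([0.0, 0.0, 1.0])
        ring_names = sorted(AROMATIC_RING_ATOMS.get(name, ()))
        if ring_names:
            center = ca[i] + 2.9 * radial
            for rname, pos in zip(
                ring_names, _ring_positions(center, u_next, len(ring_names), 1.3)
            ):
                coords[rname] = pos

        atoms = []
        for aname, xyz in coords.items():
            serial += 1
            atoms.append(
                Atom(
                    serial=serial,
                    name=aname,
                    element=aname[0],
                    coords=xyz + rng.normal(0.0, spec.coord_jitter, 3),
                    is_aromatic_ring_atom=aname in ring_names,
                )
            )
        residues.append(
            Residue(index=i + 1, name=name, chain_id="A", atoms=atoms, resseq=i + 1)
        )

    links = []
    if spec.with_ligand:
        lig_atoms = []
        zmax = _HELIX_RISE * max(n - 1, 1)
        for k in range(spec.ligand_length):
            serial += 1
            z = zmax * (k + 0.5) / spec.ligand_length
            lig_atoms.append(
                Atom(
                    serial=serial,
                    name=f"C{k + 1}",
                    element="C",
                    coords=np.array([0.3, -0.3, z]) + rng.normal(0.0, spec.coord_jitter, 3),
                )
            )
        serial += 1
        lig_atoms.append(
            Atom(
                serial=serial,
                name="NZ",
                element="N",
                coords=np.array([0.3, -0.3, zmax + 0.8]) + rng.normal(0.0, spec.coord_jitter, 3),
            )
        )
        residues.append(
            Residue(
                index=n + 1,
                name="RET",
                chain_id="X",
                atoms=lig_atoms,
                is_ligand=True,
                resseq=1,
            )
        )
        anchor = max(1, n // 2)
        links.append(((n + 1, "C1"), (anchor, "CB")))

    s = Structure(residues=residues, title=f"synthetic helix seed={spec.seed}", links=links)
    charges = rng.normal(0.0, 0.1, s.n_atoms)
    charges -= (charges.sum() - spec.net_charge) / charges.size
    for (_, atom), q in zip(s.iter_atoms(), charges):
        atom.partial_charge = float(q)
    return s


def perturb_structure(
    s: Structure, sigma: float, rng: np.random.Generator
) -> Structure:
    """A decoy copy of ``s`` with isotropic Gaussian coordinate noise (Å)."""
    import copy

    out = copy.deepcopy(s)
    for _, atom in out.iter_atoms():
        atom.coords = atom.coords + rng.normal(0.0, sigma, 3)
    return out


# ---------------------------------------------------------------------------
# alignments


def make_msa(spec: SyntheticSpec) -> tuple[MSA, dict[str, str], pd.DataFrame]:
    """A two-group alignment with planted conservation and covariation.

    Columns are sampled independently at their target conservation level
    (modal-residue frequency), except the diagnostic column, whose residue is
    fully determined by group membership, and covarying pairs, where the
    second column copies a bijective recoding of the first with probability
    equal to the coupling strength.  Returns (MSA, truth labels, per-column
    truth table).
    """
    n_g = max(1, round(spec.n_sequences * spec.green_fraction))
    n_b = spec.n_sequences - n_g
    if n_b < 1:
        raise ValueError("need at least one sequence per group")
    L = spec.alignment_length
    rng = spec.rng(_TAG_MSA)

    levels = spec.conservation_levels
    if levels is None:
        levels = rng.uniform(0.25, 0.95, L)
    levels = np.asarray(levels, dtype=float)
    if levels.shape != (L,) or np.any(levels < 0) or np.any(levels > 1):
        raise ValueError("conservation_levels must be length-L frequencies in [0, 1]")

    aa = np.array(list(AMINO_ACIDS))
    n = spec.n_sequences
    modal_idx = rng.integers(0, 20, L)
    cols = np.empty((L, n), dtype="<U1")
    for c in range(L):
        take_modal = rng.random(n) < levels[c]
        others = np.delete(np.arange(20), modal_idx[c])
        draw = aa[rng.choice(others, n)]
        draw[take_modal] = aa[modal_idx[c]]
        cols[c] = draw

    pos_to_col = {p: p - 1 for p in range(1, L + 1)}  # gap-free reference

    # covarying pairs: column j tracks a recoding of column i with prob = coupling
    lut_idx = {ch: k for k, ch in enumerate(AMINO_ACIDS)}
    for pos_i, pos_j, coupling in spec.covarying_pairs:
        if not 0.0 <= coupling <= 1.0:
            raise ValueError(f"coupling must be in [0, 1], got {coupling}")
        ci, cj = pos_to_col[pos_i], pos_to_col[pos_j]
        perm = rng.permutation(20)
        src_idx = np.array([lut_idx[ch] for ch in cols[ci]])
        coupled = aa[perm[src_idx]]
        follow = rng.random(n) < coupling
        cols[cj][follow] = coupled[follow]

    # diagnostic column fully determined by group
    dpos = spec.diagnostic_position
    if dpos not in pos_to_col:
        raise ValueError(f"diagnostic_position {dpos} outside alignment length {L}")
    green_char, blue_char = spec.diagnostic_residues
    cols[pos_to_col[dpos]][:n_g] = green_char
    cols[pos_to_col[dpos]][n_g:] = blue_char

    ids = [f"GPR_{k + 1:04d}" for k in range(n_g)] + [
        f"BPR_{k + 1:04d}" for k in range(n_b)
    ]
    labels = {sid: ("green" if k < n_g else "blue") for k, sid in enumerate(ids)}
    seqs = ["".join(cols[:, r]) for r in range(n)]
    msa = MSA(ids=ids, sequences=seqs, ref_id=ids[0])
    truth = pd.DataFrame(
        {
            "position": np.arange(1, L + 1),
            "target_conservation": levels,
            "modal_residue": aa[modal_idx],
        }
    ).set_index("position")
    return msa, labels, truth


# ---------------------------------------------------------------------------
# paired shift tables


def make_shift_pair(
    structure: Structure,
    spec: SyntheticSpec,
    conservation: Mapping[int, float],
) -> tuple[ShiftTable, ShiftTable, pd.DataFrame]:
    """Green/blue shift tables whose Δδ magnitude tracks conservation.

    The green table is the assembled mock-engine prediction for the
    structure.  The blue table perturbs one site per residue (the CA
    carbon) by ``effect_slope × conservation`` with a random sign, plus
    Gaussian noise of ``shift_noise_sigma`` — magnitudes, not signs, carry
    the conservation signal.  Returns (green, blue, truth per position).
    """
    engine = MockShieldingEngine(spec.locality_radius)
    green = assemble_shifts(fragment_all(structure, FragmentationParams()), engine)
    blue = green.copy()
    rng = spec.rng(_TAG_SHIFTS)
    rows = []
    for res in structure.residues:
        if res.is_ligand or (res.index, "CA") not in blue:
            continue
        c = conservation.get(res.index)
        if c is None:
            continue
        sign = 1.0 if rng.random() < 0.5 else -1.0
        delta = sign * spec.effect_slope * c + rng.normal(0.0, spec.shift_noise_sigma)
        blue[(res.index, "CA")].iso += delta
        rows.append({"position": res.index, "conservation": c, "delta_true": delta})
    truth = pd.DataFrame(rows).set_index("position")
    return green, blue, truth
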