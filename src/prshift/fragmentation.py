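"""Automated per-residue fragmentation with capping and electrostatic embedding.

Each residue in turn is a *core* region.  A *buffer* of surrounding residues
is added by four criteria: (i) sequence neighbours within ±``seq_window``
positions on the same chain; (ii) non-neighbouring residues with any atom
closer than ``r_any`` to a core atom; (iii) non-neighbouring residues with a
hydrogen closer than ``r_hh`` to a core hydrogen; (iv) non-neighbouring
residues with an aromatic-ring heavy atom closer than ``r_arom`` to any core
atom.  Core plus buffer form the quantum region; severed covalent bonds at
its boundary are capped with hydrogens placed along the broken bond, and the
remainder of the structure enters as point charges (electrostatic
embedding).  The charge of an atom replaced by a cap is removed so it is not
double counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import Atom, Residue, Structure, min_distance_between

__all__ = [
    "FragmentationParams",
    "CapAtom",
    "Fragment",
    "build_buffer",
    "cap_fragment",
    "embed_charges",
    "fragment_all",
]

AtomKey = tuple[int, str]  # (residue index, atom name)


@dataclass(frozen=True)
class FragmentationParams:
    """Buffer criteria thresholds and cap geometry.

    Defaults: ±2 sequence window, 4 Å any-atom cutoff, 3 Å hydrogen–hydrogen
    cutoff, 5 Å aromatic-ring cutoff, 1.09 Å cap C(N)–H bond length.
    """

    seq_window: int = 2
    r_any: float = 4.0
    r_hh: float = 3.0
    r_arom: float = 5.0
    cap_bond_length: float = 1.09

    def __post_init__(self) -> None:
        if self.seq_window < 0:
            raise ValueError("seq_window must be >= 0")
        for name in ("r_any", "r_hh", "r_arom", "cap_bond_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class CapAtom:
    """A link hydrogen replacing the outside partner of a severed bond."""

    coords: np.ndarray
    retained: AtomKey  # QM-side atom the cap is bonded to
    replaced: AtomKey  # outside atom the cap stands in for

    @property
    def element(self) -> str:
        return "H"


@dataclass
class Fragment:
    """One core residue with its quantum buffer, caps and embedding charges."""

    structure: Structure
    core_index: int
    buffer_indices: frozenset[int]
    caps: list[CapAtom]
    mm_coords: np.ndarray  # (n, 3) Å
    mm_charges: np.ndarray  # (n,) e
    mm_keys: list[AtomKey]
    replaced_keys: frozenset[AtomKey] = field(default_factory=frozenset)

    @property
    def qm_region(self) -> frozenset[int]:
        return self.buffer_indices | {self.core_index}

    def qm_atoms(self) -> list[tuple[AtomKey, Atom]]:
        """Structure atoms in the quantum region, in residue order (caps excluded)."""
        out: list[tuple[AtomKey, Atom]] = []
        for idx in sorted(self.qm_region):
            res = self.structure.residue(idx)
            out.extend(((idx, a.name), a) for a in res.atoms)
        return out

    def core_atom_keys(self) -> list[AtomKey]:
        res = self.structure.residue(self.core_index)
        return [(self.core_index, a.name) for a in res.atoms]

    def to_dict(self) -> dict:
        """JSON-serializable fragment record (buffer indices sorted ascending)."""
        return {
            "core_index": self.core_index,
            "buffer_indices": sorted(self.buffer_indices),
            "qm_atoms": [
                {
                    "residue": k[0],
                    "name": k[1],
                    "element": a.element,
                    "coords": [float(x) for x in a.coords],
                }
                for k, a in self.qm_atoms()
            ],
            "caps": [
                {
                    "coords": [float(x) for x in c.coords],
                    "retained": list(c.retained),
                    "replaced": list(c.replaced),
                }
                for c in self.caps
            ],
            "mm_charges": [
                {"coords": [float(x) for x in xyz], "charge": float(q)}
                for xyz, q in zip(self.mm_coords, self.mm_charges)
            ],
            "boundary_charge_policy": "delete-replaced-atom-only",
        }


# ---------------------------------------------------------------------------
# neighbour index (spatial acceleration)


class _NeighborIndex:
    """KD-trees over atom subsets, mapping hits back to residue indices."""

    def __init__(self, s: Structure) -> None:
        all_xyz, all_res = [], []
        h_xyz, h_res = [], []
        ring_xyz, ring_res = [], []
        for r, a in s.iter_atoms():
            all_xyz.append(a.coords)
            all_res.append(r.index)
            if a.is_hydrogen:
                h_xyz.append(a.coords)
                h_res.append(r.index)
            if a.is_aromatic_ring_atom and not a.is_hydrogen:
                ring_xyz.append(a.coords)
                ring_res.append(r.index)

        def make(xyz: list, res: list):
            if not xyz:
                return None, np.empty(0, dtype=int)
            return cKDTree(np.vstack(xyz)), np.asarray(res, dtype=int)

        self.all_tree, self.all_res = make(all_xyz, all_res)
        self.h_tree, self.h_res = make(h_xyz, h_res)
        self.ring_tree, self.ring_res = make(ring_xyz, ring_res)

    def residues_near(self, tree, res_map, points: np.ndarray, radius: float) -> set[int]:
        if tree is None or points.shape[0] == 0:
            return set()
        hits = tree.query_ball_point(points, radius)
        out: set[int] = set()
        for lst in hits:
            out.update(int(v) for v in res_map[lst])
        return out


def build_buffer(
    s: Structure,
    n: int,
    p: FragmentationParams = FragmentationParams(),
    *,
    index: "_NeighborIndex | None" = None,
    method: str = "kdtree",
) -> set[int]:
    """Buffer residue indices for core residue ``n`` under criteria (i)–(iv).

    ``method='exhaustive'`` computes every inter-residue distance directly
    (O(N²) over atoms) and exists as an independent cross-check of the
    KD-tree path; both apply the same strict ``<`` threshold comparisons, so
    they agree exactly.
    """
    core = s.residue(n)
    neighbors = {
        r.index
        for r in s.residues
        if r.index != n and s.are_sequence_neighbors(n, r.index, p.seq_window)
        and not core.is_ligand
    }
    buffer: set[int] = set(neighbors)
    candidates = [
        r.index for r in s.residues if r.index != n and r.index not in neighbors
    ]

    if method == "exhaustive":
        for c in candidates:
            d = min_distance_between(s, c, n, "all-atoms", "all-atoms")
            if d is not None and d < p.r_any:
                buffer.add(c)
                continue
            d = min_distance_between(s, c, n, "hydrogens-only", "hydrogens-only")
            if d is not None and d < p.r_hh:
                buffer.add(c)
                continue
            d = min_distance_between(s, c, n, "aromatic-ring-heavy", "all-atoms")
            if d is not None and d < p.r_arom:
                buffer.add(c)
        return buffer

    if method != "kdtree":
        raise ValueError(f"unknown method {method!r}")
    idx = index if index is not None else _NeighborIndex(s)
    core_all = core.coords_array("all-atoms")
    core_h = core.coords_array("hydrogens-only")

    cand_set = set(candidates)
    # (ii) any atom < r_any from any core atom
    near_any = idx.residues_near(idx.all_tree, idx.all_res, core_all, p.r_any) & cand_set
    # (iii) hydrogen < r_hh from a core hydrogen
    near_h = idx.residues_near(idx.h_tree, idx.h_res, core_h, p.r_hh) & cand_set
    # (iv) candidate aromatic-ring heavy atom < r_arom from any core atom
    near_ring = idx.residues_near(idx.ring_tree, idx.ring_res, core_all, p.r_arom) & cand_set

    # confirm with exact strict-< distances (tree query is inclusive at radius)
    for c in near_any:
        d = min_distance_between(s, c, n, "all-atoms", "all-atoms")
        if d is not None and d < p.r_any:
            buffer.add(c)
    for c in near_h - buffer:
        d = min_distance_between(s, c, n, "hydrogens-only", "hydrogens-only")
        if d is not None and d < p.r_hh:
            buffer.add(c)
    for c in near_ring - buffer:
        d = min_distance_between(s, c, n, "aromatic-ring-heavy", "all-atoms")
        if d is not None and d < p.r_arom:
            buffer.add(c)
    return buffer


# ---------------------------------------------------------------------------
# capping and embedding


def _severed_bonds(s: Structure, qm_region: frozenset[int] | set[int]) -> list[tuple[AtomKey, AtomKey]]:
    """(retained, replaced) atom pairs for every bond crossing the QM boundary.

    Severed bonds are peptide C–N bonds between index-adjacent residues and
    explicitly declared links only.
    """
    out: list[tuple[AtomKey, AtomKey]] = []
    for i, j in s.peptide_bonds:
        inside_i, inside_j = i in qm_region, j in qm_region
        if inside_i == inside_j:
            continue
        try:
            c_atom = s.residue(i).atom("C")
            n_atom = s.residue(j).atom("N")
        except KeyError as exc:
            raise ValueError(
                f"cannot cap severed peptide bond {i}-{j}: {exc.args[0]}"
            ) from None
        if inside_i:
            out.append(((i, "C"), (j, "N")))
        else:
            out.append(((j, "N"), (i, "C")))
    for (ra, aa), (rb, ab) in s.links:
        inside_a, inside_b = ra in qm_region, rb in qm_region
        if inside_a == inside_b:
            continue
        for ridx, aname in (((ra), aa), ((rb), ab)):
            if not s.residue(ridx).has_atom(aname):
                raise ValueError(
                    f"cannot cap severed link {(ra, aa)}-{(rb, ab)}: "
                    f"atom {aname!r} missing in residue {ridx}"
                )
        if inside_a:
            out.append(((ra, aa), (rb, ab)))
        else:
            out.append(((rb, ab), (ra, aa)))
    return out


def cap_fragment(
    s: Structure,
    qm_region: Iterable[int],
    p: FragmentationParams = FragmentationParams(),
) -> list[CapAtom]:
    """Hydrogen caps for every covalent bond crossing the QM/MM boundary.

    Each cap lies on the line of its severed bond, ``cap_bond_length`` from
    the retained (QM-side) atom.
    """
    region = frozenset(qm_region)
    caps: list[CapAtom] = []
    for retained, replaced in _severed_bonds(s, region):
        a = s.residue(retained[0]).atom(retained[1]).coords
        b = s.residue(replaced[0]).atom(replaced[1]).coords
        vec = b - a
        norm = float(np.linalg.norm(vec))
        if norm < 1e-9:
            raise ValueError(f"zero-length severed bond {retained}-{replaced}")
        caps.append(CapAtom(coords=a + p.cap_bond_length * vec / norm,
                            retained=retained, replaced=replaced))
    return caps


def embed_charges(
    s: Structure, qm_region: Iterable[int]
) -> tuple[np.ndarray, np.ndarray, list[AtomKey]]:
    """Point charges for every atom outside the QM region.

    Every outside atom must carry a partial charge; atoms without one are a
    hard error (listed), because a silently dropped charge would bias the
    embedding field.
    """
    region = frozenset(qm_region)
    coords: list[np.ndarray] = []
    charges: list[float] = []
    keys: list[AtomKey] = []
    missing: list[AtomKey] = []
    for r in s.residues:
        if r.index in region:
            continue
        for a in r.atoms:
            if a.partial_charge is None:
                missing.append((r.index, a.name))
                continue
            coords.append(a.coords)
            charges.append(a.partial_charge)
            keys.append((r.index, a.name))
    if missing:
        raise ValueError(f"atoms outside QM region lack partial charges: {missing}")
    if not coords:
        return np.empty((0, 3)), np.empty(0), []
    return np.vstack(coords), np.asarray(charges, dtype=float), keys


def fragment_all(
    s: Structure,
    p: FragmentationParams = FragmentationParams(),
    *,
    include_ligands: bool = False,
) -> list[Fragment]:
    """One capped, charge-embedded fragment per residue, in residue order.

    By default only non-ligand residues serve as cores; pass
    ``include_ligands=True`` to also fragment ligand pseudo-residues (e.g. a
    retinal–Schiff-base unit declared as its own residue).
    """
    for r in s.residues:
        if not r.atoms:
            raise ValueError(f"residue {r.index} ({r.name}) has no atoms")
    idx = _NeighborIndex(s)
    fragments: list[Fragment] = []
    for r in s.residues:
        if r.is_ligand and not include_ligands:
            continue
        buffer = frozenset(build_buffer(s, r.index, p, index=idx))
        region = buffer | {r.index}
        caps = cap_fragment(s, region, p)
        replaced = frozenset(c.replaced for c in caps)
        coords, charges, keys = embed_charges(s, region)
        if replaced:
            keep = [k not in replaced for k in keys]
            coords = coords[keep] if coords.size else coords
            charges = charges[keep] if charges.size else charges
            keys = [k for k, f in zip(keys, keep) if f]
        fragments.append(
            Fragment(
                structure=s,
                core_index=r.index,
                buffer_indices=buffer,
                caps=caps,
                mm_coords=coords,
                mm_charges=charges,
                mm_keys=keys,
                replaced_keys=replaced,
            )
        )
    return fragments
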