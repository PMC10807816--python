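"""Molecular system representation, PDB I/O and geometry queries.

The container is deliberately small: residues hold atoms, atoms hold
coordinates and optional partial charges.  Internal residue indices are
1-based and sequential over the whole structure (chains are contiguous),
while the original PDB ``resSeq`` is retained as metadata so that sites can
still be addressed in author numbering (e.g. "position 105").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "AROMATIC_RING_ATOMS",
    "DISTANCE_MODES",
    "read_structure",
    "write_structure",
    "read_charge_table",
    "write_charge_table",
    "attach_charges",
    "min_distance",
    "min_distance_between",
]

#: Ring heavy atoms per residue type (PDB atom-name convention).  Trp counts
#: both the pyrrole and the benzene ring (9 heavy atoms).  Overridable per
#: call for ligands such as a retinal ionone ring.
AROMATIC_RING_ATOMS: dict[str, frozenset[str]] = {
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    "HIS": frozenset({"CG", "ND1", "CD2", "CE1", "NE2"}),
}

DISTANCE_MODES = ("all-atoms", "heavy-only", "hydrogens-only", "aromatic-ring-heavy")


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    partial_charge: float | None = None
    is_aromatic_ring_atom: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.name!r}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: empty element symbol")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class Residue:
    index: int
    name: str
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)
    is_ligand: bool = False
    resseq: int | None = None  # author numbering (PDB resSeq), metadata only

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(f"residue {self.index}: duplicate atom names")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.index} ({self.name}) has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def select_atoms(self, mode: str) -> list[Atom]:
        """Atoms entering a distance query under the given mode."""
        if mode == "all-atoms":
            return list(self.atoms)
        if mode == "heavy-only":
            return [a for a in self.atoms if not a.is_hydrogen]
        if mode == "hydrogens-only":
            return [a for a in self.atoms if a.is_hydrogen]
        if mode == "aromatic-ring-heavy":
            return [
                a for a in self.atoms if a.is_aromatic_ring_atom and not a.is_hydrogen
            ]
        raise ValueError(f"unknown distance mode {mode!r}; expected one of {DISTANCE_MODES}")

    def coords_array(self, mode: str = "all-atoms") -> np.ndarray:
        sel = self.select_atoms(mode)
        if not sel:
            return np.empty((0, 3), dtype=float)
        return np.vstack([a.coords for a in sel])


# A declared covalent link between two atoms in different residues,
# e.g. the retinal Schiff-base carbon to the lysine Cε:
# ((residue_index, atom_name), (residue_index, atom_name))
Link = tuple[tuple[int, str], tuple[int, str]]


@dataclass
class Structure:
    residues: list[Residue] = field(default_factory=list)
    title: str = ""
    links: list[Link] = field(default_factory=list)

    def __post_init__(self) -> None:
        last: dict[str, int] = {}
        for r in self.residues:
            prev = last.get(r.chain_id)
            if prev is not None and r.index <= prev:
                raise ValueError(
                    f"residue indices not strictly increasing in chain {r.chain_id!r}"
                )
            last[r.chain_id] = r.index
        self._by_index = {r.index: r for r in self.residues}
        if len(self._by_index) != len(self.residues):
            raise ValueError("residue indices must be unique")

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, index: int) -> Residue:
        try:
            return self._by_index[index]
        except KeyError:
            raise KeyError(f"no residue with index {index}") from None

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues:
            for a in r.atoms:
                yield r, a

    @property
    def peptide_bonds(self) -> list[tuple[int, int]]:
        """Ordered (i, i+1) pairs of index-adjacent residues in one chain.

        Ligand residues do not form implicit peptide bonds; connections to
        them must be declared via :attr:`links`.
        """
        bonds: list[tuple[int, int]] = []
        for a, b in zip(self.residues, self.residues[1:]):
            if (
                a.chain_id == b.chain_id
                and b.index == a.index + 1
                and not a.is_ligand
                and not b.is_ligand
            ):
                bonds.append((a.index, b.index))
        return bonds

    def are_sequence_neighbors(self, i: int, j: int, window: int = 2) -> bool:
        """True if residues i and j are within ``window`` positions on one chain."""
        ri, rj = self.residue(i), self.residue(j)
        return (
            ri.chain_id == rj.chain_id
            and not ri.is_ligand
            and not rj.is_ligand
            and abs(ri.index - rj.index) <= window
        )

    def total_charge(self) -> float:
        return float(
            sum(a.partial_charge or 0.0 for _, a in self.iter_atoms())
        )


# ---------------------------------------------------------------------------
# distance queries


def min_distance_between(
    s: Structure, res_a: int, res_b: int, mode_a: str, mode_b: str
) -> float | None:
    """Minimum pairwise distance with a possibly different atom selection per side.

    Returns ``None`` (a distinguished "undefined" result, never 0) when either
    selection is empty, e.g. hydrogens-only on a hydrogen-free model.
    """
    ca = s.residue(res_a).coords_array(mode_a)
    cb = s.residue(res_b).coords_array(mode_b)
    if ca.shape[0] == 0 or cb.shape[0] == 0:
        return None
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    return float(d.min())


def min_distance(s: Structure, res_a: int, res_b: int, mode: str = "all-atoms") -> float | None:
    """Minimum pairwise Euclidean distance over the mode-selected atom sets.

    Symmetric in its residue arguments for every mode.
    """
    return min_distance_between(s, res_a, res_b, mode, mode)


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi)


def _flag_ring_atoms(res: Residue, ring_atoms: Mapping[str, frozenset[str]]) -> None:
    names = ring_atoms.get(res.name)
    if not names:
        return
    for a in res.atoms:
        if a.name in names:
            a.is_aromatic_ring_atom = True


def read_structure(
    path: str | Path,
    charge_table: str | Path | pd.DataFrame | None = None,
    ring_atoms: Mapping[str, frozenset[str]] | None = None,
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Alternate conformations are reduced to the highest-occupancy conformer.
    Aromatic-ring flags are set from ``ring_atoms`` (defaults to the built-in
    Phe/Tyr/Trp/His ring lists; pass an extended mapping to flag ligand
    rings).  ``charge_table`` optionally attaches per-atom partial charges,
    keyed by (chain, resSeq, atom name).
    """
    st = gemmi.read_pdb(str(path))
    rings = dict(AROMATIC_RING_ATOMS)
    if ring_atoms:
        rings.update({k: frozenset(v) for k, v in ring_atoms.items()})

    residues: list[Residue] = []
    index = 0
    model = st[0]
    for chain in model:
        for gres in chain:
            index += 1
            # keep the highest-occupancy conformer per atom name
            best: dict[str, gemmi.Atom] = {}
            for at in gres:
                cur = best.get(at.name)
                if cur is None or at.occ > cur.occ:
                    best[at.name] = at
            atoms = [
                Atom(
                    serial=k + 1,
                    name=at.name,
                    element=at.element.name,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                )
                for k, at in enumerate(best.values())
            ]
            res = Residue(
                index=index,
                name=gres.name,
                chain_id=chain.name,
                atoms=atoms,
                is_ligand=gres.het_flag == "H",
                resseq=gres.seqid.num,
            )
            _flag_ring_atoms(res, rings)
            residues.append(res)

    out = Structure(residues=residues, title=st.name or "")
    if charge_table is not None:
        table = (
            charge_table
            if isinstance(charge_table, pd.DataFrame)
            else read_charge_table(charge_table)
        )
        attach_charges(out, table)
    return out


def write_structure(s: Structure, path: str | Path) -> None:
    """Write standard fixed-column PDB text; serials renumbered from 1."""
    st = gemmi.Structure()
    st.name = s.title
    model = gemmi.Model("1")
    chain: gemmi.Chain | None = None
    for res in s.residues:
        if chain is None or chain.name != res.chain_id:
            if chain is not None:
                model.add_chain(chain)
            chain = gemmi.Chain(res.chain_id)
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.resseq if res.resseq is not None else res.index, " ")
        gres.het_flag = "H" if res.is_ligand else "A"
        for a in res.atoms:
            gat = gemmi.Atom()
            gat.name = a.name
            gat.element = gemmi.Element(a.element)
            gat.pos = gemmi.Position(*a.coords)
            gat.occ = 1.0
            gres.add_atom(gat)
        chain.add_residue(gres)
    if chain is not None:
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# charge tables


def read_charge_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited charge table with columns chain, resSeq, atom_name, charge_e."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"chain", "resSeq", "atom_name", "charge_e"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"charge table missing columns: {sorted(missing)}")
    return df


def write_charge_table(s: Structure, path: str | Path) -> None:
    rows = [
        {
            "chain": r.chain_id,
            "resSeq": r.resseq if r.resseq is not None else r.index,
            "atom_name": a.name,
            "charge_e": a.partial_charge,
        }
        for r, a in s.iter_atoms()
        if a.partial_charge is not None
    ]
    pd.DataFrame(rows, columns=["chain", "resSeq", "atom_name", "charge_e"]).to_csv(
        path, sep="\t", index=False
    )


def attach_charges(s: Structure, table: pd.DataFrame) -> int:
    """Attach charges keyed by (chain, resSeq, atom_name); unknown keys warn and skip.

    Returns the number of charges attached.
    """
    lookup: dict[tuple[str, int], Residue] = {}
    for r in s.residues:
        key = (r.chain_id, r.resseq if r.resseq is not None else r.index)
        lookup[key] = r
    n = 0
    for row in table.itertuples(index=False):
        res = lookup.get((str(row.chain), int(row.resSeq)))
        atom = None
        if res is not None and res.has_atom(str(row.atom_name)):
            atom = res.atom(str(row.atom_name))
        if atom is None:
            warnings.warn(
                f"charge entry ({row.chain}, {row.resSeq}, {row.atom_name}) "
                "not found in structure; skipped",
                stacklevel=2,
            )
            continue
        atom.partial_charge = float(row.charge_e)
        n += 1
    return n
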