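"""Shielding-tensor bookkeeping, shift assembly and CSA principal values.

Per-residue fragment calculations each yield shielding tensors for every
atom in their quantum region, but only the *core* atoms' tensors are kept
when the protein-wide shift table is assembled; buffer-atom tensors are
discarded.  Shieldings σ are converted to shifts via δ = σ_ref − σ with
per-nucleus reference shieldings.  CSA principal values follow the
shift-scale ordering δ11 ≥ δ22 ≥ δ33 (largest = least shielded); that
convention is recorded here because published tables rarely state one.

A deterministic local mock engine stands in for the quantum-chemistry
shielding engine in tests and simulations: every tensor is a per-element
baseline plus smooth contributions from surrounding atoms and embedding
charges that vanish identically beyond a locality radius.  Because buffer
construction guarantees that everything within the buffer cutoffs of a core
atom is inside the quantum region, assembling per-fragment mock tensors
reproduces a whole-system mock evaluation exactly whenever the locality
radius does not exceed the buffer cutoffs — the module's central testable
property.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .constants import ELEMENT_TO_NUCLEUS
from .fragmentation import AtomKey, Fragment
from .structure import Structure

__all__ = [
    "ShieldingTensor",
    "CSAPrincipals",
    "ShiftEntry",
    "ShiftTable",
    "ShiftDifferenceRecord",
    "ShieldingEngine",
    "MockShieldingEngine",
    "DEFAULT_REFERENCE_SHIELDINGS",
    "principal_values",
    "shielding_to_shift",
    "assemble_shifts",
    "whole_system_shifts",
    "delta_shifts",
]

#: Per-nucleus reference shieldings (ppm).  Placeholders on a plausible
#: scale; any real shielding engine must be calibrated against a reference
#: compound before these are meaningful in absolute terms.
DEFAULT_REFERENCE_SHIELDINGS = {"1H": 31.0, "13C": 185.0, "15N": 260.0, "17O": 330.0}


class ShieldingTensor:
    """A 3×3 shielding tensor in ppm, symmetrized before use."""

    def __init__(self, sigma: np.ndarray) -> None:
        sigma = np.asarray(sigma, dtype=float)
        if sigma.shape != (3, 3):
            raise ValueError("shielding tensor must be 3x3")
        if not np.all(np.isfinite(sigma)):
            raise ValueError("shielding tensor has non-finite entries")
        self.sigma = 0.5 * (sigma + sigma.T)

    @property
    def iso(self) -> float:
        return float(np.trace(self.sigma) / 3.0)


@dataclass(frozen=True)
class CSAPrincipals:
    """Shift-scale principal values, ordered δ11 ≥ δ22 ≥ δ33."""

    d11: float
    d22: float
    d33: float

    def __post_init__(self) -> None:
        if not (self.d11 >= self.d22 >= self.d33):
            raise ValueError("principal values must satisfy d11 >= d22 >= d33")

    @property
    def iso(self) -> float:
        return (self.d11 + self.d22 + self.d33) / 3.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.d11, self.d22, self.d33)


def principal_values(t: "ShieldingTensor | np.ndarray") -> CSAPrincipals:
    """Eigenvalues of the symmetrized tensor, sorted descending."""
    tensor = t if isinstance(t, ShieldingTensor) else ShieldingTensor(np.asarray(t))
    eig = np.linalg.eigvalsh(tensor.sigma)  # ascending
    return CSAPrincipals(d11=float(eig[2]), d22=float(eig[1]), d33=float(eig[0]))


def shielding_to_shift(sigma_iso: float, sigma_ref: float) -> float:
    """δ = σ_ref − σ (standard referencing)."""
    if not (np.isfinite(sigma_iso) and np.isfinite(sigma_ref)):
        raise ValueError("shieldings must be finite")
    return sigma_ref - sigma_iso


@dataclass
class ShiftEntry:
    nucleus: str
    iso: float
    csa: CSAPrincipals | None = None


class ShiftTable:
    """Per-site shifts keyed by (residue index, atom name)."""

    def __init__(self, entries: Mapping[AtomKey, ShiftEntry] | None = None) -> None:
        self.entries: dict[AtomKey, ShiftEntry] = dict(entries or {})

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: AtomKey) -> bool:
        return key in self.entries

    def __getitem__(self, key: AtomKey) -> ShiftEntry:
        return self.entries[key]

    def __iter__(self):
        return iter(self.entries)

    def set(self, key: AtomKey, entry: ShiftEntry) -> None:
        self.entries[key] = entry

    def keys(self):
        return self.entries.keys()

    def items(self):
        return self.entries.items()

    def copy(self) -> "ShiftTable":
        return ShiftTable(
            {
                k: ShiftEntry(e.nucleus, e.iso, e.csa)
                for k, e in self.entries.items()
            }
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (res, name), e in sorted(self.entries.items()):
            csa = e.csa.as_tuple() if e.csa is not None else (np.nan,) * 3
            rows.append(
                {
                    "residue": res,
                    "atom_name": name,
                    "nucleus": e.nucleus,
                    "iso_ppm": e.iso,
                    "d11": csa[0],
                    "d22": csa[1],
                    "d33": csa[2],
                }
            )
        return pd.DataFrame(
            rows, columns=["residue", "atom_name", "nucleus", "iso_ppm", "d11", "d22", "d33"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ShiftTable":
        table = cls()
        for row in df.itertuples(index=False):
            csa = None
            if not (pd.isna(row.d11) or pd.isna(row.d22) or pd.isna(row.d33)):
                csa = CSAPrincipals(float(row.d11), float(row.d22), float(row.d33))
            table.set(
                (int(row.residue), str(row.atom_name)),
                ShiftEntry(nucleus=str(row.nucleus), iso=float(row.iso_ppm), csa=csa),
            )
        return table

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "ShiftTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# engines


class ShieldingEngine(Protocol):
    """Engine contract: one shielding tensor per quantum-region structure atom."""

    def __call__(self, fragment: Fragment) -> dict[AtomKey, np.ndarray]: ...


class MockShieldingEngine:
    """Deterministic stand-in for a quantum-chemistry shielding engine.

    The tensor of a target atom is a fixed per-element baseline plus, for
    every other source within ``locality_radius`` R, a contribution

        S_src · (1 − r/R)² · (α·I + β·(3ûûᵀ − I)),

    where û is the unit displacement, S_src combines an element term and a
    charge term for quantum-region atoms and a charge term only for
    embedding point charges.  The weight is identically zero at and beyond
    R (compact support).  Cap hydrogens are assigned tensors but are not
    contribution sources: the locality model covers atoms of the parent
    structure, keeping per-fragment and whole-system evaluations directly
    comparable.
    """

    BASELINE = {"H": 28.0, "C": 110.0, "N": 160.0, "O": 280.0}
    BASELINE_DEFAULT = 90.0
    ELEMENT_SOURCE = {"H": 1.0, "C": 2.5, "N": 3.2, "O": 4.0}
    ELEMENT_SOURCE_DEFAULT = 2.0
    CHARGE_COUPLING = 0.8  # ppm per e at zero distance (before weighting)
    ALPHA = 2.0  # isotropic contribution scale, ppm
    BETA = 0.6  # traceless anisotropic contribution scale, ppm

    def __init__(self, locality_radius: float = 3.0) -> None:
        if locality_radius < 0:
            raise ValueError("locality_radius must be >= 0")
        self.locality_radius = float(locality_radius)

    def _source_arrays(self, fragment: Fragment) -> tuple[np.ndarray, np.ndarray]:
        qm = fragment.qm_atoms()
        qm_xyz = np.vstack([a.coords for _, a in qm]) if qm else np.empty((0, 3))
        qm_strength = np.array(
            [
                self.ELEMENT_SOURCE.get(a.element.upper(), self.ELEMENT_SOURCE_DEFAULT)
                + self.CHARGE_COUPLING * (a.partial_charge or 0.0)
                for _, a in qm
            ]
        )
        if fragment.mm_coords.size:
            xyz = np.vstack([qm_xyz, fragment.mm_coords])
            strength = np.concatenate(
                [qm_strength, self.CHARGE_COUPLING * fragment.mm_charges]
            )
        else:
            xyz, strength = qm_xyz, qm_strength
        return xyz, strength

    def __call__(self, fragment: Fragment) -> dict[AtomKey, np.ndarray]:
        qm = fragment.qm_atoms()
        keys = [k for k, _ in qm]
        elements = [a.element.upper() for _, a in qm]
        targets = np.vstack([a.coords for _, a in qm]) if qm else np.empty((0, 3))
        out: dict[AtomKey, np.ndarray] = {}
        R = self.locality_radius
        src_xyz, src_strength = self._source_arrays(fragment)
        eye = np.eye(3)
        for t_idx, key in enumerate(keys):
            base = self.BASELINE.get(elements[t_idx], self.BASELINE_DEFAULT)
            tensor = base * eye
            if R > 0 and src_xyz.shape[0]:
                diff = src_xyz - targets[t_idx]
                r = np.linalg.norm(diff, axis=1)
                mask = (r > 1e-9) & (r < R)
                if mask.any():
                    u = diff[mask] / r[mask, None]
                    w = src_strength[mask] * (1.0 - r[mask] / R) ** 2
                    aniso = 3.0 * np.einsum("ni,nj->nij", u, u) - eye
                    tensor = (
                        base * eye
                        + self.ALPHA * float(w.sum()) * eye
                        + self.BETA * np.einsum("n,nij->ij", w, aniso)
                    )
            out[key] = tensor.copy()
        return out


# ---------------------------------------------------------------------------
# assembly


def _entry_from_tensor(
    element: str, sigma: np.ndarray, references: Mapping[str, float]
) -> ShiftEntry:
    nucleus = ELEMENT_TO_NUCLEUS.get(element.upper())
    if nucleus is None:
        raise ValueError(f"no nucleus mapping for element {element!r}")
    ref = references[nucleus]
    # shift tensor = σ_ref·I − σ; its ordered eigenvalues are the CSA
    # principal values on the shift scale
    shift_tensor = ref * np.eye(3) - ShieldingTensor(sigma).sigma
    csa = principal_values(shift_tensor)
    return ShiftEntry(nucleus=nucleus, iso=csa.iso, csa=csa)


def assemble_shifts(
    fragments: Sequence[Fragment],
    engine: ShieldingEngine,
    references: Mapping[str, float] | None = None,
) -> ShiftTable:
    """Assemble a protein-wide shift table from per-fragment calculations.

    Each atom's entry comes from the single fragment in which its residue is
    the core; buffer-atom tensors are discarded.  An engine omitting a core
    atom is a hard error.
    """
    refs = dict(DEFAULT_REFERENCE_SHIELDINGS)
    if references:
        refs.update(references)
    table = ShiftTable()
    for frag in fragments:
        tensors = engine(frag)
        res = frag.structure.residue(frag.core_index)
        for atom in res.atoms:
            key = (frag.core_index, atom.name)
            if key not in tensors:
                raise ValueError(
                    f"engine omitted core atom {key} of fragment {frag.core_index}"
                )
            table.set(key, _entry_from_tensor(atom.element, tensors[key], refs))
    return table


def whole_system_shifts(
    s: Structure,
    engine: ShieldingEngine,
    references: Mapping[str, float] | None = None,
) -> ShiftTable:
    """Evaluate the engine on the entire structure as one quantum region.

    This is the brute-force counterpart of :func:`assemble_shifts`; with the
    mock engine at a locality radius within the buffer cutoffs the two agree
    to machine precision.
    """
    refs = dict(DEFAULT_REFERENCE_SHIELDINGS)
    if references:
        refs.update(references)
    indices = sorted(r.index for r in s.residues)
    pseudo = Fragment(
        structure=s,
        core_index=indices[0],
        buffer_indices=frozenset(indices[1:]),
        caps=[],
        mm_coords=np.empty((0, 3)),
        mm_charges=np.empty(0),
        mm_keys=[],
    )
    tensors = engine(pseudo)
    table = ShiftTable()
    for r, atom in s.iter_atoms():
        key = (r.index, atom.name)
        if key not in tensors:
            raise ValueError(f"engine omitted atom {key}")
        table.set(key, _entry_from_tensor(atom.element, tensors[key], refs))
    return table


# ---------------------------------------------------------------------------
# shift differences


@dataclass(frozen=True)
class ShiftDifferenceRecord:
    """Per-site blue-minus-green difference, isotropic and (optionally) CSA."""

    key: AtomKey
    nucleus: str
    delta_iso: float
    delta_csa: tuple[float, float, float] | None = None


def delta_shifts(table_g: ShiftTable, table_b: ShiftTable) -> list[ShiftDifferenceRecord]:
    """Δδ = δ(blue) − δ(green) on the key intersection of the two tables.

    Keys present in only one table are logged and dropped (never imputed);
    a nucleus mismatch on a shared key is a hard error.
    """
    shared = sorted(set(table_g.keys()) & set(table_b.keys()))
    dropped = (set(table_g.keys()) | set(table_b.keys())) - set(shared)
    if dropped:
        warnings.warn(
            f"{len(dropped)} site(s) present in only one table were dropped",
            stacklevel=2,
        )
    records: list[ShiftDifferenceRecord] = []
    for key in shared:
        g, b = table_g[key], table_b[key]
        if g.nucleus != b.nucleus:
            raise ValueError(
                f"nucleus mismatch at {key}: {g.nucleus} vs {b.nucleus}"
            )
        d_csa = None
        if g.csa is not None and b.csa is not None:
            d_csa = tuple(
                bb - gg for bb, gg in zip(b.csa.as_tuple(), g.csa.as_tuple())
            )
        records.append(
            ShiftDifferenceRecord(
                key=key, nucleus=g.nucleus, delta_iso=b.iso - g.iso, delta_csa=d_csa
            )
        )
    return records
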