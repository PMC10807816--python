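"""Point-charge electrostatic potential and field analysis.

Bare Coulomb sums in vacuum (no dielectric screening): the charges are the
same embedding charges used for the fragment calculations, and the derived
quantities — pocket potential maps and the field component projected on a
bond such as retinal C15–H15 — rationalize how the binding-pocket
environment polarizes the chromophore.  Units: Å, e, V, MV/cm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import COULOMB_CONSTANT, V_PER_ANGSTROM_TO_MV_PER_CM
from .structure import Structure

__all__ = [
    "PointChargeSet",
    "EFieldResult",
    "potential_at",
    "field_at",
    "bond_projected_field",
    "potential_grid",
    "write_dx",
]

_COINCIDENCE_TOL = 1e-6  # Å


@dataclass
class PointChargeSet:
    """Labelled point charges (coords in Å, charges in e)."""

    coords: np.ndarray
    charges: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.charges = np.atleast_1d(np.asarray(self.charges, dtype=float))
        if self.coords.shape != (self.charges.shape[0], 3):
            raise ValueError("coords must be (n, 3) matching n charges")
        if not (np.all(np.isfinite(self.coords)) and np.all(np.isfinite(self.charges))):
            raise ValueError("coords and charges must be finite")
        if len(self.labels) != self.charges.shape[0]:
            raise ValueError("one label per charge required")

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_structure(cls, s: Structure) -> "PointChargeSet":
        """One charge per atom carrying a partial charge, labelled ``res:atom``."""
        coords, charges, labels = [], [], []
        for r, a in s.iter_atoms():
            if a.partial_charge is None:
                continue
            coords.append(a.coords)
            charges.append(a.partial_charge)
            labels.append(f"{r.index}:{a.name}")
        if not coords:
            raise ValueError("structure carries no partial charges")
        return cls(np.vstack(coords), np.asarray(charges), labels)

    def without(self, exclusion: Iterable[str]) -> "PointChargeSet":
        excl = set(exclusion)
        keep = [i for i, lab in enumerate(self.labels) if lab not in excl]
        return PointChargeSet(
            self.coords[keep], self.charges[keep], [self.labels[i] for i in keep]
        )


def labels_for_residues(s: Structure, indices: Iterable[int]) -> set[str]:
    """Charge labels covering every atom of the given residues."""
    wanted = set(indices)
    return {
        f"{r.index}:{a.name}" for r, a in s.iter_atoms() if r.index in wanted
    }


@dataclass
class EFieldResult:
    location: np.ndarray  # Å
    field: np.ndarray  # MV/cm
    potential: float  # V
    projection_axis: np.ndarray | None = None  # unit vector
    projected_magnitude: float | None = None  # MV/cm, field·axis

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.field))


def _prepare(
    charges: PointChargeSet, exclusion: Iterable[str] | None
) -> PointChargeSet:
    return charges.without(exclusion) if exclusion else charges


def _displacements(point: np.ndarray, cs: PointChargeSet) -> tuple[np.ndarray, np.ndarray]:
    point = np.asarray(point, dtype=float)
    diff = point - cs.coords
    r = np.linalg.norm(diff, axis=1)
    if np.any(r < _COINCIDENCE_TOL):
        bad = [cs.labels[i] for i in np.nonzero(r < _COINCIDENCE_TOL)[0]]
        raise ValueError(f"evaluation point coincides with charge(s): {bad}")
    return diff, r


def potential_at(
    point: Sequence[float],
    charges: PointChargeSet,
    exclusion: Iterable[str] | None = None,
) -> float:
    """Vacuum Coulomb potential V = Σ k·qᵢ/rᵢ in volts."""
    cs = _prepare(charges, exclusion)
    if len(cs) == 0:
        return 0.0
    _, r = _displacements(np.asarray(point, dtype=float), cs)
    return float(COULOMB_CONSTANT * np.sum(cs.charges / r))


def field_at(
    point: Sequence[float],
    charges: PointChargeSet,
    exclusion: Iterable[str] | None = None,
) -> EFieldResult:
    """Vacuum Coulomb field E = Σ k·qᵢ·r̂ᵢ/rᵢ², reported in MV/cm."""
    point = np.asarray(point, dtype=float)
    cs = _prepare(charges, exclusion)
    if len(cs) == 0:
        return EFieldResult(location=point, field=np.zeros(3), potential=0.0)
    diff, r = _displacements(point, cs)
    e_v_per_ang = COULOMB_CONSTANT * np.sum(
        (cs.charges / r**3)[:, None] * diff, axis=0
    )
    v = float(COULOMB_CONSTANT * np.sum(cs.charges / r))
    return EFieldResult(
        location=point,
        field=e_v_per_ang * V_PER_ANGSTROM_TO_MV_PER_CM,
        potential=v,
    )


def bond_projected_field(
    s: Structure,
    atom_a: tuple[int, str],
    atom_b: tuple[int, str],
    charges: PointChargeSet,
    exclusion: Iterable[str] | None = None,
) -> EFieldResult:
    """Field at the a–b bond midpoint, projected on the a→b unit vector.

    The two bond atoms' own charges are always excluded so the result is the
    *environment* field polarizing the bond (e.g. retinal C15–H15).
    """
    ra, rb = s.residue(atom_a[0]), s.residue(atom_b[0])
    pa, pb = ra.atom(atom_a[1]).coords, rb.atom(atom_b[1]).coords
    axis = pb - pa
    norm = float(np.linalg.norm(axis))
    if norm < 1e-9:
        raise ValueError("zero-length bond")
    axis = axis / norm
    excl = set(exclusion or ())
    excl.update({f"{atom_a[0]}:{atom_a[1]}", f"{atom_b[0]}:{atom_b[1]}"})
    res = field_at(0.5 * (pa + pb), charges, exclusion=excl)
    res.projection_axis = axis
    res.projected_magnitude = float(np.dot(res.field, axis))
    return res


def potential_grid(
    charges: PointChargeSet,
    bounds: tuple[Sequence[float], Sequence[float]],
    spacing: float,
    exclusion: Iterable[str] | None = None,
    mask_radius: float = 1.0,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Potential sampled on a regular grid; nodes near charges masked as NaN.

    ``bounds`` is (min_corner, max_corner) in Å.  Returns the value array of
    shape (nx, ny, nz) and the three axis coordinate vectors.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    if np.any(hi < lo):
        raise ValueError("empty box: max corner below min corner")
    axes = tuple(
        np.arange(lo[d], hi[d] + 0.5 * spacing, spacing) for d in range(3)
    )
    if any(ax.size == 0 for ax in axes):
        raise ValueError("empty box")
    cs = _prepare(charges, exclusion)
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    diff = pts[:, None, :] - cs.coords[None, :, :]
    r = np.linalg.norm(diff, axis=2)
    masked = np.any(r < mask_radius, axis=1)
    with np.errstate(divide="ignore"):
        vals = COULOMB_CONSTANT * np.sum(cs.charges[None, :] / r, axis=1)
    vals[masked] = np.nan
    return vals.reshape(gx.shape), axes


def write_dx(
    values: np.ndarray,
    origin: Sequence[float],
    spacing: float,
    path: str | Path,
) -> None:
    """Write a scalar grid as an OpenDX field (NaN nodes emitted as 0)."""
    nx, ny, nz = values.shape
    out = np.nan_to_num(values, nan=0.0).ravel(order="C")
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*origin))
        fh.write(f"delta {spacing:.6f} 0 0\n")
        fh.write(f"delta 0 {spacing:.6f} 0\n")
        fh.write(f"delta 0 0 {spacing:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {out.size} data follows\n"
        )
        for i in range(0, out.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in out[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "potential" class field\n')
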