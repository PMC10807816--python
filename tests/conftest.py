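import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prshift import Atom, Residue, Structure, SyntheticSpec, make_structure

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def single_atom_residue(index: int, coords, chain="A", element="C", name="CA"):
    return Residue(
        index=index,
        name="ALA",
        chain_id=chain,
        atoms=[Atom(serial=index, name=name, element=element, coords=np.asarray(coords, float))],
        resseq=index,
    )


@pytest.fixture
def two_point_structure():
    """Two single-atom residues 5 Å apart (a 3-4-5 triangle)."""
    return Structure(
        residues=[
            single_atom_residue(1, (0.0, 0.0, 0.0)),
            single_atom_residue(2, (3.0, 4.0, 0.0)),
        ]
    )


@pytest.fixture
def helix10():
    """Seeded 10-residue synthetic helix with charges."""
    return make_structure(SyntheticSpec(seed=7, n_residues=10))


@pytest.fixture
def helix_with_ligand():
    return make_structure(SyntheticSpec(seed=11, n_residues=12, with_ligand=True))


def brute_force_min_distance(s, ia, ib, mode_a, mode_b):
    """Plain double-loop minimum distance, independent of the library path."""
    ra, rb = s.residue(ia), s.residue(ib)
    best = None
    for a in ra.select_atoms(mode_a):
        for b in rb.select_atoms(mode_b):
            d = float(np.sqrt(((a.coords - b.coords) ** 2).sum()))
            if best is None or d < best:
                best = d
    return best


def brute_force_buffer(s, n, p):
    """Criteria (i)-(iv) by exhaustive scan; the test oracle for build_buffer."""
    out = set()
    core = s.residue(n)
    for r in s.residues:
        if r.index == n:
            continue
        if s.are_sequence_neighbors(n, r.index, p.seq_window) and not core.is_ligand:
            out.add(r.index)
            continue
        d = brute_force_min_distance(s, r.index, n, "all-atoms", "all-atoms")
        if d is not None and d < p.r_any:
            out.add(r.index)
            continue
        d = brute_force_min_distance(s, r.index, n, "hydrogens-only", "hydrogens-only")
        if d is not None and d < p.r_hh:
            out.add(r.index)
            continue
        d = brute_force_min_distance(s, r.index, n, "aromatic-ring-heavy", "all-atoms")
        if d is not None and d < p.r_arom:
            out.add(r.index)
    return out
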