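import numpy as np
import pytest
from scipy.stats import ortho_group

from prshift import (
    CSAPrincipals,
    MockShieldingEngine,
    ShiftEntry,
    ShiftTable,
    SyntheticSpec,
    assemble_shifts,
    delta_shifts,
    fragment_all,
    make_structure,
    principal_values,
    shielding_to_shift,
    whole_system_shifts,
)
from prshift.fragmentation import Fragment
from prshift.shifts import ShieldingTensor


def lone_atom_fragment(element="C", charge=0.0):
    from prshift.structure import Atom, Residue, Structure

    s = Structure(
        residues=[
            Residue(
                index=1,
                name="ALA",
                chain_id="A",
                atoms=[Atom(serial=1, name="X1", element=element, coords=(0, 0, 0), partial_charge=charge)],
            )
        ]
    )
    return Fragment(
        structure=s,
        core_index=1,
        buffer_indices=frozenset(),
        caps=[],
        mm_coords=np.empty((0, 3)),
        mm_charges=np.empty(0),
        mm_keys=[],
    )


class TestPrincipalValues:
    def test_diagonal_sorted_descending(self):
        pv = principal_values(np.diag([30.0, 10.0, 20.0]))
        assert pv.as_tuple() == (30.0, 20.0, 10.0)
        assert pv.iso == pytest.approx(20.0)

    def test_isotropic_tensor(self):
        pv = principal_values(7.5 * np.eye(3))
        assert pv.as_tuple() == pytest.approx((7.5, 7.5, 7.5))
        assert pv.iso == pytest.approx(7.5)

    def test_matches_characteristic_polynomial_roots(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            m = rng.normal(size=(3, 3))
            sym = 0.5 * (m + m.T)
            pv = principal_values(sym)
            # oracle: roots of det(sym - λI) = 0
            roots = np.sort(np.roots(np.poly(sym)).real)[::-1]
            assert np.allclose(pv.as_tuple(), roots, atol=1e-9)
            assert pv.iso == pytest.approx((pv.d11 + pv.d22 + pv.d33) / 3, abs=1e-9)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(3, 3))
        sym = 0.5 * (m + m.T)
        ref = principal_values(sym).as_tuple()
        for i in range(10):
            r = ortho_group.rvs(3, random_state=i)
            rotated = r @ sym @ r.T
            assert np.allclose(principal_values(rotated).as_tuple(), ref, atol=1e-8)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            principal_values(np.full((3, 3), np.nan))

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            CSAPrincipals(1.0, 2.0, 0.0)


class TestReferencing:
    def test_reference_nucleus_zero(self):
        assert shielding_to_shift(100.0, 100.0) == 0.0

    def test_arithmetic_and_involution(self):
        assert shielding_to_shift(60.0, 180.0) == 120.0
        sigma = 57.25
        delta = shielding_to_shift(sigma, 180.0)
        assert shielding_to_shift(delta, 180.0) == sigma


class TestMockEngine:
    def test_isolated_atom_gives_element_baseline(self):
        eng = MockShieldingEngine(3.0)
        t = eng(lone_atom_fragment("N"))[(1, "X1")]
        assert np.allclose(t, MockShieldingEngine.BASELINE["N"] * np.eye(3))

    def test_translation_leaves_isotropic_values_unchanged(self):
        spec = SyntheticSpec(seed=9, n_residues=6)
        s = make_structure(spec)
        eng = MockShieldingEngine(3.0)
        before = whole_system_shifts(s, eng)
        for _, a in s.iter_atoms():
            a.coords = a.coords + np.array([11.0, -5.0, 2.0])
        after = whole_system_shifts(s, eng)
        for k in before.keys():
            assert after[k].iso == pytest.approx(before[k].iso, abs=1e-10)

    def test_contribution_beyond_radius_is_exactly_zero(self):
        from prshift.structure import Atom, Residue, Structure

        R = 3.0
        for dist, expect_equal in ((R + 1e-9, True), (R, True), (R - 0.5, False)):
            s = Structure(
                residues=[
                    Residue(index=1, name="A", chain_id="A",
                            atoms=[Atom(serial=1, name="X1", element="C", coords=(0, 0, 0))]),
                    Residue(index=2, name="A", chain_id="A",
                            atoms=[Atom(serial=2, name="X2", element="N", coords=(dist, 0, 0))]),
                ]
            )
            eng = MockShieldingEngine(R)
            t = whole_system_shifts(s, eng)
            iso_lone = principal_values(
                MockShieldingEngine.BASELINE["C"] * np.eye(3)
            ).iso
            lone_shift = 185.0 - iso_lone  # default 13C reference
            assert (t[(1, "X1")].iso == pytest.approx(lone_shift, abs=1e-12)) is expect_equal

    def test_determinism(self):
        s = make_structure(SyntheticSpec(seed=4, n_residues=8))
        eng = MockShieldingEngine(3.0)
        f = fragment_all(s)[3]
        t1, t2 = eng(f), eng(f)
        for k in t1:
            assert np.array_equal(t1[k], t2[k])


class TestAssembly:
    def test_radius_zero_equals_whole_system_exactly(self, helix10):
        eng = MockShieldingEngine(0.0)
        assembled = assemble_shifts(fragment_all(helix10), eng)
        whole = whole_system_shifts(helix10, eng)
        for k in assembled.keys():
            assert assembled[k].iso == whole[k].iso

    def test_local_engine_matches_whole_system_oracle(self, helix_with_ligand):
        eng = MockShieldingEngine(3.0)
        frags = fragment_all(helix_with_ligand, include_ligands=True)
        assembled = assemble_shifts(frags, eng)
        whole = whole_system_shifts(helix_with_ligand, eng)
        assert set(assembled.keys()) == set(whole.keys())
        for k in assembled.keys():
            assert assembled[k].iso == pytest.approx(whole[k].iso, abs=1e-10)
            assert np.allclose(
                assembled[k].csa.as_tuple(), whole[k].csa.as_tuple(), atol=1e-10
            )

    def test_every_atom_exactly_once(self, helix10):
        eng = MockShieldingEngine(2.0)
        table = assemble_shifts(fragment_all(helix10), eng)
        all_keys = {(r.index, a.name) for r, a in helix10.iter_atoms()}
        assert set(table.keys()) == all_keys

    def test_engine_omitting_core_atom_is_hard_error(self, helix10):
        def broken_engine(fragment):
            out = MockShieldingEngine(0.0)(fragment)
            out.pop((fragment.core_index, "CA"))
            return out

        with pytest.raises(ValueError, match="omitted core atom"):
            assemble_shifts(fragment_all(helix10), broken_engine)


class TestDeltaShifts:
    @staticmethod
    def tables():
        g = ShiftTable()
        g.set((197, "NE1"), ShiftEntry("15N", 130.7))
        g.set((230, "ND2"), ShiftEntry("15N", 110.0))
        g.set((15, "C15"), ShiftEntry("13C", 160.2))
        b = ShiftTable()
        b.set((197, "NE1"), ShiftEntry("15N", 137.0))
        b.set((230, "ND2"), ShiftEntry("15N", 113.8))
        b.set((15, "C15"), ShiftEntry("13C", 158.0))
        return g, b

    def test_identical_tables_give_zero(self):
        g, _ = self.tables()
        assert all(r.delta_iso == 0.0 for r in delta_shifts(g, g))

    def test_constant_offset(self):
        g, _ = self.tables()
        b = g.copy()
        for k in b.keys():
            b[k].iso += 1.5
        assert all(r.delta_iso == pytest.approx(1.5) for r in delta_shifts(g, b))

    def test_sign_convention_blue_minus_green(self):
        # a 130.7 -> 137.0 indole nitrogen perturbation must read +6.3 ppm
        g, b = self.tables()
        recs = {r.key: r for r in delta_shifts(g, b)}
        assert recs[(197, "NE1")].delta_iso == pytest.approx(6.3)

    def test_antisymmetry(self):
        g, b = self.tables()
        fwd = {r.key: r.delta_iso for r in delta_shifts(g, b)}
        rev = {r.key: r.delta_iso for r in delta_shifts(b, g)}
        assert fwd == {k: -v for k, v in rev.items()}

    def test_mismatched_keys_warn_and_intersect(self):
        g, b = self.tables()
        b.set((999, "CA"), ShiftEntry("13C", 55.0))
        with pytest.warns(UserWarning, match="dropped"):
            recs = delta_shifts(g, b)
        assert {r.key for r in recs} == set(g.keys())

    def test_nucleus_mismatch_is_hard_error(self):
        g, b = self.tables()
        b.entries[(15, "C15")] = ShiftEntry("15N", 158.0)
        with pytest.raises(ValueError, match="nucleus mismatch"):
            delta_shifts(g, b)


class TestShiftTableIO:
    def test_tsv_round_trip(self, helix10, tmp_path):
        eng = MockShieldingEngine(3.0)
        table = assemble_shifts(fragment_all(helix10), eng)
        path = tmp_path / "shifts.tsv"
        table.write(path)
        back = ShiftTable.read(path)
        assert set(back.keys()) == set(table.keys())
        for k in table.keys():
            assert back[k].iso == pytest.approx(table[k].iso, abs=1e-9)
            assert back[k].nucleus == table[k].nucleus
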