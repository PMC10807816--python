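import math

import numpy as np
import pytest

from prshift import (
    PointChargeSet,
    SyntheticSpec,
    bond_projected_field,
    field_at,
    make_structure,
    potential_at,
    potential_grid,
)
from prshift.constants import COULOMB_CONSTANT
from prshift.electrostatics import labels_for_residues, write_dx


def charge_set(coords, charges):
    coords = np.atleast_2d(np.asarray(coords, float))
    return PointChargeSet(coords, np.asarray(charges, float), [f"q{i}" for i in range(len(charges))])


def random_charges(rng, n, box=10.0):
    return charge_set(rng.uniform(-box, box, (n, 3)), rng.uniform(-1, 1, n))


class TestPotential:
    def test_unit_charge_at_coulomb_distance_gives_one_volt(self):
        cs = charge_set([[0, 0, 0]], [1.0])
        assert potential_at([COULOMB_CONSTANT, 0, 0], cs) == pytest.approx(1.0, rel=1e-12)

    def test_dipole_midplane_is_zero(self):
        cs = charge_set([[1, 0, 0], [-1, 0, 0]], [1.0, -1.0])
        assert potential_at([0, 5, 3], cs) == pytest.approx(0.0, abs=1e-12)

    def test_matches_extended_precision_summation(self):
        rng = np.random.default_rng(1)
        cs = random_charges(rng, 50)
        point = np.array([20.0, 1.0, -3.0])
        # term-by-term oracle in extended precision
        terms = [
            COULOMB_CONSTANT * q / math.dist(point, c)
            for c, q in zip(cs.coords, cs.charges)
        ]
        want = math.fsum(terms)
        assert potential_at(point, cs) == pytest.approx(want, rel=1e-12)

    def test_coincident_charge_is_hard_error(self):
        cs = charge_set([[1.0, 2.0, 3.0]], [0.5])
        with pytest.raises(ValueError, match="coincides"):
            potential_at([1.0, 2.0, 3.0], cs)

    def test_exclusion_by_label(self):
        cs = PointChargeSet(np.array([[0, 0, 0], [5, 0, 0]]), np.array([1.0, 1.0]), ["a", "b"])
        v_all = potential_at([10, 0, 0], cs)
        v_one = potential_at([10, 0, 0], cs, exclusion={"b"})
        assert v_one == pytest.approx(COULOMB_CONSTANT / 10.0)
        assert v_all > v_one


class TestField:
    def test_single_charge_closed_form(self):
        cs = charge_set([[0, 0, 0]], [1.0])
        res = field_at([10.0, 0, 0], cs)
        # k/r² V/Å → MV/cm: 14.39964/100 V/Å = 14.39964 MV/cm
        assert res.field == pytest.approx([COULOMB_CONSTANT, 0.0, 0.0], rel=1e-12)
        assert res.magnitude == pytest.approx(COULOMB_CONSTANT, rel=1e-12)

    def test_midpoint_of_equal_charges_is_null(self):
        cs = charge_set([[-2, 0, 0], [2, 0, 0]], [0.7, 0.7])
        res = field_at([0, 0, 0], cs)
        assert np.allclose(res.field, 0.0, atol=1e-12)

    def test_superposition_and_linearity(self):
        rng = np.random.default_rng(2)
        a = random_charges(rng, 10)
        b = random_charges(rng, 15)
        both = PointChargeSet(
            np.vstack([a.coords, b.coords]),
            np.concatenate([a.charges, b.charges]),
            a.labels + [f"r{i}" for i in range(15)],
        )
        p = [15.0, 15.0, 15.0]
        fa, fb, fab = field_at(p, a), field_at(p, b), field_at(p, both)
        assert np.allclose(fab.field, fa.field + fb.field, atol=0)
        doubled = PointChargeSet(a.coords, 2 * a.charges, a.labels)
        assert np.allclose(field_at(p, doubled).field, 2 * fa.field, atol=0)
        assert potential_at(p, doubled) == 2 * potential_at(p, a)


class TestBondProjection:
    @pytest.fixture
    def structure(self):
        s = make_structure(SyntheticSpec(seed=13, n_residues=8))
        return s

    def test_collinear_charge_projects_fully(self, two_point_structure):
        s = two_point_structure
        for r, a in s.iter_atoms():
            a.partial_charge = 0.0
        cs = charge_set([[6.0, 8.0, 0.0]], [1.0])  # on the bond axis beyond atom b
        res = bond_projected_field(s, (1, "CA"), (2, "CA"), cs)
        assert res.projected_magnitude == pytest.approx(-res.magnitude, rel=1e-12)

    def test_perpendicular_bisector_charge_projects_to_zero(self, two_point_structure):
        s = two_point_structure
        mid = np.array([1.5, 2.0, 0.0])
        perp = np.cross([3.0, 4.0, 0.0], [0.0, 0.0, 1.0])
        cs = charge_set([mid + 3.0 * perp / np.linalg.norm(perp)], [1.0])
        res = bond_projected_field(s, (1, "CA"), (2, "CA"), cs)
        assert res.projected_magnitude == pytest.approx(0.0, abs=1e-12)

    def test_projection_is_dot_product_with_brute_force_field(self, structure):
        cs = PointChargeSet.from_structure(structure)
        res = bond_projected_field(structure, (3, "CA"), (3, "HA"), cs)
        pa = structure.residue(3).atom("CA").coords
        pb = structure.residue(3).atom("HA").coords
        axis = (pb - pa) / np.linalg.norm(pb - pa)
        direct = field_at(
            0.5 * (pa + pb), cs, exclusion={"3:CA", "3:HA"}
        )
        assert res.projected_magnitude == pytest.approx(float(direct.field @ axis), rel=1e-12)
        assert np.linalg.norm(res.projection_axis) == pytest.approx(1.0)

    def test_bond_atoms_own_charges_excluded(self, structure):
        cs = PointChargeSet.from_structure(structure)
        res = bond_projected_field(structure, (3, "CA"), (3, "HA"), cs)
        manual = bond_projected_field(
            structure, (3, "CA"), (3, "HA"), cs.without({"3:CA", "3:HA"})
        )
        assert res.projected_magnitude == manual.projected_magnitude

    def test_zero_length_bond_rejected(self, two_point_structure):
        with pytest.raises(ValueError, match="zero-length"):
            bond_projected_field(
                two_point_structure, (1, "CA"), (1, "CA"), charge_set([[9, 9, 9]], [1.0])
            )


class TestGrid:
    def test_single_node_reduces_to_potential_at(self):
        rng = np.random.default_rng(3)
        cs = random_charges(rng, 20)
        vals, axes = potential_grid(cs, ([30.0, 0.0, 0.0], [30.0, 0.0, 0.0]), spacing=1.0)
        assert vals.shape == (1, 1, 1)
        assert vals[0, 0, 0] == pytest.approx(potential_at([30.0, 0.0, 0.0], cs))

    def test_difference_of_identical_systems_is_zero(self):
        rng = np.random.default_rng(4)
        cs = random_charges(rng, 10)
        box = ([-12.0, -12.0, -12.0], [-10.0, -10.0, -10.0])
        a, _ = potential_grid(cs, box, 0.5)
        b, _ = potential_grid(cs, box, 0.5)
        assert np.array_equal(a, b, equal_nan=True)

    def test_matches_per_node_brute_force(self):
        rng = np.random.default_rng(5)
        cs = random_charges(rng, 8, box=3.0)
        vals, axes = potential_grid(cs, ([-6, -6, -6], [-2, -2, -2]), 1.0)
        for i, x in enumerate(axes[0]):
            for j, y in enumerate(axes[1]):
                for k, z in enumerate(axes[2]):
                    if np.isnan(vals[i, j, k]):
                        continue
                    assert vals[i, j, k] == pytest.approx(potential_at([x, y, z], cs), rel=1e-12)

    def test_nodes_near_charges_masked(self):
        cs = charge_set([[0.0, 0.0, 0.0]], [1.0])
        vals, _ = potential_grid(cs, ([-0.5, -0.5, -0.5], [0.5, 0.5, 0.5]), 0.5)
        assert np.isnan(vals[1, 1, 1])

    def test_field_equals_negative_gradient(self):
        rng = np.random.default_rng(6)
        cs = random_charges(rng, 12, box=4.0)
        point = np.array([8.0, 2.0, -1.0])  # away from all charges
        h = 0.05
        box = (point - h, point + h)
        vals, _ = potential_grid(cs, box, h, mask_radius=0.0)
        grad = np.array(
            [
                (vals[2, 1, 1] - vals[0, 1, 1]) / (2 * h),
                (vals[1, 2, 1] - vals[1, 0, 1]) / (2 * h),
                (vals[1, 1, 2] - vals[1, 1, 0]) / (2 * h),
            ]
        )
        e_v_per_ang = field_at(point, cs).field / 100.0
        assert np.allclose(e_v_per_ang, -grad, rtol=0.01)

    def test_empty_box_rejected(self):
        cs = charge_set([[0, 0, 0]], [1.0])
        with pytest.raises(ValueError, match="empty box"):
            potential_grid(cs, ([1, 1, 1], [0, 0, 0]), 0.5)

    def test_dx_export_runs(self, tmp_path):
        cs = charge_set([[0, 0, 0]], [1.0])
        vals, axes = potential_grid(cs, ([2, 2, 2], [4, 4, 4]), 1.0)
        out = tmp_path / "pot.dx"
        write_dx(vals, [2, 2, 2], 1.0, out)
        text = out.read_text()
        assert "gridpositions counts 3 3 3" in text


def test_labels_for_residues(helix10):
    labels = labels_for_residues(helix10, [2])
    assert all(lab.startswith("2:") for lab in labels)
    assert len(labels) == len(helix10.residue(2).atoms)
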