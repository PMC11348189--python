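import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import capscan as cs
from capscan.errors import DataError, DegeneracyError, SelectionError, ValidationError
from capscan.models import AtomRecord, Residue, Structure
from helpers import apply_rigid, random_rigid_transform


def het_structure(atom_specs, struct_id="fixture"):
    """Structure from (name, element, xyz) triples, one het residue per atom."""
    residues = [
        Residue(author_number=i + 1, aa="LIG", is_het=True,
                atoms=[AtomRecord(name=name, element=elem, coords=xyz)])
        for i, (name, elem, xyz) in enumerate(atom_specs)
    ]
    return Structure(id=struct_id, chains={"A": residues})


class TestSuperpose:
    def test_identical_sets_give_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        tr = cs.superpose(pts, pts)
        assert tr.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)

    def test_recovers_applied_rigid_transform(self):
        pts = np.random.default_rng(1).normal(size=(12, 3)) * 10
        R, t = random_rigid_transform(5)
        tr = cs.superpose(pts, pts @ R.T + t)
        assert tr.rmsd < 1e-6
        assert np.allclose(tr.rotation, R, atol=1e-8)
        # applying then inverting restores coordinates
        restored = tr.inverse().apply(tr.apply(pts))
        assert np.abs(restored - pts).max() < 1e-9

    def test_rotation_is_always_proper(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            tr = cs.superpose(rng.normal(size=(8, 3)), rng.normal(size=(8, 3)))
            assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_matches_rotation_grid_search(self):
        rng = np.random.default_rng(3)
        mobile = rng.normal(size=(10, 3))
        target = rng.normal(size=(10, 3))
        tr = cs.superpose(mobile, target)
        # brute-force oracle: many random rotations with optimal translation each
        m_c = mobile - mobile.mean(axis=0)
        t_c = target - target.mean(axis=0)
        rots = Rotation.random(20_000, random_state=4).as_matrix()
        moved = np.einsum("rij,nj->rni", rots, m_c)
        best = np.sqrt(np.min(np.mean(np.sum((moved - t_c) ** 2, axis=2), axis=1)))
        assert tr.rmsd <= best + 1e-9
        assert abs(tr.rmsd - best) < 0.05

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(5), np.zeros(5), np.zeros(5)]).astype(float)
        with pytest.raises(DegeneracyError):
            cs.superpose(line, line)
        with pytest.raises(DegeneracyError):
            cs.superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestSegmentDisplacement:
    def test_self_comparison_is_zero(self, small_ensemble):
        result, maps = small_ensemble
        mean_d, max_d = cs.segment_displacement(
            result.members[0], result.members[0], maps[0], maps[0],
            result.spec.event_segment,
        )
        assert mean_d == pytest.approx(0.0, abs=1e-9)
        assert max_d == pytest.approx(0.0, abs=1e-9)

    def test_planted_displacement_invariant_under_rigid_motion(self, planted):
        result, maps = planted
        f = result.labels.index("folded")
        alt = result.labels.index("alternative")
        R, t = random_rigid_transform(7)
        moved = apply_rigid(result.members[alt], R, t)
        mean_d, _ = cs.segment_displacement(
            result.members[f], moved, maps[f], maps[alt], (385, 400)
        )
        assert mean_d == pytest.approx(8.0, abs=1e-6)

    def test_unfolded_member_has_undefined_displacement(self, planted):
        result, maps = planted
        f = result.labels.index("folded")
        u = result.labels.index("unfolded")
        with pytest.warns(UserWarning):
            mean_d, max_d = cs.segment_displacement(
                result.members[f], result.members[u], maps[f], maps[u], (385, 400)
            )
        assert mean_d is None and max_d is None


class TestNamedDistance:
    def test_unit_offset(self):
        st = het_structure([("A1", "C", (0, 0, 0)), ("A2", "C", (1, 0, 0))])
        assert cs.named_distance(st, ("A", 1, "A1"), ("A", 2, "A2")) == pytest.approx(1.0)

    def test_coincident_atoms(self):
        st = het_structure([("A1", "C", (2, 2, 2)), ("A2", "C", (2, 2, 2))])
        assert cs.named_distance(st, ("A", 1, "A1"), ("A", 2, "A2")) == 0.0

    def test_missing_selector_raises(self):
        st = het_structure([("A1", "C", (0, 0, 0))])
        with pytest.raises(SelectionError):
            cs.named_distance(st, ("A", 1, "A1"), ("B", 9, "ZZ"))


class TestCoordinationShell:
    def test_fixture_shell_sorted_ascending(self):
        st = cs.make_site_fixture()
        shell = cs.coordination_shell(st, "K")
        d = [x for x, _ in shell]
        assert d == sorted(d) and len(d) == 3
        assert max(d) == pytest.approx(3.2)

    def test_tight_cutoff_empties_shell(self):
        st = cs.make_site_fixture()
        assert cs.coordination_shell(st, "K", cutoff=2.0) == []

    def test_two_ions_require_explicit_selector(self):
        st = cs.make_site_fixture()
        extra = Residue(author_number=99, aa="K", is_het=True,
                        atoms=[AtomRecord(name="K", element="K", coords=(3, 3, 3))])
        st.ligands.append(("L", extra))
        with pytest.raises(SelectionError):
            cs.coordination_shell(st, "K")
        shell = cs.coordination_shell(st, ("L", 3, "K"))
        assert len(shell) == 3


class TestPocketVolume:
    def test_hollow_sphere_matches_analytic_volume(self):
        shell = cs.make_cavity_shell(inner_radius=6.0)
        vol = cs.pocket_volume(shell, seed_point=(0, 0, 0))
        analytic = 4 / 3 * np.pi * (6.0 - 1.4) ** 3
        assert vol == pytest.approx(analytic, rel=0.10)

    def test_grid_refinement_converges(self):
        shell = cs.make_cavity_shell(inner_radius=6.0)
        v1 = cs.pocket_volume(shell, seed_point=(0, 0, 0), grid_spacing=0.5)
        v2 = cs.pocket_volume(shell, seed_point=(0, 0, 0), grid_spacing=0.25)
        assert abs(v2 - v1) / v1 < 0.03

    def test_no_atoms_is_all_bulk(self):
        st = Structure(id="empty", chains={"A": [Residue(author_number=1, aa="LIG", is_het=True)]})
        with pytest.warns(UserWarning):
            assert cs.pocket_volume(st) == 0.0

    def test_largest_component_rule_without_seed(self):
        shell = cs.make_cavity_shell(inner_radius=6.0)
        assert cs.pocket_volume(shell) == cs.pocket_volume(shell, seed_point=(0, 0, 0))

    def test_seed_inside_atom_rejected(self):
        shell = cs.make_cavity_shell(inner_radius=6.0)
        atom = shell.chains["A"][0].atoms[0]
        with pytest.raises(SelectionError):
            cs.pocket_volume(shell, seed_point=tuple(atom.coords))

    def test_volume_invariant_under_rigid_motion(self):
        shell = cs.make_cavity_shell(inner_radius=6.0)
        R, t = random_rigid_transform(11)
        moved = apply_rigid(shell, R, t)
        v0 = cs.pocket_volume(shell, seed_point=(0, 0, 0))
        v1 = cs.pocket_volume(moved, seed_point=tuple(R @ np.zeros(3) + t))
        assert v1 == pytest.approx(v0, rel=0.01)

    def test_volume_scales_with_cavity_radius(self):
        v_small = cs.pocket_volume(cs.make_cavity_shell(inner_radius=6.0), seed_point=(0, 0, 0))
        v_large = cs.pocket_volume(cs.make_cavity_shell(inner_radius=6.665), seed_point=(0, 0, 0))
        expected = ((6.665 - 1.4) / (6.0 - 1.4)) ** 3
        assert v_large / v_small == pytest.approx(expected, rel=0.05)


class TestSASA:
    def test_isolated_atom_matches_analytic_area(self):
        st = het_structure([("C1", "C", (0, 0, 0))])
        areas, _ = cs.sasa(st)
        assert areas.sum() == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=0.01)

    def test_distant_atoms_are_additive(self):
        st = het_structure([("C1", "C", (0, 0, 0)), ("C2", "C", (100, 0, 0))])
        areas, _ = cs.sasa(st)
        iso = 4 * np.pi * (1.7 + 1.4) ** 2
        assert areas.sum() == pytest.approx(2 * iso, rel=0.01)

    def test_enclosed_atom_has_zero_area(self):
        # shell tight enough that its expanded spheres occlude the whole
        # expanded sphere of the central atom
        st = cs.make_cavity_shell(inner_radius=4.0)
        buried = Residue(author_number=50, aa="LIG", is_het=True,
                         atoms=[AtomRecord(name="C9", element="C", coords=(0, 0, 0))])
        st.ligands.append(("L", buried))
        areas, atoms = cs.sasa(st)
        idx = [i for i, (_, _, a) in enumerate(atoms) if a.name == "C9"]
        assert areas[idx[0]] == pytest.approx(0.0, abs=1e-6)

    def test_unknown_element_raises_with_offender(self):
        st = het_structure([("Q1", "XX", (0, 0, 0))])
        with pytest.raises(DataError, match="XX"):
            cs.sasa(st)

    def test_invariant_under_rigid_motion(self):
        st = het_structure(
            [("C1", "C", (0, 0, 0)), ("C2", "C", (2.5, 0, 0)), ("O1", "O", (1, 2, 0))]
        )
        R, t = random_rigid_transform(13)
        a0, _ = cs.sasa(st)
        a1, _ = cs.sasa(apply_rigid(st, R, t))
        assert np.allclose(a0, a1, rtol=0.01, atol=0.5)


def slab(x_offset, chain_id, n=10):
    residues = [
        Residue(author_number=i + 1, aa="LIG", is_het=True,
                atoms=[AtomRecord(name="C1", element="C",
                                  coords=(x_offset, (i % 5) * 2.0, (i // 5) * 2.0))])
        for i in range(n)
    ]
    return chain_id, residues


class TestBuriedSurfaceArea:
    def make_two_slabs(self, gap):
        ca, ra = slab(0.0, "A")
        cb, rb = slab(gap, "B")
        return Structure(id="slabs", chains={ca: ra, cb: rb})

    def test_distant_chains_bury_nothing(self):
        st = self.make_two_slabs(100.0)
        assert cs.buried_surface_area(st, {"A"}, {"B"}) == pytest.approx(0.0, abs=0.01)

    def test_symmetric_in_chain_order(self):
        st = self.make_two_slabs(3.6)
        ab = cs.buried_surface_area(st, {"A"}, {"B"})
        ba = cs.buried_surface_area(st, {"B"}, {"A"})
        assert ab == pytest.approx(ba)
        assert ab > 0

    def test_quadrature_refinement_agrees(self):
        st = self.make_two_slabs(3.6)
        coarse = cs.buried_surface_area(st, {"A"}, {"B"}, n_sphere_points=960)
        fine = cs.buried_surface_area(st, {"A"}, {"B"}, n_sphere_points=1920)
        assert coarse == pytest.approx(fine, rel=0.02)

    def test_overlapping_chain_sets_rejected(self):
        st = self.make_two_slabs(3.6)
        with pytest.raises(ValidationError):
            cs.buried_surface_area(st, {"A"}, {"A", "B"})

    def test_pair_table_invariant_under_relabeling(self):
        ca, ra = slab(0.0, "A")
        cb, rb = slab(3.6, "B")
        cc, rc = slab(7.2, "C")
        st = Structure(id="trimer", chains={"A": ra, "B": rb, "C": rc})
        relabeled = Structure(id="trimer2", chains={"A": rc, "B": rb, "C": ra})
        t1 = cs.geometry.bsa_table(st)
        t2 = cs.geometry.bsa_table(relabeled)
        assert sum(t1.values()) == pytest.approx(sum(t2.values()), rel=1e-6)
        assert all(v >= -0.01 for v in t1.values())  # within quadrature rounding
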