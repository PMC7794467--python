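"""Geometric descriptors: distances, angles, membrane frame, interfaces,
contacts, hydrogen bonds and the reductase conformational classification."""

import numpy as np
import pytest

from cypet import descriptors as dsc
from cypet import synthetic as syn
from cypet.structure import (Ensemble, ISOALLOXAZINE_RING_ATOMS, RigidTransform,
                             apply_transform, select_atoms)
from cypet.synthetic import build_structure


def cloud(center, res_id=1, chain="A", res_name="GLY", names=("C1", "C2", "C3", "C4")):
    offsets = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], dtype=float)
    return [(n, "C", res_name, res_id, chain, np.asarray(center, float) + o)
            for n, o in zip(names, offsets)]


class TestPairAndComDistances:
    def test_coincident_atoms_zero(self):
        s = build_structure([("FE", "FE", "HEM", 1, "A", (1, 2, 3)),
                             ("N5", "N", "FMN", 2, "A", (1, 2, 3))])
        assert dsc.pair_distance(s, {"name": "FE"}, {"name": "N5"}) == 0.0

    def test_symmetric_and_euclidean(self):
        s = build_structure([("FE", "FE", "HEM", 1, "A", (0, 0, 0)),
                             ("N5", "N", "FMN", 2, "A", (3, 4, 0))])
        d1 = dsc.pair_distance(s, {"name": "FE"}, {"name": "N5"})
        d2 = dsc.pair_distance(s, {"name": "N5"}, {"name": "FE"})
        assert d1 == d2 == pytest.approx(5.0)

    def test_missing_atom_named_in_error(self):
        s = build_structure([("FE", "FE", "HEM", 1, "A", (0, 0, 0))])
        with pytest.raises(KeyError, match="N5"):
            dsc.pair_distance(s, {"name": "FE"}, {"name": "N5"})

    def test_com_distance_constructed_clouds(self):
        """Two 4-atom clouds with centroids 10 Å apart."""
        s = build_structure(cloud((0, 0, 0), res_id=1) + cloud((10, 0, 0), res_id=5))
        assert dsc.domain_com_distance(s, (1, 1), (5, 5)) == pytest.approx(10.0)

    def test_same_selection_zero(self):
        s = build_structure(cloud((2, 3, 4)))
        assert dsc.domain_com_distance(s, (1, 1), (1, 1)) == 0.0

    def test_empty_selection_errors(self):
        s = build_structure(cloud((0, 0, 0)))
        with pytest.raises(ValueError):
            dsc.domain_com_distance(s, (1, 1), (7, 9))


class TestHelixAxis:
    def test_ideal_helix_direction(self):
        h = syn.make_helix(20, (1, 0, 0))
        ax = dsc.fit_helix_axis(h)
        assert dsc.angle_between(ax.direction, (1, 0, 0)) < 1.0

    def test_collinear_points_exact(self):
        rows = [("CA", "C", "ALA", i + 1, "A", (0.0, 0.0, float(i))) for i in range(6)]
        ax = dsc.fit_helix_axis(build_structure(rows))
        np.testing.assert_allclose(ax.direction, [0, 0, 1], atol=1e-12)
        assert ax.residual == pytest.approx(0.0, abs=1e-12)

    def test_reversed_residue_order_flips_sign(self):
        h = syn.make_helix(20, (0, 0, 1))
        flipped = h.copy()
        flipped.res_id = flipped.res_id[::-1].copy()
        d1 = dsc.fit_helix_axis(h).direction
        d2 = dsc.fit_helix_axis(flipped).direction
        np.testing.assert_allclose(d1, -d2, atol=1e-9)

    def test_too_few_ca_errors(self):
        rows = [("CA", "C", "ALA", i + 1, "A", (0, 0, i)) for i in range(3)]
        with pytest.raises(ValueError):
            dsc.fit_helix_axis(build_structure(rows))


class TestAngles:
    @pytest.mark.parametrize("u,v,fold,expected", [
        ((1, 0, 0), (1, 0, 0), "none", 0.0),
        ((1, 0, 0), (0, 1, 0), "none", 90.0),
        ((1, 0, 0), (-1, 0, 0), "to_90", 0.0),
        ((1, 0, 0), (-1, 0, 0), "none", 180.0),
    ])
    def test_angle_between(self, u, v, fold, expected):
        assert dsc.angle_between(u, v, fold) == pytest.approx(expected)

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            dsc.angle_between((0, 0, 0), (1, 0, 0))

    @pytest.mark.parametrize("angle", [20.0, 60.0, 120.0])
    def test_theta_between_constructed_helices(self, angle):
        rad = np.radians(angle)
        h1 = syn.make_helix(15, (0, 0, 1), chain="A", first_res=1)
        h2 = syn.make_helix(15, (np.sin(rad), 0, np.cos(rad)), chain="A",
                            first_res=91, origin=(20, 0, 0))
        rows = [(a.name, a.element, a.res_name, a.res_id, a.chain, a.xyz)
                for s in (h1, h2) for a in s.atoms()]
        theta = dsc.compute_theta(build_structure(rows), (1, 15), (91, 105))
        assert theta == pytest.approx(angle, abs=1.0)

    def test_theta_identical_ranges_zero(self):
        h = syn.make_helix(15, (0, 0, 1), first_res=91)
        assert dsc.compute_theta(h, (91, 105), (91, 105)) == pytest.approx(0.0)


class TestMembraneDescriptors:
    def test_heme_in_membrane_plane_is_90(self, membrane_system):
        s = syn.make_membrane_system(alpha=10, beta=90, tilt=90).protein
        assert dsc.heme_plane_tilt(s, membrane_system.membrane) == pytest.approx(90.0, abs=0.01)

    def test_heme_plane_containing_z_is_0(self, membrane_system):
        s = syn.make_membrane_system(alpha=10, beta=90, tilt=0).protein
        assert dsc.heme_plane_tilt(s, membrane_system.membrane) == pytest.approx(0.0, abs=0.01)

    def test_constructed_tilt_recovered(self, membrane_system):
        s = syn.make_membrane_system(alpha=10, beta=90, tilt=40).protein
        assert dsc.heme_plane_tilt(s, membrane_system.membrane) == pytest.approx(40.0, abs=0.5)

    def test_collinear_ring_errors(self, membrane_system):
        rows = [(n, "C", "HEM", 900, "A", (float(i), 0, 0))
                for i, n in enumerate(["NA", "NB", "NC", "ND"])]
        with pytest.raises(ValueError):
            dsc.heme_plane_tilt(build_structure(rows), membrane_system.membrane)

    def test_alpha_aligned_construction(self):
        sys0 = syn.make_membrane_system(alpha=0, beta=90, tilt=40)
        a, b, g = dsc.membrane_orientation_angles(sys0.protein, sys0.membrane,
                                                  sys0.domain_map)
        assert a == pytest.approx(0.0, abs=0.5)

    def test_rotated_alpha_recovered(self):
        sysr = syn.make_membrane_system(alpha=25, beta=90, tilt=40)
        a, b, g = dsc.membrane_orientation_angles(sysr.protein, sysr.membrane,
                                                  sysr.domain_map)
        assert a == pytest.approx(25.0, abs=0.5)
        assert g == pytest.approx(25.0, abs=0.5)

    def test_v2_orthogonal_to_v1(self, membrane_system):
        """v2 is orthogonalized against v1 by construction."""
        s = membrane_system
        v1 = dsc.fit_helix_axis(s.protein, "i_helix", s.domain_map).direction
        from cypet.structure import select
        c = select(s.protein, "c_helix", s.domain_map).com()
        f = select(s.protein, "f_helix", s.domain_map).com()
        v2 = f - c
        v2 -= (v2 @ v1) * v1
        assert abs(v2 / np.linalg.norm(v2) @ v1) < 1e-9

    def test_axial_distance_trivials(self, membrane_system):
        mem = membrane_system.membrane
        on_mid = build_structure([("C1", "C", "GLY", 1, "A", (5, -3, 0))])
        assert dsc.axial_membrane_distance(on_mid, on_mid, mem) == pytest.approx(0.0)
        above = build_structure([("C1", "C", "GLY", 1, "A", (5, -3, 12))])
        assert dsc.axial_membrane_distance(above, above, mem) == pytest.approx(12.0)

    def test_axial_distance_translation_oracle(self, membrane_system):
        s = membrane_system.protein
        mem = membrane_system.membrane
        d0 = dsc.axial_membrane_distance(s, s, mem)
        shifted = s.with_xyz(s.xyz + np.array([0, 0, 5.0]))
        assert dsc.axial_membrane_distance(shifted, shifted, mem) == pytest.approx(d0 + 5.0)


class TestMembraneInference:
    def test_flat_bilayer(self):
        bil = syn.make_bilayer((0, 0, 1), half_thickness=19.0)
        mf = dsc.infer_membrane_frame(bil)
        np.testing.assert_allclose(mf.normal, [0, 0, 1], atol=1e-9)
        assert mf.half_thickness == pytest.approx(19.0, abs=1e-6)

    def test_tilted_bilayer_recovered_within_1deg(self):
        n = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        mf = dsc.infer_membrane_frame(syn.make_bilayer(n, half_thickness=19.0))
        assert dsc.angle_between(mf.normal, n, fold="to_90") < 1.0

    def test_protein_only_errors(self, membrane_system):
        with pytest.raises(ValueError, match="config"):
            dsc.infer_membrane_frame(membrane_system.protein)


class TestInterfaceArea:
    def test_far_apart_zero(self):
        a = build_structure(cloud((0, 0, 0), res_id=1))
        b = build_structure(cloud((50, 0, 0), res_id=9))
        s = build_structure(cloud((0, 0, 0), res_id=1) + cloud((50, 0, 0), res_id=9))
        assert dsc.interface_area(s, (1, 1), (9, 9)) == pytest.approx(0.0, abs=1e-6)

    def test_two_spheres_against_cap_formula(self):
        """Two single-atom spheres at partial overlap: buried SASA equals the
        analytic spherical-cap area 4πR(R − d/2) with R = r_vdw + probe."""
        d = 4.0
        s = build_structure([("C1", "C", "GLY", 1, "A", (0, 0, 0)),
                             ("C2", "C", "GLY", 9, "A", (d, 0, 0))])
        got = dsc.interface_area(s, (1, 1), (9, 9), probe=1.4, point_number=5000)
        r_cap = 1.7 + 1.4  # Bondi carbon + water probe
        expected = 4 * np.pi * r_cap * (r_cap - d / 2)
        assert got == pytest.approx(expected, rel=0.02)

    def test_buried_half_convention(self):
        d = 4.0
        s = build_structure([("C1", "C", "GLY", 1, "A", (0, 0, 0)),
                             ("C2", "C", "GLY", 9, "A", (d, 0, 0))])
        total = dsc.interface_area(s, (1, 1), (9, 9), point_number=2000)
        half = dsc.interface_area(s, (1, 1), (9, 9), convention="buried_half",
                                  point_number=2000)
        assert half == pytest.approx(total / 2)

    def test_overlapping_selections_rejected(self):
        s = build_structure(cloud((0, 0, 0), res_id=1))
        with pytest.raises(ValueError):
            dsc.interface_area(s, (1, 1), (1, 1))


class TestContacts:
    @pytest.mark.parametrize("dx,expected", [(4.9, True), (5.1, False)])
    def test_threshold_straddle(self, dx, expected):
        s = build_structure([("C1", "C", "GLY", 1, "A", (0, 0, 0)),
                             ("C1", "C", "GLY", 9, "B", (dx, 0, 0))])
        table = dsc.contact_map(s, (1, 1), (9, 9))
        assert (("A", 1, "B", 9) in table.pairs) is expected

    def test_two_frame_occupancy(self):
        near = build_structure([("C1", "C", "GLY", 1, "A", (0, 0, 0)),
                                ("C1", "C", "GLY", 9, "B", (4.0, 0, 0))])
        far = near.with_xyz(np.array([[0, 0, 0], [8.0, 0, 0]]))
        far.frame_id = 1
        table = dsc.contact_map(Ensemble([near, far]), (1, 1), (9, 9))
        assert table.occupancy(("A", 1, "B", 9)) == pytest.approx(0.5)

    def test_occupancy_matches_brute_force_recount(self, rng):
        """Occupancies equal a per-frame brute-force recount on random frames."""
        base_rows = []
        for rid in range(1, 4):
            base_rows += cloud((rid * 3.0, 0, 0), res_id=rid, chain="A")
        for rid in range(11, 14):
            base_rows += cloud((rid - 8.0, 4.0, 0), res_id=rid, chain="B")
        base = build_structure(base_rows)
        frames = []
        for k in range(6):
            f = base.with_xyz(base.xyz + rng.normal(scale=1.5, size=base.xyz.shape))
            f.frame_id = k
            frames.append(f)
        ens = Ensemble(frames)
        table = dsc.contact_map(ens, [( "A", 1, 3)], [("B", 11, 13)], cutoff=5.0)
        occ = table.occupancy()
        for ra in range(1, 4):
            for rb in range(11, 14):
                count = 0
                for f in frames:
                    xa = f.xyz[(f.chain == "A") & (f.res_id == ra)]
                    xb = f.xyz[(f.chain == "B") & (f.res_id == rb)]
                    dmin = np.min(np.linalg.norm(xa[:, None] - xb[None], axis=-1))
                    count += dmin < 5.0
                assert occ.get(("A", ra, "B", rb), 0.0) == pytest.approx(count / 6)


class TestHydrogenBonds:
    def _pair(self, d, with_h=False, h_angle_linear=True):
        rows = [("OD1", "O", "ASP", 5, "A", (0.0, 0.0, 0.0)),
                ("NZ", "N", "LYS", 9, "B", (d, 0.0, 0.0))]
        if with_h:
            hx = d - 1.0 if h_angle_linear else d
            hy = 0.0 if h_angle_linear else 1.0
            rows.append(("HZ1", "H", "LYS", 9, "B", (hx, hy, 0.0)))
        return build_structure(rows)

    def test_close_pair_bonded(self):
        s = self._pair(2.9, with_h=True, h_angle_linear=True)
        assert dsc.hydrogen_bond_occupancy(s, {"name": "NZ"}, {"name": "OD1"}) == 1.0

    def test_distant_pair_not_bonded(self):
        assert dsc.hydrogen_bond_occupancy(self._pair(4.0), {"name": "NZ"},
                                           {"name": "OD1"}) == 0.0

    def test_bent_geometry_rejected(self):
        s = self._pair(2.9, with_h=True, h_angle_linear=False)
        assert dsc.hydrogen_bond_occupancy(s, {"name": "NZ"}, {"name": "OD1"}) == 0.0

    def test_ensemble_fractional_occupancy(self):
        frames = []
        for k in range(10):
            d = 2.9 if k < 7 else 4.5
            f = self._pair(d)
            f.frame_id = k
            frames.append(f)
        occ = dsc.hydrogen_bond_occupancy(Ensemble(frames), {"name": "NZ"},
                                          {"name": "OD1"})
        assert occ == pytest.approx(0.7)


def flavin_ring(res_name, center, res_id, chain="C"):
    names = [n for n in ISOALLOXAZINE_RING_ATOMS if not n.endswith("X")]
    ang = 2 * np.pi * np.arange(len(names)) / len(names)
    return [(n, "N" if n.startswith("N") else "C", res_name, res_id, chain,
             np.asarray(center, float) + [2.0 * np.cos(a), 2.0 * np.sin(a), 0.0], True)
            for n, a in zip(names, ang)]


class TestCprConformation:
    @pytest.mark.parametrize("d,state", [(14.2, "closed"), (40.0, "semi-open"),
                                         (44.7, "semi-open"), (61.3, "open")])
    def test_classification_thresholds(self, d, state):
        rows = flavin_ring("FMN", (0, 0, 0), 801) + flavin_ring("FAD", (d, 0, 0), 802)
        got_state, got_d = dsc.classify_cpr_conformation(build_structure(rows))
        assert got_state == state
        assert got_d == pytest.approx(d, abs=1e-9)

    def test_missing_cofactor_errors(self):
        rows = flavin_ring("FMN", (0, 0, 0), 801)
        with pytest.raises(ValueError, match="FAD"):
            dsc.classify_cpr_conformation(build_structure(rows))


class TestRigidInvariance:
    def test_descriptors_invariant_under_joint_transform(self, rng, membrane_system):
        """Joint rigid motion of structure and membrane frame leaves every
        membrane descriptor unchanged to 1e-6."""
        s = membrane_system.protein
        mem = membrane_system.membrane
        dm = membrane_system.domain_map
        ref = (dsc.membrane_orientation_angles(s, mem, dm)
               + (dsc.heme_plane_tilt(s, mem),
                  dsc.axial_membrane_distance(s, s, mem)))
        for _ in range(5):
            t = RigidTransform.random(rng, translation=rng.normal(size=3) * 40)
            s2 = apply_transform(s, t)
            mem2 = mem.transformed(t)
            got = (dsc.membrane_orientation_angles(s2, mem2, dm)
                   + (dsc.heme_plane_tilt(s2, mem2),
                      dsc.axial_membrane_distance(s2, s2, mem2)))
            np.testing.assert_allclose(got, ref, atol=1e-6)
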