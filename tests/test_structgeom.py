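"""Geometry: closed-form pore radii, superposition, helices, dye volumes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from vtcfret.fixtures import (
    make_cylinder,
    make_helix,
    make_structure,
    toy_pdb_text,
    write_structure_pdb,
)
from vtcfret.structgeom import (
    ALEXA488,
    CY5,
    AVCloud,
    PoreAxis,
    Selection,
    av_distance,
    chain_stoichiometry,
    channel_length,
    count_tm_helices,
    domain_rmsd,
    kabsch_superpose,
    pore_profile,
    read_structure,
    sample_dye_av,
    write_pore_profile,
)

AXIS_Z = PoreAxis((0.0, 0.0, 0.0), (0.0, 0.0, 1.0))


def rigid(rng):
    rot = Rotation.random(random_state=int(rng.integers(0, 2**31))).as_matrix()
    trans = rng.uniform(-20, 20, 3)
    return rot, trans


class TestReadStructure:
    def test_minimal_handwritten_pdb(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(toy_pdb_text())
        st = read_structure(path)
        assert st.n_atoms == 3
        assert len(np.unique(st.res_seq)) == 1
        assert set(st.elements) == {"N", "C"}

    def test_write_read_round_trip(self, tmp_path):
        st = make_helix(n_res=10)
        path = tmp_path / "helix.pdb"
        write_structure_pdb(st, path)
        back = read_structure(path)
        assert np.allclose(back.coords, st.coords, atol=1.5e-3)
        assert back.chain_ids.tolist() == st.chain_ids.tolist()

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        text = (
            "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.30  0.00           C\n"
            "ATOM      2  CA BGLY A   1       5.000   0.000   0.000  0.70  0.00           C\n"
            "END\n"
        )
        path = tmp_path / "alt.pdb"
        path.write_text(text)
        st = read_structure(path)
        assert st.n_atoms == 1
        assert st.coords[0, 0] == pytest.approx(5.0)

    def test_unknown_element_falls_back_with_warning(self, tmp_path):
        text = (
            "ATOM      1  D   UNK A   1       0.000   0.000   0.000  1.00  0.00           D\n"
            "END\n"
        )
        path = tmp_path / "odd.pdb"
        path.write_text(text)
        with pytest.warns(UserWarning, match="unknown element"):
            st = read_structure(path)
        assert st.vdw[0] == pytest.approx(1.70)

    def test_stoichiometry_of_synthetic_multichain(self, tmp_path):
        # three identical chains + two distinct ones -> 3:1:1
        from vtcfret.fixtures import merge_structures

        parts = [
            make_helix(n_res=n, origin=(30.0 * i, 0, 0), chain=chain)
            for i, (chain, n) in enumerate([("A", 12), ("B", 12), ("C", 12),
                                            ("D", 20), ("E", 7)])
        ]
        path = tmp_path / "multi.pdb"
        write_structure_pdb(merge_structures(parts), path)
        st = read_structure(path)
        groups = chain_stoichiometry(st)
        counts = sorted(len(v) for v in groups.values())
        assert counts == [1, 1, 3]


class TestKabsch:
    def test_identical_sets_zero_rmsd(self, rng):
        pts = rng.normal(size=(15, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_rigid_transform_recovered(self, rng):
        pts = rng.normal(size=(25, 3)) * 10
        rot, trans = rigid(rng)
        moved = pts @ rot.T + trans
        res = kabsch_superpose(moved, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)
        # recovered transform is the inverse of the applied one
        assert np.allclose(res.rotation, rot.T, atol=1e-8)
        assert np.allclose(res.apply(moved), pts, atol=1e-8)

    def test_rotation_is_proper(self, rng):
        pts = rng.normal(size=(10, 3))
        # mirror the points: best proper rotation must still have det +1
        res = kabsch_superpose(pts * np.array([-1, 1, 1]), pts)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_matches_independent_minimizer(self, rng):
        """RMSD agrees with scipy's align_vectors on noisy pairs."""
        pts = rng.normal(size=(30, 3)) * 8
        rot, trans = rigid(rng)
        noisy = pts @ rot.T + trans + rng.normal(0, 0.5, (30, 3))
        ours = kabsch_superpose(noisy, pts)
        r, rssd = Rotation.align_vectors(
            pts - pts.mean(axis=0), noisy - noisy.mean(axis=0)
        )
        assert ours.rmsd == pytest.approx(rssd / np.sqrt(len(pts)), rel=1e-6)

    def test_rmsd_invariant_under_rigid_transform(self, rng):
        pts = rng.normal(size=(20, 3)) * 5
        other = pts + rng.normal(0, 1.0, (20, 3))
        base = kabsch_superpose(pts, other).rmsd
        for _ in range(5):
            rot, trans = rigid(rng)
            assert kabsch_superpose(pts @ rot.T + trans, other).rmsd == pytest.approx(
                base, abs=1e-9
            )

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line + 1.0)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestDomainRmsd:
    def test_self_superposition_zero(self):
        st = make_helix(n_res=20)
        sel = Selection("A", 1, 20)
        res = domain_rmsd(st, st, sel, sel)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert res.n_atoms == 20

    def test_transformed_copy_zero(self, rng):
        st = make_helix(n_res=20)
        rot, trans = rigid(rng)
        moved = make_helix(n_res=20)
        moved.coords = st.coords @ rot.T + trans
        res = domain_rmsd(moved, st, Selection("A", 1, 20), Selection("A", 1, 20))
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)

    def test_pairs_by_residue_number_intersection(self):
        a = make_helix(n_res=20)               # residues 1..20
        b = make_helix(n_res=20)
        b.res_seq = b.res_seq + 5              # residues 6..25
        res = domain_rmsd(a, b, Selection("A", 1, 20), Selection("A", 1, 25))
        assert res.n_atoms == 15               # overlap 6..20

    def test_empty_intersection_raises(self):
        a = make_helix(n_res=10)
        b = make_helix(n_res=10)
        b.res_seq = b.res_seq + 100
        with pytest.raises(ValueError, match="intersection"):
            domain_rmsd(a, b, Selection("A", 1, 10), Selection("A", 101, 110))


class TestPoreProfile:
    def test_cylinder_closed_form_radius(self, cylinder):
        """Rings of C atoms (vdW 1.7) at radius 8 -> pore radius 6.3 at
        every ring-aligned station, to 1e-3."""
        prof = pore_profile(cylinder, AXIS_Z, (5.0, 35.0), z_step=1.0,
                            n_starts=16, seed=0)
        assert np.allclose(prof.radius, 6.3, atol=1e-3)
        assert prof.min_radius == pytest.approx(6.3, abs=1e-3)

    def test_rigid_invariance(self, rng, cylinder):
        rot, trans = rigid(rng)
        moved = make_cylinder(ring_step=1.0)
        moved.coords = cylinder.coords @ rot.T + trans
        p0 = np.array([0.0, 0.0, 0.0]) @ rot.T + trans
        p1 = np.array([0.0, 0.0, 1.0]) @ rot.T + trans
        axis = PoreAxis.from_points(p0, p1)
        a = pore_profile(cylinder, AXIS_Z, (5.0, 35.0), z_step=1.0,
                         n_starts=16, seed=0, conv_tol=1e-4)
        b = pore_profile(moved, axis, (5.0, 35.0), z_step=1.0,
                         n_starts=16, seed=0, conv_tol=1e-4)
        assert np.allclose(a.radius, b.radius, atol=1e-4)

    @pytest.mark.parametrize("delta", [0.1, 0.5])
    def test_radius_decreases_with_inflated_vdw(self, cylinder, delta):
        inflated = make_cylinder(ring_step=1.0)
        inflated.vdw = inflated.vdw + delta
        a = pore_profile(cylinder, AXIS_Z, (10.0, 20.0), z_step=1.0,
                         n_starts=8, seed=0)
        b = pore_profile(inflated, AXIS_Z, (10.0, 20.0), z_step=1.0,
                         n_starts=8, seed=0)
        assert np.all(b.radius <= a.radius + 1e-9)
        assert np.allclose(a.radius - b.radius, delta, atol=1e-3)

    def test_lining_residues_at_constriction(self, cylinder):
        prof = pore_profile(cylinder, AXIS_Z, (20.0, 20.0), z_step=1.0,
                            n_starts=8, seed=0)
        lin = prof.lining_at_min()
        assert len(lin) > 0
        chains = {c for c, _, _ in lin}
        assert chains == {"A"}

    def test_profile_tsv_output(self, cylinder, tmp_path):
        prof = pore_profile(cylinder, AXIS_Z, (18.0, 22.0), z_step=1.0,
                            n_starts=8, seed=0)
        out = tmp_path / "pore.tsv"
        write_pore_profile(prof, out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == ["z", "radius", "n_lining", "lining_residues"]
        assert len(lines) == 1 + len(prof.z_values)


class TestChannelLength:
    def test_cylinder_height_recovered(self):
        cyl = make_cylinder(ring_step=0.5)
        prof = pore_profile(cyl, AXIS_Z, (-5.0, 45.0), z_step=0.5,
                            n_starts=8, seed=0)
        # enclosure just above the bore radius terminates at the rims
        length = channel_length(prof, enclosure_radius=6.31)
        assert length == pytest.approx(40.0, abs=0.5 + 1e-9)

    def test_wide_cylinder_has_no_enclosed_interval(self):
        cyl = make_cylinder(ring_radius=13.0, ring_step=1.0)
        prof = pore_profile(cyl, AXIS_Z, (10.0, 30.0), z_step=1.0,
                            n_starts=8, seed=0, xy_search=15.0)
        assert prof.min_radius == pytest.approx(11.3, abs=1e-2)
        with pytest.raises(ValueError, match="no enclosed interval"):
            channel_length(prof, enclosure_radius=10.0)


class TestTmHelices:
    def test_spanning_helix_counts_once(self):
        st = make_helix(n_res=30)  # spans z 0 .. 43.5
        counts = count_tm_helices(st, (5.0, 35.0))
        assert counts == {"A": 1, "total": 1}

    def test_in_plane_helix_not_counted(self):
        st = make_helix(n_res=30, direction=(1.0, 0.0, 0.0))
        counts = count_tm_helices(st, (5.0, 35.0))
        assert counts["total"] == 0

    def test_short_helix_not_spanning(self):
        st = make_helix(n_res=12)  # z extent ~16.5 < slab
        assert count_tm_helices(st, (5.0, 35.0))["total"] == 0

    def test_multi_chain_counting(self):
        from vtcfret.fixtures import merge_structures

        merged = merge_structures([
            make_helix(n_res=30, origin=(20.0 * i, 0.0, 0.0), chain=ch)
            for i, ch in enumerate("ABC")
        ])
        counts = count_tm_helices(merged, (5.0, 35.0))
        assert counts["total"] == 3
        assert all(counts[c] == 1 for c in "ABC")


class TestAccessibleVolume:
    def test_free_space_acceptance_matches_reach_sphere(self):
        """With no obstacles the full reach sphere is accessible: acceptance
        fraction ~1 and mean pairwise distance matches the uniform-ball
        closed form 36R/35."""
        st = make_structure(np.array([[500.0, 500.0, 500.0]]))
        cloud = sample_dye_av(st, "A", 1, "X", ALEXA488, n_samples=1500, seed=0)
        assert cloud.n_accepted / cloud.n_attempted > 0.98
        d = av_distance(cloud, cloud)
        expected = 36 * ALEXA488.linker_length / 35
        assert d.mean == pytest.approx(expected, rel=0.02)

    def test_all_constraints_satisfied(self):
        # a few obstacle atoms near the site
        obstacles = np.array([
            [6.0, 0.0, 0.0], [0.0, 7.0, 2.0], [-5.0, -5.0, 5.0], [0.0, 0.0, -6.0],
        ])
        st = make_structure(np.vstack([obstacles, [[0.0, 0.0, 0.0]]]))
        cloud = sample_dye_av(st, "A", 5, "X", CY5, n_samples=400, seed=1)
        r = np.linalg.norm(cloud.positions - cloud.attachment_pos, axis=1)
        assert np.all(r <= CY5.linker_length + 1e-9)
        dmin = np.linalg.norm(
            cloud.positions[:, None, :] - obstacles[None, :, :], axis=-1
        ).min(axis=1)
        assert np.all(dmin >= CY5.dye_radius + 1.7 - 1e-9)

    def test_blocking_wall_displaces_centroid(self):
        xs = np.arange(-30.0, 31.0, 1.5)
        wall = np.array([[-3.0, y, z] for y in xs for z in xs])
        st = make_structure(np.vstack([wall, [[0.0, 0.0, 0.0]]]))
        cloud = sample_dye_av(st, "A", len(wall) + 1, "X", ALEXA488,
                              n_samples=400, seed=0)
        assert cloud.centroid[0] > 1.0          # pushed away from the wall
        assert abs(cloud.centroid[1]) < 2.0     # symmetric in-plane
        assert abs(cloud.centroid[2]) < 2.0

    def test_buried_site_raises(self):
        # attachment completely caged by a dense shell of atoms
        phi = np.linspace(0, np.pi, 20)
        theta = np.linspace(0, 2 * np.pi, 40)
        pts = [
            [4.0 * np.sin(p) * np.cos(t), 4.0 * np.sin(p) * np.sin(t), 4.0 * np.cos(p)]
            for p in phi for t in theta
        ]
        st = make_structure(np.vstack([pts, [[0.0, 0.0, 0.0]]]))
        with pytest.raises(ValueError, match="buried"):
            sample_dye_av(st, "A", len(pts) + 1, "X", ALEXA488, n_samples=50, seed=0)

    def test_missing_attachment_atom_raises(self):
        st = make_structure(np.zeros((1, 3)))
        with pytest.raises(ValueError, match="attachment"):
            sample_dye_av(st, "B", 1, "X", ALEXA488)


class TestAvDistance:
    def _cloud(self, positions):
        positions = np.asarray(positions, dtype=float)
        return AVCloud("synthetic", positions.mean(axis=0), positions,
                       20.0, 4.5, 3.5, len(positions), len(positions))

    def test_two_single_points(self):
        a = self._cloud([[0.0, 0.0, 0.0]])
        b = self._cloud([[10.0, 0.0, 0.0]])
        d = av_distance(a, b)
        assert d.mean == pytest.approx(10.0)
        assert d.sd == pytest.approx(0.0)
        assert d.centroid_distance == pytest.approx(10.0)

    def test_cloud_against_itself_centroids_coincide(self, rng):
        pts = rng.normal(0, 3, (200, 3))
        c = self._cloud(pts)
        assert av_distance(c, c).centroid_distance == pytest.approx(0.0)

    def test_point_versus_spherical_shell_closed_form(self, rng):
        """Mean distance from a point at distance d to a uniform shell of
        radius a (d > a) is d + a^2/(3d)."""
        a_rad, d0 = 6.0, 30.0
        u = rng.normal(size=(4000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        shell = self._cloud(u * a_rad)
        point = self._cloud([[d0, 0.0, 0.0]])
        got = av_distance(shell, point)
        expected = d0 + a_rad**2 / (3 * d0)
        assert got.mean == pytest.approx(expected, rel=0.005)

    def test_empty_cloud_rejected(self):
        a = self._cloud([[0.0, 0.0, 0.0]])
        b = AVCloud("synthetic", np.zeros(3), np.zeros((0, 3)), 20.0, 4.5, 3.5, 0, 0)
        with pytest.raises(ValueError):
            av_distance(a, b)


class TestPoreAxis:
    def test_frame_is_orthonormal(self, rng):
        for _ in range(10):
            d = rng.normal(size=3)
            axis = PoreAxis.from_points(rng.normal(size=3), rng.normal(size=3) + d)
            f = axis.frame()
            assert np.allclose(f @ f.T, np.eye(3), atol=1e-12)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            PoreAxis.from_points([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
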