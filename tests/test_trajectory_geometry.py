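"""Subdomain angles, Euler bend/twist, SASA and membrane curvature."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mrebtwist import synthetic_data as sd
from mrebtwist import trajectory_geometry as tg


def _frame_from_centers(centers: dict) -> tg.StructureFrame:
    """One atom per subdomain at the given positions."""
    names = list(centers)
    return tg.StructureFrame(
        coords=np.array([centers[n] for n in names], dtype=float),
        radii=np.full(len(names), 0.17),
        subunit=np.array(["A"] * len(names), dtype=object),
        subdomain=np.array(names, dtype=object),
        residue_index=np.arange(len(names)) + 10,
    )


class TestSubdomainCenters:
    def test_single_atom_per_subdomain_returns_positions(self):
        centers = {n: np.random.default_rng(0).normal(size=3)
                   for n in tg.SUBDOMAINS}
        frame = _frame_from_centers(centers)
        out = tg.subdomain_centers(frame, "A")
        for n in tg.SUBDOMAINS:
            assert np.allclose(out[n], centers[n])

    def test_two_symmetric_atoms_give_midpoint(self):
        coords, names = [], []
        for i, n in enumerate(tg.SUBDOMAINS):
            mid = np.array([i, 2.0 * i, -i])
            coords += [mid + [0.5, 0, 0], mid - [0.5, 0, 0]]
            names += [n, n]
        frame = tg.StructureFrame(
            coords=np.array(coords), radii=np.full(8, 0.17),
            subunit=np.array(["A"] * 8, dtype=object),
            subdomain=np.array(names, dtype=object),
            residue_index=np.arange(8) + 10)
        out = tg.subdomain_centers(frame, "A")
        for i, n in enumerate(tg.SUBDOMAINS):
            assert np.allclose(out[n], [i, 2.0 * i, -i])

    def test_random_frame_matches_direct_average(self, rng):
        n = 40
        frame = tg.StructureFrame(
            coords=rng.normal(size=(n, 3)), radii=np.full(n, 0.17),
            subunit=np.array(["A"] * n, dtype=object),
            subdomain=np.array([tg.SUBDOMAINS[i % 4] for i in range(n)], dtype=object),
            residue_index=np.arange(n) + 10)
        out = tg.subdomain_centers(frame, "A")
        for i, name in enumerate(tg.SUBDOMAINS):
            manual = frame.coords[np.arange(i, n, 4)].mean(axis=0)
            assert np.allclose(out[name], manual)

    def test_missing_subdomain_is_named_in_error(self):
        centers = {n: np.ones(3) * i for i, n in enumerate(tg.SUBDOMAINS[:3])}
        frame = _frame_from_centers(centers)
        with pytest.raises(ValueError, match="IIB"):
            tg.subdomain_centers(frame, "A")

    def test_helix_residues_must_be_unlabelled(self):
        with pytest.raises(ValueError, match="helix"):
            tg.StructureFrame(
                coords=np.zeros((1, 3)), radii=[0.17],
                subunit=np.array(["A"], dtype=object),
                subdomain=np.array(["IA"], dtype=object),
                residue_index=[3])


class TestOpeningAndDihedral:
    def test_square_arrangement_gives_90(self):
        centers = {"IA": np.array([0.0, 0, 0]), "IB": np.array([0.0, 1, 0]),
                   "IIA": np.array([1.0, 0, 0]), "IIB": np.array([1.0, 1, 0])}
        assert tg.opening_angle(centers) == pytest.approx(90.0)

    def test_collinear_centers_give_0_or_180(self):
        centers = {"IA": np.array([0.0, 0, 0]), "IB": np.array([-1.0, 0, 0]),
                   "IIA": np.array([1.0, 0, 0]), "IIB": np.array([2.0, 0, 0])}
        # at IIA: IIB and IA on opposite sides -> 180; at IA: IB vs IIA -> 180
        assert tg.opening_angle(centers) == pytest.approx(180.0)

    def test_random_centers_match_arccos_formula(self, rng):
        for _ in range(5):
            c = {n: rng.normal(size=3) for n in tg.SUBDOMAINS}

            def ang(u, v):
                return math.degrees(math.acos(
                    np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v)))

            expected = 0.5 * (ang(c["IIB"] - c["IIA"], c["IA"] - c["IIA"])
                              + ang(c["IB"] - c["IA"], c["IIA"] - c["IA"]))
            assert tg.opening_angle(c) == pytest.approx(expected)

    def test_coplanar_centers_have_zero_dihedral(self):
        centers = {"IA": np.array([0.0, 0, 0]), "IB": np.array([0.3, 1, 0]),
                   "IIA": np.array([1.0, 0.2, 0]), "IIB": np.array([1.2, 1.4, 0])}
        assert tg.dihedral_angle(centers) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("alpha", [5.0, 20.0, 60.0])
    def test_lifting_IIB_by_known_rotation_recovers_angle(self, alpha):
        # rotate IIB out of plane about the IIA-IA axis by alpha degrees
        centers = {"IA": np.array([0.0, 0, 0]), "IB": np.array([0.3, 1, 0]),
                   "IIA": np.array([2.0, 0, 0]), "IIB": np.array([1.5, 1.2, 0])}
        axis = (centers["IA"] - centers["IIA"])
        axis = axis / np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.radians(alpha) * axis)
        centers["IIB"] = centers["IIA"] + R.apply(centers["IIB"] - centers["IIA"])
        assert tg.dihedral_angle(centers) == pytest.approx(alpha, abs=1e-8)

    def test_rigid_body_motion_leaves_angles_invariant(self, rng):
        c = {n: rng.normal(size=3) for n in tg.SUBDOMAINS}
        R = Rotation.random(rng=np.random.default_rng(3))
        shift = rng.normal(size=3) * 10
        c2 = {n: R.apply(v) + shift for n, v in c.items()}
        assert tg.opening_angle(c2) == pytest.approx(tg.opening_angle(c))
        assert tg.dihedral_angle(c2) == pytest.approx(tg.dihedral_angle(c))


class TestTriadsAndEuler:
    def test_reference_frame_reproduces_reference_triad(self):
        frame, ref, triad, _ = sd.gen_rigid_pair(0.0, 0.0, 0.0, seed=0)
        t = tg.subunit_triad(ref, "minus", ref, triad)
        assert np.allclose(t.matrix, triad.matrix, atol=1e-10)

    def test_identical_triads_decompose_to_zero(self):
        _, ref, triad, _ = sd.gen_rigid_pair(0.0, 0.0, 0.0, seed=0)
        t1, t2, t3 = tg.euler_bend_twist(triad, triad)
        assert (t1, t2, t3) == (0.0, 0.0, 0.0)

    def test_translation_moves_origin_only(self):
        frame, ref, triad, _ = sd.gen_rigid_pair(0.0, 0.0, 0.0, seed=0)
        shifted = tg.StructureFrame(
            coords=ref.coords + np.array([3.0, -2.0, 7.0]),
            radii=ref.radii, subunit=ref.subunit, subdomain=ref.subdomain,
            residue_index=ref.residue_index)
        t = tg.subunit_triad(shifted, "minus", ref, triad)
        assert np.allclose(t.matrix, triad.matrix, atol=1e-10)
        assert np.allclose(t.origin - ref.coords[ref.select("minus")].mean(axis=0),
                           [3.0, -2.0, 7.0])

    def test_planted_frame_rotation_rotates_triad(self, rng):
        _, ref, triad, _ = sd.gen_rigid_pair(0.0, 0.0, 0.0, seed=0)
        R = Rotation.random(rng=np.random.default_rng(11)).as_matrix()
        rotated = tg.StructureFrame(
            coords=(R @ ref.coords.T).T, radii=ref.radii, subunit=ref.subunit,
            subdomain=ref.subdomain, residue_index=ref.residue_index)
        t = tg.subunit_triad(rotated, "minus", ref, triad)
        assert np.allclose(t.matrix, R @ triad.matrix, atol=1e-8)

    def test_pure_twist_recovered_exactly(self):
        frame, ref, triad, _ = sd.gen_rigid_pair(0.0, 0.0, 10.0, seed=1)
        tm = tg.subunit_triad(frame, "minus", ref, triad)
        tp = tg.subunit_triad(frame, "plus", ref, triad)
        t1, t2, t3 = tg.euler_bend_twist(tm, tp)
        assert abs(t3 - 10.0) < 1e-6
        assert abs(t1) < 1e-6 and abs(t2) < 1e-6

    def test_composite_rotation_recovered_in_documented_order(self):
        # 5 deg about d1 after 3 deg about d3: decomposition order is
        # d3 first, then d2, then d1, so this is exactly (5, 0, 3)
        frame, ref, triad, _ = sd.gen_rigid_pair(5.0, 0.0, 3.0, seed=2)
        tm = tg.subunit_triad(frame, "minus", ref, triad)
        tp = tg.subunit_triad(frame, "plus", ref, triad)
        t1, t2, t3 = tg.euler_bend_twist(tm, tp)
        assert abs(t1 - 5.0) < 0.1 and abs(t2) < 0.1 and abs(t3 - 3.0) < 0.1

    @pytest.mark.parametrize("angles", [(4.0, -3.0, 12.0), (-15.0, 8.0, -19.0)])
    def test_planted_euler_angles_round_trip(self, angles):
        frame, ref, triad, _ = sd.gen_rigid_pair(*angles, seed=3)
        tm = tg.subunit_triad(frame, "minus", ref, triad)
        tp = tg.subunit_triad(frame, "plus", ref, triad)
        rec = tg.euler_bend_twist(tm, tp)
        assert np.allclose(rec, angles, atol=1e-6)

    def test_global_rigid_motion_leaves_euler_angles_invariant(self):
        frame, ref, triad, _ = sd.gen_rigid_pair(4.0, -3.0, 12.0, seed=3)
        R = Rotation.random(rng=np.random.default_rng(5)).as_matrix()
        moved = tg.StructureFrame(
            coords=(R @ frame.coords.T).T + np.array([1.0, 2.0, 3.0]),
            radii=frame.radii, subunit=frame.subunit,
            subdomain=frame.subdomain, residue_index=frame.residue_index)
        tm = tg.subunit_triad(moved, "minus", ref, triad)
        tp = tg.subunit_triad(moved, "plus", ref, triad)
        assert np.allclose(tg.euler_bend_twist(tm, tp), (4.0, -3.0, 12.0),
                           atol=1e-6)

    def test_noisy_coordinates_recover_twist_within_half_degree(self):
        frame, ref, triad, _ = sd.gen_rigid_pair(0.0, 0.0, 10.0,
                                                 noise_nm=0.05, seed=4,
                                                 n_per_subdomain=30)
        tm = tg.subunit_triad(frame, "minus", ref, triad)
        tp = tg.subunit_triad(frame, "plus", ref, triad)
        _, _, t3 = tg.euler_bend_twist(tm, tp)
        assert abs(t3 - 10.0) < 0.5

    def test_gimbal_adjacent_rotation_is_flagged(self):
        frame, ref, triad, _ = sd.gen_rigid_pair(0.0, 85.0, 0.0, seed=5)
        tm = tg.subunit_triad(frame, "minus", ref, triad)
        tp = tg.subunit_triad(frame, "plus", ref, triad)
        with pytest.warns(RuntimeWarning, match="gimbal"):
            tg.euler_bend_twist(tm, tp)


class TestSASA:
    def test_single_sphere_matches_closed_form(self):
        for rho in (0.15, 0.2, 0.3):
            area = tg.sasa(np.zeros((1, 3)), np.array([rho]))
            assert area == pytest.approx(4 * math.pi * (rho + 0.14) ** 2, rel=0.01)

    def test_coincident_spheres_equal_one_sphere(self):
        one = tg.sasa(np.zeros((1, 3)), np.array([0.2]))
        two = tg.sasa(np.zeros((2, 3)), np.array([0.2, 0.2]))
        assert two == pytest.approx(one, rel=1e-9)

    def test_two_spheres_match_spherical_cap_formula(self):
        R = 0.2 + 0.14
        for d in (0.15, 0.3, 0.5):
            area = tg.sasa(np.array([[0.0, 0, 0], [d, 0, 0]]),
                           np.array([0.2, 0.2]))
            exact = 2 * (4 * math.pi * R**2 - 2 * math.pi * R * (R - d / 2))
            assert area == pytest.approx(exact, rel=0.02)

    def test_adding_a_neighbour_never_increases_per_atom_area(self, rng):
        coords = rng.normal(scale=0.3, size=(8, 3))
        radii = np.full(8, 0.17)
        before = tg.sasa(coords[:-1], radii[:-1], per_atom=True)
        after = tg.sasa(coords, radii, per_atom=True)[:-1]
        assert np.all(after <= before + 1e-12)

    def test_agrees_with_independent_library_implementation(self, rng):
        # cross-check against biotite's Shrake-Rupley on the same spheres
        import biotite.structure as struc

        n = 20
        coords = rng.normal(scale=0.4, size=(n, 3))
        radii = rng.uniform(0.15, 0.2, size=n)
        atoms = struc.AtomArray(n)
        atoms.coord = (coords * 10).astype(np.float32)  # nm -> A
        atoms.chain_id[:] = "A"
        atoms.res_id[:] = np.arange(n) + 1
        atoms.atom_name[:] = "C"
        atoms.element[:] = "C"
        ref = struc.sasa(atoms, probe_radius=1.4, point_number=960,
                         vdw_radii=(radii * 10).astype(float)).sum() / 100.0
        mine = tg.sasa(coords, radii, n_points=960)
        assert mine == pytest.approx(ref, rel=0.03)


class TestBuriedSASA:
    def test_far_separated_molecules_bury_nothing(self, rng):
        a = rng.normal(size=(5, 3))
        b = rng.normal(size=(5, 3)) + 100.0
        r = np.full(5, 0.17)
        assert tg.buried_sasa(a, r, b, r) == 0.0

    def test_symmetric_in_arguments(self, rng):
        a = rng.normal(scale=0.3, size=(6, 3))
        b = rng.normal(scale=0.3, size=(6, 3)) + 0.5
        r = np.full(6, 0.17)
        assert tg.buried_sasa(a, r, b, r) == tg.buried_sasa(b, r, a, r)

    def test_two_sphere_contact_matches_cap_formula(self):
        R = 0.2 + 0.14
        d = 0.3
        buried = tg.buried_sasa(np.zeros((1, 3)), np.array([0.2]),
                                np.array([[d, 0.0, 0.0]]), np.array([0.2]))
        # each sphere loses a cap of area 2 pi R (R - d/2); buried = mean loss
        assert buried == pytest.approx(2 * math.pi * R * (R - d / 2), rel=0.03)


class TestMembraneCurvature:
    def test_coplanar_points_have_zero_curvature(self):
        pts, _ = sd.gen_membrane_cloud(0.0, seed=0)
        assert tg.membrane_curvature(pts) == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_cylinder_curvature_recovered(self):
        # 0.8 um cell width reference: r = 400 nm, curvature 2.5e-3 /nm
        pts, truth = sd.gen_membrane_cloud(2.5e-3, seed=0)
        k = tg.membrane_curvature(pts, protein_side=truth["protein_side"])
        assert k == pytest.approx(2.5e-3, rel=0.05)
        assert k > 0  # bending toward the protein side

    def test_noisy_cylinder_curvature_within_ten_percent(self):
        pts, truth = sd.gen_membrane_cloud(2.5e-3, noise_nm=0.2, seed=1)
        k = tg.membrane_curvature(pts, protein_side=truth["protein_side"])
        assert k == pytest.approx(2.5e-3, rel=0.10)

    def test_sign_flips_with_protein_side(self):
        pts, truth = sd.gen_membrane_cloud(2.5e-3, seed=0)
        k_plus = tg.membrane_curvature(pts, protein_side=[0, 0, 1])
        k_minus = tg.membrane_curvature(pts, protein_side=[0, 0, -1])
        assert k_plus == pytest.approx(-k_minus)
        assert k_plus > 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            tg.membrane_curvature(np.zeros((4, 3)))


class TestPDBRoundTrip:
    def test_multi_model_pdb_read(self, tmp_path, rng):
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        n = 12
        stack = struc.AtomArrayStack(2, n)
        stack.coord = rng.normal(scale=5, size=(2, n, 3)).astype(np.float32)
        stack.chain_id[:] = ["A"] * 6 + ["B"] * 6
        stack.res_id[:] = list(range(9, 15)) * 2
        stack.atom_name[:] = "CA"
        stack.res_name[:] = "ALA"
        stack.element[:] = "C"
        f = pdb.PDBFile()
        f.set_structure(stack)
        path = tmp_path / "traj.pdb"
        f.write(str(path))

        frames = tg.read_pdb_frames(path, {"IA": (9, 10), "IB": (11, 12),
                                           "IIA": (13, 13), "IIB": (14, 14)})
        assert len(frames) == 2
        fr = frames[0]
        assert set(fr.subunits) == {"A", "B"}
        assert np.allclose(fr.coords, stack.coord[0] / 10.0, atol=1e-4)
        assert (fr.subdomain[fr.residue_index == 9] == "IA").all()
        assert frames[1].time_ns == pytest.approx(0.2)
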