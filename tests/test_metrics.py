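"""Superposition, RMSD/RMSF, Rg, hinge angles, dihedrals, domain rotation."""

import math

import numpy as np
import pytest

import ectodyn as ed
from ectodyn._geometry import rotation_about_axis
from ectodyn.io import Trajectory, select_atoms
from ectodyn.metrics import (
    backbone_dihedrals,
    bfactor_to_rmsf,
    domain_rotation_angle,
    hinge_angle,
    kabsch_superpose,
    radius_of_gyration,
    rmsd_series,
    rmsf,
    rmsf_to_bfactor,
)
from conftest import make_structure


# ---------------------------------------------------------------------------
# Independent oracles


def quaternion_rmsd(mobile, reference):
    """Quaternion-eigenvalue superposition RMSD (independent of Kabsch/SVD)."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    M = mob.T @ ref
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam_max = np.linalg.eigvalsh(K)[-1]
    n = len(mob)
    msd = (np.sum(mob ** 2) + np.sum(ref ** 2) - 2.0 * lam_max) / n
    return math.sqrt(max(msd, 0.0))


def nerf_chain(internal):
    """Independent internal-coordinate chain builder (matrix formulation).

    ``internal`` is a list of (bond, angle_deg, torsion_deg) triples; the
    first three atoms are seeded canonically.  Uses an explicit local-frame
    construction distinct from the package's placement routine.
    """
    coords = [np.array([0.0, 0.0, 0.0]),
              np.array([internal[0][0], 0.0, 0.0])]
    b2, a2, _ = internal[1]
    ang = math.radians(a2)
    coords.append(coords[1] + b2 * np.array([-math.cos(ang), math.sin(ang), 0.0]))
    for bond, angle_deg, torsion_deg in internal[2:]:
        A, B, C = coords[-3], coords[-2], coords[-1]
        theta, chi = math.radians(angle_deg), math.radians(torsion_deg)
        u = (C - B) / np.linalg.norm(C - B)
        n = np.cross(B - A, u)
        n = n / np.linalg.norm(n)
        # open the bond angle about the plane normal, then twist about B->C
        d = rotation_about_axis(n, -theta) @ (-u)
        d = rotation_about_axis(u, chi) @ d
        coords.append(C + bond * d)
    return np.array(coords)


def build_ideal_helix(n_res, phi=-57.0, psi=-47.0, omega=180.0):
    """Ideal polypeptide backbone (N, CA, C per residue) from internal coords."""
    b_n_ca, b_ca_c, b_c_n = 1.458, 1.525, 1.329
    a_n_ca_c, a_ca_c_n, a_c_n_ca = 111.0, 116.2, 121.7
    internal = [(b_n_ca, 0.0, 0.0), (b_ca_c, a_n_ca_c, 0.0)]
    for i in range(n_res - 1):
        internal.append((b_c_n, a_ca_c_n, psi))     # N(i+1), torsion psi(i)
        internal.append((b_n_ca, a_c_n_ca, omega))  # CA(i+1), torsion omega
        internal.append((b_ca_c, a_n_ca_c, phi))    # C(i+1), torsion phi(i+1)
    chain = nerf_chain(internal)
    return chain.reshape(n_res, 3, 3)  # (res, atom N/CA/C, xyz)


def helix_structure(n_res, **kw):
    bb = build_ideal_helix(n_res, **kw)
    coords = bb.reshape(-1, 3)
    n = len(coords)
    return make_structure(
        coords,
        elements=np.tile(["N", "C", "C"], n_res),
        names=np.tile(["N", "CA", "C"], n_res),
        res_ids=np.repeat(np.arange(1, n_res + 1), 3),
        masses=np.tile([14.007, 12.011, 12.011], n_res),
        res_names=["ALA"] * n,
    )


# ---------------------------------------------------------------------------
# Superposition


class TestKabsch:
    def test_identity(self):
        x = np.random.default_rng(0).normal(size=(8, 3))
        res = kabsch_superpose(x, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_rigid_transform_recovered(self):
        x = np.random.default_rng(1).normal(size=(10, 3))
        R = rotation_about_axis(np.array([0.0, 0.0, 1.0]), math.pi / 2)
        y = x @ R.T + np.array([5.0, -3.0, 2.0])
        res = kabsch_superpose(y, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.normal(size=(12, 3))
            b = rng.normal(size=(12, 3))
            assert kabsch_superpose(a, b).rmsd == pytest.approx(
                quaternion_rmsd(a, b), abs=1e-8)

    def test_reflection_corrected(self):
        x = np.random.default_rng(3).normal(size=(6, 3))
        res = kabsch_superpose(-x, x)  # mirror image
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_collinear_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)

    def test_rmsd_symmetric_and_rigid_invariant(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(9, 3)), rng.normal(size=(9, 3))
        r_ab = kabsch_superpose(a, b).rmsd
        assert kabsch_superpose(b, a).rmsd == pytest.approx(r_ab, abs=1e-10)
        R = rotation_about_axis(np.array([1.0, 2.0, 3.0]), 1.1)
        assert kabsch_superpose(a @ R.T + 7.0, b).rmsd == pytest.approx(
            r_ab, abs=1e-10)


class TestRmsdSeries:
    def test_identical_frames_zero(self, ala5_path):
        s = ed.read_pdb(ala5_path)
        traj = Trajectory(topology=s, frames=np.repeat(s.coords[None], 4, 0))
        assert np.allclose(rmsd_series(traj, s, atom_names=None), 0.0,
                           atol=1e-10)

    def test_translations_removed(self, ala5_path):
        s = ed.read_pdb(ala5_path)
        rng = np.random.default_rng(5)
        frames = s.coords[None] + rng.normal(size=(6, 1, 3)) * 10
        traj = Trajectory(topology=s, frames=frames)
        assert np.allclose(rmsd_series(traj, s, atom_names=None), 0.0,
                           atol=1e-9)


class TestRmsf:
    def test_static_trajectory_zero(self, ala5_path):
        s = ed.read_pdb(ala5_path)
        traj = Trajectory(topology=s, frames=np.repeat(s.coords[None], 5, 0))
        assert np.allclose(rmsf(traj, fit=False), 0.0)

    def test_single_frame_rejected(self, ala5_path):
        s = ed.read_pdb(ala5_path)
        traj = Trajectory(topology=s, frames=s.coords[None])
        with pytest.raises(ValueError, match="2 frames"):
            rmsf(traj)

    def test_isotropic_noise_gives_sigma_sqrt3(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(20, 3)) * 10
        s = make_structure(base)
        sigma = 0.5
        frames = base[None] + rng.normal(0, sigma, size=(5000, 20, 3))
        vals = rmsf(Trajectory(topology=s, frames=frames), fit=False)
        assert np.abs(vals.mean() / (sigma * math.sqrt(3)) - 1) < 0.03

    def test_fit_removes_rigid_tumbling(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(15, 3)) * 8
        frames = np.stack([
            base @ rotation_about_axis(rng.normal(size=3), ang).T + rng.normal(size=3)
            for ang in np.linspace(0, 2, 40)
        ])
        s = make_structure(base)
        vals = rmsf(Trajectory(topology=s, frames=frames), fit=True)
        assert vals.max() < 1e-8


class TestBfactorRelation:
    def test_zero(self):
        assert bfactor_to_rmsf(0.0) == 0.0

    def test_analytic_point(self):
        B = 8 * math.pi ** 2 / 3
        assert bfactor_to_rmsf(B) == pytest.approx(1.0, abs=1e-12)

    def test_roundtrip_exact(self):
        B = np.linspace(0, 120, 13)
        assert np.allclose(rmsf_to_bfactor(bfactor_to_rmsf(B)), B,
                           rtol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bfactor_to_rmsf(-1.0)
        with pytest.raises(ValueError):
            rmsf_to_bfactor(-0.1)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.zeros((1, 3)), np.ones(1)) == 0.0

    def test_two_unit_masses(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        assert radius_of_gyration(coords, np.ones(2)) == pytest.approx(1.0)

    def test_rigid_invariance_and_scaling_monotone(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(30, 3)) * 5
        m = rng.uniform(1, 16, size=30)
        rg = radius_of_gyration(x, m)
        R = rotation_about_axis(np.array([1.0, 1.0, 0.0]), 0.7)
        assert radius_of_gyration(x @ R.T + 3.0, m) == pytest.approx(rg)
        for s in (1.0, 1.5, 2.0):
            assert radius_of_gyration(x * s, m) >= rg - 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((0, 3)), np.zeros(0))


class TestHingeAngle:
    def _three_groups(self, pa, pb, pv):
        coords = np.array([pa, pb, pv], dtype=float)
        m = np.ones(3)
        return coords, m, np.array([0]), np.array([1]), np.array([2])

    def test_collinear_is_180(self):
        coords, m, a, b, v = self._three_groups([-5, 0, 0], [5, 0, 0], [0, 0, 0])
        assert hinge_angle(coords, m, a, b, v) == pytest.approx(180.0)

    def test_orthogonal_is_90(self):
        coords, m, a, b, v = self._three_groups([4, 0, 0], [0, 3, 0], [0, 0, 0])
        assert hinge_angle(coords, m, a, b, v) == pytest.approx(90.0)

    def test_plane_projection(self):
        # vectors differ only out of the XY plane: projected angle is 0
        coords, m, a, b, v = self._three_groups([1, 0, 1], [1, 0, -1], [0, 0, 0])
        assert hinge_angle(coords, m, a, b, v, plane=(0, 1)) == pytest.approx(0.0)

    def test_degenerate_projection_flagged(self):
        coords, m, a, b, v = self._three_groups([0, 0, 1], [1, 0, 0], [0, 0, 0])
        assert math.isnan(hinge_angle(coords, m, a, b, v, plane=(0, 1)))

    def test_global_rigid_invariance(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(9, 3))
        m = rng.uniform(1, 14, 9)
        a, b, v = np.arange(3), np.arange(3, 6), np.arange(6, 9)
        ang = hinge_angle(coords, m, a, b, v)
        R = rotation_about_axis(np.array([0.2, 1.0, -0.5]), 2.2)
        assert hinge_angle(coords @ R.T + 11.0, m, a, b, v) == pytest.approx(
            ang, abs=1e-9)

    def test_generator_state_mean_recovered(self, toy_topology, domain_map,
                                            two_state_run):
        traj, truth = two_state_run
        ia = select_atoms(toy_topology, ranges=domain_map["D1"])
        ib = select_atoms(toy_topology, ranges=domain_map["D3"])
        iv = select_atoms(toy_topology, ranges=domain_map["linker"])
        angles = np.array([
            hinge_angle(traj.frames[f], toy_topology.mass, ia, ib, iv)
            for f in range(traj.n_frames)
        ])
        labels = truth.state_labels()
        assert abs(angles[labels == "closed"].mean() - 115.0) < 2.0
        assert abs(angles[labels == "open"].mean() - 165.0) < 2.0


class TestBackboneDihedrals:
    def test_chain_start_phi_missing(self):
        s = helix_structure(4)
        df = backbone_dihedrals(s, [("A", 1), ("A", 2)])
        first = df[df.residue == 1].iloc[0]
        assert math.isnan(first.phi) and not math.isnan(first.psi)

    def test_ideal_helix_recovered(self):
        s = helix_structure(6, phi=-57.0, psi=-47.0)
        df = backbone_dihedrals(s, [("A", r) for r in range(2, 6)])
        assert np.allclose(df.phi, -57.0, atol=0.5)
        assert np.allclose(df.psi, -47.0, atol=0.5)

    def test_mirror_negates_angles(self):
        s = helix_structure(5)
        mirrored = s.with_coords(s.coords * np.array([-1.0, 1.0, 1.0]))
        d1 = backbone_dihedrals(s, [("A", 3)])
        d2 = backbone_dihedrals(mirrored, [("A", 3)])
        assert d2.phi.iloc[0] == pytest.approx(-d1.phi.iloc[0], abs=1e-8)
        assert d2.psi.iloc[0] == pytest.approx(-d1.psi.iloc[0], abs=1e-8)

    def test_sincos_identity(self, two_state_run, domain_map):
        traj, _ = two_state_run
        df = backbone_dihedrals(
            traj.topology.with_coords(traj.frames[0]), domain_map["linker"])
        rad = np.deg2rad(df[["phi", "psi"]].to_numpy())
        defined = rad[np.isfinite(rad)]
        assert np.allclose(np.sin(defined) ** 2 + np.cos(defined) ** 2, 1.0,
                           atol=1e-12)


class TestDomainRotation:
    def test_identical_structures_zero(self, toy_topology, domain_map):
        ang = domain_rotation_angle(toy_topology, toy_topology,
                                    domain_map["D1"] + domain_map["D2"],
                                    domain_map["D3"])
        assert ang == pytest.approx(0.0, abs=1e-6)

    def test_constructed_90_degree_rotation(self, toy_topology, domain_map):
        from ectodyn.io import select_atoms as sel
        from ectodyn.metrics import center_of_mass
        idx3 = sel(toy_topology, ranges=domain_map["D3"])
        idxl = sel(toy_topology, ranges=domain_map["linker"])
        v = center_of_mass(toy_topology.coords[idxl], toy_topology.mass[idxl])
        w = center_of_mass(toy_topology.coords[idx3], toy_topology.mass[idx3]) - v
        R = rotation_about_axis(w, math.pi / 2)
        coords = toy_topology.coords.copy()
        coords[idx3] = (coords[idx3] - v) @ R.T + v
        rotated = toy_topology.with_coords(coords)
        ang = domain_rotation_angle(toy_topology, rotated,
                                    domain_map["D1"] + domain_map["D2"],
                                    domain_map["D3"])
        assert ang == pytest.approx(90.0, abs=1e-6)

    def test_symmetry(self, toy_topology, domain_map, two_state_run):
        traj, _ = two_state_run
        other = toy_topology.with_coords(traj.frames[-1])
        args = (domain_map["D1"] + domain_map["D2"], domain_map["D3"])
        ab = domain_rotation_angle(toy_topology, other, *args)
        ba = domain_rotation_angle(other, toy_topology, *args)
        assert ab == pytest.approx(ba, abs=1e-6)
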