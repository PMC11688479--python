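import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from phytoscreen import synthdata
from phytoscreen.trajstats import (
    Trajectory,
    cluster_frames,
    dccm,
    kabsch_superpose,
    pca_modes,
    radius_of_gyration,
    read_multimodel_pdb,
    read_xyz_frames,
    rmsd_series,
    rmsf,
    sasa,
    sasa_series,
    write_multimodel_pdb,
    write_xyz_frames,
)


def ca_traj(coords):
    coords = np.asarray(coords, dtype=float)
    return Trajectory(coords=coords, atom_names=["CA"] * coords.shape[1])


@pytest.fixture(scope="module")
def wiggle():
    rng = np.random.default_rng(0)
    base = rng.normal(scale=5.0, size=(12, 3))
    return ca_traj(base[None] + rng.normal(scale=0.4, size=(40, 12, 3)))


class TestKabsch:
    def test_self_fit_is_identity(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(6, 3))
        rot, trans, fitted = kabsch_superpose(a, a)
        assert np.allclose(rot, np.eye(3), atol=1e-10)
        assert np.allclose(fitted, a, atol=1e-10)

    def test_rigid_motion_recovered_exactly(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(10, 3))
        rot = Rotation.random(random_state=3).as_matrix()
        moved = a @ rot.T + np.array([3.0, -4.0, 5.0])
        _, _, fitted = kabsch_superpose(moved, a)
        assert np.abs(fitted - a).max() < 1e-8

    def test_rotation_is_always_proper(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            rot, _, _ = kabsch_superpose(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)))
            assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_matches_numeric_minimization_on_4_atom_toys(self):
        """Fitted RMSD equals brute-force minimization over rotations to 1e-6."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            a, b = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
            _, _, fitted = kabsch_superpose(a, b)
            kabsch_rmsd = np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1)))

            def objective(v):
                rot = Rotation.from_rotvec(v).as_matrix()
                pa = (a - a.mean(0)) @ rot.T
                return np.sqrt(np.mean(np.sum((pa - (b - b.mean(0))) ** 2, axis=1)))

            numeric = min(
                minimize(
                    objective, x0, method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12},
                ).fun
                for x0 in rng.normal(size=(8, 3))
            )
            assert kabsch_rmsd == pytest.approx(numeric, abs=1e-6)

    def test_collinear_selection_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line + 1.0)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdRmsf:
    def test_static_trajectory_rmsd_zero(self):
        base = np.random.default_rng(0).normal(size=(8, 3))
        t = ca_traj(np.repeat(base[None], 5, axis=0))
        assert np.allclose(rmsd_series(t).values, 0.0, atol=1e-10)

    def test_rigid_motions_only_rmsd_vanishes(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(8, 3))
        frames = []
        for i in range(6):
            rot = Rotation.random(random_state=i).as_matrix()
            frames.append(base @ rot.T + rng.uniform(-10, 10, 3))
        assert np.all(rmsd_series(ca_traj(np.stack(frames))).values < 1e-8)

    def test_single_jittered_atom_rmsd_matches_direct_sum(self):
        # Amplitude on 1 of A atoms: RMSD_f = |d_f| / sqrt(A) without fitting;
        # anchor atoms dominate so fitting changes little.  Use the direct
        # summation oracle on the fitted coordinates themselves.
        rng = np.random.default_rng(6)
        base = rng.normal(scale=8.0, size=(30, 3))
        coords = np.repeat(base[None], 50, axis=0)
        coords[:, 0, 0] += rng.normal(scale=0.3, size=50)
        t = ca_traj(coords)
        got = rmsd_series(t).values
        for f in [3, 17, 42]:
            _, _, fitted = kabsch_superpose(coords[f], coords[0])
            direct = math.sqrt(np.mean(np.sum((fitted - coords[0]) ** 2, axis=1)))
            assert got[f] == pytest.approx(direct, abs=1e-12)

    def test_static_rmsf_zero(self):
        base = np.random.default_rng(7).normal(size=(6, 3))
        t = ca_traj(np.repeat(base[None], 4, axis=0))
        assert np.allclose(rmsf(t), 0.0, atol=1e-12)

    def test_two_state_atom_rmsf_equals_amplitude(self):
        base = np.random.default_rng(8).normal(scale=6.0, size=(10, 3))
        coords = np.repeat(base[None], 20, axis=0)
        coords[::2, 0, 0] += 0.7
        coords[1::2, 0, 0] -= 0.7
        t = ca_traj(coords)
        values = rmsf(t, superpose=False)
        assert values[0] == pytest.approx(0.7)
        assert np.allclose(values[1:], 0.0, atol=1e-12)

    def test_planted_flexible_block_exceeds_background(self):
        for seed in range(10):
            pt = synthdata.gen_trajectory(
                seed, n_frames=80, n_atoms=40,
                blocks=((0, 20), (20, 40)), sigma=(0.8, 0.2),
            )
            values = rmsf(pt.trajectory)
            assert values[:20].mean() > values[20:].mean()


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        t = Trajectory(coords=np.zeros((1, 1, 3)), atom_names=["C"])
        assert radius_of_gyration(t).values[0] == 0.0

    def test_two_equal_masses_half_distance(self):
        t = ca_traj([[[0, 0, 0], [3.0, 0, 0]]])
        assert radius_of_gyration(t).values[0] == pytest.approx(1.5)

    def test_unit_cube_corners(self):
        cube = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float
        )
        t = ca_traj(cube[None])
        assert radius_of_gyration(t).values[0] == pytest.approx(math.sqrt(3) / 2)

    def test_mass_weighting_matters(self):
        coords = np.array([[[0, 0, 0], [2.0, 0, 0]]])
        heavy = Trajectory(coords=coords, atom_names=["C", "C"],
                           masses=np.array([3.0, 1.0]))
        # com at 0.5; Rg = sqrt((3*0.25 + 1*2.25)/4) = sqrt(0.75)
        assert radius_of_gyration(heavy).values[0] == pytest.approx(math.sqrt(0.75))


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        total, _ = sasa(np.zeros((1, 3)), np.array([1.9]), probe=1.4)
        assert total == pytest.approx(4 * math.pi * 3.3**2, rel=1e-9)

    def test_distant_pair_additivity(self):
        total, _ = sasa(
            np.array([[0, 0, 0], [50.0, 0, 0]]), np.array([1.9, 1.5]), probe=1.4
        )
        isolated = 4 * math.pi * (3.3**2 + 2.9**2)
        assert total == pytest.approx(isolated, rel=0.01)

    def test_coincident_pair_counts_union_surface_once(self):
        total, _ = sasa(np.zeros((2, 3)), np.array([1.9, 1.9]), probe=1.4,
                        n_points=10000)
        assert total == pytest.approx(4 * math.pi * 3.3**2, rel=0.01)

    def test_point_count_convergence(self):
        rng = np.random.default_rng(9)
        frame = rng.uniform(0, 10, size=(20, 3))
        radii = np.full(20, 1.7)
        coarse, _ = sasa(frame, radii, n_points=960)
        fine, _ = sasa(frame, radii, n_points=4000)
        assert abs(coarse - fine) / fine < 0.02

    def test_agrees_with_mdtraj_reference(self):
        """Independent oracle: mdtraj's Shrake-Rupley on the same toy."""
        md = pytest.importorskip("mdtraj")
        rng = np.random.default_rng(10)
        xyz_nm = rng.uniform(0, 1.0, size=(1, 20, 3))
        top = md.Topology()
        chain = top.add_chain()
        for _ in range(20):
            res = top.add_residue("GLY", chain)
            top.add_atom("C", md.element.carbon, res)
        ref = md.shrake_rupley(
            md.Trajectory(xyz_nm, top), probe_radius=0.14, n_sphere_points=960
        ).sum() * 100.0  # nm^2 -> A^2
        ours, _ = sasa(xyz_nm[0] * 10.0, np.full(20, 1.7), probe=1.4, n_points=960)
        assert ours == pytest.approx(float(ref), rel=0.01)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            sasa(np.zeros((1, 3)), np.array([0.0]))


class TestDccmPca:
    ANCHORS = np.array([[0, 0, 0], [10.0, 0, 0], [0, 10.0, 0], [0, 0, 10.0]])

    def test_diagonal_is_one_and_symmetric(self, wiggle):
        m = dccm(wiggle, selection=None)
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)
        assert m.min() >= -1.0 and m.max() <= 1.0

    def test_opposite_motion_gives_minus_one(self):
        rng = np.random.default_rng(11)
        coords = np.repeat(self.ANCHORS[None], 100, axis=0)
        s = rng.normal(size=100)
        coords[:, 0, 1] += s
        coords[:, 1, 1] -= s
        m = dccm(ca_traj(coords), selection=None, superpose=False)
        assert m[0, 1] == pytest.approx(-1.0)

    def test_planted_block_correlation_recovered(self):
        for seed in range(10):
            pt = synthdata.gen_trajectory(
                seed, n_frames=120, hinge_amplitude=0.6, hinge_sign=-1
            )
            m = dccm(pt.trajectory)
            lo0, hi0 = pt.blocks[0]
            lo1, hi1 = pt.blocks[1]
            within = m[lo0:hi0, lo0:hi0][np.triu_indices(hi0 - lo0, k=1)].mean()
            between = m[lo0:hi0, lo1:hi1].mean()
            assert within > between
            assert between < -0.1  # anticorrelation has the planted sign

    def test_null_trajectory_has_weak_off_diagonal(self):
        pt = synthdata.gen_trajectory(3, n_frames=400, hinge_amplitude=0.0)
        m = dccm(pt.trajectory)
        off = np.abs(m[np.triu_indices(m.shape[0], k=1)])
        assert np.median(off) < 0.2

    def test_pc1_fraction_one_for_1d_motion(self):
        rng = np.random.default_rng(12)
        coords = np.repeat(self.ANCHORS[None], 60, axis=0)
        coords[:, 0, 0] += rng.normal(size=60)
        modes = pca_modes(ca_traj(coords), superpose=False)
        assert modes.variance_fractions[0] == pytest.approx(1.0)
        assert modes.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_jitter_gives_flat_spectrum(self):
        rng = np.random.default_rng(13)
        base = rng.normal(scale=5.0, size=(4, 3))
        coords = base[None] + rng.normal(scale=0.5, size=(4000, 4, 3))
        modes = pca_modes(ca_traj(coords), superpose=False)
        fr = modes.variance_fractions
        assert fr.max() < 2 * fr[fr > 1e-12].min()

    def test_hinge_dominates_pc1(self):
        pt = synthdata.gen_trajectory(
            5, n_frames=200, sigma=(0.15, 0.15), hinge_amplitude=1.5
        )
        modes = pca_modes(pt.trajectory)
        assert modes.variance_fractions[0] > 0.5


class TestRigidInvariance:
    def test_statistics_survive_global_rigid_contamination(self):
        clean = synthdata.gen_trajectory(8, n_frames=60, hinge_amplitude=0.5)
        dirty = synthdata.gen_trajectory(
            8, n_frames=60, hinge_amplitude=0.5, rigid_contamination=True
        )
        assert np.allclose(
            rmsd_series(clean.trajectory).values,
            rmsd_series(dirty.trajectory).values,
            atol=1e-6,
        )
        assert np.allclose(
            rmsf(clean.trajectory), rmsf(dirty.trajectory), atol=1e-6
        )
        assert np.allclose(
            dccm(clean.trajectory), dccm(dirty.trajectory), atol=1e-6
        )


class TestClusterFrames:
    def test_two_conformers_recovered(self):
        rng = np.random.default_rng(14)
        a = np.array([[0, 0, 0], [10.0, 0, 0], [0, 10.0, 0], [0, 0, 10.0]])
        b = a + np.array([[0, 0, 0], [0, 5.0, 0], [0, 0, 0], [0, 0, 0]])
        coords = np.stack([a if i % 2 == 0 else b for i in range(20)])
        coords += rng.normal(scale=0.01, size=coords.shape)
        reps = cluster_frames(ca_traj(coords), k=2, seed=0)
        assert len(reps) == 2
        assert reps[0] % 2 != reps[1] % 2  # one from each conformer

    def test_k_one_returns_frame_nearest_mean(self, wiggle):
        reps = cluster_frames(wiggle, k=1, seed=0)
        assert len(reps) == 1

    def test_k_equal_frames_returns_all(self, wiggle):
        assert cluster_frames(wiggle, k=wiggle.n_frames, seed=0) == list(
            range(wiggle.n_frames)
        )


class TestIO:
    def test_xyz_roundtrip(self, tmp_path, wiggle):
        path = tmp_path / "traj.xyz"
        write_xyz_frames(wiggle, path)
        back = read_xyz_frames(path)
        assert back.coords.shape == wiggle.coords.shape
        assert np.allclose(back.coords, wiggle.coords, atol=1e-5)

    def test_pdb_roundtrip(self, tmp_path, wiggle):
        path = tmp_path / "traj.pdb"
        write_multimodel_pdb(wiggle, path)
        back = read_multimodel_pdb(path)
        assert back.coords.shape == wiggle.coords.shape
        assert np.allclose(back.coords, wiggle.coords, atol=1e-2)  # PDB precision
        assert back.atom_names == wiggle.atom_names

    def test_histograms_normalize(self, wiggle):
        s = sasa_series(wiggle, n_points=240)
        assert s.relative_frequencies.sum() == pytest.approx(1.0, abs=1e-9)
        assert (s.relative_frequencies >= 0).all()
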