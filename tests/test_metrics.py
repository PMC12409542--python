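"""Kabsch superposition, RMSD series, RMSF profiles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from confdyn.errors import ConfigurationError, InsufficientDataError
from confdyn.metrics import apply_superposition, kabsch_superpose, rmsd_series, rmsf
from confdyn.trajectory import TrajectoryEnsemble, select_atoms

from conftest import make_peptide


def _rigid(coords, rotvec, shift):
    rot = Rotation.from_rotvec(rotvec).as_matrix()
    return coords @ rot.T + np.asarray(shift)


class TestKabsch:
    def test_identity(self):
        ref = np.random.default_rng(0).normal(size=(6, 3))
        res = kabsch_superpose(ref, ref)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_rigid_motion_removed(self):
        ref = np.random.default_rng(1).normal(size=(8, 3))
        mob = _rigid(ref, [0, 0, np.pi / 2], [5.0, 0.0, 0.0])
        res = kabsch_superpose(mob, ref)
        assert res.rmsd <= 1e-6
        np.testing.assert_allclose(apply_superposition(mob, res), ref, atol=1e-8)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a, b = rng.normal(size=(2, 7, 3))
            res = kabsch_superpose(a, b)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_reflection_excluded(self):
        """A mirrored point set must NOT reach rmsd 0 via an improper rotation."""
        ref = np.random.default_rng(3).normal(size=(10, 3))
        mirrored = ref * np.array([1.0, 1.0, -1.0])
        res = kabsch_superpose(mirrored, ref)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-10)
        assert res.rmsd > 0.1

    def test_three_point_brute_force_oracle(self):
        """Displaced 3-point case agrees with a fine rotation-grid search."""
        ref = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        mob = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 1.0]])
        res = kabsch_superpose(mob, ref)

        ref_c = ref - ref.mean(axis=0)
        mob_c = mob - mob.mean(axis=0)
        # brute force over a rotation grid, refined around the best cell
        best = np.inf
        grid = Rotation.create_group("O")  # octahedral seeds
        seeds = grid.as_rotvec()
        rng = np.random.default_rng(0)
        for seed_vec in seeds:
            vec = seed_vec
            step = 0.5
            for _ in range(60):
                cands = vec + rng.normal(scale=step, size=(40, 3))
                rmsds = []
                for c in cands:
                    r = Rotation.from_rotvec(c).as_matrix()
                    rmsds.append(np.sqrt(((mob_c @ r.T - ref_c) ** 2).sum() / 3))
                i = int(np.argmin(rmsds))
                if rmsds[i] < best:
                    best = rmsds[i]
                    vec = cands[i]
                step *= 0.9
        assert res.rmsd == pytest.approx(best, abs=1e-3)

    def test_degenerate_inputs(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ConfigurationError):
            kabsch_superpose(line, line)
        with pytest.raises(ConfigurationError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdSeries:
    def test_static_trajectory_zero(self, toy_peptide):
        static = TrajectoryEnsemble(
            coords=np.repeat(toy_peptide.coords[:1], 5, axis=0),
            dt=0.1,
            atoms=toy_peptide.atoms,
        )
        sel = select_atoms(static, "backbone")
        np.testing.assert_allclose(rmsd_series(static, sel), 0.0, atol=1e-9)

    def test_rigid_rotation_zero(self, toy_peptide):
        frames = [toy_peptide.coords[0]]
        rng = np.random.default_rng(4)
        for _ in range(6):
            frames.append(_rigid(frames[0], rng.normal(size=3), rng.normal(size=3) * 5))
        traj = TrajectoryEnsemble(coords=np.stack(frames), dt=0.1, atoms=toy_peptide.atoms)
        sel = select_atoms(traj, "all")
        np.testing.assert_allclose(rmsd_series(traj, sel), 0.0, atol=1e-6)

    def test_reference_frame_is_zero(self, two_well_data):
        _, traj, _ = two_well_data
        sel = select_atoms(traj, "calpha")
        series = rmsd_series(traj, sel, reference_frame=3)
        assert series[3] == pytest.approx(0.0, abs=1e-9)
        assert (series >= -1e-12).all()

    def test_global_rigid_motion_invariance(self, two_well_data):
        """Applying one rigid motion to every frame leaves the series unchanged."""
        _, traj, _ = two_well_data
        small = traj.stride(20)
        sel = select_atoms(small, "calpha")
        base = rmsd_series(small, sel)
        moved = TrajectoryEnsemble(
            coords=np.stack(
                [_rigid(f, [0.3, -0.2, 1.0], [4.0, -7.0, 2.0]) for f in small.coords]
            ),
            dt=small.dt,
            atoms=small.atoms,
        )
        np.testing.assert_allclose(rmsd_series(moved, sel), base, atol=1e-6)

    def test_mean_reference(self, two_well_data):
        _, traj, _ = two_well_data
        small = traj.stride(50)
        sel = select_atoms(small, "calpha")
        series = rmsd_series(small, sel, reference="mean")
        assert (series > 0).all()  # no frame equals the mean structure exactly

    def test_bad_reference_frame(self, toy_peptide):
        sel = select_atoms(toy_peptide, "all")
        with pytest.raises(ConfigurationError):
            rmsd_series(toy_peptide, sel, reference_frame=99)


class TestRmsf:
    def test_static_profile_zero(self, toy_peptide):
        static = TrajectoryEnsemble(
            coords=np.repeat(toy_peptide.coords[:1], 4, axis=0),
            dt=0.1,
            atoms=toy_peptide.atoms,
        )
        sel = select_atoms(static, "all")
        np.testing.assert_allclose(rmsf(static, sel).rmsf, 0.0, atol=1e-9)

    def test_two_point_alternation_closed_form(self):
        """An atom alternating between two points 2 A apart has RMSF 1.0 A.

        Many fixed anchor atoms surrounding the probe keep the
        superposition from absorbing the motion (translation compensation
        ~1/n_atoms; a compact anchor cloud denies the rotation any lever
        arm, which a distant cloud would provide).
        """
        rng = np.random.default_rng(5)
        n_fixed = 200
        anchors = rng.uniform(-5, 5, size=(n_fixed, 3))
        frames = []
        for t in range(40):
            pos = np.vstack([[[2.0 * (t % 2), 0.0, 0.0]], anchors])
            frames.append(pos)
        import pandas as pd

        atoms = pd.DataFrame(
            {
                "name": ["CA"] * (n_fixed + 1),
                "resname": ["ALA"] * (n_fixed + 1),
                "resid": np.arange(1, n_fixed + 2),
                "chain": ["A"] * (n_fixed + 1),
                "element": ["C"] * (n_fixed + 1),
            }
        )
        traj = TrajectoryEnsemble(coords=np.stack(frames), dt=0.1, atoms=atoms)
        sel = select_atoms(traj, "all")
        prof = rmsf(traj, sel)
        assert prof.rmsf[0] == pytest.approx(1.0, abs=0.02)
        assert prof.rmsf[1:].max() < 0.05

    def test_isotropic_jitter_closed_form(self):
        """Per-axis sigma = 0.2 A jitter gives RMSF = 0.2*sqrt(3) within 5%.

        The superposition absorbs 6 of the 3N coordinate degrees of
        freedom per frame, deflating each atom's apparent variance by
        ~(3N-6)/3N; 80 atoms keep that deflation (~1.3%) inside the 5%
        band.
        """
        rng = np.random.default_rng(6)
        n_atoms, n_frames, sigma = 80, 5000, 0.2
        base = rng.uniform(-30, 30, size=(n_atoms, 3))
        coords = base[None] + rng.normal(scale=sigma, size=(n_frames, n_atoms, 3))
        import pandas as pd

        atoms = pd.DataFrame(
            {
                "name": ["CA"] * n_atoms,
                "resname": ["GLY"] * n_atoms,
                "resid": np.arange(1, n_atoms + 1),
                "chain": ["A"] * n_atoms,
                "element": ["C"] * n_atoms,
            }
        )
        traj = TrajectoryEnsemble(coords=coords, dt=0.1, atoms=atoms)
        prof = rmsf(traj, select_atoms(traj, "all"))
        expected = sigma * np.sqrt(3.0)
        np.testing.assert_allclose(prof.rmsf, expected, rtol=0.05)

    def test_rmsf_tracks_lift_loading(self, two_well_data):
        """Atoms with larger variance-weighted lift loadings fluctuate more.

        Closed-form prediction per atom: RMSF_i^2 ~ sum_d |A_i,:,d|^2
        var(z_d) + 3 sigma^2, with A the stored lift matrix and z the
        latent trajectory.
        """
        latent, traj, _ = two_well_data
        sel = select_atoms(traj, "all")
        prof = rmsf(traj, sel)
        lift = traj.metadata["lift_matrix"]  # (n_atoms, 3, d)
        var_d = latent.positions.var(axis=0)
        sigma = traj.metadata["noise_sigma"]
        predicted = np.sqrt(
            (lift**2 * var_d[None, None, :]).sum(axis=(1, 2)) + 3 * sigma**2
        )
        from scipy.stats import spearmanr

        rho, _ = spearmanr(predicted, prof.rmsf)
        assert rho > 0.9

    def test_single_frame_error(self, toy_peptide):
        single = TrajectoryEnsemble(
            coords=toy_peptide.coords[:1], dt=0.1, atoms=toy_peptide.atoms
        )
        with pytest.raises(InsufficientDataError):
            rmsf(single, select_atoms(single, "all"))
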