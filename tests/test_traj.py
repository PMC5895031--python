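import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from _oracles import direct_radius_of_gyration, rotation_search_rmsd
from varstab import synth, traj
from varstab.errors import (
    GeometryError,
    InputError,
    InsufficientDataError,
    SelectionError,
    TrajectoryIntegrityError,
)


def _random_rigid(rng):
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    return rot, rng.uniform(-10, 10, size=3)


class TestKabsch:
    def test_identical_coordinates_give_zero_rmsd_and_identity(self, rng):
        coords = rng.normal(size=(10, 3))
        res = traj.kabsch_superpose(coords, coords)
        assert res.rmsd < 1e-12
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)
        assert abs(np.linalg.det(res.rotation) - 1.0) < 1e-9

    def test_known_rotation_is_inverted(self, rng):
        coords = rng.normal(size=(8, 3))
        rot, shift = _random_rigid(rng)
        moved = coords @ rot.T + shift
        res = traj.kabsch_superpose(moved, coords)
        assert res.rmsd < 1e-9
        assert np.allclose(res.rotation, rot.T, atol=1e-8)
        assert np.allclose(res.apply(moved), coords, atol=1e-8)

    def test_superposed_rmsd_never_exceeds_raw_rmsd(self, rng):
        for _ in range(25):
            a = rng.normal(size=(6, 3)) * 3
            b = rng.normal(size=(6, 3)) * 3
            raw = math.sqrt(((a - b) ** 2).sum(axis=1).mean())
            assert traj.kabsch_superpose(a, b).rmsd <= raw + 1e-12

    def test_agrees_with_rotation_search_oracle(self, rng):
        for case in range(10):
            n = int(rng.integers(4, 7))
            a = rng.normal(size=(n, 3)) * 2
            b = a + rng.normal(size=(n, 3)) * 0.8
            w = rng.uniform(0.5, 2.0, size=n)
            ours = traj.kabsch_superpose(a, b, weights=w).rmsd
            brute = rotation_search_rmsd(a, b, weights=w, seed=case)
            assert abs(ours - brute) < 1e-3

    def test_degenerate_geometry_raises(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(GeometryError):
            traj.kabsch_superpose(line, line + 1.0)
        with pytest.raises(GeometryError):
            traj.kabsch_superpose(np.zeros((2, 3)), np.ones((2, 3)))


class TestRmsdSeries:
    def test_static_trajectory_is_all_zero(self):
        ref = synth.helical_reference(20, atoms="backbone")
        sim = synth.gen_trajectory(ref, n_frames=10, sigma=0.0, seed=0, rigid_motion=False)
        assert np.allclose(traj.rmsd_series(sim.trajectory), 0.0, atol=1e-12)

    def test_rigid_body_motion_is_removed(self):
        ref = synth.helical_reference(20, atoms="backbone")
        sim = synth.gen_trajectory(ref, n_frames=10, sigma=0.0, seed=1, rigid_motion=True)
        assert np.allclose(traj.rmsd_series(sim.trajectory), 0.0, atol=1e-8)

    def test_mean_rmsd_grows_with_noise_amplitude(self):
        ref = synth.helical_reference(40, atoms="backbone")
        means = []
        for sigma in (0.25, 0.5, 1.0, 2.0):
            sim = synth.gen_trajectory(ref, n_frames=40, sigma=sigma, seed=2)
            means.append(traj.rmsd_series(sim.trajectory)[1:].mean())
        assert means == sorted(means)

    def test_gaussian_noise_matches_closed_form_expectation(self):
        # superposing frame = ref + noise onto the noise-free reference:
        # E[RMSD^2] ~ 3 sigma^2 for large atom counts (fit removes ~6 DOF)
        sigma = 0.8
        ref = synth.helical_reference(200, atoms="calpha")
        sim = synth.gen_trajectory(ref, n_frames=150, sigma=sigma, seed=3,
                                   rigid_motion=False)
        series = traj.rmsd_series(sim.trajectory, selection="calpha",
                                  reference=ref)
        expected = sigma * math.sqrt(3)
        assert abs(series.mean() / expected - 1.0) < 0.05

    def test_empty_selection_raises(self):
        ref = synth.helical_reference(10, atoms="calpha")
        sim = synth.gen_trajectory(ref, n_frames=3, sigma=0.1, seed=4)
        with pytest.raises(SelectionError):
            traj.rmsd_series(sim.trajectory, selection=lambda n, r: False)


class TestRmsf:
    def test_static_trajectory_is_all_zero(self):
        ref = synth.helical_reference(15)
        sim = synth.gen_trajectory(ref, n_frames=5, sigma=0.0, seed=0, rigid_motion=False)
        prof = traj.rmsf_profile(sim.trajectory, equil_start_ns=0.0)
        assert np.allclose(prof.values, 0.0, atol=1e-10)

    def test_isotropic_noise_recovers_sigma_sqrt3(self):
        sigma = 1.0
        sim = synth.gen_trajectory(
            synth.helical_reference(169), n_frames=800, sigma=sigma, seed=5
        )
        prof = traj.rmsf_profile(sim.trajectory, equil_start_ns=0.0)
        ratio = np.median(prof.values) / (sigma * math.sqrt(3))
        assert 0.95 < ratio < 1.05

    def test_two_state_atom_has_rmsf_equal_to_half_separation(self):
        # one atom alternates between z = +a and z = -a; many anchors
        a = 1.5
        ref = synth.helical_reference(80)
        frames = []
        for i in range(60):
            coords = ref.coords.copy()
            coords[0, 2] += a if i % 2 == 0 else -a
            frames.append(
                traj.StructureFrame(
                    atom_names=ref.atom_names,
                    residue_ids=ref.residue_ids,
                    elements=ref.elements,
                    masses=ref.masses,
                    coords=coords,
                    time_ps=i * 25.0,
                )
            )
        prof = traj.rmsf_profile(traj.Trajectory(frames), equil_start_ns=0.0)
        assert abs(prof.values[0] - a) / a < 0.03
        assert prof.values[1:].max() < 0.1

    def test_first_frame_reference_option(self):
        sim = synth.gen_trajectory(
            synth.helical_reference(30), n_frames=50, sigma=0.5, seed=6
        )
        prof = traj.rmsf_profile(sim.trajectory, equil_start_ns=0.0, reference="first")
        assert prof.values.shape == (30,)
        assert (prof.values > 0).all()

    def test_too_few_usable_frames_raises(self):
        sim = synth.gen_trajectory(synth.helical_reference(10), n_frames=5, sigma=0.1, seed=7)
        with pytest.raises(InsufficientDataError):
            traj.rmsf_profile(sim.trajectory, equil_start_ns=1.0)  # frames end at 0.1 ns


class TestRadiusOfGyration:
    def test_two_equal_masses_give_half_separation(self):
        d = 3.8
        frame = traj.StructureFrame(
            atom_names=("CA", "CA"),
            residue_ids=np.array([1, 2]),
            elements=("C", "C"),
            masses=np.array([12.011, 12.011]),
            coords=np.array([[0.0, 0, 0], [d, 0, 0]]),
        )
        assert math.isclose(traj.radius_of_gyration(frame), d / 2, rel_tol=1e-12)

    def test_invariant_under_rigid_motion(self, rng):
        ref = synth.helical_reference(50, atoms="backbone")
        rg0 = traj.radius_of_gyration(ref)
        rot, shift = _random_rigid(rng)
        moved = traj.StructureFrame(
            atom_names=ref.atom_names,
            residue_ids=ref.residue_ids,
            elements=ref.elements,
            masses=ref.masses,
            coords=ref.coords @ rot.T + shift,
        )
        assert abs(traj.radius_of_gyration(moved) - rg0) < 1e-8

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(5):
            n = 50
            masses = rng.uniform(1.0, 16.0, size=n)
            coords = rng.normal(size=(n, 3)) * 8
            frame = traj.StructureFrame(
                atom_names=("X",) * n,
                residue_ids=np.arange(1, n + 1),
                elements=("C",) * n,
                masses=masses,
                coords=coords,
            )
            assert abs(
                traj.radius_of_gyration(frame)
                - direct_radius_of_gyration(masses.tolist(), coords.tolist())
            ) < 1e-10


class TestEquilibriumStats:
    def test_constant_series(self):
        t = np.arange(100) * 0.025
        s = traj.equilibrium_stats(t, np.full(100, 3.3), equil_start_ns=1.0)
        assert s.mean == pytest.approx(3.3, abs=1e-12)
        assert s.sd == pytest.approx(0.0, abs=1e-12)

    def test_window_excludes_pre_equilibration_frames(self):
        t = np.arange(10, dtype=float)
        v = np.array([99.0] * 5 + [1.0] * 5)
        s = traj.equilibrium_stats(t, v, equil_start_ns=5.0)
        assert s.mean == 1.0 and s.n_frames == 5

    def test_known_gaussian_recovery(self, rng):
        v = rng.normal(3.27, 0.29, size=4000)
        t = np.arange(4000) * 0.025
        s = traj.equilibrium_stats(t, v, equil_start_ns=12.0)
        n = s.n_frames
        assert abs(s.mean - 3.27) < 4 * 0.29 / math.sqrt(n)
        assert abs(s.sd - 0.29) < 0.05

    def test_empty_window_raises(self):
        with pytest.raises(InsufficientDataError):
            traj.equilibrium_stats(np.array([0.0, 1.0]), np.array([1.0, 2.0]), 5.0)


class TestCompareGroups:
    def test_identical_samples_are_not_significant(self):
        sample = [3.1, 3.3, 3.2, 3.4, 3.25]
        res = traj.compare_groups(sample, sample)
        assert not res.significant

    def test_separated_normal_samples_are_significant(self, rng):
        a = rng.normal(3.27, 0.29, size=50)
        b = rng.normal(5.14, 0.63, size=50)
        res = traj.compare_groups(a, b)
        assert res.significant and res.pvalue < 1e-6

    def test_skewed_data_falls_back_to_rank_test(self, rng):
        a = rng.lognormal(0.0, 1.5, size=60)
        b = rng.lognormal(1.5, 1.5, size=60)
        res = traj.compare_groups(a, b)
        assert res.test_name == "mann-whitney"
        assert res.significant

    def test_undersized_sample_raises(self):
        with pytest.raises(InsufficientDataError):
            traj.compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestModelZscore:
    @pytest.mark.parametrize(
        "components,expected",
        [((0.0, 0.0, 0.0), 0.0), ((1.0, 1.0, 1.0), 1.0018), ((1.0, 0.0, 0.0), 0.1456)],
    )
    def test_weighted_combination(self, components, expected):
        assert math.isclose(traj.model_zscore(*components), expected, abs_tol=1e-12)

    def test_non_finite_input_raises(self):
        with pytest.raises(InputError):
            traj.model_zscore(float("nan"), 0.0, 0.0)


class TestPdbIO:
    def test_write_read_round_trip(self, tmp_path):
        sim = synth.gen_trajectory(
            synth.helical_reference(12, atoms="backbone"), n_frames=3, sigma=0.4, seed=8
        )
        path = tmp_path / "traj.pdb"
        traj.write_multimodel_pdb(sim.trajectory, path)
        back = traj.read_multimodel_pdb(path)
        assert len(back) == 3
        for orig, readback in zip(sim.trajectory.frames, back.frames):
            assert orig.atom_names == readback.atom_names
            assert np.array_equal(orig.residue_ids, readback.residue_ids)
            # PDB coordinates carry three decimals
            assert np.abs(orig.coords - readback.coords).max() < 1e-3
            assert np.allclose(orig.masses, readback.masses, rtol=1e-3)

    def test_single_model_file(self, tmp_path):
        ref = synth.helical_reference(5, atoms="backbone")
        path = tmp_path / "one.pdb"
        traj.write_multimodel_pdb([ref], path)
        assert len(traj.read_multimodel_pdb(path)) == 1

    def test_missing_atom_in_second_model_is_an_integrity_error(self, tmp_path):
        sim = synth.gen_trajectory(
            synth.helical_reference(5, atoms="backbone"), n_frames=2, sigma=0.0, seed=9,
            rigid_motion=False,
        )
        path = tmp_path / "broken.pdb"
        traj.write_multimodel_pdb(sim.trajectory, path)
        lines = path.read_text().splitlines()
        # drop the last ATOM line of model 2
        for i in range(len(lines) - 1, -1, -1):
            if lines[i].startswith("ATOM"):
                del lines[i]
                break
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TrajectoryIntegrityError):
            traj.read_multimodel_pdb(path)

    def test_file_without_atoms_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER  nothing\nEND\n")
        with pytest.raises(InputError):
            traj.read_multimodel_pdb(path)


class TestGlobalInvariance:
    def test_rmsd_and_rg_invariant_under_global_rigid_motion(self, rng):
        sim = synth.gen_trajectory(
            synth.helical_reference(25, atoms="backbone"), n_frames=8, sigma=0.5,
            seed=10, rigid_motion=False,
        )
        rot, shift = _random_rigid(rng)
        moved_frames = [
            traj.StructureFrame(
                atom_names=f.atom_names,
                residue_ids=f.residue_ids,
                elements=f.elements,
                masses=f.masses,
                coords=f.coords @ rot.T + shift,
                time_ps=f.time_ps,
            )
            for f in sim.trajectory.frames
        ]
        moved = traj.Trajectory(moved_frames)
        assert np.allclose(
            traj.rmsd_series(sim.trajectory), traj.rmsd_series(moved), atol=1e-8
        )
        assert np.allclose(
            traj.rg_series(sim.trajectory), traj.rg_series(moved), atol=1e-8
        )
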