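import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from motifdyn import dynamics, enm
from motifdyn.dynamics import SimulationParams, Trajectory, TimeSeries
from motifdyn.exceptions import StabilityError
from motifdyn.structio import MutationSpec
from motifdyn.synthetic_data import ToySpec, make_structure, perturb


def short_params(**kw):
    defaults = dict(n_steps=2000, save_every=50, seed=0)
    defaults.update(kw)
    return SimulationParams(**defaults)


def network_energy(model, coords):
    dx = (coords - model.structure.coords).reshape(-1)
    return 0.5 * dx @ model.hessian @ dx


class TestSimulate:
    def test_zero_temperature_from_minimum_is_frozen(self, dimer_model):
        traj = dynamics.simulate(dimer_model, short_params(kT=0.0))
        assert np.all(traj.frames == traj.frames[0])
        np.testing.assert_array_equal(traj.frames[0], dimer_model.structure.coords)

    def test_zero_temperature_descends_energy_to_minimum(self, helix30):
        model = enm.build_hessian(helix30)
        start = perturb(helix30, sigma=0.8, seed=4).coords
        traj = dynamics.simulate(
            model, short_params(kT=0.0, n_steps=5000), initial_coords=start
        )
        energies = [network_energy(model, f) for f in traj.frames]
        assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))
        assert energies[-1] < 1e-6 * energies[0]
        # descent removes the internal-mode displacement; the rigid-body
        # component of the initial perturbation is taken out by the fit
        from motifdyn import geometry

        assert geometry.rmsd(traj.frames[-1], helix30.coords, fit=True) < 0.05

    def test_same_seed_bitwise_identical(self, hlh40):
        model = enm.build_hessian(hlh40)
        t1 = dynamics.simulate(model, short_params(seed=42))
        t2 = dynamics.simulate(model, short_params(seed=42))
        assert np.array_equal(t1.frames, t2.frames)

    def test_different_seeds_differ(self, hlh40):
        model = enm.build_hessian(hlh40)
        t1 = dynamics.simulate(model, short_params(seed=1))
        t2 = dynamics.simulate(model, short_params(seed=2))
        assert not np.array_equal(t1.frames, t2.frames)

    def test_frame_zero_is_reference(self, helix30):
        model = enm.build_hessian(helix30)
        traj = dynamics.simulate(model, short_params())
        np.testing.assert_array_equal(traj.frames[0], traj.reference.coords)

    def test_frame_count_and_times(self, helix30):
        model = enm.build_hessian(helix30)
        params = short_params(n_steps=1000, save_every=100, timestep=0.01)
        traj = dynamics.simulate(model, params)
        assert traj.n_frames == 11
        np.testing.assert_allclose(traj.times, np.arange(11) * 1.0)

    def test_divergent_timestep_reported(self, helix30):
        model = enm.build_hessian(helix30)
        with pytest.raises(StabilityError, match="step"):
            dynamics.simulate(model, short_params(timestep=1000.0, n_steps=100))

    @pytest.mark.parametrize("seed", range(3))
    def test_dimer_stretch_mode_variance(self, dimer_model, seed):
        """Stationary variance of the stretch normal-mode coordinate is
        kT/λ = kT/(2γ) — the 1-D Ornstein-Uhlenbeck closed form."""
        ms = enm.diagonalize(dimer_model)
        lam, vec = ms.nonzero()
        params = SimulationParams(n_steps=100_000, save_every=10, seed=seed)
        traj = dynamics.simulate(dimer_model, params)
        disp = traj.frames.reshape(traj.n_frames, -1) - dimer_model.structure.coords.reshape(-1)
        q = disp @ vec[:, 0]
        var = q[traj.n_frames // 2 :].var()
        assert var == pytest.approx(params.kT / lam[0], rel=0.10)

    def test_rigid_noise_projection_keeps_centroid_fixed(self, helix30):
        model = enm.build_hessian(helix30)
        traj = dynamics.simulate(model, short_params(n_steps=5000))
        centroids = traj.frames.mean(axis=1)
        assert np.abs(centroids - centroids[0]).max() < 1e-9

    def test_unprojected_noise_lets_centroid_diffuse(self, helix30):
        model = enm.build_hessian(helix30)
        traj = dynamics.simulate(
            model, short_params(n_steps=5000), remove_rigid_motion=False
        )
        centroids = traj.frames.mean(axis=1)
        assert np.abs(centroids - centroids[0]).max() > 0.05


class TestTrajectoryRmsd:
    def test_frozen_trajectory_all_zero(self, helix30):
        model = enm.build_hessian(helix30)
        traj = dynamics.simulate(model, short_params(kT=0.0))
        ts = dynamics.trajectory_rmsd(traj)
        assert np.all(ts.values < 1e-6)
        assert ts.values[0] == 0.0

    def test_rigidly_rotated_frames_measure_zero(self, helix30):
        frames = [helix30.coords]
        rng = np.random.default_rng(0)
        for _ in range(5):
            rot = Rotation.random(rng=rng).as_matrix()
            frames.append(helix30.coords @ rot.T + rng.normal(size=3))
        traj = Trajectory(
            frames=np.array(frames),
            params=short_params(n_steps=5, save_every=1),
            reference=helix30,
        )
        ts = dynamics.trajectory_rmsd(traj)
        assert np.all(ts.values < 1e-6)

    def test_motif_fit_bounded_by_global_fit_per_frame(self, hlh40):
        model = enm.build_hessian(hlh40)
        traj = dynamics.simulate(model, short_params(n_steps=3000))
        motif = np.arange(18, 22)
        fm = dynamics.trajectory_rmsd(traj, selection=motif, fit_mode="fit_motif")
        fa = dynamics.trajectory_rmsd(traj, selection=motif, fit_mode="fit_all")
        assert np.all(fm.values <= fa.values + 1e-9)

    def test_first_value_zero(self, helix30):
        model = enm.build_hessian(helix30)
        traj = dynamics.simulate(model, short_params())
        assert dynamics.trajectory_rmsd(traj).values[0] == 0.0


class TestMeanRmsd:
    def test_constant_series(self):
        ts = TimeSeries(times=np.arange(10.0), values=np.full(10, 2.0))
        assert dynamics.mean_rmsd(ts, window=0.5) == pytest.approx(2.0)

    def test_trailing_half_arithmetic(self):
        ts = TimeSeries(times=np.arange(4.0), values=np.array([0.0, 1.0, 2.0, 3.0]))
        assert dynamics.mean_rmsd(ts, window=0.5, from_end=True) == pytest.approx(2.5)
        assert dynamics.mean_rmsd(ts, window=0.5, from_end=False) == pytest.approx(0.5)

    def test_equals_direct_slice_mean(self, helix30):
        model = enm.build_hessian(helix30)
        traj = dynamics.simulate(model, short_params(n_steps=4000))
        ts = dynamics.trajectory_rmsd(traj)
        k = int(np.ceil(0.5 * len(ts.values)))
        assert dynamics.mean_rmsd(ts, window=0.5) == pytest.approx(
            float(np.mean(ts.values[-k:])), abs=1e-15
        )

    def test_invalid_window(self):
        ts = TimeSeries(times=np.arange(4.0), values=np.zeros(4))
        with pytest.raises(ValueError):
            dynamics.mean_rmsd(ts, window=0.0)


class TestTrajectoryBfactors:
    def test_frozen_trajectory_zero(self, dimer_model):
        traj = dynamics.simulate(
            dimer_model, SimulationParams(n_steps=2000, save_every=50, seed=0, kT=0.0)
        )
        bf = dynamics.trajectory_bfactors(traj)
        np.testing.assert_allclose(bf.values, 0.0, atol=1e-20)

    def test_too_few_frames_rejected(self, dimer_model):
        traj = dynamics.simulate(dimer_model, short_params(n_steps=500, save_every=50))
        with pytest.raises(ValueError, match="frames"):
            dynamics.trajectory_bfactors(traj, window=0.5)

    @pytest.mark.parametrize("seed", range(3))
    def test_dimer_equipartition_within_ten_percent(self, dimer_model, seed):
        """Windowed trajectory fluctuations reproduce the exact thermal
        covariance diagonal of the harmonic model."""
        nma_b = enm.nma_bfactors(enm.diagonalize(dimer_model)).values
        traj = dynamics.simulate(
            dimer_model, SimulationParams(n_steps=100_000, save_every=10, seed=seed)
        )
        traj_b = dynamics.trajectory_bfactors(traj, window=0.5).values
        np.testing.assert_allclose(traj_b, nma_b, rtol=0.10)

    def test_helix_profile_tracks_nma_profile(self, helix30):
        model = enm.build_hessian(helix30)
        nma_b = enm.nma_bfactors(enm.diagonalize(model)).values
        traj = dynamics.simulate(
            model, SimulationParams(n_steps=100_000, save_every=100, seed=5)
        )
        traj_b = dynamics.trajectory_bfactors(traj, window=0.5).values
        assert np.corrcoef(nma_b, traj_b)[0, 1] > 0.9


class TestMutantDirection:
    def test_weakened_motif_adjacent_springs_raise_motif_statistics(self, hlh40):
        """Ensemble means over paired seeds: spring weakening at a
        motif-adjacent site increases trailing-window motif RMSD and
        motif B-factors relative to the unperturbed network."""
        motif_idx = np.array(
            [r - 1 for r in hlh40.metadata["motif_residues"]]
        )
        mut = MutationSpec(
            residue_number=hlh40.metadata["suggested_mutation_site"], spring_scale=0.5
        )
        results = {}
        for name, muts in (("WT", ()), ("MT", (mut,))):
            model = enm.build_hessian(hlh40, mutations=muts)
            rmsds, bfs = [], []
            for seed in range(5):
                traj = dynamics.simulate(
                    model, SimulationParams(n_steps=20_000, save_every=50, seed=seed)
                )
                series = dynamics.trajectory_rmsd(traj, selection=motif_idx)
                rmsds.append(dynamics.mean_rmsd(series, window=0.5))
                bfs.append(
                    float(np.mean(dynamics.trajectory_bfactors(traj).values[motif_idx]))
                )
            results[name] = (np.mean(rmsds), np.mean(bfs))
        assert results["MT"][0] >= results["WT"][0]
        assert results["MT"][1] >= results["WT"][1]


class TestPersistence:
    def test_round_trip_via_multi_model_pdb(self, tmp_path, helix30):
        from motifdyn.structio import read_structure

        model = enm.build_hessian(helix30)
        traj = dynamics.simulate(model, short_params(n_steps=500, save_every=100))
        path = tmp_path / "traj.pdb"
        meta = tmp_path / "traj.meta"
        dynamics.write_trajectory(traj, path, meta)
        for i in range(traj.n_frames):
            frame = read_structure(path, model_index=i)
            np.testing.assert_allclose(frame.coords, traj.frames[i], atol=1e-3)
        text = meta.read_text()
        assert "seed 0" in text and f"n_frames {traj.n_frames}" in text
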