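import numpy as np
import pandas as pd
import pytest

from hccimg import events as ev
from hccimg import geometry as geo
from hccimg import recon_compton as rc
from hccimg import simulator as sim

from _oracles import cone_element, listmode_mlem_step


def make_events(scatters, absorbs, thetas, angle_ids=None):
    scatters = np.atleast_2d(scatters)
    absorbs = np.atleast_2d(absorbs)
    thetas = np.atleast_1d(thetas)
    if angle_ids is None:
        angle_ids = np.zeros(len(thetas), dtype=int)
    return pd.DataFrame({
        "angle_id": angle_ids,
        "event_id": np.arange(len(thetas)),
        "camera_id": 0,
        "E_f": 100.0, "E_r": 500.0,
        "theta": thetas,
        "scatter_x": scatters[:, 0], "scatter_y": scatters[:, 1], "scatter_z": scatters[:, 2],
        "absorb_x": absorbs[:, 0], "absorb_y": absorbs[:, 1], "absorb_z": absorbs[:, 2],
    })


class TestSystemMatrixElement:
    def test_perpendicular_cone_value(self):
        # Theta = theta = 90 deg, a = 2 mm, d = 100 mm
        t = rc.system_matrix_element(
            scatter_pos=[0, 0, 0], absorb_pos=[0, 0, 10], theta_k=np.pi / 2,
            voxel_center=[100.0, 0, 0], a=2.0, sigma=np.deg2rad(2.5))
        expected = 2 * np.pi * (1 - 100.0 / np.sqrt(100.0**2 + 4.0))
        assert t == pytest.approx(expected, rel=1e-12)
        assert t == pytest.approx(1.256e-3, rel=1e-3)

    def test_one_sigma_off_cone_gaussian_factor(self):
        sigma = np.deg2rad(2.5)
        theta = np.pi / 3
        on = rc.system_matrix_element([0, 0, 0], [0, 0, 10], theta,
                                      100 * np.array([np.sin(theta), 0, -np.cos(theta)]),
                                      a=2.0, sigma=sigma)
        off_angle = theta + sigma
        off = rc.system_matrix_element([0, 0, 0], [0, 0, 10], theta,
                                       100 * np.array([np.sin(off_angle), 0, -np.cos(off_angle)]),
                                       a=2.0, sigma=sigma)
        assert off / on == pytest.approx(np.exp(-0.5), rel=1e-9)

    def test_far_field_vanishes(self):
        t = rc.system_matrix_element([0, 0, 0], [0, 0, 10], np.pi / 2,
                                     [1e9, 0, 0], a=2.0, sigma=0.04)
        assert t < 1e-16

    def test_voxel_at_scatter_position_capped_at_2pi(self):
        t = rc.system_matrix_element([0, 0, 0], [0, 0, 10], np.pi / 2,
                                     [0.0, 0, 0], a=2.0, sigma=0.5)
        # solid-angle term is 2*pi; remaining factors bounded
        assert t <= 2 * np.pi / np.sin(np.pi / 2) + 1e-12
        assert t > 0

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            rc.system_matrix_element([0, 0, 0], [0, 0, 10], 0.0, [1, 1, 1], 2.0, 0.1)

    def test_matches_oracle_on_random_geometry(self, rng):
        for _ in range(50):
            s = rng.normal(size=3) * 50
            b = s + rng.normal(size=3) * 30
            v = rng.normal(size=3) * 40
            th = rng.uniform(0.1, np.pi - 0.1)
            got = rc.system_matrix_element(s, b, th, v, a=1.15, sigma=0.3)
            want = cone_element(s, b, th, v, a=1.15, sigma=0.3)
            assert got == pytest.approx(want, rel=1e-12)


class TestSparseSystem:
    def test_matches_dense_elements_inside_shell(self, rng):
        grid = geo.VoxelGrid.centered(3, voxel_pitch=20.0)
        events = make_events(
            [[0, 0, 150]] * 4, [[0, 0, 190]] * 4, rng.uniform(0.2, 1.4, 4))
        sigma = 0.8  # wide: no truncation anywhere on this grid
        T, kept = rc.build_compton_system(events, grid, sigma=sigma)
        assert kept.all()
        dense = np.zeros((4, grid.n_voxels))
        centers = grid.centers()
        for k in range(4):
            for j, vox in enumerate(centers):
                dense[k, j] = cone_element([0, 0, 150], [0, 0, 190],
                                           events.loc[k, "theta"], vox,
                                           grid.half_voxel, sigma)
        assert np.allclose(T.toarray(), dense, rtol=1e-6, atol=1e-30)


class TestMLEM:
    def test_single_voxel_collapses_to_counts_over_sensitivity(self):
        # one voxel at (0, 0, -135); scatter axis points straight at it
        grid = geo.VoxelGrid(origin=[-5, -5, -140], voxel_pitch=10.0, shape=(1, 1, 1))
        K = 7
        s_val = 0.25
        events = make_events([[0, 0, 0]] * K, [[0, 0, 40.0]] * K, [0.5] * K)
        sens = rc.SensitivityMap(values=np.full((1, 1, 1, 1), s_val), grid=grid, n_photons=1)
        img = rc.mlem_listmode(events, grid, sens, sigma=0.5, n_iter=1)
        # the K-event, 1-voxel update collapses to K / s for any t > 0
        assert img.values.ravel()[0] == pytest.approx(K / s_val, rel=1e-9)

    def test_zero_iterations_rejected(self):
        grid = geo.VoxelGrid.centered(2)
        sens = rc.uniform_sensitivity(grid, 1)
        with pytest.raises(ValueError):
            rc.mlem_listmode(make_events([0, 0, 150], [0, 0, 190], [0.5]),
                             grid, sens, n_iter=0)

    def test_iterations_match_dense_oracle(self, rng):
        grid = geo.VoxelGrid.centered(2, voxel_pitch=25.0)  # 8 voxels
        K = 12
        scat = np.stack([rng.normal(0, 10, K), rng.normal(0, 10, K), np.full(K, 150.0)], axis=1)
        absb = scat + np.stack([rng.normal(0, 5, K), rng.normal(0, 5, K), np.full(K, 40.0)], axis=1)
        theta = rng.uniform(0.3, 1.3, K)
        events = make_events(scat, absb, theta)
        sigma = 1.0  # wide: nothing truncated
        sens_vals = rng.uniform(0.5, 2.0, size=(1,) + grid.shape)
        sens = rc.SensitivityMap(values=sens_vals, grid=grid, n_photons=1)
        T, kept = rc.build_compton_system(events, grid, sigma=sigma)
        assert kept.all()
        dense = T.toarray()
        inv_s = np.tile(1.0 / sens_vals.reshape(1, -1), (K, 1))
        lam = np.ones(grid.n_voxels)
        for n_iter in (1, 2, 3):
            lam = listmode_mlem_step(lam, dense, inv_s, np.ones(K))
            img = rc.mlem_listmode(events, grid, sens, sigma=sigma, n_iter=n_iter)
            assert np.allclose(img.values.ravel(), lam, rtol=1e-12)

    def test_nonnegativity_preserved(self, rng):
        grid = geo.VoxelGrid.centered(5, voxel_pitch=10.0)
        theta = rng.uniform(0.3, 1.2, 30)
        events = make_events([[0, 0, 150]] * 30, [[0, 0, 190]] * 30, theta)
        sens = rc.uniform_sensitivity(grid, 1)
        img = rc.mlem_listmode(events, grid, sens, sigma=0.1, n_iter=8)
        assert np.all(img.values >= 0)

    def test_poisson_likelihood_nondecreasing(self, rng):
        grid = geo.VoxelGrid.centered(3, voxel_pitch=18.0)
        K = 25
        theta = rng.uniform(0.2, 1.3, K)
        scat = np.stack([rng.normal(0, 8, K), rng.normal(0, 8, K), np.full(K, 150.0)], axis=1)
        events = make_events(scat, scat + [0, 0, 40.0], theta)
        sens = rc.uniform_sensitivity(grid, 1)
        T, kept = rc.build_compton_system(events, grid, sigma=0.4)
        events = events[kept].reset_index(drop=True)
        dense = T.toarray()
        s_j = np.ones(grid.n_voxels)

        def loglik(lam):
            y = dense @ lam
            return np.sum(np.log(y[y > 0])) - np.sum(s_j * lam)

        prev = None
        for n_iter in range(1, 6):
            img = rc.mlem_listmode(events, grid, sens, sigma=0.4, n_iter=n_iter)
            ll = loglik(img.values.ravel())
            if prev is not None:
                assert ll >= prev - 1e-9
            prev = ll


class TestSensitivity:
    def test_mc_sensitivity_positive_and_symmetric(self, ring):
        grid = geo.VoxelGrid.centered(15, voxel_pitch=4.0)
        sens = rc.sensitivity_mc(ring, grid, "cs137", n_photons=int(2e7), seed=21)
        v = sens.values
        assert v.shape[0] == ring.n_angles
        assert np.all(v > 0)
        total = v.sum(axis=0)
        mirrored = total[::-1, :, :]
        # ring symmetry: mirrored voxels agree within MC noise
        center = total[5:10, 5:10, 5:10].mean()
        assert np.abs(mirrored - total).mean() < 0.5 * center

    def test_floor_applied_outside_field_of_view(self, ring):
        grid = geo.VoxelGrid.centered(9, voxel_pitch=4.0)
        sens = rc.sensitivity_mc(ring, grid, "cs137", n_photons=int(2e6), seed=22)
        assert sens.values.min() > 0

    def test_invalid_args_rejected(self, ring):
        grid = geo.VoxelGrid.centered(3)
        with pytest.raises(ValueError):
            rc.sensitivity_mc(ring, grid, "cs137", n_photons=0)


def test_cone_passes_near_source_for_noiseless_events(ring, poses):
    """Each selected cone's 1-sigma shell comes within 2 voxels of the
    true source for blur-free simulated events."""
    src = sim.SourceSpec("cs137", activity_bq=3e6, position=(20.0, 0.0, 20.0))
    res = sim.simulate_acquisition(src, ring, duration_s=1.0, seed=23, blur=False)
    sel = ev.select_compton(ev.group_by_angle(res.hits), poses, "cs137")
    assert len(sel) > 20
    true = np.array([20.0, 0.0, 20.0])
    scat = sel[["scatter_x", "scatter_y", "scatter_z"]].to_numpy()
    absb = sel[["absorb_x", "absorb_y", "absorb_z"]].to_numpy()
    axis = scat - absb
    axis /= np.linalg.norm(axis, axis=1, keepdims=True)
    rel = true - scat
    d = np.linalg.norm(rel, axis=1)
    big = np.arccos(np.clip(np.einsum("ij,ij->i", rel, axis) / d, -1, 1))
    theta = sel["theta"].to_numpy()
    # angular miss converted to distance at the source range
    miss = np.abs(big - theta) * d
    # positions are pixel centers, so a ~2-voxel tolerance
    assert np.quantile(miss, 0.9) < 2 * 2.3
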