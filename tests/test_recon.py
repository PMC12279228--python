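"""Inverse problem: loss, analytic gradients, regularizers, optimizer."""

import numpy as np
import pytest

import muellertomo as mt
from muellertomo.forward import ForwardModel
from muellertomo.recon import (
    ReconConfig,
    analytic_gradient,
    loss,
    nesterov_step,
    proximity_metrics,
    reconstruct,
    reconstruct_absorption,
    reconstruct_multistart,
    smooth_reg_index,
    smooth_reg_orientation,
)


class TestLoss:
    def test_identical_sets_give_zero(self, geom6):
        grid = mt.make_random_init((3, 3, 3), seed=1)
        ps = mt.simulate_intensities(grid, geom6)
        assert loss(ps, ps) == 0.0

    def test_single_pixel_unit_difference(self, geom6):
        grid = mt.VoxelGrid.empty((3, 3, 3))
        ps = mt.simulate_intensities(grid, geom6)
        other = mt.ProjectionSet(
            ps.intensities.copy(), ps.angles.copy(),
            voxel_size_um=ps.voxel_size_um,
        )
        other.intensities[2, 7, 1, 2] += 1.0
        assert loss(ps, other) == pytest.approx(1.0)

    def test_matches_elementwise_sum_oracle(self, geom6):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 0.5, (6, 16, 3, 3))
        b = rng.uniform(0, 0.5, (6, 16, 3, 3))
        angles = geom6.angles
        expected = float(sum((x - y) ** 2 for x, y in zip(a.ravel(), b.ravel())))
        got = loss(
            mt.ProjectionSet(a, angles), mt.ProjectionSet(b, angles)
        )
        assert got == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_rejected(self, geom6):
        a = mt.ProjectionSet(np.zeros((6, 16, 3, 3)), geom6.angles)
        b = mt.ProjectionSet(np.zeros((6, 16, 4, 4)), geom6.angles)
        with pytest.raises(ValueError):
            loss(a, b)


class TestAnalyticGradient:
    def test_zero_at_loss_minimum(self, geom6):
        grid = mt.make_random_init((3, 3, 3), seed=4)
        measured = mt.simulate_intensities(grid, geom6)
        eps, gp, gq, gn = analytic_gradient(grid, measured, geom6)
        assert eps == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(gp, 0) and np.allclose(gq, 0) and np.allclose(gn, 0)

    def test_matches_central_finite_differences(self, geom6):
        """Every component of the analytic gradient agrees with central
        finite differences of the loss at relative error < 1e-4."""
        truth = mt.make_random_init((3, 3, 3), seed=1, absorption_range=(0, 0.3))
        measured = mt.simulate_intensities(truth, geom6)
        est = mt.make_random_init((3, 3, 3), seed=2)
        est.absorption = truth.absorption.copy()
        eps, gp, gq, gn = analytic_gradient(est, measured, geom6)
        fm = ForwardModel(est.shape, geom6)
        h = 1e-6
        max_rel = 0.0
        for name, grad in (("phi", gp), ("psi", gq), ("n_e", gn)):
            for idx in np.ndindex(est.shape):
                pert = est.copy()
                getattr(pert, name)[idx] += h
                lp = loss(measured, fm.simulate(pert))
                getattr(pert, name)[idx] -= 2 * h
                lm = loss(measured, fm.simulate(pert))
                fd = (lp - lm) / (2 * h)
                an = grad[idx]
                rel = abs(fd - an) / max(abs(fd), abs(an), 1e-10)
                max_rel = max(max_rel, rel)
        assert max_rel < 1e-4

    def test_single_voxel_matches_symbolic_derivative(self):
        """One voxel, one projection: the chain-rule gradient equals the
        hand-differentiated scalar intensity."""
        geom = mt.AcquisitionGeometry(angles=[[0.0, 0.0]])
        truth = mt.VoxelGrid.empty((1, 1, 1))
        truth.phi[:] = 1.1
        truth.psi[:] = 0.4
        truth.n_e[:] = truth.n_o + 0.0015
        measured = mt.simulate_intensities(truth, geom)
        est = truth.copy()
        est.phi[:] = 0.9
        est.n_e[:] = truth.n_o + 0.001
        _, gp, _, gn = analytic_gradient(est, measured, geom)

        # independent derivative: differentiate I_l(phi) symbolically via
        # delta(phi), theta(phi) at normal incidence (psi fixed)
        pref = 2 * np.pi * est.voxel_size_um / est.wavelength_um
        n_o, n_e = est.n_o, est.n_e[0, 0, 0]
        phi, psi = est.phi[0, 0, 0], est.psi[0, 0, 0]

        def intensity_vec(phi_v, ne_v):
            w = np.cos(phi_v)  # p . c at alpha=beta=0
            d_big = n_o**2 * (1 - w**2) + ne_v**2 * w**2
            delta = pref * (n_o * ne_v / np.sqrt(d_big) - n_o)
            theta = psi  # transverse azimuth at normal incidence
            m = mt.voxel_mueller(delta, theta, 1.0)
            from muellertomo.forward import VA_STATES, VG_STATES

            return 0.25 * np.einsum("la,ab,lb->l", VA_STATES, m, VG_STATES)

        i_est = intensity_vec(phi, n_e)
        i_meas = intensity_vec(truth.phi[0, 0, 0], truth.n_e[0, 0, 0])
        h = 1e-7
        d_iphi = (intensity_vec(phi + h, n_e) - intensity_vec(phi - h, n_e)) / (2 * h)
        d_ine = (intensity_vec(phi, n_e + h) - intensity_vec(phi, n_e - h)) / (2 * h)
        expected_gp = np.sum(2 * (i_est - i_meas) * d_iphi)
        expected_gn = np.sum(2 * (i_est - i_meas) * d_ine)
        assert gp[0, 0, 0] == pytest.approx(expected_gp, rel=1e-5)
        assert gn[0, 0, 0] == pytest.approx(expected_gn, rel=1e-5)


class TestRegularizers:
    def test_uniform_orientation_field_is_zero(self):
        grid = mt.VoxelGrid.empty((3, 3, 3))
        grid.phi[:] = 0.8
        grid.psi[:] = 1.9
        val, gp, gq = smooth_reg_orientation(grid)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_director_flip_leaves_value_unchanged(self):
        grid = mt.make_random_init((3, 3, 3), seed=6)
        v1, _, _ = smooth_reg_orientation(grid)
        flipped = grid.copy()
        flipped.phi[1, 1, 1] = np.pi - flipped.phi[1, 1, 1]
        flipped.psi[1, 1, 1] = np.mod(flipped.psi[1, 1, 1] + np.pi, 2 * np.pi)
        v2, _, _ = smooth_reg_orientation(flipped)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_orientation_value_matches_pair_loop(self):
        grid = mt.make_random_init((3, 4, 2), seed=7)
        val, _, _ = smooth_reg_orientation(grid)
        c = grid.c_axis()
        expected = 0.0
        nx, ny, nz = grid.shape
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    for di, dj, dk in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]:
                        if i + di < nx and j + dj < ny and k + dk < nz:
                            d = np.dot(c[i, j, k], c[i + di, j + dj, k + dk])
                            expected += 1 - d**2
        assert val == pytest.approx(expected, rel=1e-12)

    def test_index_value_matches_pair_loop_and_two_voxel_case(self):
        two = mt.VoxelGrid.empty((1, 1, 2))
        two.n_e[0, 0, 1] += 0.001
        val, _ = smooth_reg_index(two)
        assert val == pytest.approx(1e-6, rel=1e-12)
        grid = mt.make_random_init((3, 2, 3), seed=8)
        val, _ = smooth_reg_index(grid)
        n = grid.n_e
        expected = 0.0
        for axis in range(3):
            expected += float(np.sum(np.diff(n, axis=axis) ** 2))
        assert val == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("which", ["orientation", "index"])
    def test_regularizer_gradients_match_finite_differences(self, which):
        grid = mt.make_random_init((3, 3, 3), seed=9)
        h = 1e-7
        if which == "orientation":
            _, gp, gq = smooth_reg_orientation(grid)
            for arr, grad in (("phi", gp), ("psi", gq)):
                for idx in [(0, 0, 0), (1, 1, 1), (2, 0, 1)]:
                    pert = grid.copy()
                    getattr(pert, arr)[idx] += h
                    vp, _, _ = smooth_reg_orientation(pert)
                    getattr(pert, arr)[idx] -= 2 * h
                    vm, _, _ = smooth_reg_orientation(pert)
                    assert grad[idx] == pytest.approx(
                        (vp - vm) / (2 * h), rel=1e-5, abs=1e-8
                    )
        else:
            _, gn = smooth_reg_index(grid)
            for idx in [(0, 0, 0), (1, 2, 1), (2, 2, 2)]:
                pert = grid.copy()
                pert.n_e[idx] += h
                vp, _ = smooth_reg_index(pert)
                pert.n_e[idx] -= 2 * h
                vm, _ = smooth_reg_index(pert)
                assert gn[idx] == pytest.approx(
                    (vp - vm) / (2 * h), rel=1e-4, abs=1e-10
                )


class TestNesterov:
    def test_momentum_zero_is_plain_gradient_descent(self):
        x = np.array([1.0, 2.0])
        g = np.array([0.5, -1.0])
        x1, v1 = nesterov_step(x, np.zeros(2), g, lr=0.1, momentum=0.0)
        assert np.allclose(x1, x - 0.1 * g)

    def test_zero_gradient_keeps_parameters(self):
        x = np.array([3.0])
        v = np.zeros(1)
        for _ in range(5):
            x, v = nesterov_step(x, v, np.zeros(1), lr=0.1, momentum=0.9)
        assert x[0] == 3.0

    def test_quadratic_iterates_match_textbook_recursion(self):
        # f(x) = 0.5 a x^2; gradient evaluated at the look-ahead point
        a, lr, mu = 2.0, 0.1, 0.9
        x, v = 1.0, 0.0
        xs = []
        for _ in range(20):
            g = a * (x + mu * v)
            xn, vn = nesterov_step(np.array([x]), np.array([v]), np.array([g]), lr, mu)
            x, v = float(xn[0]), float(vn[0])
            xs.append(x)
        # independent recursion
        xe, ve = 1.0, 0.0
        for i in range(20):
            ve = mu * ve - lr * a * (xe + mu * ve)
            xe = xe + ve
            assert xs[i] == pytest.approx(xe, rel=1e-14)

    def test_nan_gradient_aborts(self):
        with pytest.raises(FloatingPointError):
            nesterov_step(np.zeros(2), np.zeros(2), np.array([np.nan, 0.0]), 0.1, 0.9)


class TestProximityMetrics:
    def test_identity_and_director_flip(self):
        grid = mt.make_random_init((3, 3, 3), seed=10, dn_range=(0.001, 0.002))
        prox, err = proximity_metrics(grid, grid)
        assert prox == pytest.approx(1.0) and err == pytest.approx(0.0)
        flipped = grid.copy()
        flipped.phi = np.pi - flipped.phi
        flipped.psi = np.mod(flipped.psi + np.pi, 2 * np.pi)
        prox, err = proximity_metrics(flipped, grid)
        assert prox == pytest.approx(1.0, abs=1e-12)

    def test_matches_explicit_loop(self):
        a = mt.make_random_init((4, 5, 5), seed=11, dn_range=(0.001, 0.002))
        b = mt.make_random_init((4, 5, 5), seed=12, dn_range=(0.001, 0.002))
        prox, err = proximity_metrics(a, b)
        ca, cb = a.c_axis(), b.c_axis()
        dots, errs = [], []
        for idx in np.ndindex(a.shape):
            dots.append(abs(np.dot(ca[idx], cb[idx])))
            errs.append(abs(a.n_e[idx] - b.n_e[idx]) / 0.002)
        assert prox == pytest.approx(np.mean(dots), rel=1e-12)
        assert err == pytest.approx(np.mean(errs), rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            proximity_metrics(
                mt.VoxelGrid.empty((2, 2, 2)), mt.VoxelGrid.empty((3, 3, 3))
            )


class TestAbsorptionTomography:
    def test_uniform_cube_recovered_in_interior(self, full_geom):
        shape = (7, 7, 7)
        grid = mt.VoxelGrid.empty(shape)
        grid.absorption[:] = 0.2
        measured = mt.simulate_intensities(grid, full_geom)
        a = reconstruct_absorption(measured, full_geom, shape)
        interior = a[1:-1, 1:-1, 1:-1]
        assert np.all(np.abs(interior - 0.2) / 0.2 < 0.05)

    def test_zero_absorption_gives_zero_tomogram(self, geom6):
        shape = (4, 4, 4)
        measured = mt.simulate_intensities(mt.VoxelGrid.empty(shape), geom6)
        a = reconstruct_absorption(measured, geom6, shape)
        assert np.allclose(a, 0.0, atol=1e-8)

    def test_single_voxel_impulse_localized(self, full_geom):
        shape = (7, 7, 7)
        grid = mt.VoxelGrid.empty(shape)
        grid.absorption[3, 3, 3] = 0.5
        measured = mt.simulate_intensities(grid, full_geom)
        a = reconstruct_absorption(measured, full_geom, shape)
        assert np.unravel_index(np.argmax(a), shape) == (3, 3, 3)
        assert a[3, 3, 3] == pytest.approx(0.5, rel=0.05)


class TestReconstruct:
    def test_init_at_truth_stays_at_truth(self):
        geom = mt.AcquisitionGeometry(angles=[[0.0, 0.0], [0.7, 0.1]])
        truth = mt.VoxelGrid.empty((1, 1, 1))
        truth.phi[:] = 1.0
        truth.psi[:] = 0.5
        truth.n_e[:] = truth.n_o + 0.001
        measured = mt.simulate_intensities(truth, geom)
        config = ReconConfig(n_iterations=20, fit_absorption=False,
                             weight_orientation=0.0, weight_index=0.0)
        state = reconstruct(measured, geom, config, init=truth)
        assert np.all(state.traces["eps_I"] < 1e-18)
        assert np.allclose(state.grid.phi, truth.phi, atol=1e-9)
        assert np.allclose(state.grid.n_e, truth.n_e, atol=1e-12)

    def test_traces_recorded_every_iteration(self, geom6):
        truth = mt.make_random_init((3, 3, 3), seed=2, dn_range=(0.001, 0.002))
        measured = mt.simulate_intensities(truth, geom6)
        config = ReconConfig(n_iterations=12, seed=1)
        state = reconstruct(measured, geom6, config, shape=truth.shape, truth=truth)
        for key in ("eps_I", "reg_o", "reg_n", "objective",
                    "orientation_proximity", "index_error"):
            assert len(state.traces[key]) == 12
        assert np.all(state.traces["eps_I"] >= 0)

    def test_deterministic_under_seed(self, geom6):
        truth = mt.make_random_init((3, 3, 3), seed=2, dn_range=(0.001, 0.002))
        measured = mt.simulate_intensities(truth, geom6)
        config = ReconConfig(n_iterations=8, seed=5)
        s1 = reconstruct(measured, geom6, config, shape=truth.shape)
        s2 = reconstruct(measured, geom6, config, shape=truth.shape)
        assert np.array_equal(s1.grid.phi, s2.grid.phi)
        assert np.array_equal(s1.grid.n_e, s2.grid.n_e)

    def test_noiseless_smooth_volume_recovered(self, full_geom):
        """Parameter recovery on a small smooth noiseless volume: mean
        orientation proximity above 0.99 after convergence."""
        shape = (3, 3, 3)
        xs = np.linspace(0, 1, 3)
        gx, gy, gz = np.meshgrid(xs, xs, xs, indexing="ij")
        truth = mt.VoxelGrid.empty(shape)
        truth.phi = 1.0 + 0.3 * gx + 0.2 * gy
        truth.psi = 0.8 + 0.4 * gz
        truth.n_e = truth.n_o + 0.0012 + 0.0006 * gy
        measured = mt.simulate_intensities(truth, full_geom)
        config = ReconConfig(n_iterations=300, fit_absorption=False, seed=0)
        state = reconstruct_multistart(
            measured, full_geom, config, n_starts=3, shape=shape
        )
        prox, ierr = proximity_metrics(state.grid, truth)
        assert prox > 0.99
        assert ierr < 0.05
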