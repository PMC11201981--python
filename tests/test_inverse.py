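"""Inverse estimation: Jacobians, LM fitting, round trips, decision rule."""

import numpy as np
import pytest

from thermoscreen.inverse import (
    DetectionConfig,
    ForwardOperator,
    InverseResult,
    LMConfig,
    classify_detection,
    initial_guess,
    jacobian_fd,
    lma_fit,
)
from thermoscreen.irview import NoiseModel, add_camera_noise, surface_residual
from thermoscreen.phantom import TumorParams, build_hemisphere_phantom


class TestInitialGuess:
    def test_diameter_is_standard_18mm(self, small_phantom):
        assert initial_guess(small_phantom).diameter == 0.018

    def test_center_on_symmetry_axis(self, small_phantom):
        c = initial_guess(small_phantom).center
        assert abs(c[0]) < small_phantom.voxel_size
        assert abs(c[1]) < small_phantom.voxel_size
        assert 0 < c[2] < small_phantom.breast_radius

    def test_mirrored_phantom_mirrors_center(self, small_phantom):
        # carve an asymmetric notch so the centroid moves off-axis
        p = small_phantom.copy()
        p.label_grid[: p.shape[0] // 3, :, :] = np.where(
            p.label_grid[: p.shape[0] // 3] == 4, 4, 0
        )
        cm = initial_guess(p.mirrored()).center
        c = initial_guess(p).center
        assert cm[0] == pytest.approx(-c[0], abs=1e-9)
        assert cm[1] == pytest.approx(c[1])
        assert cm[2] == pytest.approx(c[2])


class TestForwardModel:
    def test_silent_sources_equal_tumor_free(self, small_operator):
        base = small_operator.base_surface.T
        # sub-voxel diameter: below the source relation's domain
        t = TumorParams(center=(0.0, 0.0, 0.02), diameter=0.0002)
        assert np.array_equal(small_operator.surface(t).T, base)
        # sphere entirely outside the breast
        t = TumorParams(center=(0.3, 0.3, 0.3), diameter=0.015)
        assert np.array_equal(small_operator.surface(t).T, base)

    def test_shallow_beats_deep_at_fixed_size(self, small_operator):
        base = small_operator.base_surface.T
        shallow = small_operator.surface(
            TumorParams(center=(0.0, 0.0, 0.035), diameter=0.012)
        ).T
        deep = small_operator.surface(
            TumorParams(center=(0.0, 0.0, 0.015), diameter=0.012)
        ).T
        assert (shallow - base).max() > (deep - base).max()


class TestJacobian:
    def test_axial_symmetry_structure(self, small_operator):
        """On the symmetry axis the two lateral sensitivities are exchanged
        by a quarter turn and the lateral misfit gradient vanishes for a
        symmetric observation (the lateral parameters are locally blind)."""
        t = TumorParams(center=(0.0, 0.0, 0.025), diameter=0.015)
        J = jacobian_fd(t, small_operator)
        assert np.linalg.norm(J[:, 0]) == pytest.approx(np.linalg.norm(J[:, 1]), rel=0.05)
        r = small_operator.surface(t).T - small_operator.base_surface.T
        g = J.T @ r
        assert abs(g[0]) < 1e-3 * abs(g[3])
        assert abs(g[1]) < 1e-3 * abs(g[3])

    def test_diameter_column_never_negative(self, small_operator):
        # a bigger source never cools the skin (comparison principle)
        t = TumorParams(center=(0.0, 0.01, 0.02), diameter=0.016)
        J = jacobian_fd(t, small_operator)
        assert J[:, 3].min() > -1e-9

    def test_central_vs_one_sided_agreement(self, small_operator):
        t = TumorParams(center=(0.005, -0.008, 0.022), diameter=0.016)
        Jc = jacobian_fd(t, small_operator)
        Jo = jacobian_fd(t, small_operator, one_sided=True)
        # agreement to the truncation-error level, column by column
        for p in range(4):
            denom = np.abs(Jc[:, p]).max() + 1e-30
            assert np.abs(Jc[:, p] - Jo[:, p]).max() / denom < 0.35


class TestLMAFit:
    def test_exact_observation_converges_immediately(
        self, small_phantom, props, ambient, small_operator
    ):
        init = initial_guess(small_phantom)
        obs = small_operator.surface(init)
        res = lma_fit(obs, small_phantom, props, ambient, init=init,
                      operator=small_operator)
        assert res.converged
        assert res.iterations == 0
        assert res.residual_rms == 0.0
        assert res.theta_hat.as_array() == pytest.approx(init.as_array())

    def test_noise_free_round_trip(self, small_phantom, props, ambient, small_operator):
        truth = TumorParams(center=(0.010, -0.012, 0.022), diameter=0.015)
        obs = small_operator.surface(truth)
        res = lma_fit(obs, small_phantom, props, ambient, operator=small_operator)
        err_c = np.linalg.norm(np.subtract(res.theta_hat.center, truth.center))
        assert err_c < small_phantom.voxel_size
        assert abs(res.theta_hat.diameter - truth.diameter) < 0.1 * truth.diameter

    def test_noisy_round_trip_with_classification(
        self, small_phantom, props, ambient, small_operator
    ):
        truth = TumorParams(center=(0.010, -0.012, 0.022), diameter=0.015)
        obs = add_camera_noise(small_operator.surface(truth), NoiseModel(0.02, seed=21))
        res = lma_fit(obs, small_phantom, props, ambient, operator=small_operator)
        classify_detection(res, small_phantom)
        assert res.detected and res.decision_reason == "in-breast"
        assert np.linalg.norm(np.subtract(res.theta_hat.center, truth.center)) < 0.005
        assert abs(res.theta_hat.diameter - truth.diameter) < 0.004

    def test_tumor_free_observation_classified_absent(
        self, small_phantom, props, ambient, small_operator
    ):
        obs = add_camera_noise(small_operator.surface(None), NoiseModel(0.02, seed=33))
        res = lma_fit(obs, small_phantom, props, ambient, operator=small_operator)
        classify_detection(res, small_phantom)
        assert res.detected is False
        assert res.decision_reason in (
            "outside-breast", "chest-wall", "sub-voxel-size", "no-improvement"
        )

    def test_accepted_residuals_monotone(self, small_phantom, props, ambient, small_operator):
        truth = TumorParams(center=(-0.008, 0.015, 0.028), diameter=0.013)
        obs = add_camera_noise(small_operator.surface(truth), NoiseModel(0.02, seed=4))
        res = lma_fit(obs, small_phantom, props, ambient, operator=small_operator)
        accepted = [t["rms"] for t in res.trajectory if t["accepted"]]
        assert all(a >= b for a, b in zip(accepted, accepted[1:]))
        assert res.iterations <= LMConfig().max_iter


class TestClassifyDetection:
    def _result(self, theta, rms, base_rms, n=5000):
        return InverseResult(
            theta_hat=theta, residual_rms=rms, baseline_rms=base_rms, n_nodes=n,
            iterations=5, converged=True, stop_reason="ftol", trajectory=[],
        )

    def test_outside_breast_absent(self, small_phantom):
        # a source pushed out of the breast explains nothing
        r = self._result(TumorParams((0.2, 0.0, 0.02), 0.015), 0.02, 0.02)
        assert classify_detection(r, small_phantom).decision_reason == "outside-breast"
        assert r.detected is False

    def test_chest_wall_absent(self, small_phantom):
        r = self._result(TumorParams((0.0, 0.0, 0.001), 0.015), 0.0200, 0.0200001)
        assert classify_detection(r, small_phantom).decision_reason == "chest-wall"

    def test_silent_size_absent(self, small_phantom):
        r = self._result(TumorParams((0.0, 0.0, 0.02), 0.004), 0.0200, 0.0200001)
        assert classify_detection(r, small_phantom).decision_reason == "sub-voxel-size"

    def test_negligible_improvement_absent(self, small_phantom):
        r = self._result(TumorParams((0.0, 0.0, 0.02), 0.012), 0.0200, 0.0200005)
        assert classify_detection(r, small_phantom).decision_reason == "no-improvement"

    def test_clear_improvement_present(self, small_phantom):
        r = self._result(TumorParams((0.0, 0.0, 0.02), 0.012), 0.020, 0.035)
        out = classify_detection(r, small_phantom)
        assert out.detected and out.decision_reason == "in-breast"

    def test_significant_source_at_margin_still_present(self, small_phantom):
        """A fit whose source strongly explains the data is a detection even
        if its positional estimate drifted to the chest-wall margin."""
        r = self._result(TumorParams((0.0, 0.0, 0.001), 0.030), 0.020, 0.030)
        out = classify_detection(r, small_phantom)
        assert out.detected is True
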