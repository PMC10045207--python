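"""Noise-matrix assembly and GLM de-noising vs. an independent projection oracle."""

import numpy as np
import pytest

from aerorate.denoise import (
    FrameMatchedFlight,
    FrameMatchedGimbal,
    assemble_noise_matrix,
    denoise_roi,
    first_derivative,
    glm_denoise,
)
from aerorate.roi import RawROISignals


def projection_residual_oracle(Y, X):
    """Residual via the explicit orthogonal projector I - U_r U_r^T, with U_r
    an SVD basis of the centered design (numerically safe for columns of
    wildly different scales, unlike forming X^T X)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    r = s > s.max() * max(Xc.shape) * np.finfo(float).eps if s.size else s
    Ur = U[:, r]
    return Yc - Ur @ (Ur.T @ Yc)


def _roi(T, V, rng, label="m0", role="measurement"):
    return RawROISignals(
        label=label,
        role=role,
        red=rng.normal(120, 2, T),
        green=rng.normal(100, 2, T),
        blue=rng.normal(80, 2, T),
        pixel_count=rng.integers(50, 60, T).astype(float),
        landmarks=rng.normal(0, 1, (T, V, 2)).cumsum(axis=0) * 0.01 + 30,
        center_of_mass=rng.normal(0, 1, (T, 2)).cumsum(axis=0) * 0.01 + 40,
    )


def _logs(T, rng):
    flight = FrameMatchedFlight(
        height=8 + 0.1 * rng.standard_normal(T).cumsum() / np.sqrt(T),
        longitude=11.57 + 1e-6 * rng.standard_normal(T),
        latitude=48.15 + 1e-6 * rng.standard_normal(T),
        velocity=0.2 * rng.standard_normal((T, 3)),
    )
    roll = 0.05 * rng.standard_normal(T)
    gimbal = FrameMatchedGimbal(
        h=np.column_stack([np.zeros(T), np.cos(roll), np.sin(roll)]),
        v=np.column_stack([np.zeros(T), -np.sin(roll), np.cos(roll)]),
    )
    return flight, gimbal


def _noise_rois(T, rng):
    return [
        _roi(T, 4, rng, label=lbl, role="noise")
        for lbl in ("nostril-center", "nostril-right", "eye-center", "eye-right")
    ]


class TestFirstDerivative:
    def test_constant_is_zero(self):
        assert np.allclose(first_derivative(np.full(10, 3.5)), 0.0)

    def test_linear_is_slope(self):
        assert np.allclose(first_derivative(2.5 * np.arange(8)), 2.5)

    def test_quadratic_example(self):
        # central differences inside, one-sided at the ends
        assert first_derivative(np.array([0.0, 1.0, 4.0, 9.0])).tolist() == [1, 2, 4, 5]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            first_derivative(np.array([1.0]))


class TestAssembly:
    # the complete nuisance set: 4V landmark(+derivative) columns plus 27
    # shared columns (COM 2 + dCOM 2 + pixels 1 + height 1 + lon 1 + lat 1 +
    # velocity 3 + noise-region colors 4 + h 3 + v 3 + dh 3 + dv 3)
    @pytest.mark.parametrize("V, K", [(4, 43), (5, 47), (6, 51)])
    def test_column_count_follows_vertex_count(self, V, K, rng):
        T = 100
        X = assemble_noise_matrix(_roi(T, V, rng), _noise_rois(T, rng), *_logs(T, rng))
        assert X.K == K
        assert len(X.column_labels) == K
        assert X.values.shape == (T, K)

    def test_channel_matched_noise_columns(self, rng):
        T = 80
        roi, nrois = _roi(T, 4, rng), _noise_rois(T, rng)
        flight, gimbal = _logs(T, rng)
        Xg = assemble_noise_matrix(roi, nrois, flight, gimbal, channel="G")
        Xb = assemble_noise_matrix(roi, nrois, flight, gimbal, channel="B")
        differing = [
            lab_g
            for lab_g, cg, cb in zip(Xg.column_labels, Xg.values.T, Xb.values.T)
            if not np.array_equal(cg, cb)
        ]
        # only the four noise-region color columns depend on the channel
        assert len(differing) == 4
        assert all("nostril" in lab or "eye" in lab for lab in differing)

    def test_constant_flight_log_flagged_not_fatal(self, rng):
        T = 90
        flight = FrameMatchedFlight(
            height=np.full(T, 8.0),
            longitude=np.full(T, 11.57),
            latitude=np.full(T, 48.15),
            velocity=np.zeros((T, 3)),
        )
        _, gimbal = _logs(T, rng)
        X = assemble_noise_matrix(_roi(T, 4, rng), _noise_rois(T, rng), flight, gimbal)
        assert {"height", "longitude", "latitude"} <= set(X.degenerate_columns)

    def test_misaligned_lengths_rejected(self, rng):
        X_roi = _roi(50, 4, rng)
        flight, gimbal = _logs(40, rng)
        with pytest.raises(ValueError):
            assemble_noise_matrix(X_roi, _noise_rois(50, rng), flight, gimbal)


class TestGLM:
    def test_matches_projection_oracle(self, rng):
        for _ in range(20):
            T = int(rng.integers(60, 200))
            K = int(rng.integers(2, min(T - 10, 50)))
            X = rng.standard_normal((T, K))
            Y = rng.standard_normal((T, 3))
            resid, sol = glm_denoise(Y, X)
            assert np.allclose(resid, projection_residual_oracle(Y, X), atol=1e-6)
            assert sol.M.shape == (K, 3)

    def test_pure_noise_vanishes(self, rng):
        T, K = 150, 20
        X = rng.standard_normal((T, K))
        M_true = rng.standard_normal((K, 3))
        Y = X @ M_true
        resid, _ = glm_denoise(Y, X)
        assert np.linalg.norm(resid) < 1e-8 * np.linalg.norm(Y - Y.mean(axis=0))

    def test_orthogonal_pulse_preserved(self, rng):
        T, K = 200, 15
        X = rng.standard_normal((T, K))
        p = np.sin(2 * np.pi * 1.2 * np.arange(T) / 15)
        # project the pulse out of the (centered) column space explicitly
        p_perp = projection_residual_oracle(p[:, None], X)[:, 0]
        Y = X @ rng.standard_normal((K, 1)) + p_perp[:, None]
        resid, _ = glm_denoise(Y, X)
        corr = np.corrcoef(resid[:, 0], p_perp)[0, 1]
        assert corr >= 0.999

    def test_single_constant_column_removes_mean_only(self, rng):
        T = 100
        Y = rng.standard_normal((T, 3)) + np.array([5.0, -3.0, 0.5])
        resid, _ = glm_denoise(Y, np.ones((T, 1)))
        assert np.allclose(resid, Y - Y.mean(axis=0), atol=1e-10)

    def test_idempotent(self, rng):
        T, K = 120, 25
        X = rng.standard_normal((T, K))
        Y = rng.standard_normal((T, 3))
        resid1, _ = glm_denoise(Y, X)
        resid2, _ = glm_denoise(resid1, X)
        assert np.allclose(resid1, resid2, atol=1e-9)

    def test_variance_never_increases(self, rng):
        T, K = 140, 30
        X = rng.standard_normal((T, K))
        Y = rng.standard_normal((T, 3)) * np.array([1.0, 5.0, 0.2])
        resid, sol = glm_denoise(Y, X)
        assert np.all(resid.var(axis=0) <= Y.var(axis=0) + 1e-12)
        assert np.all(sol.residual_norms <= np.linalg.norm(Y - Y.mean(axis=0), axis=0) + 1e-12)

    def test_under_determined_rejected(self, rng):
        with pytest.raises(ValueError, match="under-determined"):
            glm_denoise(rng.standard_normal((30, 2)), rng.standard_normal((30, 40)))

    def test_rank_deficient_design_tolerated(self, rng):
        T = 100
        x = rng.standard_normal(T)
        X = np.column_stack([x, x, 2 * x])  # rank 1
        Y = rng.standard_normal((T, 2))
        resid, _ = glm_denoise(Y, X)
        assert np.allclose(resid, projection_residual_oracle(Y, X), atol=1e-8)

    def test_pulse_as_noise_column_destroys_pulse(self, rng):
        # a nuisance source correlated with the pulse removes the pulse itself
        T = 200
        p = np.sin(2 * np.pi * 1.2 * np.arange(T) / 15)
        X = np.column_stack([p, rng.standard_normal(T)])
        Y = (p + 0.1 * rng.standard_normal(T))[:, None]
        resid, _ = glm_denoise(Y, X)
        pulse_power_in = np.dot(Y[:, 0] - Y.mean(), p) ** 2
        pulse_power_out = np.dot(resid[:, 0], p) ** 2
        assert pulse_power_out < 1e-3 * pulse_power_in


class TestDenoiseROI:
    def test_synthetic_decomposition_recovered(self, calm_signals):
        """On simulator output the GLM residual recovers the pulse trace.

        Per single ROI the correlation is bounded by the generator's white
        noise (pulse RMS ~0.85 vs. noise 0.3 on the G channel); averaging
        the residual over the 30 ROIs suppresses the independent noise and
        leaves an essentially pure pulse.
        """
        signals, gt, fm_f, fm_g = calm_signals
        noise_rois = [s for s in signals if s.role == "noise"]
        meas = [s for s in signals if s.role == "measurement"]
        residuals = []
        for raw in meas:
            den, sols = denoise_roi(raw, noise_rois, fm_f, fm_g)
            residuals.append(den.green)
            assert set(sols) == {"R", "G", "B"}
        single = np.corrcoef(residuals[0], gt.pulse_trace)[0, 1]
        assert abs(single) >= 0.9
        pooled = np.corrcoef(np.mean(residuals, axis=0), gt.pulse_trace)[0, 1]
        assert abs(pooled) > abs(single)

    def test_noise_free_scene_residual_is_projected_pulse(self):
        """Without observation noise the nuisance mixture is exactly linearly
        removable: the GLM residual equals the pulse minus its own projection
        onto the nuisance space (machine precision), i.e. the only loss is
        the chance overlap of the finite-window columns with the pulse."""
        from aerorate.synthetic import (
            SceneConfig,
            _matched_logs,
            frame_times,
            simulate_flight_logs,
            simulate_roi_signals,
        )

        cfg = SceneConfig(seed=21, white_noise_std=0.0)
        signals, gt = simulate_roi_signals(cfg)
        gimbal, flight = simulate_flight_logs(cfg)
        fm_g, fm_f = _matched_logs(cfg, gimbal, flight, frame_times(cfg))
        noise_rois = [s for s in signals if s.role == "noise"]
        raw = next(s for s in signals if s.role == "measurement")
        den, _ = denoise_roi(raw, noise_rois, fm_f, fm_g)
        from aerorate.denoise import assemble_noise_matrix

        X = assemble_noise_matrix(raw, noise_rois, fm_f, fm_g, channel="G")
        g_amp = cfg.skin_base_color[1] * cfg.pulse_strength * cfg.pulse_color[1]
        expected = projection_residual_oracle(
            (g_amp * gt.pulse_trace)[:, None], X.values
        )[:, 0]
        assert np.allclose(den.green, expected, atol=1e-8)
        corr = np.corrcoef(den.green, gt.pulse_trace)[0, 1]
        assert abs(corr) >= 0.95  # finite-window absorption stays small
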