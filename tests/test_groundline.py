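"""Stance detection, robust groundline fitting, rectification, angle error."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linprog

import hoofline as hl
from conftest import stance_mask_from_events


def l1_fit_by_linear_program(u, v):
    """Independent L1 regression oracle: minimise sum |v - (m u + b)| as an LP."""
    n = len(u)
    # variables: m, b, t_1..t_n ; minimise sum t_i with t_i >= |v_i - m u_i - b|
    c = np.concatenate([[0.0, 0.0], np.ones(n)])
    a_ub = np.zeros((2 * n, n + 2))
    b_ub = np.zeros(2 * n)
    a_ub[:n, 0] = u
    a_ub[:n, 1] = 1.0
    a_ub[:n, 2:] = -np.eye(n)
    b_ub[:n] = v
    a_ub[n:, 0] = -u
    a_ub[n:, 1] = -1.0
    a_ub[n:, 2:] = -np.eye(n)
    b_ub[n:] = -v
    res = linprog(c, A_ub=a_ub, b_ub=b_ub,
                  bounds=[(None, None)] * 2 + [(0, None)] * n,
                  method="highs")
    assert res.success
    return res.x[0], res.x[1]


class TestL1Fit:
    def test_exact_on_collinear_points(self):
        u = np.array([0.0, 50.0, 100.0])
        m, b = hl.l1_line_fit(u, 0.01 * u + 300.0)
        assert m == pytest.approx(0.01, abs=1e-12)
        assert b == pytest.approx(300.0, abs=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(min_value=3, max_value=10), st.integers(0, 10_000))
    def test_matches_linear_program_oracle(self, n, seed):
        """The pair-enumeration fit attains the LP optimum (angle within 0.01 deg)."""
        rng = np.random.default_rng(seed)
        u = rng.uniform(0, 1000, n)
        if np.ptp(u) < 1.0:
            u[0] += 10.0
        v = 0.02 * u + 400 + rng.normal(0, 3, n)
        m, b = hl.l1_line_fit(u, v)
        m_lp, b_lp = l1_fit_by_linear_program(u, v)
        cost = np.abs(v - (m * u + b)).sum()
        cost_lp = np.abs(v - (m_lp * u + b_lp)).sum()
        assert cost <= cost_lp + 1e-6    # never worse than the LP optimum
        assert abs(np.degrees(np.arctan(m) - np.arctan(m_lp))) < 0.01 or \
            cost <= cost_lp + 1e-9

    def test_duplicate_abscissae_are_merged(self):
        u = np.array([0.0, 0.0, 100.0])
        v = np.array([10.0, 20.0, 15.0])
        m, b = hl.l1_line_fit(u, v)
        assert b == pytest.approx(15.0)   # mean of the duplicate pair
        assert m == pytest.approx(0.0)


class TestDetectStance:
    def test_recovers_duty_factor_noiseless(self, clean_world, clean_traj):
        params, world = clean_world
        events = hl.detect_stance(clean_traj, clean_traj.fps)
        for leg in ("lf", "rf", "lh", "rh"):
            frac = sum(e.n_frames for e in events if e.leg == leg) / clean_traj.n_frames
            assert frac == pytest.approx(params.duty_factor, abs=0.03)

    def test_overlap_with_truth_at_one_pixel_noise(self, clean_world, noisy_traj):
        _, world = clean_world
        events = hl.detect_stance(noisy_traj, noisy_traj.fps)
        inter = union = 0
        for j, leg in enumerate(world.legs):
            det = stance_mask_from_events(events, leg, noisy_traj.n_frames)
            tru = world.stance[:, j]
            inter += int((det & tru).sum())
            union += int((det | tru).sum())
        assert inter / union >= 0.9

    def test_never_resting_hoof_gives_no_events(self):
        """A hoof that never stops moving: any frames passing the speed
        threshold near the turning point are too few to form a stance run."""
        n, fps = 300, 30.0
        t = np.arange(n) / fps
        xy = np.zeros((n, 1, 2))
        xy[:, 0, 0] = 400.0
        xy[:, 0, 1] = 600 + 50 * np.sin(2 * np.pi * 1.0 * t)
        traj = hl.TrajectorySet(xy, np.ones((n, 1), bool), fps,
                                keypoints=("lf_hoof",))
        assert hl.detect_stance(traj, fps) == []

    def test_trajectory_without_hooves_rejected(self):
        traj = hl.TrajectorySet(np.zeros((10, 1, 2)), np.ones((10, 1), bool),
                                30.0, keypoints=("withers",))
        with pytest.raises(ValueError, match="hoof"):
            hl.detect_stance(traj, 30.0)


class TestEstimateGroundline:
    def _stance_from_points(self, traj):
        return hl.detect_stance(traj, traj.fps)

    def test_collinear_horizontal_points(self):
        """Three stance points at image row 500 -> angle 0, offset 500."""
        n = 31
        kps = ("lf_hoof", "rf_hoof", "lh_hoof")
        xy = np.zeros((n, 3, 2))
        xy[:, :, 0] = [300.0, 600.0, 900.0]
        xy[:, :, 1] = 500.0
        traj = hl.TrajectorySet(xy, np.ones((n, 3), bool), 30.0, keypoints=kps)
        ev = [hl.StanceEvent(leg, 0, n - 1, (xy[0, k, 0], 500.0))
              for k, leg in enumerate(("lf", "rf", "lh"))]
        gl = hl.estimate_groundline(traj, ev)
        np.testing.assert_allclose(gl.angle_deg, 0.0, atol=1e-9)
        np.testing.assert_allclose(gl.offset_px, 500.0, atol=1e-9)

    def test_sloped_line_angle_arctangent(self):
        """Points on y = 0.01 x + 300: |angle| = atan(0.01) = 0.573 deg,
        negative under the rising-left-to-right-positive convention."""
        n = 31
        kps = ("lf_hoof", "rf_hoof")
        xy = np.zeros((n, 2, 2))
        xy[:, 0, 0], xy[:, 1, 0] = 100.0, 900.0
        xy[:, :, 1] = 0.01 * xy[:, :, 0] + 300.0
        traj = hl.TrajectorySet(xy, np.ones((n, 2), bool), 30.0, keypoints=kps)
        ev = [hl.StanceEvent("lf", 0, n - 1, (100, 301)),
              hl.StanceEvent("rf", 0, n - 1, (900, 309))]
        gl = hl.estimate_groundline(traj, ev)
        assert gl.angle_deg[n // 2] == pytest.approx(-0.573, abs=1e-3)

    def test_noiseless_recovery_matches_true_groundline(self, clean_world, clean_traj):
        _, world = clean_world
        events = hl.detect_stance(clean_traj, clean_traj.fps)
        gl = hl.estimate_groundline(clean_traj, events)
        ref = hl.true_groundline(world, hl.default_cameras()[2])
        err = hl.angle_error(gl, ref)
        assert err.mae < 0.05

    def test_invalid_frames_interpolated(self):
        n = 60
        kps = ("lf_hoof", "rf_hoof")
        xy = np.zeros((n, 2, 2))
        xy[:, 0, 0], xy[:, 1, 0] = 200.0, 800.0
        xy[:, :, 1] = 500.0
        vis = np.ones((n, 2), bool)
        traj = hl.TrajectorySet(xy, vis, 30.0, keypoints=kps)
        # support only at both ends; middle frames have no stance points
        ev = [hl.StanceEvent("lf", 0, 9, (200, 500)),
              hl.StanceEvent("rf", 0, 9, (800, 500)),
              hl.StanceEvent("lf", 50, 59, (200, 500)),
              hl.StanceEvent("rf", 50, 59, (800, 500))]
        gl = hl.estimate_groundline(traj, ev, window=5)
        assert not gl.valid.all()
        assert np.isfinite(gl.angle_deg).all()
        np.testing.assert_allclose(gl.offset_px, 500.0, atol=1e-6)

    def test_no_support_raises_with_diagnostics(self, clean_traj):
        with pytest.raises(RuntimeError, match="stance"):
            hl.estimate_groundline(clean_traj, [])

    def test_noise_monotonicity_of_angle_error(self, clean_world):
        """Median |angle error| does not decrease as keypoint noise grows."""
        params, world = clean_world
        cam = hl.default_cameras()[2]
        ref = hl.true_groundline(world, cam)
        base = hl.project(world, cam)
        medians = []
        for sigma in (0.0, 1.0, 2.0, 4.0):
            errs = []
            for seed in (1, 2, 3):
                traj = hl.corrupt(base, sigma, 0.0, seed=seed)
                ev = hl.detect_stance(traj, traj.fps)
                gl = hl.estimate_groundline(traj, ev)
                e = hl.angle_error(gl, ref).errors[:100]
                errs.extend(np.abs(e[np.isfinite(e)]))
            medians.append(np.median(errs))
        assert all(a <= b + 1e-4 for a, b in zip(medians, medians[1:]))


class TestRectify:
    def test_horizontal_groundline_is_identity(self, clean_traj):
        gl = hl.Groundline.fixed(0.0, 700.0, clean_traj.n_frames)
        out = hl.rectify(clean_traj, gl, mode="per_frame")
        np.testing.assert_allclose(out.xy, clean_traj.xy, atol=1e-9)

    def test_per_frame_rectification_levels_stance_hooves(self, clean_world):
        _, world = clean_world
        cam = hl.default_cameras()[0]          # oblique: line genuinely sloped
        traj = hl.project(world, cam)
        gl = hl.true_groundline(world, cam)
        out = hl.rectify(traj, gl, mode="per_frame")
        ys = []
        for j, leg in enumerate(world.legs):
            ys.extend(out.xy[world.stance[:, j], out.index(f"{leg}_hoof"), 1])
        assert np.ptp(ys) < 1e-3

    def test_rectification_is_an_isometry(self, clean_traj):
        gl = hl.Groundline.fixed(3.7, 650.0, clean_traj.n_frames)
        out = hl.rectify(clean_traj, gl, mode="central_frame")
        d0 = np.linalg.norm(clean_traj.xy[:, 0] - clean_traj.xy[:, 5], axis=-1)
        d1 = np.linalg.norm(out.xy[:, 0] - out.xy[:, 5], axis=-1)
        np.testing.assert_allclose(d1, d0, rtol=1e-6)

    def test_central_frame_requires_valid_centre(self, clean_traj):
        n = clean_traj.n_frames
        valid = np.ones(n, bool)
        valid[n // 2] = False
        gl = hl.Groundline(np.zeros(n), np.full(n, 500.0), valid)
        with pytest.raises(ValueError, match="central"):
            hl.rectify(clean_traj, gl, mode="central_frame")


class TestAngleError:
    def test_identical_lines_zero(self):
        gl = hl.Groundline.fixed(1.0, 500.0, 10)
        err = hl.angle_error(gl, gl)
        assert err.mean_signed == 0.0 and err.mae == 0.0 and err.n == 10

    def test_constant_offset_error(self):
        est = hl.Groundline.fixed(0.573, 500.0, 10)
        ref = hl.Groundline.fixed(0.0, 500.0, 10)
        err = hl.angle_error(est, ref)
        assert err.mean_signed == pytest.approx(0.573)
        assert err.mae == pytest.approx(0.573)

    def test_signed_errors_cancel_but_absolute_do_not(self):
        est = hl.Groundline(np.array([1.0, -1.0]), np.zeros(2))
        ref = hl.Groundline(np.zeros(2), np.zeros(2))
        err = hl.angle_error(est, ref)
        assert err.mean_signed == pytest.approx(0.0)
        assert err.mae == pytest.approx(1.0)

    def test_frame_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            hl.angle_error(hl.Groundline.fixed(0, 0, 5),
                           hl.Groundline.fixed(0, 0, 6))
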