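"""Vertical displacement signals: distances, calibration, frequency, filter."""

import numpy as np
import pytest

import hoofline as hl
from hoofline.vds import butter_gain


def _single_kp_traj(y_values, fps=30.0, keypoint="withers", x=960.0):
    n = len(y_values)
    xy = np.zeros((n, 1, 2))
    xy[:, 0, 0] = x
    xy[:, 0, 1] = y_values
    return hl.TrajectorySet(xy, np.ones((n, 1), bool), fps,
                            keypoints=(keypoint,))


class TestComputeVds:
    def test_point_on_the_groundline(self):
        traj = _single_kp_traj(np.full(10, 500.0))
        gl = hl.Groundline.fixed(0.0, 500.0, 10)
        assert np.abs(hl.compute_vds(traj, gl, "withers").values).max() < 1e-12

    def test_vertical_distance_to_horizontal_line(self):
        traj = _single_kp_traj(np.full(10, 300.0))
        gl = hl.Groundline.fixed(0.0, 500.0, 10)
        np.testing.assert_allclose(hl.compute_vds(traj, gl, "withers").values,
                                   200.0)

    def test_perpendicular_distance_to_sloped_line(self):
        """45-degree line through the origin, point (100, 0): 100/sqrt(2)."""
        traj = _single_kp_traj(np.zeros(5), x=100.0)
        gl = hl.Groundline.fixed(45.0, 0.0, 5)
        vals = hl.compute_vds(traj, gl, "withers").values
        np.testing.assert_allclose(np.abs(vals), 100.0 / np.sqrt(2), rtol=1e-9)

    def test_hidden_frames_become_gaps(self):
        traj = _single_kp_traj(np.full(10, 300.0))
        traj.visible[4, 0] = False
        vals = hl.compute_vds(traj, hl.Groundline.fixed(0, 500, 10),
                              "withers").values
        assert np.isnan(vals[4]) and np.isfinite(np.delete(vals, 4)).all()

    def test_unknown_keypoint_rejected(self):
        traj = _single_kp_traj(np.zeros(5))
        with pytest.raises(KeyError, match="poll"):
            hl.compute_vds(traj, hl.Groundline.fixed(0, 0, 5), "poll")


class TestCalibrate:
    def test_scale_arithmetic(self):
        """160 cm withers at a median 800 px above the line -> 2.0 mm/px."""
        traj = _single_kp_traj(np.full(20, 200.0))   # 800 px above y=1000
        gl = hl.Groundline.fixed(0.0, 1000.0, 20)
        raw = hl.compute_vds(traj, gl, "withers")
        cal = hl.calibrate(raw, traj, gl, withers_height=160.0)
        assert cal.calibration_scale == pytest.approx(2.0)
        assert cal.values[0] == pytest.approx(1600.0)   # 800 px * 2 mm/px

    def test_zoom_invariance(self, clean_world):
        """Doubling all pixel coordinates leaves calibrated VDS unchanged."""
        params, world = clean_world
        traj = hl.project(world, hl.default_cameras()[2])
        gl = hl.true_groundline(world, hl.default_cameras()[2])
        raw = hl.compute_vds(traj, gl, "withers")
        cal = hl.calibrate(raw, traj, gl, params.withers_height)
        zoomed = traj.copy()
        zoomed.xy *= 2.0
        gl2 = hl.Groundline.fixed(gl.angle_deg[0], 2 * gl.offset_px[0],
                                  traj.n_frames)
        cal2 = hl.calibrate(hl.compute_vds(zoomed, gl2, "withers"),
                            zoomed, gl2, params.withers_height)
        np.testing.assert_allclose(cal2.values, cal.values, rtol=1e-6)

    def test_amplitude_round_trip(self, clean_world, opts):
        """Simulated 30 mm withers oscillation is recovered within 1 mm."""
        params, world = clean_world
        from hoofline.session import analyze_recording
        traj = hl.project(world, hl.default_cameras()[2])
        res = analyze_recording(traj, params.withers_height, opts)
        v = res.vds[("dynamic", "withers")].values
        core = v[60:-60]
        amp = (np.nanmax(core) + np.abs(np.nanmin(core))) / 2
        assert amp == pytest.approx(30.0, abs=1.0)

    def test_insufficient_withers_coverage_fails(self):
        traj = _single_kp_traj(np.full(20, 200.0))
        traj.visible[: 15, 0] = False
        gl = hl.Groundline.fixed(0.0, 1000.0, 20)
        raw = hl.compute_vds(traj, gl, "withers")
        with pytest.raises(ValueError, match="%"):
            hl.calibrate(raw, traj, gl, 160.0)


class TestStrideFrequency:
    def test_pure_tone(self):
        t = np.arange(int(20 * 30)) / 30.0
        sig = np.sin(2 * np.pi * 1.25 * t)
        f = hl.estimate_stride_frequency(sig, 30.0)
        assert f == pytest.approx(1.25, abs=0.05)

    def test_synthetic_horse_limb_signal(self, noisy_traj):
        xy, vis = noisy_traj.point("lf_hoof")
        y = np.where(vis, xy[:, 1], np.nan)
        f = hl.estimate_stride_frequency(y, 30.0)
        assert f == pytest.approx(1.25, abs=0.05)

    def test_trunk_like_signal_not_mistaken_for_double_rate(self):
        """A limb signal with 1f fundamental + strong 2f harmonic -> 1f."""
        t = np.arange(int(20 * 30)) / 30.0
        sig = np.sin(2 * np.pi * 1.25 * t) + 1.5 * np.sin(2 * np.pi * 2.5 * t)
        f = hl.estimate_stride_frequency(sig, 30.0)
        assert f == pytest.approx(1.25, abs=0.05)

    def test_white_noise_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="periodic|band"):
            hl.estimate_stride_frequency(rng.normal(size=600), 30.0)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="5 s|short"):
            hl.estimate_stride_frequency(np.sin(np.arange(60)), 30.0)


class TestHighpass:
    def _series(self, values, fps=30.0):
        return hl.VDSeries("withers", values, fps)

    def test_dc_fully_removed(self):
        out = hl.highpass(self._series(np.full(600, 7.0)), 1.25)
        assert np.abs(out.values[50:-50]).max() < 1e-6

    def test_two_pass_gain_at_cutoff_is_half(self):
        """|H|=1/sqrt(2) at cutoff per pass; forward-backward squares it."""
        fps, f_est = 30.0, 1.25
        cutoff = 0.95 * f_est
        t = np.arange(int(400 * fps)) / fps
        sig = np.sin(2 * np.pi * cutoff * t)
        out = hl.highpass(self._series(sig, fps), f_est)
        core = out.values[3000:-3000]
        gain = (np.max(core) - np.min(core)) / 2.0
        assert gain == pytest.approx(0.5, abs=0.01)
        assert butter_gain(cutoff, cutoff, "highpass", 3, passes=2) == \
            pytest.approx(0.5, abs=1e-12)

    def test_camera_bounce_attenuated_but_trunk_passes(self):
        """Cutoff 1.1875 Hz: 1 Hz bounce < 45% amplitude after two passes,
        while the 2.5 Hz trunk component passes a single pass above 99%."""
        assert butter_gain(1.0, 1.1875, "highpass", 3, passes=2) < 0.45
        assert butter_gain(2.5, 1.1875, "highpass", 3, passes=1) > 0.99
        # measured two-pass attenuation agrees with the closed form
        fps = 30.0
        t = np.arange(int(400 * fps)) / fps
        out = hl.highpass(self._series(np.sin(2 * np.pi * 1.0 * t), fps), 1.25)
        core = out.values[3000:-3000]
        measured = (np.max(core) - np.min(core)) / 2.0
        assert measured == pytest.approx(
            butter_gain(1.0, 1.1875, "highpass", 3, passes=2), abs=0.01)

    def test_linearity_superposition(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=600)
        b = rng.normal(size=600)
        fa = hl.highpass(self._series(a), 1.25).values
        fb = hl.highpass(self._series(b), 1.25).values
        fab = hl.highpass(self._series(a + 2 * b), 1.25).values
        np.testing.assert_allclose(fab, fa + 2 * fb, atol=1e-9)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            hl.highpass(self._series(np.zeros(100), fps=2.0), 2.0)

    def test_filtered_series_mean_near_zero(self, clean_world, opts):
        from hoofline.session import analyze_recording
        params, world = clean_world
        traj = hl.project(world, hl.default_cameras()[2])
        res = analyze_recording(traj, params.withers_height, opts)
        v = res.vds[("dynamic", "withers")].values
        core = v[60:60 + 24 * 18]        # integer number of strides
        ptp = np.nanmax(core) - np.nanmin(core)
        assert abs(np.nanmean(core)) < 0.01 * ptp

    def test_gaps_bridged_and_remasked(self):
        t = np.arange(600) / 30.0
        sig = np.sin(2 * np.pi * 2.5 * t)
        sig[100:103] = np.nan
        out = hl.highpass(self._series(sig), 1.25)
        assert np.isnan(out.values[100:103]).all()
        assert np.isfinite(np.delete(out.values, slice(100, 103))).all()
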