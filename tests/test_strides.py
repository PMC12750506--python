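"""Stride segmentation, Maxdiff/Mindiff computation, trial aggregation."""

import numpy as np
import pytest

import hoofline as hl
from hoofline.session import analyze_recording
from hoofline.strides import StrideRecord, split_trials


@pytest.fixture(scope="module")
def clean_analysis(clean_world, opts):
    params, world = clean_world
    traj = hl.project(world, hl.default_cameras()[2])
    return params, analyze_recording(traj, params.withers_height, opts)


class TestSegmentation:
    def test_stride_count_from_generator_timing(self, clean_analysis):
        """20 s at 1.25 Hz: 25 reference-fore onsets -> 24 onset-to-onset
        strides; the two touching the filter warm-up margins are excluded."""
        _, res = clean_analysis
        recs = res.strides[("dynamic", "withers")]
        onsets = [e.start for e in res.stances if e.leg == "lf" and e.start > 0]
        assert len(onsets) in (24, 25)
        assert len(recs) == len(onsets) - 1
        assert sum(r.valid for r in recs) >= len(recs) - 2
        assert all(r.reason == "warmup" for r in recs if not r.valid)

    def test_strides_are_contiguous_and_half_split(self, clean_analysis):
        _, res = clean_analysis
        recs = res.strides[("dynamic", "withers")]
        for a, b in zip(recs[:-1], recs[1:]):
            assert a.end == b.start
        for r in recs:
            assert r.start < r.mid < r.end

    def test_occluded_stride_excluded_not_imputed(self, clean_world, opts):
        params, world = clean_world
        traj = hl.project(world, hl.default_cameras()[2])
        k = traj.index("withers")
        traj.visible[250, k] = False        # one hidden frame mid-recording
        res = analyze_recording(traj, params.withers_height, opts)
        recs = res.strides[("dynamic", "withers")]
        hit = [r for r in recs if r.start <= 250 < r.end]
        assert len(hit) == 1 and not hit[0].valid
        assert hit[0].reason == "occlusion"
        assert np.isnan(hit[0].maxdiff)

    def test_spiky_stride_flagged_invalid(self, clean_world, opts):
        """A VDS with three prominent maxima in one stride is refused."""
        params, world = clean_world
        res = analyze_recording(hl.project(world, hl.default_cameras()[2]),
                                params.withers_height, opts)
        vds = res.vds[("dynamic", "withers")]
        target = [r for r in res.strides[("dynamic", "withers")] if r.valid][5]
        spiked = vds.replace(values=vds.values.copy())
        j = target.start + 3                # between the two genuine maxima
        spiked.values[j] += 40.0
        recs = hl.segment_strides(
            hl.project(world, hl.default_cameras()[2]), res.stances, spiked)
        hit = [r for r in recs if r.start == target.start]
        assert len(hit) == 1 and not hit[0].valid
        assert "extrema" in hit[0].reason or "poor_fit" in hit[0].reason

    def test_fewer_than_two_onsets_gives_empty(self, clean_world, opts):
        params, world = clean_world
        traj = hl.project(world, hl.default_cameras()[2])
        res = analyze_recording(traj, params.withers_height, opts)
        vds = res.vds[("dynamic", "withers")]
        assert hl.segment_strides(traj, [], vds) == []


class TestSymmetry:
    def test_symmetric_gait_near_zero_metrics(self, opts):
        """50 strides at 1 px noise: mean Maxdiff and Mindiff within 0.3 mm."""
        p = hl.GaitParams(duration=42.0, asym_amp=0.0, noise_sigma=1.0)
        world = hl.simulate_gait(p)
        traj = hl.corrupt(hl.project(world, hl.default_cameras()[2]),
                          1.0, 0.0, seed=0)
        res = analyze_recording(traj, p.withers_height, opts)
        recs = res.valid_strides("dynamic", "withers")
        assert len(recs) >= 45
        assert abs(np.mean([r.maxdiff for r in recs])) < 0.3
        assert abs(np.mean([r.mindiff for r in recs])) < 0.3

    def test_injected_asymmetry_recovered_against_oracle(self, opts):
        """asym 2.5 mm, phase 0: mean Maxdiff ~ 5 mm, Mindiff ~ 0 (dense-grid
        oracle on the closed-form trunk trajectory is the reference)."""
        p = hl.GaitParams(duration=42.0, trunk_amp=30.0, asym_amp=2.5,
                          asym_phase=0.0, noise_sigma=1.0)
        world = hl.simulate_gait(p)
        traj = hl.corrupt(hl.project(world, hl.default_cameras()[2]),
                          1.0, 0.0, seed=0)
        res = analyze_recording(traj, p.withers_height, opts)
        recs = res.valid_strides("dynamic", "withers")
        assert len(recs) >= 45
        _, omax, omin = hl.symmetry_oracle(p, "withers")
        assert np.mean([r.maxdiff for r in recs]) == \
            pytest.approx(omax.mean(), abs=0.5)
        assert np.mean([r.mindiff for r in recs]) == \
            pytest.approx(omin.mean(), abs=0.5)

    def test_label_swap_negates_both_metrics(self, clean_analysis):
        _, res = clean_analysis
        vds = res.vds[("dynamic", "withers")]
        for rec in res.valid_strides("dynamic", "withers")[:5]:
            md, nd = hl.compute_symmetry(rec, vds)
            md_s, nd_s = hl.compute_symmetry(rec, vds, swap_labels=True)
            assert md_s == pytest.approx(-md, abs=1e-12)
            assert nd_s == pytest.approx(-nd, abs=1e-12)

    def test_invalid_stride_refused(self, clean_analysis):
        _, res = clean_analysis
        vds = res.vds[("dynamic", "withers")]
        bad = StrideRecord(start=0, end=24, reference_leg="lf",
                           keypoint="withers", valid=False, reason="occlusion")
        with pytest.raises(ValueError, match="invalid"):
            hl.compute_symmetry(bad, vds)

    def test_gap_in_neighbouring_stride_barely_moves_metrics(self, clean_world, opts):
        """A 3-frame gap changes adjacent strides' Maxdiff by < 0.2 mm."""
        params, world = clean_world
        traj = hl.project(world, hl.default_cameras()[2])
        res0 = analyze_recording(traj, params.withers_height, opts)
        base = {r.start: r.maxdiff for r in res0.valid_strides("dynamic", "withers")}
        traj2 = traj.copy()
        k = traj2.index("withers")
        mid = [r for r in res0.valid_strides("dynamic", "withers")][8].start
        traj2.visible[mid + 5:mid + 8, k] = False
        res1 = analyze_recording(traj2, params.withers_height, opts)
        for r in res1.valid_strides("dynamic", "withers"):
            if r.start in base and not (r.start <= mid + 7 and r.end > mid + 5):
                assert abs(r.maxdiff - base[r.start]) < 0.2


class TestParameterRecovery:
    def test_maxdiff_linear_in_injected_asymmetry(self, opts):
        """Regression of recovered mean Maxdiff on 2*asym_amp: slope 1 +/- 0.05,
        intercept 0 +/- 0.3 mm (50 strides, 1 px noise, static side view)."""
        amps = [0.0, 1.0, 2.5, 5.0]
        recovered = []
        for a in amps:
            p = hl.GaitParams(duration=42.0, asym_amp=a, asym_phase=0.0,
                              noise_sigma=1.0)
            world = hl.simulate_gait(p)
            traj = hl.corrupt(hl.project(world, hl.default_cameras()[2]),
                              1.0, 0.0, seed=0)
            res = analyze_recording(traj, p.withers_height, opts)
            recovered.append(np.mean([r.maxdiff for r in
                                      res.valid_strides("dynamic", "withers")]))
        x = 2.0 * np.asarray(amps)
        slope, intercept = np.polyfit(x, recovered, 1)
        assert slope == pytest.approx(1.0, abs=0.05)
        assert intercept == pytest.approx(0.0, abs=0.3)


class TestTrials:
    def _records(self, n, maxdiffs=None):
        recs = []
        for i in range(n):
            md = 0.0 if maxdiffs is None else maxdiffs[i]
            recs.append(StrideRecord(start=24 * i, end=24 * (i + 1),
                                     reference_leg="lf", keypoint="withers",
                                     maxdiff=md, mindiff=-md, valid=True))
        return recs

    def test_exact_division(self):
        trials = split_trials(self._records(51), target_len=17)
        assert [t.n_strides for t in trials] == [17, 17, 17]

    def test_remainder_kept_if_at_least_half(self):
        trials = split_trials(self._records(60), target_len=17)
        assert [t.n_strides for t in trials] == [17, 17, 17, 9]

    def test_short_remainder_dropped(self):
        trials = split_trials(self._records(42), target_len=17)
        assert [t.n_strides for t in trials] == [17, 17]

    def test_trial_metric_is_mean_of_member_strides(self):
        recs = self._records(3, maxdiffs=[4.0, 5.0, 6.0])
        trials = split_trials(recs, target_len=3)
        assert trials[0].maxdiff == pytest.approx(5.0)
        assert trials[0].mindiff == pytest.approx(-5.0)

    def test_target_len_must_be_at_least_two(self):
        with pytest.raises(ValueError):
            split_trials(self._records(10), target_len=1)

    def test_trial_aggregation_reduces_scatter(self, opts):
        """SD of trial-level Maxdiff error is below stride-level SD."""
        p = hl.GaitParams(duration=120.0, asym_amp=2.0, noise_sigma=1.0)
        world = hl.simulate_gait(p)
        traj = hl.corrupt(hl.project(world, hl.default_cameras()[2]),
                          1.0, 0.0, seed=0)
        res = analyze_recording(traj, p.withers_height, opts)
        recs = res.valid_strides("dynamic", "withers")
        _, omax, _ = hl.symmetry_oracle(p, "withers")
        truth = omax.mean()
        stride_sd = np.std([r.maxdiff - truth for r in recs])
        trials = split_trials(recs, target_len=17)
        trial_sd = np.std([t.maxdiff - truth for t in trials])
        assert trial_sd < stride_sd
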