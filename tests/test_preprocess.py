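"""Tests of every preprocessing stage rule and the end-to-end properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import latflow as lf
from latflow.preprocess import (ACCEPTED, REJECTED_RANGE, REJECTED_SPIKE,
                                REPAIRED, PreprocessConfig, SignalRecording,
                                downsample, flag_extreme_points,
                                heart_cycle_integrate, normalize,
                                repair_or_reject, segment_epochs, trial_se)


class TestDownsample:
    def test_every_fourth_sample_from_index_zero(self):
        assert downsample(np.arange(12), 4).tolist() == [0, 4, 8]

    def test_rate_conversion_100_to_25(self):
        rec = SignalRecording(sampling_rate=100, left=np.zeros(400),
                             right=np.zeros(400), markers=[])
        out = lf.downsample_recording(rec, 4)
        assert out.sampling_rate == 25
        assert out.n_samples == 100

    def test_constant_series_invariant(self):
        assert (downsample(np.full(100, 3.3), 4) == 3.3).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            downsample(np.array([]), 4)

    @given(st.integers(1, 10), st.integers(1, 500))
    @settings(max_examples=30, deadline=None)
    def test_length_is_ceil_n_over_factor(self, factor, n):
        out = downsample(np.arange(n), factor)
        assert len(out) == -(-n // factor)


class TestSegmentEpochs:
    def _recording(self, markers, n=30000):
        return SignalRecording(sampling_rate=25, left=np.zeros(n),
                               right=np.zeros(n), markers=markers)

    def test_epoch_has_825_samples_and_covers_minus7_to_26(self):
        rec = self._recording([(1000, "A")])
        (ep,) = segment_epochs(rec, PreprocessConfig())
        assert len(ep.left) == 825
        assert ep.times[0] == -7.0
        assert ep.times[-1] == pytest.approx(26.0 - 1 / 25)

    def test_one_epoch_per_marker(self):
        markers = [(500 + 900 * i, "B") for i in range(30)]
        rec = self._recording(markers)
        assert len(segment_epochs(rec, PreprocessConfig())) == 30

    def test_marker_too_close_to_edge_dropped_with_warning(self, caplog):
        rec = self._recording([(100, "A"), (1000, "A")])
        with caplog.at_level("WARNING"):
            eps = segment_epochs(rec, PreprocessConfig())
        assert len(eps) == 1
        assert "dropped" in caplog.text


class TestFlagExtremePoints:
    def test_constant_channel_flags_nothing(self):
        rec = SignalRecording(sampling_rate=25, left=np.full(1000, 50.0),
                             right=np.full(1000, 60.0), markers=[])
        ml, mr = flag_extreme_points(rec, PreprocessConfig())
        assert not ml.any() and not mr.any()

    def test_single_huge_spike_among_1e5_samples_flagged_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(40, 60, 100_000)
        spike_at = 1234
        base[spike_at] = 10 * base.max()
        rec = SignalRecording(sampling_rate=25, left=base,
                             right=np.full(100_000, 50.0), markers=[])
        ml, mr = flag_extreme_points(rec, PreprocessConfig())
        # oracle: explicit sort-based quantiles of the left channel
        s = np.sort(base)
        qlo = np.quantile(s, 0.0001)
        qhi = np.quantile(s, 0.9999)
        expected = (base < qlo) | (base > qhi)
        assert (ml == expected).all()
        assert ml[spike_at]
        assert not mr.any()


class TestRepairOrReject:
    def test_no_flags_is_identity(self, toy_epoch):
        ep = toy_epoch(left=np.random.default_rng(0).normal(100, 3, 825))
        before = ep.left.copy()
        out = repair_or_reject(ep, np.zeros(825, bool), np.zeros(825, bool))
        assert out.status == ACCEPTED
        assert (out.left == before).all()

    def test_single_flag_replaced_by_mean_of_remaining_824(self, toy_epoch):
        left = np.full(825, 100.0)
        left[10] = 1000.0
        ep = toy_epoch(left=left)
        mask = np.zeros(825, bool)
        mask[10] = True
        out = repair_or_reject(ep, mask, np.zeros(825, bool))
        assert out.status == REPAIRED
        assert out.left[10] == pytest.approx(100.0)  # spike excluded from mean

    def test_two_flags_reject(self, toy_epoch):
        ep = toy_epoch()
        mask = np.zeros(825, bool)
        mask[[10, 20]] = True
        assert repair_or_reject(ep, mask, np.zeros(825, bool)).status == REJECTED_SPIKE

    def test_one_flag_per_channel_also_rejects(self, toy_epoch):
        ep = toy_epoch()
        ml = np.zeros(825, bool); ml[10] = True
        mr = np.zeros(825, bool); mr[20] = True
        assert repair_or_reject(ep, ml, mr).status == REJECTED_SPIKE


class TestNormalize:
    def test_constant_becomes_100(self):
        assert (normalize(np.full(10, 7.0)) == 100.0).all()

    def test_mean_is_100(self):
        rng = np.random.default_rng(1)
        out = normalize(rng.uniform(30, 80, 5000))
        assert out.mean() == pytest.approx(100.0, abs=1e-9)

    def test_series_with_mean_100_unchanged(self):
        assert normalize(np.array([50.0, 150.0])).tolist() == [50.0, 150.0]

    def test_dead_probe_raises(self):
        with pytest.raises(ValueError):
            normalize(np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            normalize(np.array([1.0, -3.0]))


class TestHeartCycleIntegrate:
    def test_constant_channels_unchanged(self):
        left = np.full(500, 100.0)
        out_l, out_r = heart_cycle_integrate(left, left, 25)
        assert (out_l == 100.0).all()

    def test_known_cycle_means_recovered(self):
        # peaks every 20 samples with varying heights; oracle segments at
        # the peak indices
        n = 200
        left = np.full(n, 100.0)
        peaks = np.arange(20, n, 20)
        left[peaks] += 50.0 + 5.0 * np.arange(len(peaks))
        right = left * 0.5
        out_l, out_r = heart_cycle_integrate(left, right, 25,
                                             min_beat_interval_s=0.5)
        bounds = np.concatenate(([0], peaks, [n]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            assert np.allclose(out_l[a:b], left[a:b].mean())
            assert np.allclose(out_r[a:b], right[a:b].mean())

    def test_variance_reduced_on_cardiac_waveform(self):
        t = np.arange(0, 40, 1 / 25)
        cardiac = 100 + 10 * np.cos(2 * np.pi * 1.17 * t) \
            + 3 * np.cos(2 * np.pi * 2.34 * t)
        out_l, _ = heart_cycle_integrate(cardiac, cardiac, 25)
        assert out_l.var() < cardiac.var()

    def test_channel_mean_preserved_exactly(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 40, 1 / 25)
        left = 100 + 10 * np.cos(2 * np.pi * 1.2 * t) + rng.normal(0, 1, len(t))
        right = 95 + 10 * np.cos(2 * np.pi * 1.2 * t) + rng.normal(0, 1, len(t))
        out_l, out_r = heart_cycle_integrate(left, right, 25)
        assert out_l.mean() == pytest.approx(left.mean(), abs=1e-9)
        assert out_r.mean() == pytest.approx(right.mean(), abs=1e-9)

    def test_no_cycles_in_nonconstant_signal_raises(self):
        ramp = np.linspace(0, 1, 100)
        with pytest.raises(ValueError, match="cardiac"):
            heart_cycle_integrate(ramp, ramp, 25)


class TestBaselineAndRangeCheck:
    def test_constant_100_becomes_zero(self, toy_epoch):
        ep = lf.baseline_correct(toy_epoch(), PreprocessConfig())
        assert np.allclose(ep.left, 0.0) and np.allclose(ep.right, 0.0)

    def test_constant_channel_offset_cancels_in_difference(self, toy_epoch):
        rng = np.random.default_rng(4)
        right = 100 + rng.normal(0, 5, 825)
        ep = toy_epoch(left=right + 3.0, right=right)
        lf.baseline_correct(ep, PreprocessConfig())
        assert np.allclose(ep.difference(), 0.0, atol=1e-12)

    def test_baseline_window_is_minus5_to_2(self, toy_epoch):
        # samples 50..224 (175 samples) form the window at 25 Hz
        left = np.full(825, 100.0)
        left[50:225] = 110.0
        ep = lf.baseline_correct(toy_epoch(left=left), PreprocessConfig())
        assert np.allclose(ep.left[50:225], 0.0)
        assert np.allclose(ep.left[:50], -10.0)

    def test_range_check_accepts_90_to_110(self, toy_epoch):
        rng = np.random.default_rng(5)
        ep = toy_epoch(left=rng.uniform(90, 110, 825))
        assert lf.range_check(ep, PreprocessConfig()) == ACCEPTED

    @pytest.mark.parametrize("bad", [150.0, 59.9, 140.5])
    def test_range_check_rejects_any_excursion(self, toy_epoch, bad):
        left = np.full(825, 100.0)
        left[400] = bad
        ep = toy_epoch(left=left)
        assert lf.range_check(ep, PreprocessConfig()) == REJECTED_RANGE


class TestTaskLI:
    def test_identical_channels_give_zero(self, toy_epoch):
        rng = np.random.default_rng(6)
        ch = rng.normal(0, 1, 825)
        ep = toy_epoch(left=ch, right=ch)
        assert lf.compute_task_li([ep], PreprocessConfig()).li == 0.0

    def test_swapping_channels_negates(self, toy_epoch):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 825), rng.normal(0, 1, 825)
        t1 = lf.compute_task_li([toy_epoch(left=a, right=b)], PreprocessConfig())
        t2 = lf.compute_task_li([toy_epoch(left=b, right=a)], PreprocessConfig())
        assert t1.li == -t2.li

    def test_ramp_difference_time_average(self, toy_epoch):
        # diff = 2 * ramp rising 0 -> 1 across the 6..23 s POI; the discrete
        # mean over samples j=0..424 of 2j/425 is 424/425 (continuum: 1)
        cfg = PreprocessConfig()
        times = -7.0 + np.arange(825) / 25.0
        ramp = np.clip((times - 6.0) / 17.0, 0, None)
        ep = toy_epoch(left=2 * ramp, right=np.zeros(825), task="B")
        li = lf.compute_task_li([ep], cfg).li
        assert li == pytest.approx(424 / 425, abs=1e-12)
        assert li == pytest.approx(1.0, abs=0.01)

    def test_poi_depends_on_task(self, toy_epoch):
        # a deflection at 20 s counts for decision tasks (POI to 23 s) but
        # not for overt-report tasks (POI ends at 17 s)
        diff = np.zeros(825)
        diff[(np.arange(825) / 25 - 7 >= 19) & (np.arange(825) / 25 - 7 < 21)] = 1.0
        cfg = PreprocessConfig()
        li_b = lf.compute_task_li([toy_epoch(left=diff, right=np.zeros(825),
                                             task="B")], cfg).li
        li_a = lf.compute_task_li([toy_epoch(left=diff, right=np.zeros(825),
                                             task="A")], cfg).li
        assert li_b > 0
        assert li_a == 0.0

    def test_zero_accepted_epochs_raise(self, toy_epoch):
        ep = toy_epoch()
        ep.status = REJECTED_SPIKE
        with pytest.raises(ValueError):
            lf.compute_task_li([ep], PreprocessConfig())

    def test_peak_li_on_constant_difference(self, toy_epoch):
        ep = toy_epoch(left=np.full(825, 3.0), right=np.zeros(825), task="B")
        assert lf.compute_peak_li([ep], PreprocessConfig()).li == pytest.approx(3.0)

    def test_peak_li_triangular_matches_discrete_window_oracle(self, toy_epoch):
        cfg = PreprocessConfig()
        times = -7.0 + np.arange(825) / 25.0
        tri = np.clip(1 - np.abs(times - 14.5) / 4.0, 0, None)  # peak mid-POI
        ep = toy_epoch(left=tri, right=np.zeros(825), task="B")
        li = lf.compute_peak_li([ep], cfg).li
        # oracle: explicit discrete sum over the 2 s window centred on the peak
        poi = slice(325, 750)
        seg = tri[poi]
        p = int(np.argmax(np.abs(seg)))
        expected = seg[max(p - 25, 0):p + 26].mean()
        assert li == pytest.approx(expected, abs=1e-12)

    def test_trial_se_formula(self):
        assert trial_se([2.0, 2.0, 2.0]) == 0.0
        assert trial_se([1.0, 2.0, 3.0]) == pytest.approx(1 / np.sqrt(3))
        assert np.isnan(trial_se([1.0]))


class TestEpochCountRule:
    def _mk(self, task, n):
        return lf.TaskLI(subject="S", task=task, session=1, li=0.1, se=0.01,
                         n_accepted_epochs=n)

    def test_11_epochs_excluded_15_retained(self):
        out = lf.apply_epoch_count_rule(
            [self._mk("A", 11), self._mk("B", 15)], PreprocessConfig())
        by = {t.task: t for t in out}
        assert by["A"].excluded and not by["B"].excluded

    def test_12_epochs_is_enough(self):
        out = lf.apply_epoch_count_rule([self._mk("A", 12)], PreprocessConfig())
        assert not out[0].excluded

    def test_two_short_tasks_exclude_the_whole_session(self):
        out = lf.apply_epoch_count_rule(
            [self._mk("A", 10), self._mk("B", 11), self._mk("C", 15)],
            PreprocessConfig())
        assert all(t.excluded for t in out)
        assert "participant" in [t for t in out if t.task == "C"][0].reason


class TestEndToEndProperties:
    def test_swapping_channels_negates_every_li(self):
        plan = lf.RecordingPlan(noise_sd_cm_s=0.4)
        rec = lf.simulate_recording(plan, seed=21)
        swapped = SignalRecording(sampling_rate=rec.sampling_rate,
                                  left=rec.right.copy(), right=rec.left.copy(),
                                  markers=list(rec.markers))
        cfg = lf.PreprocessConfig()
        a = {t.task: t.li for t in lf.preprocess_recording(rec, cfg).task_lis}
        b = {t.task: t.li for t in lf.preprocess_recording(swapped, cfg).task_lis}
        for task in a:
            assert a[task] == pytest.approx(-b[task], abs=1e-9)

    def test_rescaling_both_channels_leaves_lis_unchanged(self):
        plan = lf.RecordingPlan(noise_sd_cm_s=0.4)
        rec = lf.simulate_recording(plan, seed=22)
        scaled = SignalRecording(sampling_rate=rec.sampling_rate,
                                 left=3.7 * rec.left, right=3.7 * rec.right,
                                 markers=list(rec.markers))
        cfg = lf.PreprocessConfig()
        a = {t.task: t.li for t in lf.preprocess_recording(rec, cfg).task_lis}
        b = {t.task: t.li for t in lf.preprocess_recording(scaled, cfg).task_lis}
        for task in a:
            assert a[task] == pytest.approx(b[task], abs=1e-9)

    def test_stage_order_matches_pipeline_contract(self, monkeypatch):
        import latflow.preprocess as pp
        calls = []

        def record(name, fn):
            def wrapper(*a, **kw):
                if name not in calls:
                    calls.append(name)
                return fn(*a, **kw)
            return wrapper

        for name in ("downsample_recording", "flag_extreme_points",
                     "segment_epochs", "repair_or_reject", "normalize",
                     "heart_cycle_integrate", "range_check",
                     "baseline_correct", "compute_task_li"):
            monkeypatch.setattr(pp, name, record(name, getattr(pp, name)))
        rec = lf.simulate_recording(lf.RecordingPlan(), seed=23)
        pp.preprocess_recording(rec, lf.PreprocessConfig())
        assert calls == ["downsample_recording", "flag_extreme_points",
                         "segment_epochs", "repair_or_reject", "normalize",
                         "heart_cycle_integrate", "range_check",
                         "baseline_correct", "compute_task_li"]
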