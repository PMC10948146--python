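import numpy as np
import pytest

import kymodiff as kd
from kymodiff.diffusion import rolling_profile
from kymodiff.transloc import Call, FitError, Scenario

from conftest import brownian_positions, make_track

DT = 0.0424


def drift_track(meta, speed_bp_s, dur_s, noise_sd=0.0, x0=5.0, seed=0):
    n = int(round(dur_s / DT))
    v = speed_bp_s * meta.rise_nm_per_bp / 1000.0  # µm/s
    x = x0 + v * np.arange(n) * DT
    if noise_sd:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, n)
    return make_track(x, meta, "tr", "red")


class TestFitSegment:
    def test_exact_line(self, meta):
        n = 200
        x = 2.0 + 0.01 * np.arange(n) * DT
        seg = kd.fit_segment(make_track(x, meta), meta)
        assert seg.speed_um_s == pytest.approx(0.01, rel=1e-9)
        assert seg.r2 == pytest.approx(1.0)
        assert seg.speed_bp_s == pytest.approx(
            0.01 * 1000 / meta.rise_nm_per_bp, rel=1e-9)

    def test_constant_position_fails_filters(self, meta):
        seg = kd.fit_segment(make_track(np.full(200, 3.0), meta), meta)
        assert seg.speed_um_s == 0.0
        assert seg.r2 == 0.0
        assert not seg.passes_filters

    def test_short_span_filter_reason(self, meta):
        # 250 bp over 10 s: clean line, long enough, but span < 300 bp
        seg = kd.fit_segment(drift_track(meta, 25.0, 10.0), meta)
        assert not seg.passes_filters
        assert seg.filter_reasons == ["span<300bp"]

    def test_filters_are_conjunctive(self, meta):
        # 2 s at 50 bp/s: fails duration AND span
        seg = kd.fit_segment(drift_track(meta, 50.0, 2.0), meta)
        assert not seg.passes_filters
        assert "duration<5s" in seg.filter_reasons
        assert "span<300bp" in seg.filter_reasons

    def test_too_few_points_raises(self, meta):
        with pytest.raises(FitError):
            kd.fit_segment(make_track([1.0, 2.0], meta), meta)


class TestSegmentation:
    def test_single_speed_recovery(self, meta):
        """29 bp/s traces with 72 nm noise are recovered by one passing
        segment per trace with the cohort mean speed within 1.5 bp/s."""
        speeds = []
        detected = 0
        for seed in range(50):
            tr = drift_track(meta, 29.0, 40.0, noise_sd=0.072, seed=seed)
            segs = [s for s in kd.segment_translocations(tr, meta)
                    if s.passes_filters]
            detected += len(segs) > 0
            speeds += [abs(s.speed_bp_s) for s in segs]
        assert detected >= 45
        assert abs(np.mean(speeds) - 29.0) <= 1.5

    def test_two_speed_noiseless_changepoint(self, meta):
        n1 = n2 = int(30 / DT)
        v1 = 15 * meta.rise_nm_per_bp / 1000
        v2 = 45 * meta.rise_nm_per_bp / 1000
        t = np.arange(n1 + n2) * DT
        x = np.where(np.arange(n1 + n2) < n1, v1 * t,
                     v1 * n1 * DT + v2 * (t - n1 * DT)) + 5.0
        segs = kd.segment_translocations(make_track(x, meta), meta)
        assert len(segs) == 2
        assert abs(segs[0].end_frame - (n1 - 1)) <= 2
        assert segs[0].speed_bp_s == pytest.approx(15.0, rel=1e-3)
        assert segs[1].speed_bp_s == pytest.approx(45.0, rel=1e-3)

    def test_brownian_null_rarely_passes(self, meta):
        """Free diffusion at the high-diffusive boundary (the stand-in for
        the no-hydrolysis control) almost never yields passing segments."""
        fp = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            x = brownian_positions(rng, int(40 / DT), 0.04, DT, 0.072, x0=7.0)
            segs = [s for s in kd.segment_translocations(make_track(x, meta), meta)
                    if s.passes_filters]
            fp += len(segs) > 0
        assert fp / 50 <= 0.05

    def test_segments_time_ordered_non_overlapping(self, meta):
        tr = drift_track(meta, 29.0, 40.0, noise_sd=0.072, seed=3)
        segs = kd.segment_translocations(tr, meta)
        for a, b in zip(segs, segs[1:]):
            assert a.end_s <= b.start_s


class TestDirectionStats:
    def _seg(self, speed, track_id="t", start=0.0):
        return kd.TranslocSegment(
            track_id=track_id, start_s=start, end_s=start + 10,
            speed_um_s=speed * 0.318e-3, speed_bp_s=speed,
            distance_bp=abs(speed) * 10, r2=0.9, passes_filters=True)

    def test_opposite_signs_count_one_switch(self):
        stats = kd.direction_stats([self._seg(30.0), self._seg(-30.0, start=11)])
        assert stats["n_switches"] == 1
        assert stats["mean_speed_bp_s"] == pytest.approx(30.0)

    def test_same_sign_no_switch(self):
        stats = kd.direction_stats([self._seg(30.0), self._seg(28.0, start=11)])
        assert stats["n_switches"] == 0
        assert stats["n_positive"] == 2

    def test_cohort_speed_recovery(self, meta):
        """60 long traces at ground-truth 29 +/- 10 bp/s: the cohort mean is
        within a couple of bp/s of 29.  (Traces are 80 s so the slow tail of
        the speed distribution still clears the R^2 filter; shorter traces
        would truncate it and bias the mean upward.)"""
        rng = np.random.default_rng(0)
        segs = []
        for i in range(60):
            sp = abs(rng.normal(29.0, 10.0))
            tr = drift_track(meta, sp, 80.0, noise_sd=0.072, seed=200 + i)
            segs += [s for s in kd.segment_translocations(tr, meta)
                     if s.passes_filters]
        stats = kd.direction_stats(segs)
        sem = stats["sd_speed_bp_s"] / np.sqrt(stats["n_passing"])
        assert abs(stats["mean_speed_bp_s"] - 29.0) <= max(2 * sem, 2.0)


class TestPushPull:
    def _approach_then_transloc(self, meta, approach_sign, transloc_sign,
                                seed=0):
        """Directed approach at 0.3 µm/s (apparent window D ~0.011 µm²/s:
        low-diffusive), then slow processive translocation."""
        rng = np.random.default_rng(seed)
        n_d = 300
        v_app = approach_sign * 0.3  # µm/s
        xd = 7.0 + v_app * np.arange(n_d) * DT
        n_t = int(30 / DT)
        v = transloc_sign * 29 * meta.rise_nm_per_bp / 1000
        xt = xd[-1] + v * np.arange(1, n_t + 1) * DT
        x = np.concatenate([xd, xt]) + rng.normal(0, 0.03, n_d + n_t)
        return make_track(x, meta, "pp", "red")

    def test_same_direction_is_push(self, meta):
        tr = self._approach_then_transloc(meta, +1, +1)
        prof = rolling_profile(tr, meta)
        segs = [s for s in kd.segment_translocations(tr, meta, profile=prof)
                if s.passes_filters]
        call = kd.classify_push_pull(tr, segs[0], prof, meta)
        assert call.call is Call.PUSH
        assert call.scenario is Scenario.APPROACH_TO_TRANSLOC

    def test_opposite_direction_is_pull(self, meta):
        tr = self._approach_then_transloc(meta, +1, -1)
        prof = rolling_profile(tr, meta)
        segs = [s for s in kd.segment_translocations(tr, meta, profile=prof)
                if s.passes_filters]
        call = kd.classify_push_pull(tr, segs[0], prof, meta)
        assert call.call is Call.PULL

    def test_mirror_symmetry(self, meta):
        """Negating all positions flips every sign but keeps the call."""
        tr = self._approach_then_transloc(meta, +1, +1)
        mirrored = make_track(-tr.positions_um + 16.0, meta, "pp", "red")
        for t in (tr, mirrored):
            prof = rolling_profile(t, meta)
            segs = [s for s in kd.segment_translocations(t, meta, profile=prof)
                    if s.passes_filters]
            call = kd.classify_push_pull(t, segs[0], prof, meta)
            assert call.call is Call.PUSH

    def test_sub_precision_approach_is_indeterminate(self, meta):
        """A net approach below the localization precision carries no sign."""
        rng = np.random.default_rng(4)
        n_d = 300
        xd = 7.0 + np.cumsum(rng.normal(0, np.sqrt(2 * 0.05 * DT), n_d))
        xd = xd - np.linspace(0, xd[-1] - 7.0, n_d)  # zero net displacement
        n_t = int(30 / DT)
        v = 29 * meta.rise_nm_per_bp / 1000
        x = np.concatenate([xd, xd[-1] + v * np.arange(1, n_t + 1) * DT])
        tr = make_track(x, meta, "pp", "red")
        prof = rolling_profile(tr, meta)
        segs = [s for s in kd.segment_translocations(tr, meta, profile=prof)
                if s.passes_filters]
        call = kd.classify_push_pull(tr, segs[0], prof, meta,
                                     precision_um=10.0)
        assert call.call is Call.INDETERMINATE

    def test_simulated_push_mode_recovered(self, meta):
        """Simulated encounters in push mode are called push in >= 90% of
        determinate calls."""
        calls = []
        for seed in range(30):
            cfg = kd.SimConfig(seed=seed, duration_s=90,
                               nucleosome_positions_um=(8.0,),
                               capture_radius_um=0.08,
                               sequestration_tau_s=2.0, p_translocate=1.0,
                               transloc_mode="push",
                               transloc_duration_tau_s=60.0,
                               start_position_um=7.0, start_state=2)
            tr, _ = kd.simulate_track(cfg)
            m = cfg.meta()
            prof = rolling_profile(tr, m)
            segs = [s for s in kd.segment_translocations(tr, m, profile=prof)
                    if s.passes_filters]
            if not segs:
                continue
            seg = max(segs, key=lambda s: s.end_s - s.start_s)
            call = kd.classify_push_pull(tr, seg, prof, m)
            if call.call is not Call.INDETERMINATE:
                calls.append(call.call)
        assert len(calls) >= 10
        assert calls.count(Call.PUSH) / len(calls) >= 0.9
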