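import numpy as np
import pytest

import kymodiff as kd
from kymodiff.coloc import ColocKind
from kymodiff.diffusion import rolling_profile

from conftest import brownian_positions, make_track

DT = 0.0424


class TestThreshold:
    def test_zero_diffusion_gives_zero_threshold(self):
        assert kd.coloc_threshold(0.0, 0.0, DT).d_um == 0.0

    def test_closed_form_reproduces_printed_scale(self):
        """Two molecules at mean D = 0.25 µm²/s give d = 0.29 µm, the scale
        of published remodeler-pair thresholds."""
        thr = kd.coloc_threshold(0.25, 0.25, DT)
        assert thr.x1_um == pytest.approx(np.sqrt(2 * 0.25 * DT), rel=1e-12)
        assert thr.d_um == pytest.approx(0.29, abs=0.005)

    def test_threshold_scales_as_sqrt_dt(self):
        d1 = kd.coloc_threshold(0.1, 0.2, DT).d_um
        d2 = kd.coloc_threshold(0.1, 0.2, 2 * DT).d_um
        assert d2 == pytest.approx(np.sqrt(2) * d1, rel=1e-12)

    def test_negative_D_rejected(self):
        with pytest.raises(ValueError):
            kd.coloc_threshold(-0.1, 0.1, DT)


class TestIntervals:
    def test_identical_trajectories_full_overlap(self, meta):
        rng = np.random.default_rng(0)
        x = brownian_positions(rng, 100, 0.05, DT)
        A = make_track(x, meta, "a", "green")
        B = make_track(x.copy(), meta, "b", "red")
        thr = kd.coloc_threshold(0.05, 0.05, DT)
        assert kd.find_coloc_intervals(A, B, thr) == [(0, 99)]

    def test_constant_separation_above_threshold_empty(self, meta):
        thr = kd.coloc_threshold(0.05, 0.05, DT)
        A = make_track(np.full(50, 5.0), meta, "a", "green")
        B = make_track(np.full(50, 5.0 + 2 * thr.d_um), meta, "b", "red")
        assert kd.find_coloc_intervals(A, B, thr) == []

    def test_no_temporal_overlap_is_empty_not_error(self, meta):
        A = kd.Track("a", "green", np.arange(10), np.full(10, 5.0), meta)
        B = kd.Track("b", "red", np.arange(20, 30), np.full(10, 5.0), meta)
        assert kd.find_coloc_intervals(A, B, kd.coloc_threshold(0.1, 0.1, DT)) == []

    def test_symmetry(self, meta):
        rng = np.random.default_rng(5)
        A = make_track(brownian_positions(rng, 200, 0.06, DT), meta, "a", "green")
        B = make_track(brownian_positions(rng, 200, 0.06, DT), meta, "b", "red")
        thr = kd.coloc_threshold(0.06, 0.06, DT)
        assert kd.find_coloc_intervals(A, B, thr) == kd.find_coloc_intervals(B, A, thr)

    def test_raising_threshold_never_loses_frames(self, meta):
        rng = np.random.default_rng(6)
        A = make_track(brownian_positions(rng, 300, 0.06, DT), meta, "a", "green")
        B = make_track(brownian_positions(rng, 300, 0.06, DT), meta, "b", "red")
        total = []
        for d in (0.05, 0.1, 0.2, 0.4, 0.8):
            thr = kd.ColocThreshold(d / 2, d / 2)
            ivs = kd.find_coloc_intervals(A, B, thr)
            total.append(sum(e - s + 1 for s, e in ivs))
        assert total == sorted(total)

    def test_tethered_vs_independent_detection(self, meta):
        """Co-diffusing pairs are detected as colocalized for most frames;
        independent pairs only rarely, at the diffusion-derived threshold."""
        tp = fp = tot_t = tot_f = 0
        for seed in range(10):
            A, B, _ = kd.simulate_pair(kd.SimConfig(seed=seed, duration_s=40),
                                       coupled=True, coupling_jitter_um=0.02)
            Da = rolling_profile(A, meta).mean_D_raw
            Db = rolling_profile(B, meta).mean_D_raw
            thr = kd.coloc_threshold(max(Da, 0), max(Db, 0), DT)
            tp += sum(e - s + 1 for s, e in kd.find_coloc_intervals(A, B, thr))
            tot_t += len(A)
            A2, B2, _ = kd.simulate_pair(
                kd.SimConfig(seed=seed + 500, duration_s=40), coupled=False)
            Da = rolling_profile(A2, meta).mean_D_raw
            Db = rolling_profile(B2, meta).mean_D_raw
            thr = kd.coloc_threshold(max(Da, 0), max(Db, 0), DT)
            fp += sum(e - s + 1 for s, e in kd.find_coloc_intervals(A2, B2, thr))
            tot_f += min(len(A2), len(B2))
        assert tp / tot_t > 0.9
        assert fp / tot_f < 0.1


class TestEventTyping:
    def test_interval_beyond_five_exposures_is_long(self, meta):
        rng = np.random.default_rng(1)
        x = brownian_positions(rng, 100, 0.05, DT)
        A = make_track(x, meta, "a", "green")
        B = make_track(x + 0.01, meta, "b", "red")
        thr = kd.coloc_threshold(0.05, 0.05, DT)
        ev = kd.classify_coloc((10, 17), A, B, thr)  # 8 frames
        assert ev.kind is ColocKind.LONG
        assert ev.duration_s == pytest.approx(8 * DT)

    def test_every_event_gets_exactly_one_kind(self, meta):
        rng = np.random.default_rng(2)
        A = make_track(brownian_positions(rng, 400, 0.08, DT, 0.072), meta,
                       "a", "green")
        B = make_track(brownian_positions(rng, 400, 0.08, DT, 0.072), meta,
                       "b", "red")
        thr = kd.coloc_threshold(0.08, 0.08, DT)
        for ev in kd.pair_coloc_events(A, B, thr):
            assert ev.kind in (ColocKind.SHORT, ColocKind.LONG, ColocKind.BYPASS)

    def test_recoil_vs_codiffusion_agreement(self, meta):
        """Ground-truth labeled events: sub-threshold chance collisions of
        independent fast movers should type short; bound co-diffusing pairs
        should type long.  Pooled agreement >= 85%."""
        thr = kd.coloc_threshold(0.25, 0.25, DT)
        ok = tot = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            n = 500
            xa = brownian_positions(rng, n, 0.08, DT, 0.072, x0=4.0)
            xb = brownian_positions(rng, n, 0.08, DT, 0.072, x0=4.6)
            A = make_track(xa, meta, "a", "green")
            B = make_track(xb, meta, "b", "red")
            for ev in kd.pair_coloc_events(A, B, thr):
                if (ev.end_frame - ev.start_frame + 1) <= 5 \
                        and ev.kind is not ColocKind.BYPASS:
                    tot += 1
                    ok += ev.kind is ColocKind.SHORT
            base = brownian_positions(rng, n, 0.08, DT, x0=4.0)
            xc = base + rng.normal(0, 0.02, n) + rng.normal(0, 0.072, n)
            xd = base + rng.normal(0, 0.02, n) + rng.normal(0, 0.072, n)
            C = make_track(xc, meta, "c", "green")
            D = make_track(xd, meta, "d", "red")
            for ev in kd.pair_coloc_events(C, D, thr):
                tot += 1
                ok += ev.kind is ColocKind.LONG
        assert tot > 60
        assert ok / tot >= 0.85


class TestBypass:
    def test_linear_crossing_is_bypass(self, meta):
        n = 100
        xa = 4.0 + 0.02 * np.arange(n)   # crosses 5.0 at frame 50
        xb = np.full(n, 5.0)
        A = make_track(xa, meta, "a", "green")
        B = make_track(xb, meta, "b", "red")
        thr = kd.coloc_threshold(0.05, 0.05, DT)
        evs = kd.pair_coloc_events(A, B, thr)
        assert any(e.kind is ColocKind.BYPASS for e in evs)

    def test_approach_and_recoil_is_not_bypass(self, meta):
        n = 100
        xa = 5.0 + np.abs(0.02 * (np.arange(n) - 50)) + 0.05
        B = make_track(np.full(n, 5.0), meta, "b", "red")
        A = make_track(xa, meta, "a", "green")
        thr = kd.coloc_threshold(0.05, 0.05, DT)
        evs = kd.pair_coloc_events(A, B, thr)
        assert not any(e.kind is ColocKind.BYPASS for e in evs)

    def test_noisy_crossings_detected_without_false_positives(self, meta):
        det = false = 0
        n_pairs = 100
        for seed in range(n_pairs):
            rng = np.random.default_rng(seed)
            n = 200
            xa = 5.0 + 0.01 * (np.arange(n) - 100) + rng.normal(0, 0.072, n)
            xb = 5.0 + rng.normal(0, 0.072, n)
            A = make_track(xa, meta, "a", "green")
            B = make_track(xb, meta, "b", "red")
            thr = kd.coloc_threshold(0.05, 0.05, DT)
            det += any(e.kind is ColocKind.BYPASS
                       for e in kd.pair_coloc_events(A, B, thr))
            xc = 5.0 + np.abs(0.01 * (np.arange(n) - 100)) + 0.1 \
                + rng.normal(0, 0.072, n)
            C = make_track(xc, meta, "c", "green")
            false += any(e.kind is ColocKind.BYPASS
                         for e in kd.pair_coloc_events(C, B, thr))
        assert det / n_pairs >= 0.95
        assert false / n_pairs <= 0.02

    def test_insufficient_flank_leaves_event_flagged(self, meta):
        x = np.full(10, 5.0)
        A = make_track(x, meta, "a", "green")
        B = make_track(x + 0.01, meta, "b", "red")
        ev = kd.classify_coloc((0, 9), A, B, kd.coloc_threshold(0.05, 0.05, DT))
        out = kd.detect_bypass(A, B, [ev])
        assert out[0].bypass_flagged
        assert out[0].kind is not ColocKind.BYPASS


class TestNucleosomeColoc:
    def test_dark_gap_forward_filled(self, meta):
        vis = np.zeros(101, bool)
        vis[0] = vis[100] = True
        nuc = kd.Track("n", "green", np.arange(101), np.full(101, 8.0), meta, vis)
        rem = kd.Track("r", "red", np.arange(101), np.full(101, 8.05), meta)
        events, excluded = kd.nucleosome_coloc(rem, [nuc])
        assert not excluded["n"]
        assert len(events) == 1
        assert (events[0].start_frame, events[0].end_frame) == (0, 100)

    def test_unstable_signal_excluded(self, meta):
        rng = np.random.default_rng(0)
        nuc = make_track(8.0 + rng.normal(0, 0.5, 200), meta, "wander", "green")
        rem = make_track(np.full(200, 8.0), meta, "r", "red")
        events, excluded = kd.nucleosome_coloc(rem, [nuc], stability_sd_um=0.1)
        assert excluded["wander"]
        assert events == []

    def test_remodeler_outside_radius_no_event(self, meta):
        nuc = make_track(np.full(100, 8.0), meta, "n", "green")
        rem = make_track(np.full(100, 8.3), meta, "r", "red")
        events, _ = kd.nucleosome_coloc(rem, [nuc], radius_um=0.17)
        assert events == []
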