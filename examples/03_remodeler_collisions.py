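"""Two-color collision analysis of a remodeler pair on the same DNA.

Simulates a co-diffusing (transiently bound) pair and an independent pair,
derives the diffusion-based distance threshold d = sqrt(2 D1 dt) +
sqrt(2 D2 dt), and types the resulting colocalization events as short
(touch-and-recoil), long (co-diffusion) or bypass (the molecules swap
sides).
"""

import kymodiff as kd

dt = 0.0424  # line time, s

for label, coupled in (("co-diffusing pair", True), ("independent pair", False)):
    A, B, _ = kd.simulate_pair(kd.SimConfig(seed=5, duration_s=60),
                               coupled=coupled, coupling_jitter_um=0.02)
    prof_A = kd.rolling_profile(A)
    prof_B = kd.rolling_profile(B)
    thr = kd.coloc_threshold(max(prof_A.mean_D_raw, 0),
                             max(prof_B.mean_D_raw, 0), dt)
    events = kd.pair_coloc_events(A, B, thr)
    frames = sum(e.end_frame - e.start_frame + 1 for e in events)
    print(f"{label}: threshold d = {thr.d_um:.3f} µm, "
          f"{len(events)} events, {frames / len(A):.1%} of frames colocalized")
    for kind in kd.ColocKind:
        k = sum(e.kind is kind for e in events)
        if k:
            print(f"    {kind.value}: {k}")
print()
print("A bound pair stays within threshold almost continuously (long events")
print("split only by brief noise excursions); independent molecules only")
print("brush past each other by chance.")
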