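"""Generative ground-truth engine for tethered-DNA single-particle data.

Emulates what the instrument records: state-switching 1D Brownian motion of
a remodeler along a stretched tether (continuous-time Markov switching among
non/low/high-diffusive states, Euler-Maruyama increments, reflecting
boundaries), Gaussian localization noise (~72 nm), 42.4 ms line time,
co-diffusing or independent two-color pairs, nucleosome encounters with
exponential sequestration, constant-speed processive translocation
(~29 +/- 10 bp/s, push or pull relative to the approach direction, the
nucleosome co-moving), pulsed-illumination dark gaps, single-rate
photobleaching, and 25 nm staircase force-extension curves for nucleosome
counting.  Every simulated object carries its ground truth so each analysis
stage can be scored against what actually happened.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import AcquisitionMeta, Track, write_tracks

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_track",
    "simulate_pair",
    "simulate_fd_staircase",
    "make_cohort",
]

STATES = ("non_diffusive", "low", "high")


@dataclass(frozen=True)
class SimConfig:
    """Full generative specification for one synthetic trajectory.

    Defaults are the study conditions: 42.4 ms lines, 72 nm localization
    noise, diffusivities spanning the three mobility classes, 18 s
    nucleosome sequestration, 29 +/- 10 bp/s translocation, and a ~1 s-on /
    ~9 s-off green illumination pulse scheme when pulsing is enabled.
    """

    seed: int = 0
    duration_s: float = 60.0
    line_time_s: float = 0.0424
    tether_length_um: float = 15.4
    noise_sd_um: float = 0.072
    D_by_state: tuple = (0.0, 0.02, 0.08)  # µm²/s for (non_diffusive, low, high)
    rate_matrix: tuple = (
        (0.0, 0.25, 0.25),
        (0.25, 0.0, 0.25),
        (0.25, 0.25, 0.0),
    )  # per-second transition rates between diffusive states
    start_state: int | None = None  # None -> drawn uniformly
    start_position_um: float | None = None  # None -> uniform in mid-tether
    nucleosome_positions_um: tuple = ()
    capture_radius_um: float = 0.05
    sequestration_tau_s: float = 18.0
    p_translocate: float = 0.0
    transloc_speed_bp_s: tuple = (29.0, 10.0)  # (mean, sd)
    transloc_mode: str = "push"  # or "pull"
    transloc_duration_tau_s: float = 30.0
    pause_rate_per_s: float = 0.0
    pause_tau_s: float = 2.0
    switch_rate_per_s: float = 0.0
    bleach_rate_per_s: float = 0.0
    pulse_scheme: tuple | None = None  # (on_s, off_s); None -> continuous
    rise_nm_per_bp: float = 0.318

    def __post_init__(self) -> None:
        if self.D_by_state[0] != 0.0:
            raise ValueError("D_by_state[non_diffusive] must be 0")
        if not (0.0 <= self.p_translocate <= 1.0):
            raise ValueError("p_translocate must be in [0, 1]")
        if self.transloc_mode not in ("push", "pull"):
            raise ValueError("transloc_mode must be 'push' or 'pull'")
        for row in self.rate_matrix:
            if any(r < 0 for r in row):
                raise ValueError("rates must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.line_time_s))

    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta(
            line_time_s=self.line_time_s,
            tether_length_um=self.tether_length_um,
            rise_nm_per_bp=self.rise_nm_per_bp,
        )


@dataclass
class GroundTruth:
    """Latent truth emitted alongside a simulated track."""

    states: np.ndarray                 # per-frame code: 0/1/2 diffusive,
                                       # 3 sequestered, 4 translocating, 5 paused
    change_points: list                # frame indices of latent transitions
    segment_speeds: list               # (start_frame, end_frame, speed_um_s)
    coloc_intervals: list              # (start_frame, end_frame) true proximity
    capture_events: list               # (frame, nucleosome_index)
    nucleosome_paths_um: np.ndarray | None = None  # (n_nuc, n_frames)
    n_nucleosomes: int = 0

    SEQUESTERED = 3
    TRANSLOCATING = 4
    PAUSED = 5


def _pulse_visible(n_frames: int, dt: float, scheme: tuple | None) -> np.ndarray:
    if scheme is None:
        return np.ones(n_frames, dtype=bool)
    on_s, off_s = scheme
    t = np.arange(n_frames) * dt
    return (t % (on_s + off_s)) < on_s


def simulate_track(config: SimConfig, channel: str = "red",
                   track_id: str = "sim-0") -> tuple[Track, GroundTruth]:
    """Simulate one remodeler trajectory with full latent ground truth.

    Continuous-time Markov switching among the diffusive states with
    exponential holding times; within a state, increments are
    sqrt(2 D dt) * N(0,1) with reflecting boundaries at [0, tether_length].
    Entering a nucleosome capture radius sequesters the remodeler for an
    Exp(sequestration_tau_s) dwell, after which (with ``p_translocate``) a
    constant-speed translocation starts, directed per ``transloc_mode``
    relative to the approach sign and carrying the nucleosome along.
    Gaussian measurement noise is added last; dark frames follow the pulse
    scheme; photobleaching truncates the track.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.line_time_s
    L = config.tether_length_um
    n_frames = config.n_frames
    if config.bleach_rate_per_s > 0:
        t_bleach = rng.exponential(1.0 / config.bleach_rate_per_s)
        n_frames = max(10, min(n_frames, int(np.ceil(t_bleach / dt))))

    rates = np.asarray(config.rate_matrix, dtype=float)
    D = np.asarray(config.D_by_state, dtype=float)
    nucs = np.asarray(config.nucleosome_positions_um, dtype=float)
    n_nuc = nucs.size
    nuc_paths = np.tile(nucs[:, None], (1, n_frames)) if n_nuc else None

    state = (int(config.start_state) if config.start_state is not None
             else int(rng.integers(0, 3)))
    x = (float(config.start_position_um) if config.start_position_um is not None
         else float(rng.uniform(0.2 * L, 0.8 * L)))

    def hold_time(s: int) -> float:
        total = rates[s].sum()
        return rng.exponential(1.0 / total) if total > 0 else np.inf

    def next_state(s: int) -> int:
        p = rates[s] / rates[s].sum()
        return int(rng.choice(3, p=p))

    mode = "diffusing"
    hold = hold_time(state)
    seq_left = 0.0
    trans_left = 0.0
    pause_left = 0.0
    speed = 0.0
    bound_nuc = -1
    prev_x = x

    positions = np.empty(n_frames)
    states = np.empty(n_frames, dtype=np.int8)
    change_points: list[int] = []
    capture_events: list[tuple[int, int]] = []
    coloc_intervals: list[list[int]] = []
    seg_speeds: list[tuple[int, int, float]] = []
    seg_start = 0
    last_code = -1

    for f in range(n_frames):
        if mode == "diffusing":
            code = state
            prev_x = x
            x += np.sqrt(2.0 * D[state] * dt) * rng.standard_normal()
            hold -= dt
            if hold <= 0:
                state = next_state(state)
                hold = hold_time(state)
            # nucleosome capture
            if n_nuc:
                dists = np.abs(nucs - x)
                j = int(np.argmin(dists))
                if dists[j] < config.capture_radius_um:
                    mode = "sequestered"
                    bound_nuc = j
                    approach = np.sign(nucs[j] - prev_x) or 1.0
                    seq_left = rng.exponential(config.sequestration_tau_s)
                    x = nucs[j]
                    capture_events.append((f, j))
                    coloc_intervals.append([f, f])
                    code = GroundTruth.SEQUESTERED
        elif mode == "sequestered":
            code = GroundTruth.SEQUESTERED
            coloc_intervals[-1][1] = f
            x = nucs[bound_nuc]
            seq_left -= dt
            if seq_left <= 0:
                if rng.uniform() < config.p_translocate:
                    mode = "translocating"
                    mag = abs(rng.normal(*config.transloc_speed_bp_s))
                    mag = max(mag, 5.0) * config.rise_nm_per_bp / 1000.0  # µm/s
                    sign = approach if config.transloc_mode == "push" else -approach
                    speed = float(sign * mag)
                    trans_left = rng.exponential(config.transloc_duration_tau_s)
                    seg_speeds.append([f, f, speed])
                else:
                    mode = "diffusing"
                    state = int(rng.integers(0, 3))
                    hold = hold_time(state)
        elif mode == "paused":
            code = GroundTruth.PAUSED
            coloc_intervals[-1][1] = f
            pause_left -= dt
            if pause_left <= 0:
                mode = "translocating"
                seg_speeds.append([f, f, speed])
        else:  # translocating
            code = GroundTruth.TRANSLOCATING
            coloc_intervals[-1][1] = f
            x += speed * dt
            x = float(np.clip(x, 0.0, L))
            nucs[bound_nuc] = x
            seg_speeds[-1][1] = f
            if config.switch_rate_per_s > 0 and rng.uniform() < config.switch_rate_per_s * dt:
                speed = -speed
                seg_speeds.append([f, f, speed])
            if config.pause_rate_per_s > 0 and rng.uniform() < config.pause_rate_per_s * dt:
                mode = "paused"
                pause_left = rng.exponential(config.pause_tau_s)
            trans_left -= dt
            if trans_left <= 0:
                mode = "diffusing"
                bound_nuc = -1
                state = int(rng.integers(0, 3))
                hold = hold_time(state)

        # reflecting boundaries
        while x < 0.0 or x > L:
            x = -x if x < 0.0 else 2.0 * L - x
        positions[f] = x
        states[f] = code
        if nuc_paths is not None:
            nuc_paths[:, f] = nucs
        if code != last_code:
            if f:
                change_points.append(f)
            last_code = code

    noisy = positions + rng.normal(0.0, config.noise_sd_um, n_frames)
    noisy = np.clip(noisy, 0.0, L)
    visible = _pulse_visible(n_frames, dt, config.pulse_scheme)
    track = Track(
        track_id=track_id,
        channel=channel,
        frames=np.arange(n_frames, dtype=np.int64),
        positions_um=noisy,
        meta=config.meta(),
        visible=visible,
    )
    truth = GroundTruth(
        states=states,
        change_points=change_points,
        segment_speeds=[tuple(s) for s in seg_speeds],
        coloc_intervals=[tuple(iv) for iv in coloc_intervals],
        capture_events=capture_events,
        nucleosome_paths_um=nuc_paths,
        n_nucleosomes=n_nuc,
    )
    return track, truth


def nucleosome_tracks(truth: GroundTruth, config: SimConfig,
                      pulse_scheme: tuple | None = (1.0, 9.0),
                      noise_sd_um: float | None = None) -> list[Track]:
    """Green-channel tracks for the simulated nucleosomes (pulsed by default)."""
    if truth.nucleosome_paths_um is None:
        return []
    rng = np.random.default_rng(config.seed + 7)
    sd = config.noise_sd_um if noise_sd_um is None else noise_sd_um
    n_frames = truth.nucleosome_paths_um.shape[1]
    visible = _pulse_visible(n_frames, config.line_time_s, pulse_scheme)
    out = []
    for j in range(truth.n_nucleosomes):
        pos = truth.nucleosome_paths_um[j] + rng.normal(0.0, sd, n_frames)
        out.append(
            Track(
                track_id=f"nuc-{j}",
                channel="green",
                frames=np.arange(n_frames, dtype=np.int64),
                positions_um=np.clip(pos, 0.0, config.tether_length_um),
                meta=config.meta(),
                visible=visible.copy(),
            )
        )
    return out


def simulate_pair(
    config: SimConfig,
    coupled: bool,
    coupling_jitter_um: float = 0.02,
) -> tuple[Track, Track, GroundTruth]:
    """Two-color pair: co-diffusing (one latent path + per-channel jitter)
    or two independent molecules.  True colocalization intervals are the
    full overlap when coupled and empty otherwise."""
    if coupled:
        # one latent (noise-free) path; each channel sees it through its own
        # coupling jitter plus localization noise
        clean_cfg = _with(config, noise_sd_um=0.0)
        clean, truth = simulate_track(clean_cfg, channel="green", track_id="pair-A")
        rng = np.random.default_rng(config.seed + 1)
        n = len(clean)
        xa = clean.positions_um + rng.normal(0, coupling_jitter_um, n) \
            + rng.normal(0, config.noise_sd_um, n)
        xb = clean.positions_um + rng.normal(0, coupling_jitter_um, n) \
            + rng.normal(0, config.noise_sd_um, n)
        meta = config.meta()
        A = Track("pair-A", "green", clean.frames, np.clip(xa, 0, config.tether_length_um),
                  meta, clean.visible.copy())
        B = Track("pair-B", "red", clean.frames, np.clip(xb, 0, config.tether_length_um),
                  meta, clean.visible.copy())
        truth.coloc_intervals = [(0, n - 1)]
        return A, B, truth
    A, truth_a = simulate_track(config, channel="green", track_id="pair-A")
    B, _ = simulate_track(_with(config, seed=config.seed + 104729),
                          channel="red", track_id="pair-B")
    n = min(len(A), len(B))
    truth_a.coloc_intervals = []
    return A, B, truth_a


def _with(config: SimConfig, **kw) -> SimConfig:
    d = asdict(config)
    d.update(kw)
    # asdict flattens nested tuples to lists; restore tuples
    for key in ("D_by_state", "transloc_speed_bp_s", "nucleosome_positions_um"):
        d[key] = tuple(d[key])
    d["rate_matrix"] = tuple(tuple(r) for r in d["rate_matrix"])
    if d["pulse_scheme"] is not None:
        d["pulse_scheme"] = tuple(d["pulse_scheme"])
    return SimConfig(**d)


def simulate_fd_staircase(
    n_nucleosomes: int,
    step_nm: float = 25.0,
    noise_nm: float = 3.0,
    seed: int = 0,
    dt_s: float = 0.01,
    mean_wait_s: float = 1.0,
    settle_s: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Monotone unwrapping staircase: exponential waits, Gaussian noise.

    Returns ``(t, distance_nm, truth)`` with truth holding the step times
    and count.
    """
    if n_nucleosomes < 0:
        raise ValueError("n_nucleosomes must be >= 0")
    rng = np.random.default_rng(seed)
    waits = rng.exponential(mean_wait_s, size=n_nucleosomes)
    step_times = settle_s + np.cumsum(waits)
    total = settle_s + (step_times[-1] if n_nucleosomes else 0.0) + settle_s
    t = np.arange(0.0, total, dt_s)
    clean = np.zeros_like(t)
    for st in step_times:
        clean[t >= st] += step_nm
    trace = clean + rng.normal(0.0, noise_nm, t.size)
    truth = {"n_steps": int(n_nucleosomes), "step_times_s": step_times.tolist(),
             "step_nm": float(step_nm)}
    return t, trace, truth


def make_cohort(
    grid: dict[str, SimConfig],
    n_per_cell: int,
    seed: int,
    outdir,
    overwrite: bool = False,
) -> dict:
    """Write a reproducible cohort of simulated track files plus a manifest.

    ``grid`` maps condition names to base configs; each condition gets
    ``n_per_cell`` tracks with per-file seeds derived deterministically from
    ``seed``.  The manifest records per-file seeds, parameters, and sha256
    checksums; an existing manifest is refused unless ``overwrite``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    manifest = {"seed": int(seed), "conditions": {}}
    for name, cfg in sorted(grid.items()):
        entries = []
        for i in range(n_per_cell):
            sub_seed = (seed * 100003 + hash_stable(f"{name}:{i}")) % (2**31)
            c = _with(cfg, seed=sub_seed)
            track, truth = simulate_track(c, track_id=f"{name}-{i}")
            fname = f"{name}_{i:03d}.csv"
            write_tracks([track], outdir / fname)
            entries.append(
                {
                    "file": fname,
                    "seed": sub_seed,
                    "n_frames": len(track),
                    "sha256": _sha256(outdir / fname),
                    "true_states": np.bincount(
                        np.clip(truth.states, 0, 5), minlength=6
                    ).tolist(),
                }
            )
        manifest["conditions"][name] = {
            "config": _config_json(cfg),
            "tracks": entries,
        }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def hash_stable(s: str) -> int:
    return int.from_bytes(hashlib.sha256(s.encode()).digest()[:4], "big")


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _config_json(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    return json.loads(json.dumps(d))
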