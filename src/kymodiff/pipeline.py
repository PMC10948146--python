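"""End-to-end orchestration: simulate -> diffusion -> dwell -> coloc ->
transloc -> report, driven by one declarative config.

The config is a nested key/value tree (YAML or a plain dict).  Stages run in
dependency order, each writing delimited-text tables into the run directory;
a :class:`RunManifest` records per-stage outputs with sha256 checksums,
seeds, and wall-clock times, so an unchanged config reproduces identical
checksums for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import coloc_threshold, pair_coloc_events
from .diffusion import DiffusionState, rolling_profile, UndefinedWindowError
from .dwell import LifetimeSample, select_model
from .io import AcquisitionMeta, read_tracks
from .simulate import SimConfig, make_cohort
from .transloc import direction_stats, segment_translocations

__all__ = ["RunManifest", "run_pipeline", "report"]


class ConfigError(ValueError):
    pass


@dataclass
class RunManifest:
    config_hash: str
    version: str
    outdir: str
    seed: int
    stages: dict = field(default_factory=dict)  # name -> {outputs, wall_s}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    return yaml.safe_load(Path(config).read_text())


_KNOWN_STAGES = {"simulate", "diffusion", "dwell", "coloc", "transloc"}


def run_pipeline(config, outdir=None) -> RunManifest:
    """Run the configured stages in dependency order.

    ``config`` is a dict or a YAML path with keys ``outdir``, ``seed`` and a
    subset of stage sections (``simulate``, ``diffusion``, ``dwell``,
    ``coloc``, ``transloc``).  Unknown stage names raise a
    :class:`ConfigError` naming the field.  A stage failure halts the run,
    leaving a partial manifest on disk.
    """
    cfg = _load_config(config)
    unknown = set(cfg) - _KNOWN_STAGES - {"outdir", "seed", "meta"}
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    outdir = Path(outdir or cfg.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    meta = AcquisitionMeta(**cfg.get("meta", {}))
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    manifest = RunManifest(
        config_hash=hashlib.sha256(blob).hexdigest(),
        version=__version__,
        outdir=str(outdir),
        seed=seed,
    )

    def record(name, outputs, t0):
        manifest.stages[name] = {
            "outputs": {str(p.name): _sha256(p) for p in outputs},
            "wall_s": round(time.monotonic() - t0, 3),
        }
        manifest.to_json(outdir / "run_manifest.json")

    track_files: list[Path] = []
    if "simulate" in cfg:
        t0 = time.monotonic()
        sim = cfg["simulate"]
        grid = {
            name: SimConfig(**params)
            for name, params in sim.get("conditions", {}).items()
        }
        cohort = make_cohort(grid, int(sim.get("n_per_cell", 1)), seed, outdir,
                             overwrite=True)
        for cond in cohort["conditions"].values():
            track_files += [outdir / e["file"] for e in cond["tracks"]]
        record("simulate", track_files + [outdir / "manifest.json"], t0)
    else:
        track_files = sorted(outdir.glob("*.csv"))
        track_files = [p for p in track_files
                       if p.name not in ("windows.csv", "segments.csv",
                                         "profiles.csv", "transloc.csv",
                                         "coloc.csv")]
        if not track_files and any(k in cfg for k in _KNOWN_STAGES):
            raise FileNotFoundError(f"no track tables found in {outdir}")

    profiles = {}
    if "diffusion" in cfg:
        t0 = time.monotonic()
        d = cfg["diffusion"]
        win_rows, seg_rows, prof_rows = [], [], []
        for path in track_files:
            for tr in read_tracks(path, meta):
                try:
                    prof = rolling_profile(
                        tr, meta,
                        window=int(d.get("window", 20)),
                        smooth_span=int(d.get("smooth_span", 5)),
                        min_segment=int(d.get("min_segment", 10)),
                    )
                except UndefinedWindowError:
                    continue  # too short; skipped with reason implicit
                profiles[(path.name, tr.track_id, tr.channel)] = (tr, prof)
                for w in prof.windows:
                    win_rows.append((path.name, tr.track_id, tr.channel,
                                     w.start_frame, w.D_um2_s, w.state.value))
                for s in prof.segments:
                    seg_rows.append((path.name, tr.track_id, tr.channel,
                                     s.state.value, s.start_window,
                                     s.end_window, s.duration_s))
                row = {"file": path.name, "track_id": tr.track_id,
                       "channel": tr.channel,
                       "discarded_fraction": prof.discarded_fraction,
                       "mean_D_raw": prof.mean_D_raw}
                for st in DiffusionState:
                    row[f"fraction_{st.value}"] = prof.fraction_by_state[st]
                    row[f"mean_D_{st.value}"] = prof.mean_D_by_state.get(st, np.nan)
                prof_rows.append(row)
        pd.DataFrame(win_rows, columns=["file", "track_id", "channel",
                                        "start_frame", "D_um2_s", "state"]
                     ).to_csv(outdir / "windows.csv", index=False)
        pd.DataFrame(seg_rows, columns=["file", "track_id", "channel", "state",
                                        "start_window", "end_window",
                                        "duration_s"]
                     ).to_csv(outdir / "segments.csv", index=False)
        prof_cols = (["file", "track_id", "channel", "discarded_fraction",
                      "mean_D_raw"]
                     + [f"{k}_{st.value}" for st in DiffusionState
                        for k in ("fraction", "mean_D")])
        pd.DataFrame(prof_rows, columns=None if prof_rows else prof_cols
                     ).to_csv(outdir / "profiles.csv", index=False)
        record("diffusion", [outdir / f for f in
                             ("windows.csv", "segments.csv", "profiles.csv")], t0)

    if "dwell" in cfg:
        t0 = time.monotonic()
        dw = cfg["dwell"] or {}
        # events shorter than 2 frames are below temporal resolution
        min_dur = float(dw.get("min_frames", 2)) * meta.line_time_s
        seg_df = pd.read_csv(outdir / "segments.csv")
        results = {}
        for state, g in seg_df.groupby("state"):
            durations = g["duration_s"].to_numpy(float)
            durations = durations[durations >= min_dur]
            if durations.size < 2:
                continue
            fit = select_model(LifetimeSample(durations), seed=seed)
            results[state] = {
                "n_events": int(durations.size),
                "order": fit.order,
                "tau_s": list(fit.tau_s),
                "half_life_s": list(fit.half_life_s),
                "weight_fast": fit.weight_fast,
                "aic": fit.aic,
            }
        (outdir / "dwell.json").write_text(json.dumps(results, indent=1,
                                                      sort_keys=True))
        record("dwell", [outdir / "dwell.json"], t0)

    if "coloc" in cfg:
        t0 = time.monotonic()
        c = cfg["coloc"]
        rows = []
        for path in track_files:
            tracks = read_tracks(path, meta)
            greens = [t for t in tracks if t.channel == "green"]
            reds = [t for t in tracks if t.channel == "red"]
            for a in greens:
                for b in reds:
                    pa = profiles.get((path.name, a.track_id, a.channel))
                    pb = profiles.get((path.name, b.track_id, b.channel))
                    Da = pa[1].mean_D_raw if pa else float(c.get("mean_D", 0.25))
                    Db = pb[1].mean_D_raw if pb else float(c.get("mean_D", 0.25))
                    thr = coloc_threshold(max(Da, 0), max(Db, 0), meta.line_time_s)
                    for ev in pair_coloc_events(a, b, thr):
                        rows.append((path.name, a.track_id, b.track_id,
                                     ev.kind.value, ev.start_frame,
                                     ev.end_frame, ev.duration_s))
        pd.DataFrame(rows, columns=["file", "track_a", "track_b", "kind",
                                    "start_frame", "end_frame", "duration_s"]
                     ).to_csv(outdir / "coloc.csv", index=False)
        record("coloc", [outdir / "coloc.csv"], t0)

    if "transloc" in cfg:
        t0 = time.monotonic()
        tl = cfg["transloc"]
        rows = []
        for path in track_files:
            for tr in read_tracks(path, meta):
                key = (path.name, tr.track_id, tr.channel)
                prof = profiles[key][1] if key in profiles else None
                segs = segment_translocations(
                    tr, meta,
                    min_dur_s=float(tl.get("min_dur_s", 5.0)),
                    min_span_bp=float(tl.get("min_span_bp", 300.0)),
                    min_r2=float(tl.get("min_r2", 0.5)),
                    profile=prof,
                )
                for s in segs:
                    rows.append((path.name, s.track_id, s.start_s, s.end_s,
                                 s.speed_bp_s, s.distance_bp, s.r2,
                                 s.passes_filters,
                                 ";".join(s.filter_reasons)))
        pd.DataFrame(rows, columns=["file", "track_id", "start_s", "end_s",
                                    "speed_bp_s", "distance_bp", "r2",
                                    "passes_filters", "filter_reasons"]
                     ).to_csv(outdir / "transloc.csv", index=False)
        record("transloc", [outdir / "transloc.csv"], t0)

    manifest.to_json(outdir / "run_manifest.json")
    return manifest


def report(manifest: RunManifest) -> tuple[str, pd.DataFrame]:
    """Summarise a completed run: one row of headline statistics per stage
    output, plus a human-readable text block.  Lists missing stages when the
    manifest is incomplete."""
    outdir = Path(manifest.outdir)
    lines = [f"kymodiff run {manifest.config_hash[:12]} (v{manifest.version})"]
    rows = {}
    missing = [s for s, info in manifest.stages.items()
               if any(not (outdir / f).exists() for f in info["outputs"])]
    if missing:
        lines.append("missing stage outputs: " + ", ".join(missing))

    if "diffusion" in manifest.stages and (outdir / "profiles.csv").exists():
        prof = pd.read_csv(outdir / "profiles.csv")
        if len(prof):
            for st in DiffusionState:
                col = f"mean_D_{st.value}"
                if col in prof:
                    rows[f"mean_D_{st.value}_um2_s"] = float(np.nanmean(prof[col]))
                rows[f"fraction_{st.value}"] = float(prof[f"fraction_{st.value}"].mean())
            lines.append(f"diffusion: {len(prof)} tracks profiled")
    if "dwell" in manifest.stages and (outdir / "dwell.json").exists():
        dw = json.loads((outdir / "dwell.json").read_text())
        for state, fit in dw.items():
            rows[f"dwell_{state}_tau_s"] = fit["tau_s"][-1]
            lines.append(
                f"dwell[{state}]: order {fit['order']}, tau = "
                + "/".join(f"{t:.3g}" for t in fit["tau_s"]) + " s"
            )
    if "coloc" in manifest.stages and (outdir / "coloc.csv").exists():
        cl = pd.read_csv(outdir / "coloc.csv")
        for kind in ("short", "long", "bypass"):
            rows[f"coloc_{kind}_count"] = int((cl["kind"] == kind).sum())
        lines.append(f"coloc: {len(cl)} events")
    if "transloc" in manifest.stages and (outdir / "transloc.csv").exists():
        tr = pd.read_csv(outdir / "transloc.csv")
        passing = tr[tr["passes_filters"] == True]  # noqa: E712
        rows["transloc_n_passing"] = int(len(passing))
        if len(passing):
            rows["transloc_mean_speed_bp_s"] = float(passing["speed_bp_s"].abs().mean())
            rows["transloc_median_duration_s"] = float(
                (passing["end_s"] - passing["start_s"]).median())
            lines.append(
                f"transloc: {len(passing)} passing segments, "
                f"mean |speed| {rows['transloc_mean_speed_bp_s']:.1f} bp/s")
        else:
            lines.append("transloc: no passing segments")

    table = pd.DataFrame([rows]) if rows else pd.DataFrame()
    return "\n".join(lines), table
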