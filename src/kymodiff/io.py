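"""Track tables, acquisition metadata, and synthetic kymograph fixtures.

All downstream stages consume :class:`Track` objects produced here; nothing
else re-parses files.  Positions are 1D coordinates along the tethered DNA in
micrometres, measured from the trap-1 bead edge; frames are 0-based kymograph
line indices.  Dark frames (illumination off) are kept as ``visible=False``
rows rather than dropped, so downstream gap-filling is explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

from .calibration import WlcParams, extension_per_bp

__all__ = [
    "AcquisitionMeta",
    "Track",
    "read_tracks",
    "write_tracks",
    "render_kymograph",
    "fixture_track",
]

CHANNELS = ("green", "red")

#: default stretched length of lambda DNA (48,502 bp) at 5 pN, in µm
LAMBDA_BP = 48_502


class TrackFormatError(ValueError):
    """A track table is missing a required column or malformed."""


class TrackValidationError(ValueError):
    """A track violates an invariant (e.g. non-monotonic time)."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition geometry and timing shared by every stage.

    line_time_s : seconds per kymograph line (42.4 ms on the instrument)
    pixel_size_um : µm per scan pixel
    tether_length_um : bead-to-bead DNA extension
    tension_pN : nominal tension during imaging
    rise_nm_per_bp : extension per bp at ``tension_pN``; derived from the
        worm-like chain when not given explicitly (~0.318 nm/bp at 5 pN)
    contour_bp : tether length in base pairs (lambda DNA)
    """

    line_time_s: float = 0.0424
    pixel_size_um: float = 0.1
    tether_length_um: float | None = None
    tension_pN: float = 5.0
    rise_nm_per_bp: float | None = None
    contour_bp: int = LAMBDA_BP
    wlc: WlcParams = field(default_factory=WlcParams)

    def __post_init__(self) -> None:
        if self.line_time_s <= 0:
            raise ValueError("line_time_s must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.tension_pN < 0:
            raise ValueError("tension_pN must be non-negative")
        if self.rise_nm_per_bp is None:
            rise = extension_per_bp(max(self.tension_pN, 0.5), self.wlc)
            object.__setattr__(self, "rise_nm_per_bp", rise)
        if self.tether_length_um is None:
            object.__setattr__(
                self, "tether_length_um", self.contour_bp * self.rise_nm_per_bp / 1000.0
            )
        if self.tether_length_um <= 0:
            raise ValueError("tether_length_um must be positive")

    @property
    def bp_per_um(self) -> float:
        return 1000.0 / self.rise_nm_per_bp


@dataclass
class Track:
    """One particle's 1D positional time series in one color channel."""

    track_id: str
    channel: str
    frames: np.ndarray
    positions_um: np.ndarray
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    visible: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.track_id = str(self.track_id)
        if self.channel not in CHANNELS:
            raise TrackValidationError(
                f"track {self.track_id}: channel must be one of {CHANNELS}"
            )
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.frames.shape != self.positions_um.shape:
            raise TrackValidationError(
                f"track {self.track_id}: frames and positions differ in length"
            )
        if self.visible is None:
            self.visible = np.ones(self.frames.size, dtype=bool)
        else:
            self.visible = np.asarray(self.visible, dtype=bool)
        if np.unique(self.frames).size != self.frames.size:
            raise TrackValidationError(f"track {self.track_id}: duplicate frames")
        if np.any(np.diff(self.frames) <= 0):
            raise TrackValidationError(
                f"track {self.track_id}: frames/times not strictly increasing"
            )

    def __len__(self) -> int:
        return int(self.frames.size)

    @property
    def times_s(self) -> np.ndarray:
        return self.frames * self.meta.line_time_s

    def slice(self, start_frame: int, end_frame: int) -> "Track":
        """Sub-track covering frames in [start_frame, end_frame]."""
        m = (self.frames >= start_frame) & (self.frames <= end_frame)
        return replace(
            self,
            frames=self.frames[m],
            positions_um=self.positions_um[m],
            visible=self.visible[m],
        )


_COLUMNS = ("track_id", "channel", "frame", "time_s", "position_um")


def read_tracks(
    path,
    meta: AcquisitionMeta | None = None,
    column_map: dict | None = None,
    position_unit: str = "um",
) -> list[Track]:
    """Read a delimited track table into a list of :class:`Track`.

    The header must declare (possibly via ``column_map``, which maps the
    canonical names to the file's names) the columns ``track_id``,
    ``channel``, ``frame``, ``time_s`` and ``position_um``.  One Track is
    produced per unique (track_id, channel); rows are sorted by frame.  An
    optional ``visible`` column marks illumination-off gaps.

    ``position_unit`` may be ``"um"`` or ``"pixel"`` (converted with
    ``meta.pixel_size_um``), since deposited tables do not always declare
    their unit.
    """
    if meta is None:
        meta = AcquisitionMeta()
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    for col in _COLUMNS:
        if col not in df.columns:
            raise TrackFormatError(f"missing required column: {col}")
    if position_unit == "pixel":
        df = df.assign(position_um=df["position_um"] * meta.pixel_size_um)
    elif position_unit != "um":
        raise ValueError("position_unit must be 'um' or 'pixel'")

    tracks: list[Track] = []
    for (tid, channel), g in df.groupby(["track_id", "channel"], sort=True):
        g = g.sort_values("frame")
        times = g["time_s"].to_numpy(float)
        if np.any(np.diff(times) <= 0):
            raise TrackValidationError(
                f"track {tid}/{channel}: time_s not strictly increasing"
            )
        expected = g["frame"].to_numpy(np.int64) * meta.line_time_s
        if not np.allclose(times, expected, atol=1e-6):
            warnings.warn(
                f"track {tid}/{channel}: time_s deviates from frame * line_time_s",
                stacklevel=2,
            )
        visible = (
            g["visible"].to_numpy(bool)
            if "visible" in g.columns
            else np.ones(len(g), dtype=bool)
        )
        tracks.append(
            Track(
                track_id=str(tid),
                channel=str(channel),
                frames=g["frame"].to_numpy(np.int64),
                positions_um=g["position_um"].to_numpy(float),
                meta=meta,
                visible=visible,
            )
        )
    return tracks


def write_tracks(tracks, path) -> None:
    """Write tracks as a comma-separated table re-readable by read_tracks.

    Column order is fixed; floats are written with full repr precision so a
    read/write round trip is the identity to well below 1e-9 µm.
    """
    rows = []
    for t in tracks:
        for f, time, x, v in zip(t.frames, t.times_s, t.positions_um, t.visible):
            rows.append((t.track_id, t.channel, int(f), repr(float(time)),
                         repr(float(x)), bool(v)))
    df = pd.DataFrame(rows, columns=list(_COLUMNS) + ["visible"])
    df.to_csv(path, index=False)


def render_kymograph(
    tracks,
    meta: AcquisitionMeta,
    psf_sigma_um: float = 0.15,
    photons_per_line: float = 200.0,
    seed: int = 0,
    background: float = 2.0,
    n_lines: int | None = None,
    noiseless: bool = False,
):
    """Render a two-channel synthetic kymograph TIFF stack from tracks.

    Each visible track point contributes a Gaussian intensity profile of SD
    ``psf_sigma_um`` centred at its position; Poisson photon noise is applied
    unless ``noiseless`` (the photons-to-infinity limit used by exact tests).
    Returns ``(image, info)`` where image has shape (2, lines, pixels) for
    (green, red) and info counts clipped out-of-field points.
    """
    if psf_sigma_um <= 0:
        raise ValueError("psf_sigma_um must be positive")
    rng = np.random.default_rng(seed)
    n_pix = int(np.ceil(meta.tether_length_um / meta.pixel_size_um)) + 1
    if n_lines is None:
        n_lines = 1 + max((int(t.frames.max()) for t in tracks), default=0)
    img = np.full((2, n_lines, n_pix), float(background))
    # pixel i is centred at i * pixel_size, so the brightest pixel for a
    # static emitter is round(position / pixel_size)
    centers = np.arange(n_pix) * meta.pixel_size_um
    n_clipped = 0
    for t in tracks:
        ch = CHANNELS.index(t.channel)
        for f, x, v in zip(t.frames, t.positions_um, t.visible):
            if not v or f >= n_lines:
                continue
            if not (0.0 <= x <= meta.tether_length_um):
                n_clipped += 1
                x = float(np.clip(x, 0.0, meta.tether_length_um))
            prof = np.exp(-0.5 * ((centers - x) / psf_sigma_um) ** 2)
            prof *= photons_per_line / prof.sum()
            img[ch, int(f)] += prof
    if n_clipped:
        warnings.warn(f"{n_clipped} track points clipped to the field of view",
                      stacklevel=2)
    if not noiseless:
        img = rng.poisson(img).astype(float)
    info = {"n_clipped": n_clipped, "n_lines": n_lines, "n_pixels": n_pix}
    return img.astype(np.float64), info


def save_kymograph_tiff(image, path) -> None:
    """Save a (2, lines, pixels) stack as a 2-page 16-bit TIFF."""
    arr = np.clip(np.asarray(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)


def load_kymograph_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.float64)


def fixture_track(
    image: np.ndarray,
    meta: AcquisitionMeta,
    channel: str = "green",
    min_snr: float = 3.0,
    gate_um: float = 0.5,
    max_gap: int = 8,
    min_length: int = 4,
) -> list[Track]:
    """Naive greedy centroid tracker for synthetic kymograph fixtures.

    Per line, pixels exceeding background + ``min_snr`` * noise are grouped
    into local maxima and centroid-refined over +/-3 pixels; detections are
    linked greedily to the nearest open track within ``gate_um``.  Gaps up to
    ``max_gap`` lines are bridged, mirroring the tracking gap window used on
    the real kymographs; tracks shorter than ``min_length`` detections are
    dropped as shot-noise flicker (pass 1 to keep everything, e.g. on
    noiseless single-line images).  This exists to close the loop on
    synthetic data only — it is not an instrument-grade tracker.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty single-channel (lines x pixels) image")
    n_lines, n_pix = img.shape
    bg = np.median(img)
    noise = 1.4826 * np.median(np.abs(img - bg)) + 1e-12
    thresh = bg + min_snr * noise

    open_tracks: list[dict] = []  # {'frames': [], 'pos': [], 'last_frame', 'last_pos'}
    done: list[dict] = []
    for line in range(n_lines):
        row = img[line]
        above = row > thresh
        detections = []
        i = 0
        while i < n_pix:
            if above[i]:
                j = i
                while j + 1 < n_pix and above[j + 1]:
                    j += 1
                peak = i + int(np.argmax(row[i : j + 1]))
                lo, hi = max(0, peak - 3), min(n_pix, peak + 4)
                wts = np.clip(row[lo:hi] - bg, 0, None)
                if wts.sum() > 0:
                    c = (np.arange(lo, hi) * wts).sum() / wts.sum()
                    detections.append(c * meta.pixel_size_um)
                i = j + 1
            else:
                i += 1
        # greedy nearest-neighbour assignment
        unmatched = list(range(len(detections)))
        pairs = []
        for ti, tr in enumerate(open_tracks):
            for di in unmatched:
                dist = abs(detections[di] - tr["last_pos"])
                if dist <= gate_um:
                    pairs.append((dist, ti, di))
        pairs.sort()
        used_t, used_d = set(), set()
        for dist, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            tr = open_tracks[ti]
            tr["frames"].append(line)
            tr["pos"].append(detections[di])
            tr["last_frame"] = line
            tr["last_pos"] = detections[di]
            used_t.add(ti)
            used_d.add(di)
        for di, x in enumerate(detections):
            if di not in used_d:
                open_tracks.append(
                    {"frames": [line], "pos": [x], "last_frame": line, "last_pos": x}
                )
        still_open = []
        for tr in open_tracks:
            if line - tr["last_frame"] > max_gap:
                done.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
    done.extend(open_tracks)

    done = [tr for tr in done if len(tr["frames"]) >= min_length]
    tracks = []
    for k, tr in enumerate(sorted(done, key=lambda d: (d["frames"][0], d["pos"][0]))):
        tracks.append(
            Track(
                track_id=str(k),
                channel=channel,
                frames=np.asarray(tr["frames"], dtype=np.int64),
                positions_um=np.asarray(tr["pos"], dtype=float),
                meta=meta,
            )
        )
    return tracks
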