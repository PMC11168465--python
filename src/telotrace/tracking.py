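"""Particle linking, photobleach correction, colocalization events and
cis/trans localization classification.

Linking is frame-to-frame assignment minimizing total displacement among
candidate pairs within ``max_disp`` (optimal per frame step), with gap
closing up to ``max_gap`` missed frames. Frame-wise telomere colocalization
uses a physical radius; maximal runs of colocalized frames become dwell
events, a run of k frames at interval Δ having duration k·Δ, stable when
≥ 10 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .imaging import ImageStack

__all__ = [
    "Detection",
    "Track",
    "ColocEvent",
    "LOCALIZATION_CLASSES",
    "estimate_bleach_rate",
    "correct_photobleaching",
    "link_detections",
    "assign_coloc_events",
    "classify_localization",
    "summarize_cis_trans",
    "percent_telomeres_colocalized",
    "detections_from_csv",
    "tracks_from_csv",
]

STABLE_MIN_DURATION_S = 10.0
PROXIMITY_UM = 0.6

LOCALIZATION_CLASSES = (
    "origin_telomere",
    "origin_proximal",
    "other_telomere",
    "nontelomeric",
)


@dataclass
class Detection:
    frame: int
    t: float  # s
    position: np.ndarray  # μm (z, y, x)
    intensity: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class Track:
    track_id: int
    detections: list[Detection]

    def __post_init__(self) -> None:
        frames = self.frames
        if np.any(np.diff(frames) <= 0):
            raise ValueError("detection frames must be strictly increasing")

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections])

    @property
    def positions(self) -> np.ndarray:
        return np.array([d.position for d in self.detections])

    @property
    def n_gaps(self) -> int:
        return int(np.sum(np.diff(self.frames) - 1))

    def position_at(self, frame: int) -> np.ndarray | None:
        for d in self.detections:
            if d.frame == frame:
                return d.position
        return None


@dataclass
class ColocEvent:
    """An interval during which a track is colocalized with one telomere."""

    track_id: int
    telomere_id: int
    start_frame: int
    end_frame: int
    frame_interval: float

    @property
    def t_start(self) -> float:
        return self.start_frame * self.frame_interval

    @property
    def t_end(self) -> float:
        return self.end_frame * self.frame_interval

    @property
    def duration(self) -> float:
        """k consecutive frames at interval Δ last k·Δ seconds."""
        return (self.end_frame - self.start_frame + 1) * self.frame_interval

    @property
    def stable(self) -> bool:
        return self.duration >= STABLE_MIN_DURATION_S


# ---------------------------------------------------------------------------
# CSV interchange (track_id, frame, t_s, z_um, y_um, x_um[, intensity])
# ---------------------------------------------------------------------------

def detections_from_csv(path, frame_interval: float = 5.0) -> dict[int, list[Detection]]:
    """Read per-frame detections from a CSV table (track_id optional)."""
    import pandas as pd

    df = pd.read_csv(path)
    out: dict[int, list[Detection]] = {}
    for r in df.itertuples():
        t = float(getattr(r, "t_s", r.frame * frame_interval))
        out.setdefault(int(r.frame), []).append(
            Detection(int(r.frame), t,
                      np.array([r.z_um, r.y_um, r.x_um]),
                      float(getattr(r, "intensity", 0.0)))
        )
    return out


def tracks_from_csv(path, frame_interval: float = 5.0) -> list[Track]:
    """Read pre-linked tracks from a CSV table with a track_id column."""
    import pandas as pd

    df = pd.read_csv(path).sort_values(["track_id", "frame"])
    tracks = []
    for tid, grp in df.groupby("track_id"):
        dets = [
            Detection(int(r.frame),
                      float(getattr(r, "t_s", r.frame * frame_interval)),
                      np.array([r.z_um, r.y_um, r.x_um]),
                      float(getattr(r, "intensity", 0.0)))
            for r in grp.itertuples()
        ]
        tracks.append(Track(int(tid), dets))
    return tracks


# ---------------------------------------------------------------------------
# photobleaching
# ---------------------------------------------------------------------------

def estimate_bleach_rate(movie: ImageStack, channel: int | None = None) -> float:
    """Per-frame fractional intensity loss from a log-linear fit of frame means."""
    if not movie.is_timelapse:
        raise ValueError("expected a time-lapse stack")
    data = movie.voxels if channel is None else movie.voxels[:, channel]
    means = data.reshape(data.shape[0], -1).mean(axis=1)
    if len(means) < 2 or np.any(means <= 0):
        return 0.0
    t = np.arange(len(means))
    slope = np.polyfit(t, np.log(means), 1)[0]
    return float(1.0 - np.exp(slope))


def correct_photobleaching(movie: ImageStack) -> ImageStack:
    """Rescale frames so the fitted mono-exponential intensity trend is flat.

    Frame 0 keeps its original scale; a single-frame movie is returned
    unchanged.
    """
    if not movie.is_timelapse:
        raise ValueError("expected a time-lapse stack")
    if movie.n_frames < 2:
        return movie
    b = estimate_bleach_rate(movie)
    t = np.arange(movie.n_frames, dtype=float)
    scale = (1.0 - b) ** (-t)
    corrected = movie.voxels * scale[:, None, None, None, None]
    return ImageStack(corrected, movie.voxel_size, movie.frame_interval,
                      movie.channel_names)


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def link_detections(
    detections_by_frame: dict[int, list[Detection]],
    max_disp: float,
    max_gap: int = 1,
) -> list[Track]:
    """Link detections into tracks by minimal-total-displacement assignment.

    For each frame, open track ends (last seen ≤ ``max_gap`` frames ago)
    are matched to the new detections by an optimal assignment restricted
    to pairs within ``max_disp × (gap + 1)``; unmatched detections start
    new tracks.
    """
    if max_disp < 0:
        raise ValueError("max_disp must be non-negative")
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    frames = sorted(detections_by_frame)
    open_tracks: list[list[Detection]] = []
    closed: list[list[Detection]] = []

    for f in frames:
        dets = detections_by_frame[f]
        # retire tracks whose gap budget is spent
        still_open = []
        for tr in open_tracks:
            if f - tr[-1].frame - 1 > max_gap:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        if not dets:
            continue
        if open_tracks:
            cost = np.full((len(open_tracks), len(dets)), np.inf)
            for i, tr in enumerate(open_tracks):
                gap = f - tr[-1].frame - 1
                allowance = max_disp * (gap + 1)
                for j, d in enumerate(dets):
                    dist = float(np.linalg.norm(tr[-1].position - d.position))
                    if dist <= allowance:
                        cost[i, j] = dist
            # pad infeasible entries with a large finite cost, then discard
            big = 1e9
            finite = np.where(np.isfinite(cost), cost, big)
            rows, cols = linear_sum_assignment(finite)
            matched_dets = set()
            for i, j in zip(rows, cols):
                if np.isfinite(cost[i, j]):
                    open_tracks[i].append(dets[j])
                    matched_dets.add(j)
            for j, d in enumerate(dets):
                if j not in matched_dets:
                    open_tracks.append([d])
        else:
            open_tracks.extend([d] for d in dets)

    closed.extend(open_tracks)
    closed.sort(key=lambda tr: (tr[0].frame, tuple(tr[0].position)))
    return [Track(i, tr) for i, tr in enumerate(closed)]


# ---------------------------------------------------------------------------
# colocalization events
# ---------------------------------------------------------------------------

def assign_coloc_events(
    tracks: list[Track],
    telomere_tracks: list[Track],
    coloc_radius: float = 0.3,
    tolerance_gap: int = 1,
    frame_interval: float = 5.0,
) -> list[ColocEvent]:
    """Frame-wise nearest-telomere colocalization grouped into dwell events.

    A particle frame is colocalized with the nearest telomere within
    ``coloc_radius`` μm; maximal runs of frames colocalized with the same
    telomere, bridging up to ``tolerance_gap`` missing/excursion frames,
    become :class:`ColocEvent`s.
    """
    if not telomere_tracks:
        return []
    events: list[ColocEvent] = []
    tel_by_frame: dict[int, tuple[np.ndarray, list[int]]] = {}
    all_frames = sorted({d.frame for tr in telomere_tracks for d in tr.detections})
    for f in all_frames:
        pos, ids = [], []
        for tr in telomere_tracks:
            p = tr.position_at(f)
            if p is not None:
                pos.append(p)
                ids.append(tr.track_id)
        if pos:
            tel_by_frame[f] = (np.array(pos), ids)

    for tr in tracks:
        hits: list[tuple[int, int]] = []  # (frame, telomere_id)
        for d in tr.detections:
            if d.frame not in tel_by_frame:
                continue
            pos, ids = tel_by_frame[d.frame]
            dists = np.linalg.norm(pos - d.position, axis=1)
            j = int(np.argmin(dists))
            if dists[j] <= coloc_radius:
                hits.append((d.frame, ids[j]))
        if not hits:
            continue
        # group runs per telomere, bridging short interruptions
        start_f, last_f, cur_tel = hits[0][0], hits[0][0], hits[0][1]
        for f, tel in hits[1:]:
            if tel == cur_tel and f - last_f - 1 <= tolerance_gap:
                last_f = f
            else:
                events.append(ColocEvent(tr.track_id, cur_tel, start_f, last_f,
                                         frame_interval))
                start_f, last_f, cur_tel = f, f, tel
        events.append(ColocEvent(tr.track_id, cur_tel, start_f, last_f,
                                 frame_interval))
    return events


# ---------------------------------------------------------------------------
# cis/trans classification
# ---------------------------------------------------------------------------

def classify_localization(
    particle_position: np.ndarray,
    origin_position: np.ndarray | None,
    telomere_positions: np.ndarray,
    proximity_um: float = PROXIMITY_UM,
    overlap_um: float = 0.3,
    same_z: bool = True,
    z_step_um: float | None = 0.3,
) -> str:
    """Classify one particle observation relative to its telomere of origin.

    Precedence: overlapping the origin signal → ``origin_telomere``; within
    ``proximity_um`` (0.6 μm) of the origin (and in the same z slice when
    ``same_z``) → ``origin_proximal``; overlapping any other telomere →
    ``other_telomere``; otherwise ``nontelomeric``. With no origin the
    first two classes are unavailable.
    """
    p = np.asarray(particle_position, dtype=float)
    tel = np.asarray(telomere_positions, dtype=float).reshape(-1, 3)

    def _dist(q: np.ndarray) -> float:
        if same_z and z_step_um:
            if round(p[0] / z_step_um) != round(q[0] / z_step_um):
                return np.inf
            return float(np.linalg.norm(p[1:] - q[1:]))
        return float(np.linalg.norm(p - q))

    if origin_position is not None:
        d0 = _dist(np.asarray(origin_position, dtype=float))
        if d0 <= overlap_um:
            return "origin_telomere"
        if d0 <= proximity_um:
            return "origin_proximal"
    origin = None if origin_position is None else np.asarray(origin_position, float)
    for q in tel:
        if origin is not None and np.allclose(q, origin):
            continue
        if _dist(q) <= overlap_um:
            return "other_telomere"
    return "nontelomeric"


def summarize_cis_trans(classifications) -> dict[str, float]:
    """Percentage of particles per localization class.

    ``cis_percent`` pools ``origin_telomere`` and ``origin_proximal``.
    """
    labels = list(classifications)
    if not labels:
        raise ValueError("no classified particles")
    bad = set(labels) - set(LOCALIZATION_CLASSES)
    if bad:
        raise ValueError(f"unknown localization classes: {bad}")
    n = len(labels)
    counts = {c: labels.count(c) for c in LOCALIZATION_CLASSES}
    out = {f"{c}_percent": 100.0 * counts[c] / n for c in LOCALIZATION_CLASSES}
    out["cis_percent"] = 100.0 * (counts["origin_telomere"] + counts["origin_proximal"]) / n
    out["n"] = n
    return out


def percent_telomeres_colocalized(
    events: list[ColocEvent], telomere_ids
) -> float:
    """100 × (telomeres with ≥1 stable event) / (all telomeres)."""
    telomere_ids = list(telomere_ids)
    if not telomere_ids:
        raise ValueError("no telomeres supplied")
    with_stable = {e.telomere_id for e in events if e.stable}
    return 100.0 * sum(t in with_stable for t in telomere_ids) / len(telomere_ids)
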