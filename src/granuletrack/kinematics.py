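"""Gliding-window kinematics, persistence, fluorescence profiles and
event/growth maps.

The local track speed at time point t is the path length travelled
over the 8-frame window t-3 .. t+4 divided by the window duration in
minutes; the local advance speed is the net (straight-line)
displacement across the same window divided by the same duration.
Their ratio quantifies directionality.  Windows are only evaluated
where all 8 spots exist, so tracks shorter than 8 spots yield an empty
profile and no values are produced at track edges.  Gap-closed steps
contribute their full Euclidean length over their longer duration (no
interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import TrackGraph

WINDOW = 8           # spots per gliding window (t-3 .. t+4)
_BACK, _FWD = 3, 4   # spots before / after the centre


@dataclass
class KinematicsProfile:
    """Per-time-point kinematics of one track (µm/min)."""

    track_id: int
    frames: np.ndarray              # centre frame of each window
    local_track_speed: np.ndarray
    local_advance_speed: np.ndarray
    speed_ratio: np.ndarray
    fluorescence: np.ndarray | None
    dF: np.ndarray | None

    def __len__(self) -> int:
        return int(self.frames.size)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "track_id": np.full(len(self), self.track_id),
            "frame": self.frames,
            "local_track_speed_um_per_min": self.local_track_speed,
            "local_advance_speed_um_per_min": self.local_advance_speed,
            "speed_ratio": self.speed_ratio,
        }
        if self.fluorescence is not None:
            data["fluo"] = self.fluorescence
            data["dF"] = self.dF
        return pd.DataFrame(data)


@dataclass
class TrackSummary:
    """Whole-track statistics."""

    track_id: int
    overall_track_speed: float   # path length / duration, µm/min
    mean_local_speed: float      # mean of the gliding local track speed
    persistence: float
    lifetime_min: float
    max_fluorescence: float
    t_peak_min: float            # time of the fluorescence maximum


def _steps(track) -> np.ndarray:
    return np.linalg.norm(np.diff(track.positions_um, axis=0), axis=1)


def local_speeds(track, frame_interval_s: float = 20.0) -> KinematicsProfile:
    """Gliding 8-spot local track speed and advance speed.

    For each interior spot with three predecessors and four successors
    the track speed is the summed step lengths across the window and
    the advance speed the net displacement, both divided by the window
    duration (the actual frame span, in minutes; 7 steps of 20 s =
    140 s for a gap-free track).
    """
    pos = track.positions_um
    frames = track.frames
    fluo = getattr(track, "fluorescence", None)
    n = len(frames)
    if n < WINDOW:
        empty = np.empty(0)
        return KinematicsProfile(getattr(track, "track_id", -1),
                                 empty.astype(int), empty, empty, empty,
                                 None if fluo is None else empty,
                                 None if fluo is None else empty)
    steps = _steps(track)
    centres = np.arange(_BACK, n - _FWD)
    track_speed = np.empty(centres.size)
    advance = np.empty(centres.size)
    for k, i in enumerate(centres):
        lo, hi = i - _BACK, i + _FWD
        dur_min = (frames[hi] - frames[lo]) * frame_interval_s / 60.0
        track_speed[k] = steps[lo:hi].sum() / dur_min
        advance[k] = np.linalg.norm(pos[hi] - pos[lo]) / dur_min
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(track_speed > 0, advance / track_speed, np.nan)
    if fluo is not None:
        f_centre = fluo[centres]
        dF = np.append(np.diff(fluo), np.nan)[centres]
    else:
        f_centre = dF = None
    return KinematicsProfile(getattr(track, "track_id", -1), frames[centres],
                             track_speed, advance, ratio, f_centre, dF)


def persistence(track) -> float:
    """Net start-to-end displacement over total path length, in [0, 1].

    Returns NaN for a zero-length path (undefined).
    """
    pos = track.positions_um
    if len(pos) < 2:
        raise ValueError("persistence needs at least 2 spots")
    path = _steps(track).sum()
    if path == 0:
        return float("nan")
    return float(np.linalg.norm(pos[-1] - pos[0]) / path)


def summarize_track(track, frame_interval_s: float = 20.0) -> TrackSummary:
    frames = track.frames
    lifetime_min = (frames[-1] - frames[0]) * frame_interval_s / 60.0
    path = _steps(track).sum()
    overall = path / lifetime_min if lifetime_min > 0 else float("nan")
    prof = local_speeds(track, frame_interval_s)
    mean_local = float(np.mean(prof.local_track_speed)) if len(prof) else float("nan")
    fluo = getattr(track, "fluorescence", None)
    if fluo is not None and len(fluo):
        imax = int(np.argmax(fluo))
        fmax = float(fluo[imax])
        t_peak = (frames[imax] - frames[0]) * frame_interval_s / 60.0
    else:
        fmax = t_peak = float("nan")
    return TrackSummary(getattr(track, "track_id", -1), overall, mean_local,
                        persistence(track), lifetime_min, fmax, t_peak)


def fluorescence_profile(tracks, frame_interval_s: float = 20.0) -> pd.DataFrame:
    """Peak-aligned, self-normalized fluorescence growth/shrink profile.

    Each track's fluorescence is divided by its own maximum and
    time-shifted so the maximum sits at 0 min; the mean and SD across
    tracks are returned per relative time point (columns ``t_min``,
    ``mean``, ``sd``, ``n``).
    """
    dt_min = frame_interval_s / 60.0
    values: dict[int, list[float]] = {}
    for t in tracks:
        fluo = np.asarray(t.fluorescence, dtype=float)
        if fluo.size == 0 or np.max(fluo) <= 0:
            continue
        rel = t.frames - t.frames[int(np.argmax(fluo))]
        norm = fluo / np.max(fluo)
        for r, v in zip(rel, norm):
            values.setdefault(int(r), []).append(float(v))
    rows = []
    for r in sorted(values):
        v = np.array(values[r])
        rows.append((r * dt_min, v.mean(), v.std(), v.size))
    return pd.DataFrame(rows, columns=["t_min", "mean", "sd", "n"])


def event_and_growth_maps(graph: TrackGraph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Positions of appearance, merging and disappearance events, plus
    per-step fluorescence growth sign.

    Returns ``(events, growth)``.  ``events`` has columns (kind, frame,
    x_um, y_um, track_id) with kind in {appear, merge, disappear}: one
    appear per track start, one disappear per track end that does not
    merge, one merge per merge edge (at the merge-target spot).
    ``growth`` has one row per consecutive step of every track with the
    fluorescence change dF and its sign.
    """
    ev_rows = []
    growth_rows = []
    merge_targets = {v: u for u, v in graph.merge_edges()}
    spot_to_track = graph.track_of_spot()
    for t in graph.tracks:
        first, last = t.spots[0], t.spots[-1]
        ev_rows.append(("appear", first.frame, first.x, first.y, t.track_id))
        last_id = t.spot_ids[-1]
        if not any(graph.graph.edges[e]["kind"] == "merge"
                   for e in graph.graph.out_edges(last_id)):
            ev_rows.append(("disappear", last.frame, last.x, last.y, t.track_id))
        fluo = t.fluorescence
        for i in range(len(t.spots) - 1):
            dF = fluo[i + 1] - fluo[i]
            s = t.spots[i]
            growth_rows.append((s.frame, s.x, s.y, dF,
                                int(np.sign(dF)), t.track_id))
    for v, u in merge_targets.items():
        s = graph.spot(v)
        ev_rows.append(("merge", s.frame, s.x, s.y, spot_to_track[u]))
    events = pd.DataFrame(ev_rows,
                          columns=["kind", "frame", "x_um", "y_um", "track_id"])
    growth = pd.DataFrame(growth_rows,
                          columns=["frame", "x_um", "y_um", "dF", "sign",
                                   "track_id"])
    return events.sort_values(["frame", "kind"]).reset_index(drop=True), growth


def merge_count_vs_fluorescence(graph: TrackGraph) -> tuple[float, int]:
    """Per-movie pair (total spot fluorescence, number of merge events)."""
    total = float(sum(graph.spot(sid).fluorescence
                      for sid in graph.graph.nodes))
    return total, len(graph.merge_edges())
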