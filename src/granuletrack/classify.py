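"""Track taxonomy: solo tracks versus merging groups (main + sub tracks).

A track group is a weakly-connected component of the track graph.  A
single-member group is a solo track (its granule never fused).  In a
multi-member group the member with the longest duration is the main
track and the others are sub tracks; each fusion contributes exactly
one merge edge, so a group of k members holds k - 1 merge events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracking import Track, TrackGraph


@dataclass
class TrackGroup:
    """One connected family of tracks."""

    group_id: int
    track_ids: list[int]
    classes: dict[int, str] = field(default_factory=dict)
    n_merge_events: int = 0
    is_complete: dict[int, bool] = field(default_factory=dict)

    @property
    def is_solo(self) -> bool:
        return len(self.track_ids) == 1

    @property
    def main_track_id(self) -> int | None:
        for tid, cls in self.classes.items():
            if cls == "main":
                return tid
        return None


def classify(graph: TrackGraph, frame_interval_s: float = 20.0,
             movie_n_frames: int | None = None) -> list[TrackGroup]:
    """Partition the graph into solo tracks and merging groups.

    The main track of a merging group is the member with the longest
    duration (start to end, in seconds); duration ties are broken by
    larger total fluorescence, then by lower track id.  Track objects
    are annotated in place with ``cls`` (and ``is_complete`` when the
    movie length is given).
    """
    tracks = graph.tracks
    by_group: dict[int, list[Track]] = {}
    for t in tracks:
        by_group.setdefault(t.group_id, []).append(t)

    merge_by_group: dict[int, int] = {}
    spot_to_track = graph.track_of_spot()
    track_group = {t.track_id: t.group_id for t in tracks}
    for u, v in graph.merge_edges():
        gid = track_group[spot_to_track[u]]
        merge_by_group[gid] = merge_by_group.get(gid, 0) + 1

    groups: list[TrackGroup] = []
    for gid in sorted(by_group):
        members = by_group[gid]
        group = TrackGroup(group_id=gid,
                           track_ids=[t.track_id for t in members],
                           n_merge_events=merge_by_group.get(gid, 0))
        if len(members) == 1:
            members[0].cls = "solo"
        else:
            main = max(members, key=lambda t: (
                t.duration_s(frame_interval_s),
                float(np.sum(t.fluorescence)),
                -t.track_id))
            for t in members:
                t.cls = "main" if t is main else "sub"
        for t in members:
            group.classes[t.track_id] = t.cls
            if movie_n_frames is not None:
                t.is_complete = complete_track_flag(t, movie_n_frames)
                group.is_complete[t.track_id] = t.is_complete
        groups.append(group)
    return groups


def complete_track_flag(track: Track, movie_n_frames: int) -> bool:
    """True iff both the birth and the death of the granule fall inside
    the recording: the track neither starts on the first frame nor ends
    on the last."""
    return track.start_frame >= 1 and track.end_frame <= movie_n_frames - 2
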