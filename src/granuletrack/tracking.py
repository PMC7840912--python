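"""Linear-assignment tracking with gap closing and merging.

Spots are linked frame-to-frame by an exact Hungarian assignment with
squared-distance costs gated at a maximum link distance; the resulting
segments are then joined in a single global assignment that considers
both gap closing (a segment end to a later segment start, within a
distance gate and a maximum frame gap) and merging (a segment end to a
mid-track spot of another segment in the next frame).  Splitting is
never introduced.  The result is a directed acyclic track graph whose
linear chains are tracks and whose weakly-connected components are
track groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .detect import Spot, quality_auto_threshold

_BIG = 1e12


@dataclass
class LinkingParams:
    """Tracker configuration.

    Defaults follow the granule-tracking setup: 1 µm frame-to-frame
    linking, gap closing at 1 µm over at most 2 frames, merging at
    1 µm, splitting disabled, and a minimum track length of 10 spots
    (granules followed for 10 or more consecutive frames).
    """

    max_link_dist: float = 1.0
    gap_max_dist: float = 1.0
    max_frame_gap: int = 2
    merge_max_dist: float = 1.0
    allow_split: bool = False
    min_track_len: int = 10

    def __post_init__(self) -> None:
        for name in ("max_link_dist", "gap_max_dist", "merge_max_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_frame_gap < 0:
            raise ValueError("max_frame_gap must be >= 0")
        if self.allow_split:
            raise ValueError("track splitting is not supported")


@dataclass
class Track:
    """An ordered run of spots forming one linear track."""

    track_id: int
    spots: list[Spot]
    spot_ids: list[int] = field(default_factory=list)
    group_id: int = -1
    cls: str | None = None          # solo / main / sub
    is_complete: bool | None = None

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.spots], dtype=int)

    @property
    def positions_um(self) -> np.ndarray:
        return np.array([[s.x, s.y] for s in self.spots], dtype=float)

    @property
    def fluorescence(self) -> np.ndarray:
        return np.array([s.fluorescence for s in self.spots], dtype=float)

    @property
    def quality(self) -> np.ndarray:
        return np.array([s.quality for s in self.spots], dtype=float)

    @property
    def start_frame(self) -> int:
        return self.spots[0].frame

    @property
    def end_frame(self) -> int:
        return self.spots[-1].frame

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.quality))

    def duration_s(self, frame_interval_s: float) -> float:
        return (self.end_frame - self.start_frame) * frame_interval_s


class TrackGraph:
    """Spots linked over time, including merge events.

    Nodes are spot ids, edges carry ``kind`` in {link, gap, merge} and
    always point forward in time.  Linear chains of link/gap edges are
    tracks; weakly-connected components are track groups.
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()
        self._tracks: list[Track] | None = None

    # -- construction -----------------------------------------------------
    def add_spot(self, spot_id: int, spot: Spot) -> None:
        self.graph.add_node(spot_id, spot=spot)
        self._tracks = None

    def add_edge(self, src: int, dst: int, kind: str) -> None:
        if kind not in ("link", "gap", "merge"):
            raise ValueError(f"unknown edge kind {kind!r}")
        su, sv = self.spot(src), self.spot(dst)
        if sv.frame <= su.frame:
            raise ValueError("edges must go forward in time")
        self.graph.add_edge(src, dst, kind=kind)
        self._tracks = None

    def spot(self, spot_id: int) -> Spot:
        return self.graph.nodes[spot_id]["spot"]

    # -- queries ----------------------------------------------------------
    @property
    def n_spots(self) -> int:
        return self.graph.number_of_nodes()

    def merge_edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u, v, k in self.graph.edges(data="kind")
                if k == "merge"]

    @property
    def tracks(self) -> list[Track]:
        if self._tracks is None:
            self._tracks = self._build_tracks()
        return self._tracks

    def track_of_spot(self) -> dict[int, int]:
        """Map spot id -> track id."""
        return {sid: t.track_id for t in self.tracks for sid in t.spot_ids}

    def _chain_edges(self):
        return [(u, v) for u, v, k in self.graph.edges(data="kind")
                if k in ("link", "gap")]

    def _build_tracks(self) -> list[Track]:
        succ: dict[int, int] = {}
        has_pred: set[int] = set()
        for u, v in self._chain_edges():
            succ[u] = v
            has_pred.add(v)
        chains = []
        for sid in self.graph.nodes:
            if sid in has_pred:
                continue
            chain = [sid]
            while chain[-1] in succ:
                chain.append(succ[chain[-1]])
            chains.append(chain)
        chains.sort(key=lambda ch: (self.spot(ch[0]).frame, ch[0]))
        tracks = [Track(track_id=i, spots=[self.spot(s) for s in ch],
                        spot_ids=list(ch))
                  for i, ch in enumerate(chains)]
        # group ids from weakly-connected components, numbered by the
        # lowest member track id for determinism
        comp_of: dict[int, int] = {}
        for ci, comp in enumerate(nx.weakly_connected_components(self.graph)):
            for sid in comp:
                comp_of[sid] = ci
        comp_to_tracks: dict[int, list[Track]] = {}
        for t in tracks:
            comp_to_tracks.setdefault(comp_of[t.spot_ids[0]], []).append(t)
        ordered = sorted(comp_to_tracks.values(),
                         key=lambda ts: min(t.track_id for t in ts))
        for gid, ts in enumerate(ordered):
            for t in ts:
                t.group_id = gid
        return tracks

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        """Raise AssertionError if any structural invariant is broken."""
        for sid in self.graph.nodes:
            out_edges = list(self.graph.out_edges(sid))
            assert len(out_edges) <= 1, f"spot {sid} has a split"
            in_kinds = [self.graph.edges[e]["kind"]
                        for e in self.graph.in_edges(sid)]
            n_merge = sum(k == "merge" for k in in_kinds)
            n_chain = sum(k != "merge" for k in in_kinds)
            assert n_chain <= 1, f"spot {sid} has two chain predecessors"
            if n_merge:
                assert n_merge == 1 and len(in_kinds) == 2, (
                    f"merge target {sid} must have exactly 2 incoming edges")
        for u, v in self.graph.edges:
            assert self.spot(v).frame > self.spot(u).frame, \
                "edge goes backward in time"
        assert nx.is_directed_acyclic_graph(self.graph)


# ---------------------------------------------------------------------------
# assignment machinery
# ---------------------------------------------------------------------------

def gated_assignment(cost: np.ndarray, gate_cost: float) -> list[tuple[int, int]]:
    """Min-cost assignment allowing non-assignment.

    Entries above ``gate_cost`` are disallowed.  Leaving a row or a
    column unassigned costs 1.05x the gate, so any admissible link is
    preferred over dropping both of its endpoints, and the solution is
    the exact minimum of (sum of link costs + penalty x dropped).
    Cost ties are broken toward lower indices by an infinitesimal
    perturbation.
    """
    cost = np.asarray(cost, dtype=float)
    n, m = cost.shape
    if n == 0 or m == 0:
        return []
    allowed = cost <= gate_cost
    if not allowed.any():
        return []
    # deterministic tie-break: prefer lower (row, col) indices
    tiny = 1e-9 * max(gate_cost, 1.0)
    perturb = tiny * (np.arange(n)[:, None] * (m + 1) + np.arange(m)[None, :]) \
        / ((n + 1) * (m + 1))
    b = 1.05 * gate_cost if gate_cost > 0 else 1.0
    mat = np.full((n + m, n + m), _BIG)
    mat[:n, :m] = np.where(allowed, cost + perturb, _BIG)
    mat[np.arange(n), m + np.arange(n)] = b
    mat[n + np.arange(m), np.arange(m)] = b
    mat[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(mat)
    return [(int(i), int(j)) for i, j in zip(rows, cols)
            if i < n and j < m and allowed[i, j]]


def _positions(spots: list[Spot]) -> np.ndarray:
    return np.array([[s.x, s.y] for s in spots], dtype=float)


def link_frames(spots_by_frame, params: LinkingParams) -> list[list[Spot]]:
    """Frame-to-frame linking into maximal consecutive-frame segments.

    ``spots_by_frame`` is a list of per-frame spot lists or a mapping
    frame -> spots.  Per consecutive frame pair a min-cost assignment
    with squared-distance cost, gated at ``max_link_dist``, extends
    open segments; unmatched spots open new segments.
    """
    if isinstance(spots_by_frame, dict):
        frame_map = {int(f): list(s) for f, s in spots_by_frame.items()}
    else:
        frame_map = {f: list(s) for f, s in enumerate(spots_by_frame)}
    frames = sorted(frame_map)
    segments: list[list[Spot]] = []
    open_segs: list[list[Spot]] = []
    gate2 = params.max_link_dist**2
    prev_frame = None
    for f in frames:
        curr = frame_map[f]
        if prev_frame is not None and f == prev_frame + 1 and open_segs and curr:
            prev_pts = _positions([seg[-1] for seg in open_segs])
            curr_pts = _positions(curr)
            diff = prev_pts[:, None, :] - curr_pts[None, :, :]
            cost = np.einsum("ijk,ijk->ij", diff, diff)
            pairs = gated_assignment(cost, gate2)
            matched_next = set()
            next_open = []
            assigned = dict(pairs)
            for i, seg in enumerate(open_segs):
                if i in assigned:
                    seg.append(curr[assigned[i]])
                    matched_next.add(assigned[i])
                    next_open.append(seg)
            for j, s in enumerate(curr):
                if j not in matched_next:
                    seg = [s]
                    segments.append(seg)
                    next_open.append(seg)
            open_segs = next_open
        else:
            open_segs = []
            for s in curr:
                seg = [s]
                segments.append(seg)
                open_segs.append(seg)
        if curr:
            prev_frame = f
        elif prev_frame is not None and f > prev_frame:
            prev_frame = None  # an empty frame closes all segments
            open_segs = []
    segments.sort(key=lambda seg: (seg[0].frame, seg[0].x, seg[0].y))
    return segments


def close_gaps_and_merge(segments: list[list[Spot]],
                         params: LinkingParams) -> TrackGraph:
    """Join segments by gap closing and merging in one global assignment.

    Rows are segment ends; columns are (a) later segment starts within
    the gap gates and (b) mid-track spots of other segments in the
    frame right after the end (merge gate).  Costs are squared
    distances; each end and each target is used at most once.
    """
    tg = TrackGraph()
    sid_of: dict[tuple[int, int], int] = {}
    next_id = 0
    for si, seg in enumerate(segments):
        for k, spot in enumerate(seg):
            tg.add_spot(next_id, spot)
            sid_of[(si, k)] = next_id
            next_id += 1
        for k in range(len(seg) - 1):
            tg.add_edge(sid_of[(si, k)], sid_of[(si, k + 1)], "link")

    n_seg = len(segments)
    gap_gate2 = params.gap_max_dist**2
    merge_gate2 = params.merge_max_dist**2

    # merge-target candidates: mid-track spots one frame after some end
    end_frames = [seg[-1].frame for seg in segments]
    merge_cols: list[tuple[int, int]] = []  # (segment, spot index)
    wanted_frames = set(f + 1 for f in end_frames)
    for sj, seg in enumerate(segments):
        for k in range(1, len(seg)):
            if seg[k].frame in wanted_frames:
                merge_cols.append((sj, k))

    n_cols = n_seg + len(merge_cols)
    if n_seg and n_cols:
        cost = np.full((n_seg, n_cols), _BIG)
        for i, seg_i in enumerate(segments):
            end = seg_i[-1]
            for j, seg_j in enumerate(segments):
                if j == i:
                    continue
                dt = seg_j[0].frame - end.frame
                if 1 <= dt <= params.max_frame_gap:
                    d2 = (end.x - seg_j[0].x) ** 2 + (end.y - seg_j[0].y) ** 2
                    if d2 <= gap_gate2:
                        cost[i, j] = d2
            for c, (sj, k) in enumerate(merge_cols):
                if sj == i:
                    continue
                s = segments[sj][k]
                if s.frame != end.frame + 1:
                    continue
                d2 = (end.x - s.x) ** 2 + (end.y - s.y) ** 2
                if d2 <= merge_gate2:
                    cost[i, n_seg + c] = d2
        gate = max(gap_gate2, merge_gate2)
        for i, j in gated_assignment(cost, gate):
            end_id = sid_of[(i, len(segments[i]) - 1)]
            if j < n_seg:
                tg.add_edge(end_id, sid_of[(j, 0)], "gap")
            else:
                sj, k = merge_cols[j - n_seg]
                tg.add_edge(end_id, sid_of[(sj, k)], "merge")
    return tg


def filter_tracks(graph: TrackGraph, params: LinkingParams,
                  quality_threshold: float | None = None) -> TrackGraph:
    """Drop tracks below the minimum length or mean-quality threshold.

    Returns a new graph restricted to the surviving tracks; group
    membership is recomputed.
    """
    keep_ids: set[int] = set()
    for t in graph.tracks:
        if t.n_spots < params.min_track_len:
            continue
        if quality_threshold is not None and t.mean_quality < quality_threshold:
            continue
        keep_ids.update(t.spot_ids)
    out = TrackGraph()
    for sid in sorted(keep_ids):
        out.add_spot(sid, graph.spot(sid))
    for u, v, kind in graph.graph.edges(data="kind"):
        if u in keep_ids and v in keep_ids:
            out.add_edge(u, v, kind)
    return out


def track_spots(spots_by_frame, params: LinkingParams | None = None,
                quality_threshold="auto") -> TrackGraph:
    """Full tracking pass: link, close gaps / merge, filter.

    ``quality_threshold='auto'`` applies Otsu's threshold to the track
    mean qualities (after length filtering); a number applies that
    threshold; ``None`` disables quality filtering.
    """
    params = params or LinkingParams()
    segments = link_frames(spots_by_frame, params)
    graph = close_gaps_and_merge(segments, params)
    if quality_threshold == "auto":
        by_len = filter_tracks(graph, params, None)
        qualities = [t.mean_quality for t in by_len.tracks]
        if not qualities:
            return by_len
        thr = quality_auto_threshold(qualities)
        return filter_tracks(by_len, params, thr)
    return filter_tracks(graph, params, quality_threshold)
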