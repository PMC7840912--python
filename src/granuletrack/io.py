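"""File formats: TIFF movies, spot/track/event CSV tables, truth export.

All tables carry explicit units in their column names (``_um``,
``_s``, ``_um_per_min``).  Positions are micrometres in the image
coordinate frame: origin at the centre of the top-left pixel, x
rightward (columns), y downward (rows); frames are 0-based.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import Calibration, Movie
from .detect import Spot
from .kinematics import event_and_growth_maps
from .simulate import SyntheticMovie, config_to_dict
from .tracking import TrackGraph

log = logging.getLogger("granuletrack")

_FLOAT_FMT = "%.6f"

TRACK_COLUMNS = ["movie", "group_id", "track_id", "class", "is_complete",
                 "frame", "t_s", "x_um", "y_um", "quality", "fluo"]
EVENT_COLUMNS = ["kind", "frame", "x_um", "y_um", "track_id",
                 "target_track_id"]


def read_movie(path, calibration: Calibration | None = None) -> Movie:
    """Read a multi-page TIFF stack.

    The calibration comes from the supplied configuration; TIFF
    resolution tags are honoured as a consistency check only — a
    conflict above 1% logs a warning and the configuration wins.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"movie file not found: {path}")
    calibration = calibration or Calibration()
    try:
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            tag_pixel = _pixel_size_from_tags(tf)
    except ValueError:
        raise
    except Exception as exc:  # tifffile raises various types on corrupt input
        raise ValueError(f"could not read {path} as a TIFF movie: {exc}") from exc
    if stack.ndim == 2:
        raise ValueError(f"{path} holds a single frame, not a movie")
    if stack.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D time series, got shape "
                         f"{stack.shape}")
    if tag_pixel is not None and abs(tag_pixel - calibration.pixel_size) \
            > 0.01 * calibration.pixel_size:
        log.warning("%s: TIFF resolution tag (%.4f um/px) conflicts with the "
                    "configured pixel size (%.4f um/px); using the "
                    "configuration", path, tag_pixel, calibration.pixel_size)
    return Movie(stack=stack, calibration=calibration)


def _pixel_size_from_tags(tf: "tifffile.TiffFile") -> float | None:
    page = tf.pages[0]
    tag = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if tag is None:
        return None
    num, den = tag.value
    if num == 0:
        return None
    per_unit = num / den  # pixels per unit
    unit_um = {2: 25400.0, 3: 10000.0}.get(getattr(unit, "value", 2).real
                                           if unit else 2, None)
    if unit_um is None:
        return None
    return unit_um / per_unit


def write_movie(path, movie: Movie) -> None:
    """Write a 16-bit multi-page TIFF with resolution tags."""
    px_um = movie.calibration.pixel_size
    ppcm = 10000.0 / px_um  # pixels per centimetre
    tifffile.imwrite(path, movie.stack.astype(np.uint16),
                     photometric="minisblack",
                     resolution=(ppcm, ppcm), resolutionunit="CENTIMETER")


def write_synthetic(outdir, syn: SyntheticMovie, stem: str = "movie") -> dict:
    """Write a simulated movie: TIFF stack, ground-truth CSV, config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tiff": outdir / f"{stem}.tif",
        "truth": outdir / f"{stem}_truth.csv",
        "config": outdir / f"{stem}_config.yaml",
    }
    write_movie(paths["tiff"], Movie(syn.stack, syn.calibration))
    rows = []
    for g in syn.truth:
        for k in range(g.birth_frame, g.death_frame + 1):
            i = k - g.birth_frame
            rows.append((g.granule_id, k, g.positions[i, 0], g.positions[i, 1],
                         g.fluorescence[i],
                         "" if g.merged_into is None else g.merged_into))
    pd.DataFrame(rows, columns=["granule_id", "frame", "x_um", "y_um", "fluo",
                                "merged_into"]) \
        .to_csv(paths["truth"], index=False, float_format=_FLOAT_FMT)
    if syn.config is not None:
        paths["config"].write_text(
            yaml.safe_dump(config_to_dict(syn.config), sort_keys=True))
    return paths


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_spots(path, spots_by_frame: list[list[Spot]]) -> None:
    rows = [(s.frame, s.x, s.y, s.quality, s.fluorescence, s.radius)
            for frame_spots in spots_by_frame for s in frame_spots]
    pd.DataFrame(rows, columns=["frame", "x_um", "y_um", "quality", "fluo",
                                "radius_um"]) \
        .to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spots(path) -> list[list[Spot]]:
    df = pd.read_csv(path)
    required = {"frame", "x_um", "y_um", "quality", "fluo"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"spots table {path} is missing columns {sorted(missing)}")
    n_frames = int(df["frame"].max()) + 1 if len(df) else 0
    out: list[list[Spot]] = [[] for _ in range(n_frames)]
    for row in df.itertuples():
        out[int(row.frame)].append(Spot(
            frame=int(row.frame), x=float(row.x_um), y=float(row.y_um),
            quality=float(row.quality), fluorescence=float(row.fluo),
            radius=float(getattr(row, "radius_um", 0.5))))
    return out


def write_tracks(tracks_path, graph: TrackGraph,
                 frame_interval_s: float = 20.0, movie: str = "movie",
                 events_path=None) -> None:
    """Write the track table CSV (and optionally the events CSV).

    Track columns: movie, group_id, track_id, class, is_complete,
    frame, t_s, x_um, y_um, quality, fluo.  Events hold appearance,
    merge and disappearance positions; merge rows carry the receiving
    track in ``target_track_id``.
    """
    rows = []
    for t in graph.tracks:
        for s in t.spots:
            rows.append((movie, t.group_id, t.track_id, t.cls or "",
                         "" if t.is_complete is None else t.is_complete,
                         s.frame, s.frame * frame_interval_s, s.x, s.y,
                         s.quality, s.fluorescence))
    pd.DataFrame(rows, columns=TRACK_COLUMNS) \
        .to_csv(tracks_path, index=False, float_format=_FLOAT_FMT)
    if events_path is not None:
        events, _ = event_and_growth_maps(graph)
        spot_to_track = graph.track_of_spot()
        target = []
        merge_target_of: dict[tuple, int] = {}
        for u, v in graph.merge_edges():
            merge_target_of[(spot_to_track[u],
                             graph.spot(v).frame)] = spot_to_track[v]
        for row in events.itertuples():
            if row.kind == "merge":
                target.append(merge_target_of.get((row.track_id, row.frame), ""))
            else:
                target.append("")
        events = events.assign(target_track_id=target)
        events.to_csv(events_path, index=False, float_format=_FLOAT_FMT)


def read_tracks(tracks_path, events_path=None) -> TrackGraph:
    """Reconstruct a track graph from the track table (+ events) CSV.

    Consecutive spots of a track are joined by link edges (gap edges
    where frames jump); merge edges are restored from the events table
    when given.  Raises on missing columns or non-monotone frames.
    """
    df = pd.read_csv(tracks_path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"track table {tracks_path} is missing columns {sorted(missing)}")
    graph = TrackGraph()
    sid = 0
    last_spot_of_track: dict[int, int] = {}
    first_spot_of_track: dict[int, int] = {}
    spots_by_track_frame: dict[tuple[int, int], int] = {}
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_index()
        frames = sub["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise ValueError(
                f"track {tid} in {tracks_path} has non-monotone frames")
        prev = None
        for row in sub.itertuples():
            spot = Spot(frame=int(row.frame), x=float(row.x_um),
                        y=float(row.y_um), quality=float(row.quality),
                        fluorescence=float(row.fluo), radius=0.5)
            graph.add_spot(sid, spot)
            spots_by_track_frame[(int(tid), int(row.frame))] = sid
            if prev is not None:
                kind = "link" if int(row.frame) == graph.spot(prev).frame + 1 \
                    else "gap"
                graph.add_edge(prev, sid, kind)
            else:
                first_spot_of_track[int(tid)] = sid
            prev = sid
            sid += 1
        last_spot_of_track[int(tid)] = prev
    if events_path is not None:
        ev = pd.read_csv(events_path)
        for row in ev.itertuples():
            if row.kind != "merge" or pd.isna(row.target_track_id):
                continue
            src = last_spot_of_track.get(int(row.track_id))
            dst = spots_by_track_frame.get((int(row.target_track_id),
                                            int(row.frame)))
            if src is not None and dst is not None:
                graph.add_edge(src, dst, "merge")
    # carry over class / completeness annotations
    meta = df.drop_duplicates("track_id").set_index("track_id")
    for t in graph.tracks:
        # identify the original track id via its first spot
        key = None
        for tid, fsid in first_spot_of_track.items():
            if fsid == t.spot_ids[0]:
                key = tid
                break
        if key is not None and key in meta.index:
            cls = meta.loc[key, "class"]
            t.cls = None if pd.isna(cls) or cls == "" else str(cls)
            comp = meta.loc[key, "is_complete"]
            t.is_complete = None if pd.isna(comp) else bool(comp)
    return graph
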