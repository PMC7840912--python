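"""Overlay rendering: detection circles and colour-coded track paths.

Frames are converted to RGB and annotated with a circle per detected
granule and the track path of the last ``history`` frames, coloured by
a chosen per-track (or per-time-point) variable.  The colour range
spans the 2nd to 98th percentile of the variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib import colormaps
from skimage.draw import circle_perimeter, line

from .core import Movie
from .tracking import TrackGraph

VALID_COLOR_VARIABLES = ("local_track_speed", "advance_speed", "speed_ratio",
                         "merge_count", "alpha")


@dataclass
class OverlayStyle:
    color_variable: str = "local_track_speed"
    colormap: str = "viridis"
    history: int = 10   # only track paths of the last ten frames are drawn

    def __post_init__(self) -> None:
        if self.color_variable not in VALID_COLOR_VARIABLES:
            raise ValueError(
                f"unknown color variable {self.color_variable!r}; "
                f"valid choices: {', '.join(VALID_COLOR_VARIABLES)}")
        if self.history < 1:
            raise ValueError("history must be >= 1")


def _norm_stack(stack: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(stack, [2, 98])
    if hi <= lo:
        hi = lo + 1
    return np.clip((stack.astype(float) - lo) / (hi - lo), 0, 1)


def render_overlay(movie: Movie, graph: TrackGraph, values,
                   style: OverlayStyle | None = None) -> list[np.ndarray]:
    """Render RGB overlay frames.

    ``values`` maps the colour variable onto the tracks: either a
    mapping / Series keyed by track id (one colour per track) or a
    DataFrame with columns (track_id, frame, value) for per-time-point
    colouring.  An empty graph returns the plain grayscale frames as
    RGB.
    """
    style = style or OverlayStyle()
    px = movie.calibration.pixel_size
    gray = _norm_stack(movie.stack)
    cmap = colormaps[style.colormap]

    per_point = isinstance(values, pd.DataFrame)
    if per_point:
        missing = {"track_id", "frame", "value"} - set(values.columns)
        if missing:
            raise ValueError(f"per-point values need columns {sorted(missing)}")
        vals = values["value"].to_numpy(dtype=float)
        lookup = {(int(r.track_id), int(r.frame)): float(r.value)
                  for r in values.itertuples()}
    else:
        mapping = dict(values) if not isinstance(values, dict) else values
        vals = np.array(list(mapping.values()), dtype=float)
        lookup = {int(k): float(v) for k, v in mapping.items()}
    finite = vals[np.isfinite(vals)] if vals.size else np.array([0.0])
    if finite.size == 0:
        finite = np.array([0.0])
    lo, hi = np.percentile(finite, [2, 98])
    span = hi - lo if hi > lo else 1.0

    def colour(track_id: int, frame: int) -> tuple:
        v = lookup.get((track_id, frame)) if per_point else lookup.get(track_id)
        if v is None or not np.isfinite(v):
            return (1.0, 1.0, 0.0)  # unvalued tracks drawn in yellow
        return cmap(float(np.clip((v - lo) / span, 0, 1)))[:3]

    frames_rgb = []
    h, w = gray.shape[1:]
    for f in range(movie.n_frames):
        rgb = np.stack([gray[f]] * 3, axis=-1)
        for t in graph.tracks:
            frames = t.frames
            if frames[0] > f or frames[-1] < f:
                continue
            sel = (frames <= f) & (frames > f - style.history)
            pts = t.positions_um[sel] / px
            cols = np.rint(pts[:, 0]).astype(int)
            rows = np.rint(pts[:, 1]).astype(int)
            for k in range(len(rows) - 1):
                rr, cc = line(rows[k], cols[k], rows[k + 1], cols[k + 1])
                ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                rgb[rr[ok], cc[ok]] = colour(t.track_id, int(frames[sel][k + 1]))
            if frames[-1] >= f and sel.any():
                r0, c0 = rows[-1], cols[-1]
                radius = max(int(round(t.spots[0].radius / px)), 2)
                rr, cc = circle_perimeter(r0, c0, radius, shape=(h, w))
                rgb[rr, cc] = (1.0, 0.0, 1.0)  # magenta detection circle
        frames_rgb.append((rgb * 255).astype(np.uint8))
    return frames_rgb


def save_overlay_frames(frames: list[np.ndarray], outdir) -> list:
    """Write overlay frames as numbered PNGs; returns the paths."""
    import imageio.v3 as iio
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = outdir / f"overlay_{i:04d}.png"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths
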