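"""Shared containers: physical calibration, image stacks and bare trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of a recording.

    Parameters
    ----------
    pixel_size : float
        Lateral pixel size in micrometres per pixel.
    frame_interval : float
        Time between consecutive frames in seconds.
    """

    pixel_size: float = 0.077
    frame_interval: float = 20.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def frame_interval_min(self) -> float:
        return self.frame_interval / 60.0


@dataclass
class Movie:
    """A time-lapse image stack with its physical calibration.

    ``stack`` is a (frames, height, width) array of non-negative
    intensities.  Positions elsewhere in the package are expressed in
    micrometres with the origin at the centre of the top-left pixel,
    x increasing rightward (columns) and y downward (rows).
    """

    stack: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack)
        if self.stack.ndim != 3:
            raise ValueError("movie stack must be 3-D (frames, height, width)")
        if self.stack.shape[0] < 2:
            raise ValueError("a movie needs at least 2 frames")

    @property
    def n_frames(self) -> int:
        return int(self.stack.shape[0])

    @property
    def shape(self) -> tuple:
        return self.stack.shape


@dataclass
class TrackPath:
    """A bare trajectory: frame indices plus positions in micrometres.

    This is the minimal duck-typed interface the kinematics and MSD
    routines need (``frames``, ``positions_um`` and optionally
    ``fluorescence``); full tracks built by the tracker expose the
    same attributes.
    """

    frames: np.ndarray
    positions_um: np.ndarray
    fluorescence: np.ndarray | None = None
    track_id: int = -1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.positions_um.shape != (self.frames.size, 2):
            raise ValueError("positions_um must have shape (n_frames, 2)")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if self.fluorescence is not None:
            self.fluorescence = np.asarray(self.fluorescence, dtype=float)

    def __len__(self) -> int:
        return int(self.frames.size)

    @property
    def n_spots(self) -> int:
        return len(self)

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])
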