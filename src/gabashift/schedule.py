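"""PET acquisition frame schedules.

Dynamic emission data are binned into successive frames of increasing
duration; every frame-wise quantity in this package (time-activity curves,
model predictions, fit weights) is indexed against a :class:`FrameSchedule`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FrameSchedule", "make_frame_schedule"]


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous frame decomposition of a dynamic scan.

    Parameters
    ----------
    frame_start : array-like
        Frame start times in minutes; first frame must start at 0.
    frame_duration : array-like
        Frame durations in minutes; all strictly positive.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or dur.shape != start.shape:
            raise ValueError("frame_start and frame_duration must be 1-D and equal length")
        if start.size == 0:
            raise ValueError("empty schedule")
        if start[0] != 0.0:
            raise ValueError("first frame must start at t=0")
        if np.any(dur <= 0):
            raise ValueError("all frame durations must be positive")
        if not np.allclose(start[1:], start[:-1] + dur[:-1], rtol=0, atol=1e-9):
            raise ValueError("frames must be contiguous")

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def frame_mid(self) -> np.ndarray:
        return self.frame_start + 0.5 * self.frame_duration

    @property
    def total_duration(self) -> float:
        return float(self.frame_end[-1])


def make_frame_schedule() -> FrameSchedule:
    """The 19-frame, 90-minute dynamic acquisition schedule.

    Frame durations: 4 x 15 s, 3 x 1 min, 3 x 2 min, 2 x 5 min, 7 x 10 min.
    """
    durations = np.concatenate(
        [
            np.full(4, 0.25),
            np.full(3, 1.0),
            np.full(3, 2.0),
            np.full(2, 5.0),
            np.full(7, 10.0),
        ]
    )
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations)
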