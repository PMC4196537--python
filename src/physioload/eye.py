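"""Gap-based blink detection and eye features.

A blink is a maximal run of 60 Hz frames in which the tracker reports both
eyes invalid, lasting between 2 and 25 frames (33-416 ms).  Single invalid
frames are treated as tracking noise and runs longer than 25 frames as
tracking loss; neither counts as a blink.  Segment features are the mean
pupil diameter over frames with at least one valid eye, the blink rate per
minute, and the mean blink duration (missing when a segment has no blinks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BlinkEvent", "detect_blinks", "eye_metrics", "GAZE_FS"]

GAZE_FS = 60.0
MIN_FRAMES = 2
MAX_FRAMES = 25


@dataclass(frozen=True)
class BlinkEvent:
    start: int          # frame index
    length: int         # frames, 2..25

    @property
    def duration(self) -> float:
        return self.length / GAZE_FS


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, length)."""
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def detect_blinks(gaze: pd.DataFrame) -> list[BlinkEvent]:
    """Blinks from a gaze frame table with ``left_valid``/``right_valid`` flags."""
    invalid = (gaze["left_valid"].to_numpy() == 0) & (gaze["right_valid"].to_numpy() == 0)
    return [
        BlinkEvent(start, length)
        for start, length in _runs(invalid)
        if MIN_FRAMES <= length <= MAX_FRAMES
    ]


def eye_metrics(
    gaze: pd.DataFrame,
    blinks: list[BlinkEvent] | None = None,
    duration: float | None = None,
) -> tuple[float, float, float]:
    """``(mean pupil mm, blink rate per min, mean blink duration s)``.

    The pupil average uses, per frame, the mean of the valid eyes (both when
    both are valid); frames with no valid eye are excluded.  ``blinks``
    defaults to detection on the given frames; pass the precomputed
    session-level events when segmenting, so that a run straddling a segment
    boundary is counted once, in the segment containing its first frame.
    """
    if blinks is None:
        blinks = detect_blinks(gaze)
    if duration is None:
        duration = len(gaze) / GAZE_FS
    lv = gaze["left_valid"].to_numpy() == 1
    rv = gaze["right_valid"].to_numpy() == 1
    lp = gaze["left_pupil"].to_numpy(dtype=float)
    rp = gaze["right_pupil"].to_numpy(dtype=float)
    num = np.where(lv, lp, 0.0) + np.where(rv, rp, 0.0)
    den = lv.astype(int) + rv.astype(int)
    any_valid = den > 0
    if not any_valid.any():
        warnings.warn("no valid pupil frames in segment", stacklevel=2)
        mean_pupil = float("nan")
    else:
        mean_pupil = float((num[any_valid] / den[any_valid]).mean())
    rate = 60.0 * len(blinks) / duration
    mean_dur = float(np.mean([b.duration for b in blinks])) if blinks else float("nan")
    return mean_pupil, rate, mean_dur
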