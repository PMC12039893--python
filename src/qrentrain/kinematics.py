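"""From raw 2D keypoint tracks to per-segment displacement series.

The kinematic unit of analysis is a one-dimensional movement-magnitude
series: the Euclidean distance travelled by an articulator between
consecutive video frames, within one annotated question or response window.
Using scalar displacement rather than raw coordinates makes the series
comparable across speakers seated in different parts of the frame, and is
invariant to translation and rotation of the camera view.

Pose trackers drop or mistrack frames, so segments pass through a
confidence-gated repair step first: frames below a confidence threshold are
linearly interpolated from their nearest valid neighbours (edges held), and
segments with too large an invalid fraction are rejected outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    SegmentRangeError,
    TooShortSegmentError,
    TrackRejectedError,
    ValidationError,
)
from .io_formats import Keypoint, KeypointTrack, Segment

logger = logging.getLogger(__name__)

__all__ = [
    "DisplacementSeries",
    "frame_index",
    "slice_track",
    "repair_missing",
    "displacement",
    "smooth",
]


@dataclass
class DisplacementSeries:
    """Per-frame movement magnitude (pixels/frame) for one articulator."""

    values: np.ndarray
    segment_id: str
    keypoint: Keypoint

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValidationError("displacement series must be 1D, length >= 1")
        if (self.values < 0).any():
            raise ValidationError("displacement values must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


def frame_index(t_ms: int, frame_rate: float) -> int:
    """Map an annotation time (ms) onto a frame index: floor(t * fps / 1000)."""
    return int(np.floor(t_ms * frame_rate / 1000.0))


def slice_track(track: KeypointTrack, segment: Segment) -> KeypointTrack:
    """Extract the sub-track covering [onset, offset) of a segment.

    A 1,000 ms segment at 25 fps yields exactly 25 frames.  Segments shorter
    than two frames carry no displacement and are rejected.
    """
    start = frame_index(segment.onset, track.frame_rate)
    stop = frame_index(segment.offset, track.frame_rate)
    if start < 0 or stop > len(track):
        raise SegmentRangeError(
            f"segment {segment.segment_id!r} [{segment.onset}, "
            f"{segment.offset}) ms is outside the track span "
            f"({len(track)} frames at {track.frame_rate} fps)"
        )
    if stop - start < 2:
        raise TooShortSegmentError(
            f"segment {segment.segment_id!r} spans {stop - start} frame(s); "
            "at least 2 are required"
        )
    return replace(
        track,
        positions=track.positions[start:stop].copy(),
        confidence=track.confidence[start:stop].copy(),
    )


def repair_missing(
    track: KeypointTrack,
    conf_threshold: float = 0.3,
    max_missing_fraction: float = 0.5,
) -> KeypointTrack:
    """Interpolate low-confidence frames; reject tracks that are mostly gaps.

    Frames with confidence below ``conf_threshold`` (or missing positions)
    are filled by linear interpolation between the nearest valid frames;
    leading/trailing invalid frames are held at the nearest valid value.
    """
    if not 0.0 <= conf_threshold <= 1.0:
        raise ValidationError("conf_threshold must lie in [0, 1]")
    conf = track.confidence
    invalid = (conf < conf_threshold) | ~np.isfinite(track.positions).all(
        axis=1)
    n = len(track)
    if invalid.all():
        raise TrackRejectedError(
            f"{track.speaker_id}/{track.keypoint.value}: no valid frame"
        )
    frac = invalid.mean()
    if frac > max_missing_fraction:
        raise TrackRejectedError(
            f"{track.speaker_id}/{track.keypoint.value}: "
            f"{frac:.0%} of frames invalid (limit {max_missing_fraction:.0%})"
        )
    if not invalid.any():
        return track
    idx = np.arange(n)
    valid = ~invalid
    pos = track.positions.copy()
    for d in range(2):
        pos[invalid, d] = np.interp(idx[invalid], idx[valid], pos[valid, d])
    return replace(track, positions=pos)


def displacement(track: KeypointTrack,
                 segment_id: str = "") -> DisplacementSeries:
    """Frame-to-frame Euclidean displacement of an articulator.

    Requires a gap-free track (run :func:`repair_missing` first); output
    length is one less than the frame count.
    """
    if len(track) < 2:
        raise TooShortSegmentError("need at least 2 frames for displacement")
    if not np.isfinite(track.positions).all():
        raise ValidationError(
            "track has missing positions; run repair_missing first"
        )
    steps = np.diff(track.positions, axis=0)
    return DisplacementSeries(
        values=np.hypot(steps[:, 0], steps[:, 1]),
        segment_id=segment_id,
        keypoint=track.keypoint,
    )


def smooth(series: DisplacementSeries, window: int) -> DisplacementSeries:
    """Optional centred moving average (window 0 or 1 = off)."""
    if window <= 1:
        return series
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(series.values, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad:pad + len(series)]
    return replace(series, values=out)
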