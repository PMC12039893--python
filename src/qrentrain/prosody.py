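"""Fundamental-frequency (F0) estimation and question-response F0 mismatch.

Prosodic matching between a question and its response is measured as the
absolute difference of their F0 statistics, with F0 restricted to the
conversational band of 75-300 Hz.  Candidates outside the band are never
reported; segments with no voiced frame yield an undefined mean and the
pair is dropped from prosodic analyses (kinematic analyses are unaffected).

The tracker is a short-time normalized-autocorrelation pitch detector: each
analysis frame's best autocorrelation lag within the band gives a candidate
period (refined by parabolic interpolation), a frame is voiced when the
normalized peak exceeds a voicing threshold, and a sub-lag harmonic check
rejects frames whose true fundamental lies above the ceiling (e.g. a 400 Hz
tone must not surface as its 200 Hz subharmonic).

The per-segment statistic is the mean F0 over voiced frames by default; the
maximum is available behind the ``statistic`` switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import SegmentRangeError, ValidationError
from .io_formats import AudioClip, Segment

logger = logging.getLogger(__name__)

__all__ = ["PitchResult", "estimate_pitch", "segment_f0", "f0_mismatch"]

DEFAULT_FLOOR_HZ = 75.0
DEFAULT_CEILING_HZ = 300.0

# a sub-lag whose normalized autocorrelation reaches this fraction of the
# in-band peak marks the true (higher) fundamental
_HARMONIC_RATIO = 0.9


@dataclass
class PitchResult:
    """Per-segment pitch summary; ``mean_f0`` is None when nothing is voiced."""

    mean_f0: float | None
    voiced_frames: int
    contour: np.ndarray = field(default_factory=lambda: np.empty(0))
    floor: float = DEFAULT_FLOOR_HZ
    ceiling: float = DEFAULT_CEILING_HZ

    def __post_init__(self) -> None:
        self.contour = np.asarray(self.contour, dtype=float)
        if self.voiced_frames != len(self.contour):
            raise ValidationError("voiced_frames must match contour length")
        if self.contour.size and (
            (self.contour < self.floor).any()
            or (self.contour > self.ceiling).any()
        ):
            raise ValidationError("contour leaves the [floor, ceiling] band")
        if self.voiced_frames > 0 and self.mean_f0 is None:
            raise ValidationError("voiced frames present but mean undefined")

    @property
    def max_f0(self) -> float | None:
        return float(self.contour.max()) if self.voiced_frames else None


def _frame_f0(
    frame: np.ndarray,
    sample_rate: int,
    lag_min: int,
    lag_max: int,
    voicing_threshold: float,
    ceiling: float,
) -> float | None:
    """Best F0 candidate of one analysis frame, or None if unvoiced."""
    x = frame - frame.mean()
    energy = float(np.dot(x, x))
    if energy <= 0.0:
        return None
    n = len(x)
    # full autocorrelation via FFT, normalized per lag by the geometric mean
    # of the two overlapping-portion energies (normalized cross-correlation)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    r = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    sq = np.concatenate(([0.0], np.cumsum(x * x)))
    lags = np.arange(n)
    e_head = sq[n - lags] - sq[0]
    e_tail = sq[n] - sq[lags]
    denom = np.sqrt(e_head * e_tail)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, r / denom, 0.0)
    band = rho[lag_min:lag_max + 1]
    if band.size == 0:
        return None
    peak = float(band.max())
    if peak < voicing_threshold:
        return None
    # prefer the smallest lag (highest frequency) among near-maximal peaks
    near = np.flatnonzero(band >= peak - 0.01)
    lag = int(lag_min + near[0])
    # harmonic check: a comparably strong sub-lag means the real fundamental
    # sits at a multiple of the candidate frequency, possibly over the ceiling
    for k in (2, 3, 4):
        sub = int(round(lag / k))
        if sub >= 2 and rho[sub] >= _HARMONIC_RATIO * peak:
            if k * sample_rate / lag > ceiling:
                return None
            break
    # parabolic refinement of the peak location
    refined = float(lag)
    if 1 <= lag < n - 1:
        a, b, c = rho[lag - 1], rho[lag], rho[lag + 1]
        denom2 = a - 2 * b + c
        if denom2 < 0:
            refined = lag + 0.5 * (a - c) / denom2
    f0 = sample_rate / refined
    return f0


def estimate_pitch(
    clip: AudioClip,
    segment: Segment | None = None,
    floor: float = DEFAULT_FLOOR_HZ,
    ceiling: float = DEFAULT_CEILING_HZ,
    frame_step_ms: float = 10.0,
    voicing_threshold: float = 0.45,
) -> PitchResult:
    """Track F0 over a segment of a clip within [floor, ceiling].

    Analysis frames are ``3 / floor`` seconds long (three periods of the
    lowest admissible pitch) and advance by ``frame_step_ms``.
    """
    if clip.sample_rate < 2 * ceiling:
        raise ValidationError(
            f"sample rate {clip.sample_rate} Hz cannot represent the pitch "
            f"ceiling {ceiling} Hz"
        )
    sr = clip.sample_rate
    samples = clip.samples
    if segment is not None:
        i0 = int(round(segment.onset * sr / 1000.0))
        i1 = int(round(segment.offset * sr / 1000.0))
        if i0 < 0 or i1 > len(samples):
            raise SegmentRangeError(
                f"segment {segment.segment_id!r} lies outside the clip"
            )
        samples = samples[i0:i1]
    frame_len = int(round(3.0 * sr / floor))
    step = max(1, int(round(frame_step_ms * sr / 1000.0)))
    lag_min = max(2, int(np.floor(sr / ceiling)))
    lag_max = int(np.ceil(sr / floor))
    contour = []
    for start in range(0, len(samples) - frame_len + 1, step):
        f0 = _frame_f0(samples[start:start + frame_len], sr, lag_min,
                       min(lag_max, frame_len - 1), voicing_threshold,
                       ceiling)
        if f0 is not None and floor <= f0 <= ceiling:
            contour.append(f0)
    contour_arr = np.asarray(contour)
    mean = float(contour_arr.mean()) if contour else None
    if mean is None:
        logger.debug("no voiced frame in %s",
                     segment.segment_id if segment else "<clip>")
    return PitchResult(mean_f0=mean, voiced_frames=len(contour),
                       contour=contour_arr, floor=floor, ceiling=ceiling)


def segment_f0(result: PitchResult, statistic: str = "mean") -> float | None:
    """The segment-level F0 statistic (``mean`` by default, or ``max``)."""
    if statistic == "mean":
        return result.mean_f0
    if statistic == "max":
        return result.max_f0
    raise ValidationError(f"unknown F0 statistic {statistic!r}")


def f0_mismatch(
    q: PitchResult, r: PitchResult, statistic: str = "mean"
) -> float | None:
    """|F0(question) - F0(response)| in Hz; None when either is unvoiced.

    Lower mismatch means closer prosodic matching across the two turns.
    Pairs with an undefined side are excluded from prosodic analyses only.
    """
    fq, fr = segment_f0(q, statistic), segment_f0(r, statistic)
    if fq is None or fr is None:
        return None
    return abs(fq - fr)
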