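"""Readers and writers for the pipeline's external data formats.

Four kinds of input feed the analysis: turn annotations (delimited text
exported from an annotation tool), per-frame 2D keypoint tracks (an
OpenPose-style JSON directory or a flat CSV), mono PCM speech recordings
(WAV), and empathy-quotient questionnaire sheets (CSV).  Everything is
parsed into small frozen domain types; scored results round-trip through a
plain CSV with one row per (pair, condition).

All annotation times are integer milliseconds.  Frame index for a time t at
frame rate fps is ``floor(t * fps / 1000)``; at the corpus frame rate of
25 fps one frame equals the 40 ms time resolution of the annotations.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, fields
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel
from scipy.io import wavfile

from .errors import ConfigurationError, StructuralError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Role",
    "Keypoint",
    "Segment",
    "KeypointTrack",
    "AudioClip",
    "EQSheet",
    "AnnotationDialect",
    "read_annotations",
    "read_keypoints",
    "read_audio",
    "write_audio",
    "read_eq_sheets",
    "write_records",
    "read_records",
]


class Role(str, Enum):
    QUESTION = "question"
    RESPONSE = "response"


class Keypoint(str, Enum):
    NOSE = "nose"
    LEFT_HAND = "left_hand"
    RIGHT_HAND = "right_hand"


# OpenPose BODY_25 indices for the three articulators used here.
DEFAULT_OPENPOSE_INDEX_MAP = {
    Keypoint.NOSE: 0,
    Keypoint.RIGHT_HAND: 4,   # right wrist
    Keypoint.LEFT_HAND: 7,    # left wrist
}


@dataclass(frozen=True)
class Segment:
    """One annotated speech event (a question or a response)."""

    segment_id: str
    dyad_id: str
    speaker_id: str
    role: Role
    onset: int   # ms
    offset: int  # ms

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValidationError(
                f"segment {self.segment_id!r}: onset {self.onset} < 0"
            )
        if self.offset <= self.onset:
            raise ValidationError(
                f"segment {self.segment_id!r}: offset {self.offset} "
                f"must exceed onset {self.onset}"
            )
        object.__setattr__(self, "role", Role(self.role))

    @property
    def duration_ms(self) -> int:
        return self.offset - self.onset


@dataclass
class KeypointTrack:
    """Per-frame 2D positions of one articulator of one speaker.

    Missing detections carry confidence 0 and NaN positions.
    """

    speaker_id: str
    keypoint: Keypoint
    positions: np.ndarray        # (n_frames, 2) float, pixels; NaN = missing
    confidence: np.ndarray       # (n_frames,) float in [0, 1]
    frame_rate: float = 25.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        self.keypoint = Keypoint(self.keypoint)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValidationError("positions must have shape (n_frames, 2)")
        if len(self.confidence) != len(self.positions):
            raise ValidationError(
                "confidence and positions must have equal length "
                f"({len(self.confidence)} != {len(self.positions)})"
            )
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def duration_ms(self) -> float:
        return len(self) * 1000.0 / self.frame_rate


@dataclass
class AudioClip:
    """A mono audio recording of one speaker."""

    samples: np.ndarray
    sample_rate: int
    speaker_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValidationError("audio clip is empty")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")

    def __len__(self) -> int:
        return len(self.samples)


N_EQ_ITEMS = 60
N_EQ_TARGETS = 40


@dataclass
class EQSheet:
    """One respondent's empathy-quotient sheet: 60 items, 40 of them scored.

    ``item_scores`` holds per-item points in {0, 1, 2} with NaN for skipped
    items; ``item_is_target`` marks the 40 items that count toward the total.
    """

    participant_id: str
    item_scores: np.ndarray      # (60,) float; values in {0,1,2} or NaN
    item_is_target: np.ndarray   # (60,) bool, exactly 40 True

    def __post_init__(self) -> None:
        self.item_scores = np.asarray(self.item_scores, dtype=float)
        self.item_is_target = np.asarray(self.item_is_target, dtype=bool)
        if self.item_scores.shape != (N_EQ_ITEMS,):
            raise ValidationError(
                f"EQ sheet must have exactly {N_EQ_ITEMS} items"
            )
        if self.item_is_target.shape != (N_EQ_ITEMS,):
            raise ValidationError("target mask must cover all 60 items")
        if int(self.item_is_target.sum()) != N_EQ_TARGETS:
            raise ValidationError(
                f"target mask must mark exactly {N_EQ_TARGETS} items "
                f"(got {int(self.item_is_target.sum())})"
            )
        finite = self.item_scores[np.isfinite(self.item_scores)]
        if not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValidationError("EQ item scores must be 0, 1 or 2")


class AnnotationDialect(BaseModel):
    """Column naming for the exported annotation table."""

    dyad: str = "dyad"
    speaker: str = "speaker"
    role: str = "role"
    onset_ms: str = "onset_ms"
    offset_ms: str = "offset_ms"
    segment_id: str = "segment_id"
    sep: str = "\t"


def read_annotations(
    path: str | os.PathLike,
    dialect: AnnotationDialect | None = None,
) -> list[Segment]:
    """Parse an exported annotation table into Segments.

    Rows are returned sorted by (dyad_id, onset).  Segment durations are
    observed, not enforced: the corpus's own questions range from 99 ms to
    over 13 s and both extremes parse.
    """
    dialect = dialect or AnnotationDialect()
    df = pd.read_csv(path, sep=dialect.sep, dtype=str)
    required = [dialect.dyad, dialect.speaker, dialect.role,
                dialect.onset_ms, dialect.offset_ms]
    for col in required:
        if col not in df.columns:
            raise ConfigurationError(
                f"annotation file {path} is missing column {col!r}"
            )
    has_ids = dialect.segment_id in df.columns
    segments: list[Segment] = []
    for idx, row in df.iterrows():
        seg_id = row[dialect.segment_id] if has_ids else f"seg{idx:05d}"
        try:
            segments.append(
                Segment(
                    segment_id=str(seg_id),
                    dyad_id=str(row[dialect.dyad]),
                    speaker_id=str(row[dialect.speaker]),
                    role=Role(str(row[dialect.role]).strip().lower()),
                    onset=int(row[dialect.onset_ms]),
                    offset=int(row[dialect.offset_ms]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"annotation row {idx}: {exc}") from exc
    segments.sort(key=lambda s: (s.dyad_id, s.onset, s.segment_id))
    return segments


def _tracks_from_long_frame(
    df: pd.DataFrame, frame_rate: float
) -> list[KeypointTrack]:
    tracks: list[KeypointTrack] = []
    counts: dict[str, set[int]] = {}
    for (speaker, keypoint), grp in df.groupby(["speaker", "keypoint"],
                                               sort=True):
        grp = grp.sort_values("frame")
        n = int(grp["frame"].max()) + 1
        counts.setdefault(str(speaker), set()).add(n)
        pos = np.full((n, 2), np.nan)
        conf = np.zeros(n)
        idx = grp["frame"].to_numpy(dtype=int)
        pos[idx, 0] = grp["x"].to_numpy(dtype=float)
        pos[idx, 1] = grp["y"].to_numpy(dtype=float)
        conf[idx] = grp["confidence"].to_numpy(dtype=float)
        pos[conf <= 0.0] = np.nan
        tracks.append(
            KeypointTrack(
                speaker_id=str(speaker),
                keypoint=Keypoint(str(keypoint)),
                positions=pos,
                confidence=conf,
                frame_rate=frame_rate,
            )
        )
    for speaker, ns in counts.items():
        if len(ns) > 1:
            raise StructuralError(
                f"speaker {speaker!r}: keypoints disagree on frame count {ns}"
            )
    return tracks


def _tracks_from_openpose_dir(
    directory: Path,
    index_map: Mapping[Keypoint, int],
    frame_rate: float,
) -> list[KeypointTrack]:
    files = sorted(directory.glob("*.json"))
    if not files:
        raise StructuralError(f"no per-frame JSON files in {directory}")
    speaker = directory.name
    n = len(files)
    out = {
        kp: (np.full((n, 2), np.nan), np.zeros(n)) for kp in index_map
    }
    for i, f in enumerate(files):
        with open(f) as fh:
            payload = json.load(fh)
        people = payload.get("people", [])
        if not people:
            continue  # no detection: confidence stays 0, position missing
        kp_flat = np.asarray(people[0]["pose_keypoints_2d"], dtype=float)
        for kp, j in index_map.items():
            x, y, c = kp_flat[3 * j: 3 * j + 3]
            pos, conf = out[kp]
            conf[i] = c
            if c > 0:
                pos[i] = (x, y)
    return [
        KeypointTrack(speaker_id=speaker, keypoint=kp, positions=pos,
                      confidence=conf, frame_rate=frame_rate)
        for kp, (pos, conf) in out.items()
    ]


def read_keypoints(
    path_or_dir: str | os.PathLike,
    dialect: str = "flat_csv",
    index_map: Mapping[Keypoint, int] | None = None,
    frame_rate: float = 25.0,
) -> list[KeypointTrack]:
    """Read keypoint tracks from a flat CSV or an OpenPose JSON directory.

    ``flat_csv`` expects columns frame, speaker, keypoint, x, y, confidence.
    ``openpose_json_per_frame`` expects a directory of per-frame JSON files
    (body-25 layout, keypoints addressed via ``index_map``); the directory
    name is taken as the speaker id.
    """
    path = Path(path_or_dir)
    if dialect == "flat_csv":
        df = pd.read_csv(path)
        missing = {"frame", "speaker", "keypoint", "x", "y",
                   "confidence"} - set(df.columns)
        if missing:
            raise ConfigurationError(
                f"keypoint CSV {path} is missing columns {sorted(missing)}"
            )
        return _tracks_from_long_frame(df, frame_rate)
    if dialect == "openpose_json_per_frame":
        return _tracks_from_openpose_dir(
            path, index_map or DEFAULT_OPENPOSE_INDEX_MAP, frame_rate
        )
    raise ConfigurationError(f"unknown keypoint dialect {dialect!r}")


def read_audio(path: str | os.PathLike, speaker_id: str = "") -> AudioClip:
    """Read a PCM WAV file; stereo input keeps the first channel only."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise IOError(f"audio file {path} is missing or empty")
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        logger.warning("%s has %d channels; keeping the first",
                       path, data.shape[1])
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return AudioClip(samples=data.astype(float), sample_rate=int(rate),
                     speaker_id=speaker_id or path.stem)


def write_audio(clip: AudioClip, path: str | os.PathLike) -> None:
    """Write a clip as 16-bit PCM WAV."""
    scaled = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, int(clip.sample_rate),
                  (scaled * 32767.0).astype(np.int16))


def read_eq_sheets(
    scores_path: str | os.PathLike,
    key_path: str | os.PathLike,
) -> list[EQSheet]:
    """Read EQ sheets from a participant x item CSV plus an item key file.

    The scores file has one row per participant: a ``participant`` column
    followed by 60 item columns; blanks are skipped items.  The key file has
    columns ``item`` (1-based index) and ``is_target`` (0/1), marking the 40
    scored items.  The 0/1/2 scoring of raw options is assumed already
    applied upstream.
    """
    key = pd.read_csv(key_path)
    if not {"item", "is_target"} <= set(key.columns):
        raise ConfigurationError("EQ key file needs columns item,is_target")
    mask = np.zeros(N_EQ_ITEMS, dtype=bool)
    mask[key["item"].to_numpy(dtype=int) - 1] = key["is_target"].to_numpy(
        dtype=bool)
    df = pd.read_csv(scores_path)
    if "participant" not in df.columns:
        raise ConfigurationError("EQ scores file needs a participant column")
    item_cols = [c for c in df.columns if c != "participant"]
    if len(item_cols) != N_EQ_ITEMS:
        raise StructuralError(
            f"EQ scores file has {len(item_cols)} item columns, "
            f"expected {N_EQ_ITEMS}"
        )
    sheets = []
    for _, row in df.iterrows():
        sheets.append(
            EQSheet(
                participant_id=str(row["participant"]),
                item_scores=row[item_cols].to_numpy(dtype=float),
                item_is_target=mask.copy(),
            )
        )
    return sheets


RECORD_COLUMNS = [
    "pair_id", "dyad_id", "responder_id", "condition",
    "head_distance", "hand_distance", "f0_diff", "eq_diff",
]


def write_records(records, path: str | os.PathLike) -> None:
    """Write entrainment records as CSV, one row per (pair, condition).

    Accepts either a sequence of ``scoring.EntrainmentRecord`` or a
    DataFrame already carrying the record columns.  Missing measures (an
    unrecoverable articulator, an unvoiced segment) serialize as blanks.
    """
    if isinstance(records, pd.DataFrame):
        df = records.loc[:, RECORD_COLUMNS]
    else:
        records = list(records)
        if not records:
            raise ValidationError("no records to write")
        df = pd.DataFrame(
            [{f.name: getattr(r, f.name) for f in fields(r)}
             for r in records]
        ).loc[:, RECORD_COLUMNS]
    df.to_csv(path, index=False)


def read_records(path: str | os.PathLike) -> pd.DataFrame:
    """Companion reader for :func:`write_records`."""
    df = pd.read_csv(
        path,
        dtype={"pair_id": str, "dyad_id": str, "responder_id": str,
               "condition": str},
    )
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise StructuralError(f"records file lacks columns {sorted(missing)}")
    return df
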